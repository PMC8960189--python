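"""Single-term over-representation testing of motif-bearing protein sets.

Classic per-term analysis: for each annotation term, a one-sided Fisher
exact test (upper-tail hypergeometric) asks whether the study set
(e.g. all proteins with a G-motif) contains more term members than
expected from the population, followed by Benjamini-Hochberg control of
the false discovery rate across terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class AnnotationMap:
    """term -> set of annotated protein ids, with optional term metadata."""

    term_to_proteins: dict[str, set[str]]
    term_names: dict[str, str] = field(default_factory=dict)
    term_namespaces: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_tsv(cls, path: str | Path, metadata: str | Path | None = None) -> "AnnotationMap":
        """Load a two-column (protein_id, term_id) TSV; optional metadata
        TSV with columns term_id, name, namespace."""
        df = pd.read_csv(path, sep="\t", header=None, names=["protein_id", "term_id"],
                         dtype=str, comment="#")
        mapping: dict[str, set[str]] = {}
        for pid, term in zip(df["protein_id"], df["term_id"]):
            mapping.setdefault(term, set()).add(pid)
        names: dict[str, str] = {}
        namespaces: dict[str, str] = {}
        if metadata is not None:
            meta = pd.read_csv(metadata, sep="\t", dtype=str)
            for _, row in meta.iterrows():
                names[row["term_id"]] = row.get("name", "")
                namespaces[row["term_id"]] = row.get("namespace", "")
        return cls(mapping, names, namespaces)

    def collapse_isoforms(self, canonical: Mapping[str, str]) -> "AnnotationMap":
        """Map isoform ids onto canonical ids (user-supplied mapping);
        ids absent from the mapping pass through unchanged."""
        collapsed = {
            term: {canonical.get(p, p) for p in prots}
            for term, prots in self.term_to_proteins.items()
        }
        return AnnotationMap(collapsed, self.term_names, self.term_namespaces)


def fisher_enrich(
    study: Iterable[str],
    population: Iterable[str],
    annotations: AnnotationMap,
) -> pd.DataFrame:
    """One-sided Fisher exact test per term, BH-adjusted.

    For a term annotating K of the N population proteins, of which k
    fall in the n-protein study set, the p-value is the upper-tail
    hypergeometric probability P(X >= k).  Terms with no population
    member are dropped.  Results are sorted by adjusted p.
    """
    study_set = set(study)
    pop_set = set(population)
    if not pop_set:
        raise ValueError("empty population")
    stray = study_set - pop_set
    if stray:
        raise ValueError(
            f"study proteins not in population: {sorted(stray)[:10]}"
        )
    N, n = len(pop_set), len(study_set)
    rows = []
    for term, prots in annotations.term_to_proteins.items():
        members = prots & pop_set
        K = len(members)
        if K == 0:
            continue
        k = len(members & study_set)
        # P(X >= k) for X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "term_id": term,
                "name": annotations.term_names.get(term, ""),
                "study_hits": k,
                "study_size": n,
                "population_hits": K,
                "population_size": N,
                "p_value": min(p, 1.0),
            }
        )
    result = pd.DataFrame(
        rows,
        columns=[
            "term_id", "name", "study_hits", "study_size",
            "population_hits", "population_size", "p_value",
        ],
    )
    if len(result):
        result["p_adjusted"] = bh_adjust(result["p_value"].tolist())
        result = result.sort_values(
            ["p_adjusted", "p_value", "term_id"], kind="stable"
        ).reset_index(drop=True)
    else:
        result["p_adjusted"] = []
    return result


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order."""
    arr = np.asarray(pvalues, dtype=float)
    if arr.size == 0:
        return arr
    if np.any((arr <= 0) | (arr > 1)) or np.any(~np.isfinite(arr)):
        raise ValueError("p-values must lie in (0, 1]")
    _, adjusted, _, _ = multipletests(arr, method="fdr_bh")
    return adjusted
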