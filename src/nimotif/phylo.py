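"""Cross-species motif-density tables and tree-annotation export.

Builds the per-species filaggrin (or any protein family) table of
merged motif counts normalised per 100 residues, and serialises it as
an iTOL simple-bar annotation dataset whose labels are matched against
the leaves of a Newick species tree.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd

from .io import ProteinRecord
from .motifs import X_PATTERN, MotifPattern, find_motifs, motif_density


def species_density_table(
    records: Sequence[ProteinRecord],
    pattern: MotifPattern = X_PATTERN,
    orders: Mapping[str, str] | None = None,
    merge_mode: str = "chain",
) -> pd.DataFrame:
    """One row per record: species, merged motif count, density.

    ``orders`` optionally maps species label -> taxonomic order label
    (user-supplied metadata).  Rows with a missing species label are
    kept and flagged.  Sorted by density descending within order.
    """
    rows = []
    for rec in records:
        hits = find_motifs(rec, pattern, merge_mode=merge_mode)
        n = len(hits)
        species = rec.species or ""
        rows.append(
            {
                "species": species,
                "protein_id": rec.id,
                "protein_label": rec.description,
                "n_motifs": n,
                "seq_length": len(rec.sequence),
                "density": motif_density(n, len(rec.sequence)),
                "order": (orders or {}).get(species, ""),
                "missing_species": not bool(species),
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df = df.sort_values(
            ["order", "density"], ascending=[True, False], kind="stable"
        ).reset_index(drop=True)
    return df


def _fold(label: str) -> str:
    return label.strip().lower().replace("_", " ")


ITOL_HEADER = (
    "DATASET_SIMPLEBAR\n"
    "SEPARATOR COMMA\n"
    "DATASET_LABEL,Ni-hydrolytic motif density\n"
    "COLOR,#c0392b\n"
    "DATA\n"
)


def export_tree_bars(
    table: pd.DataFrame,
    tree_path: str | Path | None = None,
    value_column: str = "density",
) -> tuple[str, pd.DataFrame, list[str]]:
    """iTOL simple-bar dataset text for one value per species.

    When several rows share a species the maximum value is used (one
    bar per leaf).  If a Newick tree is given, labels are resolved
    against its leaves case-insensitively with underscore/space folding
    and unmatched species are reported (and excluded from the dataset).

    Returns ``(dataset_text, tsv_table, unmatched_species)``.
    """
    per_species = (
        table[table["species"] != ""]
        .groupby("species", sort=True)[value_column]
        .max()
        .reset_index()
    )
    unmatched: list[str] = []
    if tree_path is not None:
        tree = dendropy.Tree.get(
            path=str(tree_path), schema="newick", preserve_underscores=True
        )
        leaves = {
            _fold(leaf.taxon.label): leaf.taxon.label
            for leaf in tree.leaf_node_iter()
            if leaf.taxon is not None
        }
        resolved = []
        for _, row in per_species.iterrows():
            key = _fold(row["species"])
            if key in leaves:
                resolved.append({"species": leaves[key], value_column: row[value_column]})
            else:
                unmatched.append(row["species"])
        per_species = pd.DataFrame(resolved, columns=["species", value_column])
        if per_species.empty:
            raise ValueError("no species in the table match any tree leaf")
    lines = [
        f"{row['species']},{row[value_column]:g}"
        for _, row in per_species.iterrows()
    ]
    return ITOL_HEADER + "\n".join(lines) + "\n", per_species, unmatched


def parse_tree_bars(text: str) -> pd.DataFrame:
    """Re-import an exported simple-bar dataset (label, value rows)."""
    lines = text.splitlines()
    try:
        start = lines.index("DATA") + 1
    except ValueError as e:
        raise ValueError("no DATA block in dataset text") from e
    rows = []
    for line in lines[start:]:
        if not line.strip():
            continue
        label, _, value = line.rpartition(",")
        rows.append({"species": label, "value": float(value)})
    return pd.DataFrame(rows)
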