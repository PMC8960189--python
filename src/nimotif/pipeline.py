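"""End-to-end census and kinetics runs driven by a flat config.

``run_census`` executes read -> filter -> dedupe -> scan -> merge ->
count -> statistics (-> optional term enrichment) and writes every
intermediate table plus a summary JSON; ``run_kinetics`` batch-fits
time courses and titrations, collecting per-dataset failures without
aborting the run.  Outputs contain no timestamps, so a rerun on the
same inputs is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import census as census_mod
from . import io as pio
from .enrichment import AnnotationMap, fisher_enrich
from .kinetics import (
    FitError,
    KineticTimeCourse,
    fit_consecutive,
    fit_hill,
    rate_ratio,
)
from .motifs import G_PATTERN_TEXT, X_PATTERN_TEXT, MotifScanner, hits_table

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1


class PipelineError(RuntimeError):
    """A census stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Declarative configuration of a pipeline run.

    Defaults reproduce the published methodological choices: the two
    motif patterns, the "(Fragment)"/"Truncated" description filters,
    exact-duplicate removal, chain overlap merging, log2 enrichment and
    exact Poisson bands.
    """

    fasta: str = ""
    out_dir: str = "nimotif_out"
    x_pattern: str = X_PATTERN_TEXT
    g_pattern: str = G_PATTERN_TEXT
    exclude_words: tuple[str, ...] = pio.DEFAULT_EXCLUDE_WORDS
    dedupe_mode: str = "exact"  # "exact" | "none"
    merge_mode: str = "chain"
    enrichment_score: str = "log2_ratio"
    poisson_min_bin: int = 5
    poisson_persistence: int = 2
    poisson_exact_bands: bool = True
    annotations: str = ""  # optional protein->term TSV
    timecourses: tuple[str, ...] = ()
    titrations: tuple[str, ...] = ()
    condition_pairs: tuple[tuple[str, str], ...] = ()
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load a flat ``key = value`` config file (lists comma-split)."""
        kwargs: dict = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key in ("exclude_words", "timecourses", "titrations"):
                kwargs[key] = tuple(v.strip() for v in value.split(",") if v.strip())
            elif key == "condition_pairs":
                kwargs[key] = tuple(
                    tuple(p.strip().split(":")) for p in value.split(",") if p.strip()
                )
            elif key in ("poisson_min_bin", "poisson_persistence", "seed"):
                kwargs[key] = int(value)
            elif key == "poisson_exact_bands":
                kwargs[key] = value.lower() in ("1", "true", "yes")
            else:
                kwargs[key] = value
        return cls(**kwargs)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_census(
    config: RunConfig,
    records: Sequence[pio.ProteinRecord] | None = None,
) -> dict:
    """Full proteome census; returns the summary dict and writes reports.

    ``records`` may be passed directly (e.g. from the synthetic
    generator) instead of ``config.fasta``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"schema_version": SCHEMA_VERSION, "stages": {}}

    def stage(name: str, fn):
        try:
            result = fn()
        except Exception as e:
            raise PipelineError(f"stage {name!r} failed: {e}") from e
        return result

    if records is None:
        if not config.fasta:
            raise PipelineError("stage 'read' failed: no FASTA input configured")
        records = stage("read", lambda: pio.read_fasta(config.fasta))
        manifest["input_sha256"] = _sha256(Path(config.fasta))
    records = list(records)
    manifest["stages"]["read"] = len(records)

    records = stage(
        "filter", lambda: pio.filter_records(records, config.exclude_words)
    )
    manifest["stages"]["filter"] = len(records)
    if config.dedupe_mode == "exact":
        records = stage("dedupe", lambda: pio.dedupe(records))
    manifest["stages"]["dedupe"] = len(records)
    if not records:
        raise PipelineError("stage 'filter' failed: no records after filtering")

    scanner = MotifScanner(
        x_pattern=config.x_pattern,
        g_pattern=config.g_pattern,
        merge_mode=config.merge_mode,
    ).fit()
    census = stage("scan", lambda: scanner.transform(records))
    manifest["stages"]["scan"] = int(census["n_x_motifs"].sum())
    hits_table(scanner.hits()).to_csv(out / "hits.tsv", sep="\t", index=False)
    census.to_csv(out / "census.tsv", sep="\t", index=False)

    background = stage("background", lambda: pio.aa_frequencies(records))
    pio.frequencies_table(background).to_csv(
        out / "background.tsv", sep="\t", index=False
    )

    # X1 enrichment per S/T variant and combined
    x_hits = scanner.hits("X-motif")
    enrich_frames = []
    for variant in ("S", "T", "both"):
        try:
            obs = census_mod.x1_composition(x_hits, variant)
        except ValueError:
            continue
        tab = census_mod.x1_enrichment(obs, background, score=config.enrichment_score)
        tab.insert(0, "variant", variant)
        enrich_frames.append(tab)
    if enrich_frames:
        pd.concat(enrich_frames).to_csv(out / "enrichment.tsv", sep="\t", index=False)

    # Density CDFs with the glycine-corrected expectation
    cdf_x = census_mod.density_cdf(census["density_x"], label="X-motif")
    cdf_g = census_mod.density_cdf(census["density_g"], label="G-motif")
    cdf_exp = census_mod.expected_g_cdf(cdf_x, background.f_g)
    pd.concat([cdf_x.table(), cdf_g.table(), cdf_exp.table()]).to_csv(
        out / "cdf.tsv", sep="\t", index=False
    )

    # Poisson count model, per motif class
    poisson_summary = {}
    for label, col in (("x", "n_x_motifs"), ("g", "n_g_motifs")):
        det = census_mod.PoissonOutlierDetector(
            min_bin_count=config.poisson_min_bin,
            persistence=config.poisson_persistence,
            exact_bands=config.poisson_exact_bands,
        ).fit(census[col].to_numpy(), protein_ids=census["protein_id"].tolist())
        det.report_.to_csv(out / f"poisson_{label}.tsv", sep="\t", index=False)
        poisson_summary[label] = {
            "lambda": det.lambda_,
            "outlier_threshold": det.outlier_threshold_,
            "n_outliers": len(det.outlier_ids_),
            "outlier_ids": det.outlier_ids_[:200],
        }

    summary = {
        "schema_version": SCHEMA_VERSION,
        "n_proteins": len(records),
        **census_mod.motif_percentages(census),
        "median_density_x": cdf_x.median,
        "median_density_g": cdf_g.median,
        "f_g_background": background.f_g,
        "poisson": poisson_summary,
        "manifest": manifest,
    }

    if config.annotations:
        ann = AnnotationMap.from_tsv(config.annotations)
        study = census.loc[census["n_g_motifs"] >= 1, "protein_id"].tolist()
        population = census["protein_id"].tolist()
        res = stage("go", lambda: fisher_enrich(study, population, ann))
        res.to_csv(out / "go_enrichment.tsv", sep="\t", index=False)
        summary["go_significant_005"] = int((res["p_adjusted"] <= 0.05).sum())

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


def run_kinetics(config: RunConfig) -> dict:
    """Batch kinetics/titration fitting with per-dataset fault isolation.

    Returns a report dict; ``report["failed"]`` lists datasets that
    errored.  Exit-code semantics (0 ok / 1 partial) are applied by the
    command-line layer.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "schema_version": SCHEMA_VERSION,
        "timecourses": {},
        "titrations": {},
        "rate_ratios": {},
        "failed": [],
    }
    fits: dict[str, object] = {}
    for path in config.timecourses:
        name = Path(path).stem
        try:
            df = pd.read_csv(path)
            conditions = (
                sorted(df["condition"].unique()) if "condition" in df else [""]
            )
            for cond in conditions:
                tc = KineticTimeCourse.from_frame(df, condition=cond)
                fit = fit_consecutive(tc)
                key = f"{name}:{cond}" if cond else name
                fits[cond or name] = fit
                report["timecourses"][key] = fit.summary()
        except (FitError, OSError, KeyError, ValueError) as e:
            report["failed"].append({"dataset": path, "error": str(e)})
    for a, b in config.condition_pairs:
        if a in fits and b in fits:
            r, se = rate_ratio(fits[a], fits[b])
            report["rate_ratios"][f"{a}/{b}"] = {"ratio": r, "se": se}
    for path in config.titrations:
        name = Path(path).stem
        try:
            df = pd.read_csv(path)
            fit = fit_hill(df)
            report["titrations"][name] = fit.summary()
        except (FitError, OSError, KeyError, ValueError) as e:
            report["failed"].append({"dataset": path, "error": str(e)})
    with open(out / "kinetics_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
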