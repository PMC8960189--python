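"""Seeded synthetic-data generators for every pipeline stage.

Each generator is a pure function of its parameters and seed (identical
calls reproduce byte-identical output) and returns its ground truth
alongside the data, so recovery tests close the loop without any
external downloads.

The proteome generator draws i.i.d. residues at background frequencies
(default: a human-proteome-like composition with 7.07% glycine), spikes
Poisson-distributed motif occurrences at uniform non-overlapping
positions, and optionally appends a block of repeat-protein-like
outliers carrying a fixed large number of motifs — the structure the
Poisson census assumes plus the deviation it must detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .enrichment import AnnotationMap
from .io import CANONICAL_AA, ProteinRecord
from .kinetics import KineticTimeCourse, consecutive_model, hill_model
from .motifs import (
    G_PATTERN,
    X_PATTERN,
    MotifPattern,
    _Kind,
    find_motifs,
)

#: Human-proteome-like background composition (UniProt-style averages),
#: with glycine pinned at 7.07% and the rest renormalised.
_RAW_COMPOSITION = {
    "A": 7.01, "R": 5.64, "N": 3.59, "D": 4.74, "C": 2.30,
    "E": 7.09, "Q": 4.77, "G": 7.07, "H": 2.63, "I": 4.34,
    "L": 9.96, "K": 5.73, "M": 2.13, "F": 3.65, "P": 6.31,
    "S": 8.33, "T": 5.36, "W": 1.22, "Y": 2.66, "V": 5.96,
}
_total = sum(_RAW_COMPOSITION.values())
DEFAULT_BACKGROUND: dict[str, float] = {
    aa: v / _total for aa, v in _RAW_COMPOSITION.items()
}


@dataclass
class SyntheticProteomeSpec:
    """Parameters of a synthetic proteome.

    ``length`` is either a fixed integer or ``("lognormal", mean_log,
    sigma_log)`` (default: median ~375 residues, a typical proteome
    length scale).  ``lambda_spike`` is the Poisson mean of planted
    motifs per protein; ``spike_pattern`` selects whether spikes satisfy
    the general X-motif or the glycine-restricted G-motif.
    ``n_outliers`` proteins with ``outlier_motifs`` planted motifs each
    are appended after the background block.
    """

    n_proteins: int = 1000
    length: int | tuple = ("lognormal", 5.93, 0.6)
    background: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BACKGROUND)
    )
    lambda_spike: float = 0.5
    spike_pattern: str = "X"
    motif_template: str | None = None
    n_outliers: int = 0
    outlier_motifs: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.background.values())
        if abs(total - 1.0) > 1e-9:
            self.background = {k: v / total for k, v in self.background.items()}
        if self.lambda_spike < 0:
            raise ValueError("lambda_spike must be >= 0")
        if self.spike_pattern not in ("X", "G"):
            raise ValueError("spike_pattern must be 'X' or 'G'")


def _sample_motif(rng: np.random.Generator, pattern: MotifPattern) -> str:
    """One 6-mer drawn uniformly from each position's satisfying set."""
    out = []
    for pos in pattern.positions:
        if pos.kind is _Kind.ANY:
            choices = CANONICAL_AA
        elif pos.kind is _Kind.ALLOWED:
            choices = "".join(sorted(pos.residues))
        else:
            choices = "".join(c for c in CANONICAL_AA if c not in pos.residues)
        out.append(choices[rng.integers(len(choices))])
    return "".join(out)


def _place_nonoverlapping(
    rng: np.random.Generator, seq_len: int, n: int, motif_len: int, pid: str
) -> list[int]:
    """Uniform non-overlapping 0-based insertion offsets, or error."""
    if n * motif_len > seq_len:
        raise ValueError(
            f"protein {pid}: {n} motifs of length {motif_len} do not fit "
            f"in {seq_len} residues"
        )
    placed: list[int] = []
    tries = 0
    while len(placed) < n:
        tries += 1
        if tries > 2000 * n:
            raise ValueError(
                f"protein {pid}: could not place {n} non-overlapping motifs "
                f"in {seq_len} residues"
            )
        s = int(rng.integers(0, seq_len - motif_len + 1))
        if all(abs(s - q) >= motif_len for q in placed):
            placed.append(s)
    return sorted(placed)


def gen_proteome(
    spec: SyntheticProteomeSpec,
) -> tuple[list[ProteinRecord], pd.DataFrame]:
    """Generate a spiked proteome and its ground-truth table.

    The truth table has one row per protein: planted motif count and
    insertion sites, plus scanned-truth counts (merged X- and G-motif
    hits found by the scanner, which include chance motifs arising from
    the background).
    """
    rng = np.random.default_rng(spec.seed)
    residues = np.array(list(spec.background.keys()))
    probs = np.array(list(spec.background.values()))
    pattern = X_PATTERN if spec.spike_pattern == "X" else G_PATTERN
    L = pattern.length

    records: list[ProteinRecord] = []
    rows: list[dict] = []

    def lengths(n: int, floor: int = L) -> np.ndarray:
        if isinstance(spec.length, int):
            return np.full(n, max(spec.length, floor))
        tag, mu, sigma = spec.length
        if tag != "lognormal":
            raise ValueError(f"unknown length distribution {tag!r}")
        draw = np.maximum(rng.lognormal(mu, sigma, size=n).astype(int), floor)
        return draw

    n_bg = spec.n_proteins
    bg_lengths = lengths(n_bg)
    bg_spikes = rng.poisson(spec.lambda_spike, size=n_bg)

    def build(pid: str, seq_len: int, n_spike: int) -> None:
        seq = rng.choice(residues, size=seq_len, p=probs)
        sites = _place_nonoverlapping(rng, seq_len, n_spike, L, pid)
        for s in sites:
            motif = spec.motif_template or _sample_motif(rng, pattern)
            seq[s : s + L] = list(motif)
        rec = ProteinRecord(id=pid, description="synthetic", sequence="".join(seq))
        x_hits = find_motifs(rec, X_PATTERN)
        g_hits = find_motifs(rec, G_PATTERN)
        records.append(rec)
        rows.append(
            {
                "protein_id": pid,
                "length": seq_len,
                "n_planted": n_spike,
                "planted_sites": ",".join(str(s + 1) for s in sites),
                "n_x_scanned": len(x_hits),
                "n_g_scanned": len(g_hits),
                "is_outlier": pid.startswith("SYNOUT"),
            }
        )

    for i in range(n_bg):
        # guarantee capacity for the drawn spike count
        seq_len = int(max(bg_lengths[i], bg_spikes[i] * (L + 2)))
        build(f"SYN{i:06d}", seq_len, int(bg_spikes[i]))

    for j in range(spec.n_outliers):
        seq_len = int(max(lengths(1)[0], spec.outlier_motifs * (L + 4)))
        build(f"SYNOUT{j:04d}", seq_len, spec.outlier_motifs)

    return records, pd.DataFrame(rows)


def gen_timecourse(
    k1: float,
    k2: float,
    A0: float = 1.0,
    times: Sequence[float] | None = None,
    sigma: float = 0.01,
    seed: int = 0,
    condition: str = "synthetic",
) -> tuple[KineticTimeCourse, dict]:
    """Noisy consecutive-first-order time course plus its truth record.

    Gaussian noise of sd ``sigma`` is added independently per species
    and the result clipped to [0, 1.05] (a molar fraction measured by
    peak integration cannot stray far outside [0, 1]).
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if times is None:
        # 15 points out to ~4 half-lives of the slower step
        times = np.linspace(0.0, 4.0 * np.log(2) / min(k1, k2), 15)
    t = np.asarray(times, dtype=float)
    A, B, C = consecutive_model(t, k1, k2, A0)
    rng = np.random.default_rng(seed)
    frac = {}
    for name, y in (("substrate", A), ("intermediate", B), ("product", C)):
        noisy = y + rng.normal(0.0, sigma, size=t.size) if sigma > 0 else y.copy()
        frac[name] = np.clip(noisy, 0.0, 1.05)
    tc = KineticTimeCourse(times=t, fractions=frac, condition=condition)
    truth = {"k1": k1, "k2": k2, "A0": A0, "sigma": sigma, "seed": seed}
    return tc, truth


def gen_titration(
    pKa: float,
    n_hill: float = 1.0,
    A_min: float = 0.0,
    A_max: float = 1.0,
    pH_grid: Sequence[float] | None = None,
    sigma: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Noisy sigmoidal titration table (columns pH, signal) plus truth.

    The default grid spans pH 3-11.5 in 0.25 steps, the range scanned
    in complexometric titrations; it must bracket the pKa.
    """
    if pH_grid is None:
        pH_grid = np.arange(3.0, 11.51, 0.25)
    pH = np.asarray(pH_grid, dtype=float)
    if not (pH.min() < pKa < pH.max()):
        raise ValueError("pH grid must span the pKa")
    signal = hill_model(pH, pKa, n_hill, A_min, A_max)
    rng = np.random.default_rng(seed)
    if sigma > 0:
        signal = signal + rng.normal(0.0, sigma, size=pH.size)
    table = pd.DataFrame({"pH": pH, "signal": signal})
    truth = {
        "pKa": pKa, "n_hill": n_hill, "A_min": A_min, "A_max": A_max,
        "sigma": sigma, "seed": seed,
    }
    return table, truth


def gen_annotations(
    population_ids: Sequence[str],
    n_terms: int = 50,
    base_rate: float = 0.05,
    study_ids: Sequence[str] | None = None,
    enriched_term: str = "TERM_ENRICHED",
    odds: float = 1.0,
    seed: int = 0,
) -> tuple[AnnotationMap, dict]:
    """Random term annotations with one optionally enriched term.

    Every term annotates each population protein independently at
    ``base_rate``.  For ``enriched_term`` the membership probability of
    study proteins is raised so the study/population odds ratio equals
    ``odds`` (``odds=1`` is the null).  The truth record names the
    enriched term and its probabilities.
    """
    if odds < 1:
        raise ValueError("odds must be >= 1")
    rng = np.random.default_rng(seed)
    pop = list(population_ids)
    study = set(study_ids or [])
    p_base = base_rate
    p_study = odds * p_base / (1 - p_base + odds * p_base)
    mapping: dict[str, set[str]] = {}
    for i in range(n_terms):
        term = f"TERM_{i:04d}"
        members = {pid for pid in pop if rng.random() < p_base}
        if members:
            mapping[term] = members
    members = set()
    for pid in pop:
        p = p_study if (pid in study and odds > 1) else p_base
        if rng.random() < p:
            members.add(pid)
    mapping[enriched_term] = members
    truth = {
        "enriched_term": enriched_term,
        "odds": odds,
        "p_base": p_base,
        "p_study": p_study,
    }
    return AnnotationMap(mapping), truth
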