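"""Proteome-level statistics of the motif census.

Three analyses run downstream of the scanner:

* X1 composition and enrichment — which residues precede the cleaved
  S/T more often than their whole-proteome abundance predicts
  (score = log2 observed/background).
* Empirical CDFs of motif density (motifs per 100 residues), including
  the expected G-motif CDF obtained by scaling the X-motif densities by
  the glycine background fraction: if X1 were drawn at random, a
  fraction f_G of X-motifs would be G-motifs.
* A Poisson model of per-protein motif counts.  Under the
  no-correlation assumption the count histogram follows n*P(k; lambda);
  proteins whose counts persistently exceed the 95% band of that
  expectation (filaggrin-like repeat proteins) are flagged as outliers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .io import CANONICAL_AA, BackgroundFrequencies
from .motifs import MotifHit

NEG_INF = float("-inf")


# ---------------------------------------------------------------------------
# X1 composition and enrichment


def x1_composition(hits: Sequence[MotifHit], variant: str = "both") -> dict[str, float]:
    """Fraction of each canonical residue at X1 among hits of a variant.

    ``variant`` is ``"S"``, ``"T"`` or ``"both"``; hits are
    hit-weighted (each merged hit contributes once, via its first
    window's X1 residue).
    """
    if variant not in ("S", "T", "both"):
        raise ValueError(f"variant must be 'S', 'T' or 'both', got {variant!r}")
    selected = [
        h for h in hits if variant == "both" or h.st_residue == variant
    ]
    if not selected:
        raise ValueError(f"empty variant: no hits with S/T = {variant!r}")
    counts = {aa: 0 for aa in CANONICAL_AA}
    n = 0
    for h in selected:
        if h.x1_residue in counts:
            counts[h.x1_residue] += 1
            n += 1
    if n == 0:
        raise ValueError("no canonical X1 residues among selected hits")
    return {aa: c / n for aa, c in counts.items()}


def x1_enrichment(
    observed: Mapping[str, float],
    background: BackgroundFrequencies,
    score: str = "log2_ratio",
) -> pd.DataFrame:
    """Per-residue enrichment of the X1 position over background.

    ``score="log2_ratio"`` gives log2(observed/background); residues
    never observed get a -inf sentinel and ``absent=True``.
    ``score="difference"`` gives observed - background.
    """
    if score not in ("log2_ratio", "difference"):
        raise ValueError(f"unknown score mode {score!r}")
    rows = []
    for aa in CANONICAL_AA:
        obs = observed.get(aa, 0.0)
        bg = background[aa]
        if obs > 0 and bg == 0:
            raise ValueError(f"residue {aa}: observed > 0 but background 0")
        if score == "difference":
            s = obs - bg
            absent = False
        elif obs == 0:
            s, absent = NEG_INF, True
        else:
            s, absent = float(np.log2(obs / bg)), False
        rows.append(
            {"residue": aa, "observed": obs, "background": bg, "score": s, "absent": absent}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Density CDFs


@dataclass(frozen=True)
class DensityCDF:
    """Empirical CDF of per-protein motif densities.

    Each protein contributes one step of height 1/n at its density;
    ties stack.  ``densities`` is sorted ascending.
    """

    densities: np.ndarray
    label: str = ""

    @property
    def n(self) -> int:
        return len(self.densities)

    @property
    def median(self) -> float:
        return float(np.median(self.densities))

    def evaluate(self, x: np.ndarray | float) -> np.ndarray | float:
        """F(x) = fraction of proteins with density <= x."""
        return np.searchsorted(self.densities, x, side="right") / self.n

    def table(self) -> pd.DataFrame:
        frac = np.arange(1, self.n + 1) / self.n
        return pd.DataFrame(
            {"density": self.densities, "cumulative_fraction": frac, "label": self.label}
        )


def density_cdf(densities: Sequence[float], label: str = "") -> DensityCDF:
    """Build the empirical CDF with equal steps 1/n at sorted densities."""
    arr = np.sort(np.asarray(densities, dtype=float))
    if arr.size == 0:
        raise ValueError("density_cdf: empty input")
    return DensityCDF(arr, label=label)


def expected_g_cdf(x_cdf: DensityCDF, f_g: float) -> DensityCDF:
    """Expected G-motif CDF from the X-motif CDF under random X1.

    Scales every X-motif density by the glycine background fraction
    ``f_g``; step heights are unchanged, so quantiles (and the median)
    scale by the same factor.
    """
    if not 0 < f_g <= 1:
        raise ValueError("f_g must be in (0, 1]")
    return DensityCDF(x_cdf.densities * f_g, label=f"{x_cdf.label or 'X'}-expected-G")


# ---------------------------------------------------------------------------
# Poisson model of per-protein counts


def fit_poisson(counts: Sequence[int], min_bin_count: int | None = 5) -> float:
    """Maximum-likelihood Poisson rate over the central histogram portion.

    The MLE for a Poisson sample is the mean.  Proteome count
    histograms have heavy repeat-protein tails, so by default the mean
    is taken over the central portion of the histogram: the contiguous
    run of count values, containing the modal bin, whose bins each hold
    at least ``min_bin_count`` observations.  An isolated well-populated
    tail bin (a block of repeat proteins) therefore does not enter the
    fit.  ``min_bin_count=None`` uses all counts.
    """
    arr = np.asarray(counts, dtype=int)
    if arr.size == 0:
        raise ValueError("fit_poisson: empty input")
    if np.any(arr < 0):
        raise ValueError("fit_poisson: negative counts")
    if min_bin_count is None:
        return float(arr.mean())
    ks, freqs = np.unique(arr, return_counts=True)
    keep = freqs >= min_bin_count
    if not keep.any():
        return float(arr.mean())
    mode_idx = int(np.argmax(freqs))
    # expand the contiguous (in k) kept run around the modal bin
    lo = mode_idx
    while lo > 0 and keep[lo - 1] and ks[lo - 1] == ks[lo] - 1:
        lo -= 1
    hi = mode_idx
    while hi + 1 < len(ks) and keep[hi + 1] and ks[hi + 1] == ks[hi] + 1:
        hi += 1
    central = ks[lo : hi + 1]
    sel = np.isin(arr, central)
    return float(arr[sel].mean())


def poisson_expected_with_bands(
    lam: float,
    n: int,
    k_max: int,
    exact: bool = True,
) -> pd.DataFrame:
    """Expected histogram n*P(k; lambda) with central 95% bands per bin.

    Per bin the observed count is itself modelled as Poisson with mean
    equal to the expectation; bands are its exact 2.5/97.5% quantiles,
    or the normal approximation ``n_e +- 1.96 sqrt(n_e)`` when
    ``exact=False`` (floored at 0).
    """
    if lam < 0 or n < 1:
        raise ValueError("require lambda >= 0 and n >= 1")
    k = np.arange(k_max + 1)
    expected = n * stats.poisson.pmf(k, lam)
    if exact:
        low = stats.poisson.ppf(0.025, expected)
        high = stats.poisson.ppf(0.975, expected)
        # ppf of mu=0 returns nan/-1 conventions; degenerate bin -> [0, 0]
        low = np.where(expected > 0, low, 0.0)
        high = np.where(expected > 0, high, 0.0)
        # discrete quantiles can fall below a fractional expectation in
        # sparse bins; the band must always bracket the expectation
        low = np.minimum(low, expected)
        high = np.maximum(high, expected)
    else:
        half = 1.96 * np.sqrt(expected)
        low = np.maximum(expected - half, 0.0)
        high = expected + half
    return pd.DataFrame(
        {"k": k, "expected": expected, "band_low": low, "band_high": high}
    )


def observed_histogram(counts: Sequence[int], k_max: int | None = None) -> pd.DataFrame:
    arr = np.asarray(counts, dtype=int)
    if k_max is None:
        k_max = int(arr.max(initial=0))
    k = np.arange(k_max + 1)
    obs = np.bincount(arr, minlength=k_max + 1)[: k_max + 1]
    return pd.DataFrame({"k": k, "observed": obs})


def flag_outliers(
    observed: pd.DataFrame,
    bands: pd.DataFrame,
    counts_by_protein: Mapping[str, int] | None = None,
    persistence: int = 2,
) -> tuple[int | None, list[str]]:
    """Smallest count beyond which bins persistently exceed the 95% band.

    Empty bins are ignored (a repeat-protein tail is sparse).  The
    outlier region is the longest suffix of occupied bins that *all*
    exceed band_high; it is accepted only when it is persistent — at
    least ``persistence`` occupied bins, or a total excess over the
    upper bands of at least ``persistence`` proteins — so a single bin
    marginally above its band is never flagged, while a block of
    repeat proteins piled far in the tail is.  Proteins with count >=
    the threshold are returned.
    """
    merged = observed.merge(bands, on="k", how="left")
    occupied = merged[merged["observed"] > 0].reset_index(drop=True)
    exceed = (occupied["observed"] > occupied["band_high"]).to_numpy()
    threshold: int | None = None
    if len(occupied) and exceed[-1]:
        i = len(occupied) - 1
        while i > 0 and exceed[i - 1]:
            i -= 1
        suffix = occupied.iloc[i:]
        excess = float((suffix["observed"] - suffix["band_high"]).sum())
        if len(suffix) >= persistence or excess >= persistence:
            threshold = int(suffix["k"].iloc[0])
    if threshold is None:
        return None, []
    if counts_by_protein is None:
        return threshold, []
    ids = sorted(
        pid for pid, c in counts_by_protein.items() if c >= threshold
    )
    return threshold, ids


class PoissonOutlierDetector(BaseEstimator):
    """Poisson count model with band-based outlier flagging.

    Fits lambda on the central histogram portion, computes the expected
    histogram with 95% bands, and flags proteins whose motif counts
    persistently exceed the upper band — a scikit-learn style estimator
    (``fit`` on counts, then ``predict`` labels outliers as -1).

    Parameters
    ----------
    min_bin_count : int or None
        Histogram bins with fewer observations are excluded from the
        rate fit (None fits on everything).
    persistence : int
        Consecutive occupied exceeding bins required to open the
        outlier region.
    exact_bands : bool
        Exact Poisson quantile bands (default) vs normal approximation.

    Attributes
    ----------
    lambda_ : float
        Fitted mean motifs per protein.
    report_ : pandas.DataFrame
        Per-k observed/expected/band table.
    outlier_threshold_ : int or None
        Smallest flagged count.
    outlier_ids_ : list of str
        Protein ids at or above the threshold (when ids were supplied).
    """

    def __init__(
        self,
        min_bin_count: int | None = 5,
        persistence: int = 2,
        exact_bands: bool = True,
    ):
        self.min_bin_count = min_bin_count
        self.persistence = persistence
        self.exact_bands = exact_bands

    def fit(self, X: Sequence[int], y=None, protein_ids: Sequence[str] | None = None):
        counts = np.asarray(X, dtype=int).ravel()
        self.n_ = len(counts)
        self.lambda_ = fit_poisson(counts, self.min_bin_count)
        k_max = int(counts.max(initial=0))
        obs = observed_histogram(counts, k_max)
        bands = poisson_expected_with_bands(
            self.lambda_, self.n_, k_max, exact=self.exact_bands
        )
        self.report_ = obs.merge(bands, on="k")
        by_id = (
            dict(zip(protein_ids, counts)) if protein_ids is not None else None
        )
        self.outlier_threshold_, self.outlier_ids_ = flag_outliers(
            obs, bands, by_id, persistence=self.persistence
        )
        return self

    def predict(self, X: Sequence[int]) -> np.ndarray:
        """-1 for counts at/above the outlier threshold, 1 otherwise."""
        if not hasattr(self, "lambda_"):
            raise AttributeError("fit() has not been called")
        counts = np.asarray(X, dtype=int).ravel()
        if self.outlier_threshold_ is None:
            return np.ones(len(counts), dtype=int)
        return np.where(counts >= self.outlier_threshold_, -1, 1)


# ---------------------------------------------------------------------------
# Headline percentages


def motif_percentages(census: pd.DataFrame) -> dict[str, float]:
    """Percent of proteins carrying >= 1 X-motif and >= 1 G-motif."""
    n = len(census)
    if n == 0:
        raise ValueError("empty census")
    return {
        "pct_with_x_motif": 100.0 * float((census["n_x_motifs"] >= 1).sum()) / n,
        "pct_with_g_motif": 100.0 * float((census["n_g_motifs"] >= 1).sum()) / n,
    }
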