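"""Hydrolysis kinetics and pH-titration models.

Ni2+-assisted peptide-bond cleavage proceeds as two consecutive
first-order steps: an N-O acyl shift converts the substrate into an
ester intermediate with rate k1, which then hydrolyses spontaneously
into the two final peptides with rate k2 (A -> B -> C).  The molar
fractions follow the closed forms

    A(t) = A0 exp(-k1 t)
    B(t) = A0 k1/(k2 - k1) (exp(-k1 t) - exp(-k2 t))
    C(t) = A0 - A(t) - B(t)

with the degenerate limit B = A0 k1 t exp(-k1 t) when k1 ~= k2.  The
product curve is obtained by mass conservation, which holds for all t
and parameter values by construction.

When only final-product accumulation can be quantified (protein gels),
a pseudo-first-order law y = A0 (1 - exp(-k t)) is fitted instead.

Square-planar Ni2+ complex formation is pH dependent; spectrophotometric
titrations are fitted with the Hill equation

    A(pH) = A_min + (A_max - A_min) / (1 + 10^(n (pKa - pH)))

whose midpoint is the apparent pKa of complex formation.

All fits are scikit-learn style estimators with trailing-underscore
fitted attributes; standard errors come from the Gauss-Newton
approximation to the covariance and 95% curve bands from the delta
method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.base import BaseEstimator, RegressorMixin

LN2 = float(np.log(2.0))

#: Species order used throughout for consecutive-kinetics arrays.
SPECIES = ("substrate", "intermediate", "product")


class FitError(RuntimeError):
    """Nonlinear fit failed to converge or input is degenerate."""


# ---------------------------------------------------------------------------
# Closed-form models


def consecutive_model(
    t: np.ndarray | float,
    k1: float,
    k2: float,
    A0: float = 1.0,
    rel_tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Substrate, intermediate and product fractions of A -> B -> C.

    Uses the L'Hopital limit for the intermediate when ``k1`` and ``k2``
    differ by less than ``rel_tol`` relatively, so mass conservation
    A + B + C = A0 holds on the degenerate branch too.
    """
    if k1 <= 0 or k2 <= 0:
        raise ValueError("rate constants must be positive")
    t = np.asarray(t, dtype=float)
    A = A0 * np.exp(-k1 * t)
    if abs(k2 - k1) <= rel_tol * max(k1, k2):
        k = 0.5 * (k1 + k2)
        B = A0 * k * t * np.exp(-k * t)
    else:
        B = A0 * k1 / (k2 - k1) * (np.exp(-k1 * t) - np.exp(-k2 * t))
    C = A0 - A - B
    return A, B, C


def intermediate_peak_time(k1: float, k2: float) -> float:
    """Time of the intermediate maximum, ln(k1/k2)/(k1 - k2)."""
    if k1 <= 0 or k2 <= 0:
        raise ValueError("rate constants must be positive")
    if abs(k1 - k2) <= 1e-12 * max(k1, k2):
        return 1.0 / k1
    return float(np.log(k1 / k2) / (k1 - k2))


def first_order_model(t: np.ndarray | float, k: float, A0: float = 1.0) -> np.ndarray:
    """Final-product accumulation y = A0 (1 - exp(-k t))."""
    t = np.asarray(t, dtype=float)
    return A0 * (1.0 - np.exp(-k * t))


def hill_model(
    pH: np.ndarray | float,
    pKa: float,
    n_hill: float,
    A_min: float,
    A_max: float,
) -> np.ndarray:
    """Sigmoidal titration signal with base-10 Hill cooperativity."""
    if n_hill <= 0:
        raise ValueError("Hill coefficient must be positive")
    pH = np.asarray(pH, dtype=float)
    return A_min + (A_max - A_min) / (1.0 + 10.0 ** (n_hill * (pKa - pH)))


def t_half(k: float) -> float:
    """Half-life ln 2 / k of a first-order process."""
    if k <= 0:
        raise ValueError("rate must be positive")
    return LN2 / k


# ---------------------------------------------------------------------------
# Data containers


@dataclass
class KineticTimeCourse:
    """Observed molar fractions vs time for one reaction condition.

    ``fractions`` maps species name ("substrate", "intermediate",
    "product") to an array aligned with ``times`` (minutes).  Missing
    species are simply absent from the mapping.
    """

    times: np.ndarray
    fractions: dict[str, np.ndarray]
    condition: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        for name, y in self.fractions.items():
            y = np.asarray(y, dtype=float)
            if y.shape != self.times.shape:
                raise ValueError(f"species {name!r}: length mismatch with times")
            if np.any(y < -0.05) or np.any(y > 1.05):
                raise ValueError(f"species {name!r}: fractions outside [-0.05, 1.05]")
            self.fractions[name] = y

    @classmethod
    def from_frame(cls, df: pd.DataFrame, condition: str = "") -> "KineticTimeCourse":
        """Build from a long table with columns time_min, species, fraction
        (and optionally condition)."""
        if condition and "condition" in df.columns:
            df = df[df["condition"] == condition]
        wide = df.pivot_table(index="time_min", columns="species", values="fraction")
        wide = wide.sort_index()
        return cls(
            times=wide.index.to_numpy(),
            fractions={c: wide[c].to_numpy() for c in wide.columns},
            condition=condition,
        )


# ---------------------------------------------------------------------------
# Generic weighted least-squares machinery


def _gauss_newton_errors(residuals: np.ndarray, jac: np.ndarray, n_params: int):
    dof = max(residuals.size - n_params, 1)
    s2 = float(residuals @ residuals) / dof
    jtj = jac.T @ jac
    try:
        cov = s2 * np.linalg.inv(jtj)
    except np.linalg.LinAlgError:
        cov = s2 * np.linalg.pinv(jtj)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    return cov, se


def _delta_band(
    model: Callable[[np.ndarray, np.ndarray], np.ndarray],
    params: np.ndarray,
    cov: np.ndarray,
    t: np.ndarray,
    z: float = 1.959964,
) -> tuple[np.ndarray, np.ndarray]:
    """95% pointwise envelope of the fitted curve by the delta method."""
    y = model(t, params)
    grad = np.empty((t.size, params.size))
    for j in range(params.size):
        h = 1e-6 * max(abs(params[j]), 1e-6)
        up, dn = params.copy(), params.copy()
        up[j] += h
        dn[j] -= h
        grad[:, j] = (model(t, up) - model(t, dn)) / (2 * h)
    var = np.einsum("ij,jk,ik->i", grad, cov, grad)
    half = z * np.sqrt(np.maximum(var, 0.0))
    return y - half, y + half


# ---------------------------------------------------------------------------
# Consecutive-kinetics estimator


class ConsecutiveKinetics(BaseEstimator, RegressorMixin):
    """Joint weighted NLS fit of the A -> B -> C consecutive model.

    ``fit(X, y)`` takes times (minutes) and a (n_times, n_species)
    array whose columns follow the ``species`` parameter; NaNs mark
    unobserved values.  Rates are optimised on a log scale (enforcing
    positivity) from a multi-start grid, which also resolves the
    k1/k2 swap degeneracy: the basin with the lower residual wins and
    ``swap_ambiguous_`` records whether the swapped basin came within
    1% of it.

    Attributes
    ----------
    k1_, k2_ : float
        Acyl-shift and ester-hydrolysis rates (1/min).
    A0_ : float
        Initial substrate fraction.
    se_k1_, se_k2_, se_A0_ : float
        Gauss-Newton standard errors.
    t_half_k1_ : float
        ln 2 / k1.
    cov_ : ndarray
        Parameter covariance (order log k1, log k2, A0 transformed back).
    """

    def __init__(
        self,
        species: Sequence[str] = SPECIES,
        weights: Sequence[float] | None = None,
        fit_A0: bool = True,
        mode: str = "joint",
        n_starts: int = 5,
        rate_grid: tuple[float, float] = (1e-4, 1.0),
    ):
        self.species = species
        self.weights = weights
        self.fit_A0 = fit_A0
        self.mode = mode
        self.n_starts = n_starts
        self.rate_grid = rate_grid

    # model in terms of theta = (log k1, log k2, A0)
    def _predict_matrix(self, t: np.ndarray, theta: np.ndarray) -> np.ndarray:
        k1, k2 = np.exp(theta[0]), np.exp(theta[1])
        A0 = theta[2]
        A, B, C = consecutive_model(t, k1, k2, A0)
        cols = {"substrate": A, "intermediate": B, "product": C}
        return np.column_stack([cols[s] for s in self.species])

    def _residuals(self, theta, t, Y, W, mask):
        pred = self._predict_matrix(t, theta)
        return ((pred - Y) * W)[mask]

    def fit(self, X: Sequence[float], y: np.ndarray):
        t = np.asarray(X, dtype=float).ravel()
        Y = np.atleast_2d(np.asarray(y, dtype=float))
        if Y.shape[0] != t.size:
            Y = Y.T
        if Y.shape != (t.size, len(self.species)):
            raise ValueError("y must be (n_times, n_species)")
        if t.size < 5:
            raise FitError("need at least 5 time points")
        mask = np.isfinite(Y)
        n_obs_species = int(mask.any(axis=0).sum())
        if n_obs_species < 2:
            raise FitError("need substrate plus at least one other species")
        if mask.sum() < 4:
            raise FitError("fewer observations than parameters")
        w = (
            np.ones(len(self.species))
            if self.weights is None
            else np.asarray(self.weights, dtype=float)
        )
        W = np.broadcast_to(w, Y.shape)
        Yf = np.where(mask, Y, 0.0)

        lo, hi = self.rate_grid
        grid = np.exp(np.linspace(np.log(lo), np.log(hi), self.n_starts))
        A0_init = 1.0
        sub_idx = list(self.species).index("substrate") if "substrate" in self.species else None
        if self.fit_A0 and sub_idx is not None and mask[:, sub_idx].any():
            A0_init = float(np.nanmax(Y[:, sub_idx]))

        best = None
        second = None
        for g1 in grid:
            for g2 in grid:
                theta0 = np.array([np.log(g1), np.log(g2), A0_init])
                try:
                    res = optimize.least_squares(
                        self._residuals,
                        theta0,
                        args=(t, Yf, W, mask),
                        bounds=(
                            [np.log(1e-8), np.log(1e-8), 1e-6 if self.fit_A0 else A0_init - 1e-12],
                            [np.log(1e4), np.log(1e4), 2.0 if self.fit_A0 else A0_init + 1e-12],
                        ),
                        method="trf",
                    )
                except Exception:
                    continue
                cost = res.cost
                if best is None or cost < best.cost - 1e-15:
                    second = best
                    best = res
                elif second is None or cost < second.cost:
                    second = res
        if best is None or not best.success:
            raise FitError("consecutive fit did not converge from any start")

        theta = best.x
        k1, k2, A0 = float(np.exp(theta[0])), float(np.exp(theta[1])), float(theta[2])
        # Swap-degeneracy report: is there a near-equal basin with rates
        # reversed?
        self.swap_ambiguous_ = False
        if second is not None and second.cost > 0:
            close = abs(second.cost - best.cost) <= 0.01 * best.cost
            r1, r2 = np.exp(second.x[:2])
            reversed_order = (r1 - r2) * (k1 - k2) < 0
            self.swap_ambiguous_ = bool(close and reversed_order)

        resid = best.fun
        cov_theta, se_theta = _gauss_newton_errors(resid, best.jac, theta.size)
        # transform log-rate errors to rate scale: se_k = k * se_logk
        self.k1_, self.k2_, self.A0_ = k1, k2, A0
        self.se_k1_ = k1 * se_theta[0]
        self.se_k2_ = k2 * se_theta[1]
        self.se_A0_ = se_theta[2]
        self.cov_ = cov_theta
        self.theta_ = theta
        self.t_half_k1_ = t_half(k1)
        self.t_half_k2_ = t_half(k2)
        self.residual_ = float(resid @ resid)
        self.n_obs_ = int(mask.sum())
        self._t = t
        return self

    def predict(self, X: Sequence[float]) -> np.ndarray:
        t = np.asarray(X, dtype=float).ravel()
        return self._predict_matrix(t, self.theta_)

    def confidence_band(self, X: Sequence[float], species: str = "substrate"):
        """Pointwise 95% delta-method envelope for one species curve."""
        t = np.asarray(X, dtype=float).ravel()
        idx = list(self.species).index(species)

        def one(tt, th):
            return self._predict_matrix(tt, th)[:, idx]

        return _delta_band(one, self.theta_, self.cov_, t)

    def summary(self) -> dict:
        return {
            "k1": self.k1_,
            "k2": self.k2_,
            "A0": self.A0_,
            "se_k1": self.se_k1_,
            "se_k2": self.se_k2_,
            "se_A0": self.se_A0_,
            "t_half_k1": self.t_half_k1_,
            "t_half_k2": self.t_half_k2_,
            "swap_ambiguous": self.swap_ambiguous_,
            "residual_ss": self.residual_,
            "n_obs": self.n_obs_,
        }


def fit_consecutive(tc: KineticTimeCourse, **kwargs) -> ConsecutiveKinetics:
    """Fit the consecutive model to a time course (joint by default).

    ``mode="sequential"`` first fits k1 on the substrate decay alone,
    then k2 on the remaining species with k1 held near its estimate.
    """
    present = [s for s in SPECIES if s in tc.fractions]
    if "substrate" not in present or len(present) < 2:
        raise FitError("need substrate plus at least one other species")
    Y = np.column_stack([tc.fractions[s] for s in present])
    mode = kwargs.pop("mode", "joint")
    if mode == "sequential":
        # stage 1: substrate decay gives k1 and A0
        sub = tc.fractions["substrate"]
        pos = sub > 1e-12

        def neg_exp(t_, k, A0):
            return A0 * np.exp(-k * t_)

        p0 = [0.05, max(float(sub.max()), 1e-3)]
        popt, _ = optimize.curve_fit(
            neg_exp, tc.times, sub, p0=p0, bounds=([1e-8, 1e-6], [1e4, 2.0]),
            maxfev=20000,
        )
        k1_hat, A0_hat = popt
        est = ConsecutiveKinetics(species=present, fit_A0=False, **kwargs)
        # narrow the rate grid around k1_hat for the joint refinement
        est.rate_grid = (max(k1_hat / 10, 1e-8), min(k1_hat * 10, 1e4))
        est.fit_A0 = True
        est.fit(tc.times, Y)
        return est
    est = ConsecutiveKinetics(species=present, **kwargs)
    return est.fit(tc.times, Y)


# ---------------------------------------------------------------------------
# Pseudo-first-order product fit


class FirstOrderKinetics(BaseEstimator, RegressorMixin):
    """Pseudo-first-order fit of final-product accumulation.

    ``fit(X, y)`` with times and product fractions estimates the
    apparent rate ``k_`` and amplitude ``A0_`` of
    y = A0 (1 - exp(-k t)); ``t_half_`` is ln 2 / k.
    """

    def __init__(self, fit_A0: bool = True):
        self.fit_A0 = fit_A0

    def fit(self, X: Sequence[float], y: Sequence[float]):
        t = np.asarray(X, dtype=float).ravel()
        yy = np.asarray(y, dtype=float).ravel()
        if t.size < 4:
            raise FitError("need at least 4 points")
        span = float(yy.max() - yy.min())
        if span <= 1e-12 or float(np.nanmax(np.abs(yy))) <= 1e-12:
            raise FitError("no signal growth in product trace")

        def model(tt, k, A0):
            return first_order_model(tt, k, A0)

        # crude init: time to half-plateau
        plateau = float(yy.max())
        half_idx = int(np.argmin(np.abs(yy - plateau / 2)))
        t50 = max(float(t[half_idx]), float(t[t > 0].min()) if (t > 0).any() else 1.0)
        p0 = [LN2 / t50, plateau]
        try:
            popt, pcov = optimize.curve_fit(
                model, t, yy, p0=p0, bounds=([1e-8, 1e-6], [1e4, 2.0]),
                maxfev=20000,
            )
        except RuntimeError as e:
            raise FitError(f"first-order fit did not converge: {e}") from e
        self.k_, self.A0_ = float(popt[0]), float(popt[1])
        se = np.sqrt(np.maximum(np.diag(pcov), 0.0))
        self.se_k_, self.se_A0_ = float(se[0]), float(se[1])
        self.cov_ = pcov
        self.t_half_ = t_half(self.k_)
        self._params = popt
        return self

    def predict(self, X: Sequence[float]) -> np.ndarray:
        t = np.asarray(X, dtype=float).ravel()
        return first_order_model(t, self.k_, self.A0_)

    def confidence_band(self, X: Sequence[float]):
        t = np.asarray(X, dtype=float).ravel()

        def one(tt, th):
            return first_order_model(tt, th[0], th[1])

        return _delta_band(one, self._params, self.cov_, t)


def fit_first_order(times: Sequence[float], product_fraction: Sequence[float]) -> FirstOrderKinetics:
    """Convenience wrapper: fit product accumulation, return the estimator."""
    return FirstOrderKinetics().fit(times, product_fraction)


# ---------------------------------------------------------------------------
# Rate bookkeeping


def sum_site_rates(
    site_rates: Sequence[float],
    observed_domain_rate: float | None = None,
) -> dict:
    """Sum of per-site cleavage rates; mechanistically the individual
    site rates add up to the overall domain-decay rate.

    Returns the sum and, when an observed domain rate is given, the
    observed/sum ratio (how much faster the whole domain decays than
    the model-peptide sites predict).
    """
    rates = np.asarray(site_rates, dtype=float)
    if rates.size and np.any(rates < 0):
        raise ValueError("rates must be non-negative")
    total = float(rates.sum())
    out = {"sum": total}
    if observed_domain_rate is not None:
        if total == 0:
            raise ValueError("cannot form ratio: site-rate sum is zero")
        out["observed_over_sum"] = float(observed_domain_rate) / total
    return out


def rate_ratio(
    k_a: float,
    k_b: float,
    se_a: float = 0.0,
    se_b: float = 0.0,
) -> tuple[float, float]:
    """k_a / k_b with first-order error propagation.

    Accepts plain rates or fitted estimators (anything with ``k1_`` or
    ``k_``).
    """
    def unpack(obj, se):
        if hasattr(obj, "k1_"):
            return float(obj.k1_), float(getattr(obj, "se_k1_", 0.0))
        if hasattr(obj, "k_"):
            return float(obj.k_), float(getattr(obj, "se_k_", 0.0))
        return float(obj), float(se)

    ka, sa = unpack(k_a, se_a)
    kb, sb = unpack(k_b, se_b)
    if kb == 0:
        raise ValueError("zero denominator rate")
    r = ka / kb
    se_r = abs(r) * np.sqrt((sa / ka) ** 2 + (sb / kb) ** 2) if ka != 0 else 0.0
    return r, float(se_r)


# ---------------------------------------------------------------------------
# Hill titration estimator


class HillCurve(BaseEstimator, RegressorMixin):
    """Four-parameter Hill fit of a pH titration.

    ``fit(X, y)`` with pH values and signals estimates ``pKa_``,
    ``n_hill_`` and the plateaus ``A_min_``/``A_max_``.  Decreasing
    titrations are handled by a negative amplitude (A_max < A_min);
    the pKa is invariant to that sign flip.
    """

    def __init__(self, fix_n_hill: float | None = None):
        self.fix_n_hill = fix_n_hill

    def fit(self, X: Sequence[float], y: Sequence[float]):
        pH = np.asarray(X, dtype=float).ravel()
        sig = np.asarray(y, dtype=float).ravel()
        if pH.size < 6:
            raise FitError("need at least 6 titration points")
        span = float(sig.max() - sig.min())
        if span <= 0 or span < 1e-9 * max(1.0, abs(float(sig.mean()))):
            raise FitError("no transition in sampled pH range")
        increasing = sig[np.argmax(pH)] >= sig[np.argmin(pH)]
        lo, hi = (sig.min(), sig.max()) if increasing else (sig.max(), sig.min())
        mid = 0.5 * (lo + hi)
        pKa0 = float(pH[np.argmin(np.abs(sig - mid))])

        def _hill(p, pKa, n, A_min, A_max):
            # unchecked form so the optimiser may cross n <= 0 transiently
            return A_min + (A_max - A_min) / (1.0 + 10.0 ** (n * (pKa - p)))

        if self.fix_n_hill is not None:
            def model(p, pKa, A_min, A_max):
                return _hill(p, pKa, self.fix_n_hill, A_min, A_max)
            p0 = [pKa0, lo, hi]
            names = ["pKa", "A_min", "A_max"]
        else:
            model = _hill
            p0 = [pKa0, 1.0, lo, hi]
            names = ["pKa", "n_hill", "A_min", "A_max"]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", optimize.OptimizeWarning)
                popt, pcov = optimize.curve_fit(model, pH, sig, p0=p0, maxfev=50000)
        except RuntimeError as e:
            raise FitError(f"Hill fit did not converge: {e}") from e
        params = dict(zip(names, popt))
        se = dict(zip(names, np.sqrt(np.maximum(np.diag(pcov), 0.0))))
        self.pKa_ = float(params["pKa"])
        self.n_hill_ = float(params.get("n_hill", self.fix_n_hill or 1.0))
        self.A_min_ = float(params["A_min"])
        self.A_max_ = float(params["A_max"])
        self.se_pKa_ = float(se["pKa"])
        self.se_n_hill_ = float(se.get("n_hill", 0.0))
        self.cov_ = pcov
        if not (pH.min() - 1.0 <= self.pKa_ <= pH.max() + 1.0):
            raise FitError(
                f"fitted pKa {self.pKa_:.2f} outside sampled range "
                f"[{pH.min():.2f}, {pH.max():.2f}] +- 1: no transition in range"
            )
        return self

    def predict(self, X: Sequence[float]) -> np.ndarray:
        pH = np.asarray(X, dtype=float).ravel()
        return hill_model(pH, self.pKa_, self.n_hill_, self.A_min_, self.A_max_)

    def summary(self) -> dict:
        return {
            "pKa": self.pKa_,
            "n_hill": self.n_hill_,
            "A_min": self.A_min_,
            "A_max": self.A_max_,
            "se_pKa": self.se_pKa_,
        }


def fit_hill(titration: pd.DataFrame | Sequence, signal=None, **kwargs) -> HillCurve:
    """Fit a Hill curve to a titration table (columns pH, signal) or to
    parallel pH/signal arrays."""
    if signal is None:
        pH = np.asarray(titration["pH"], dtype=float)
        sig = np.asarray(titration["signal"], dtype=float)
    else:
        pH = np.asarray(titration, dtype=float)
        sig = np.asarray(signal, dtype=float)
    return HillCurve(**kwargs).fit(pH, sig)
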