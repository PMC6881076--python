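"""The robustness formalism: saturation curves, n0 fitting, rho, and
distributed-robustness diagnostics.

A property M of n parameters is r-robust when its log-variance under
perturbation of r randomly chosen parameters follows the saturation curve

    Var(log M) = (1 - (1 - n0/n)^r) * V0,

with n0 sensitive parameters each contributing V0 non-cumulatively. The
half-saturation point r_half relates to n0 by n0 = n * (1 - 2^(-1/r_half)).
Distributed robustness instead shows Var(log M) = V_K * r / n^2, linear in r
and vanishing as 1/n at full perturbation. The robustness ratio
rho = Var(log M-fold-change) / Var(log input-fold-change) classifies single
perturbations: below 1 robust, above 1 sensitive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize


@dataclass
class RobustnessCurve:
    """Var(log M) per number of perturbed parameters r, out of n total."""

    r: np.ndarray
    var_log_m: np.ndarray
    n: int
    n_reps: int | np.ndarray = 0

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.var_log_m = np.asarray(self.var_log_m, dtype=float)
        if self.r.shape != self.var_log_m.shape:
            raise ValueError("r and var_log_m must align")
        if (np.diff(self.r) <= 0).any():
            raise ValueError("r must be strictly increasing")
        if (self.r < 1).any() or (self.r > self.n).any():
            raise ValueError("r must lie in [1, n]")
        if (self.var_log_m < 0).any():
            raise ValueError("variances must be non-negative")


@dataclass
class SaturationFit:
    """Fitted saturation parameters; error_terms holds (c0, c1) when used."""

    n0: float
    V0: float
    r_half: float
    sse: float
    n: int
    error_terms: tuple[float, float] | None = None
    degenerate: bool = False


@dataclass
class RhoResult:
    rho: float
    var_log_m: float
    var_log_k: float
    classification: str = field(init=False)

    def __post_init__(self) -> None:
        self.classification = ("robust" if self.rho < 1.0
                               else "sensitive" if self.rho > 1.0 else "marginal")


@dataclass
class DistributedPrediction:
    """Linear-in-r variance law of a distributed-robust system."""

    n: int
    V_K: float
    r: np.ndarray
    var_log_m: np.ndarray
    full_perturbation: float


# ---------------------------------------------------------------------------
# closed forms


def expected_saturation_variance(r, n: int, n0: float, V0: float):
    """(1 - (1 - n0/n)^r) * V0: the r-robust saturation curve."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= n0 <= n:
        raise ValueError("n0 must lie in [0, n]")
    r = np.asarray(r, dtype=float)
    out = (1.0 - (1.0 - n0 / n) ** r) * V0
    return float(out) if out.ndim == 0 else out


def n0_from_rhalf(n: int, r_half: float) -> float:
    """Sensitive-parameter count from the half-saturation point."""
    if r_half <= 0:
        raise ValueError("r_half must be positive")
    return n * (1.0 - 2.0 ** (-1.0 / r_half))


def rhalf_from_n0(n: int, n0: float) -> float:
    """Half-saturation point of the fitted curve; inf when n0 = 0."""
    if n0 <= 0:
        return float("inf")
    if n0 >= n:
        # every parameter sensitive: variance is V0 from the first hit on
        return 0.0
    return float(-1.0 / np.log2(1.0 - n0 / n))


def distributed_prediction(n: int, V_K: float, r) -> DistributedPrediction:
    """Var(log M) = V_K * r / n^2, and V_K / n at full perturbation."""
    if n < 1:
        raise ValueError("n must be >= 1")
    r = np.atleast_1d(np.asarray(r, dtype=float))
    return DistributedPrediction(n=n, V_K=V_K, r=r, var_log_m=V_K * r / n**2,
                                 full_perturbation=V_K / n)


def rho(var_log_m: float, var_log_k: float) -> RhoResult:
    """Robustness ratio of output to input log-fold-change variance."""
    if var_log_k <= 0:
        raise ValueError("var_log_k must be positive")
    return RhoResult(var_log_m / var_log_k, var_log_m, var_log_k)


# ---------------------------------------------------------------------------
# saturation-curve fitting


def _model(params, r, n, with_error_terms):
    n0, V0 = params[0], params[1]
    base = (1.0 - (1.0 - n0 / n) ** r) * V0
    if with_error_terms:
        base = base + params[2] + params[3] * r
    return base


def fit_saturation(curve: RobustnessCurve, with_error_terms: bool = False,
                   seed: int = 0, maxfun: int = 20_000,
                   weights: np.ndarray | None = None) -> SaturationFit:
    """Least-squares fit of the saturation curve by seeded simulated annealing.

    Minimizes the (optionally weighted) squared deviation over n0 in [0, n]
    and V0 in [0, 4 * max variance], plus non-negative error terms c0 + c1*r
    when requested, using a generalized simulated-annealing global search
    followed by a local polish. n is fixed from the curve. Unweighted by
    default; pass per-point weights (e.g. replicate counts) to weight.
    """
    r, y, n = curve.r, curve.var_log_m, curve.n
    if len(r) < 4:
        raise ValueError("need at least 4 points to fit")
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    ymax = float(y.max())
    if ymax <= 0.0:
        return SaturationFit(0.0, 0.0, float("inf"), 0.0, n,
                             error_terms=(0.0, 0.0) if with_error_terms else None,
                             degenerate=True)
    bounds = [(0.0, float(n)), (0.0, 4.0 * ymax)]
    if with_error_terms:
        bounds += [(0.0, ymax), (0.0, ymax / max(float(r.max()), 1.0))]

    def sse(params):
        resid = y - _model(params, r, n, with_error_terms)
        return float((w * resid**2).sum())

    res = optimize.dual_annealing(sse, bounds=bounds, seed=seed, maxfun=maxfun)
    polish = optimize.minimize(sse, res.x, method="Nelder-Mead",
                               options={"xatol": 1e-10, "fatol": 1e-14,
                                        "maxiter": 5000})
    best = polish.x if polish.fun <= res.fun else res.x
    best = np.clip(best, [b[0] for b in bounds], [b[1] for b in bounds])
    n0, V0 = float(best[0]), float(best[1])
    terms = (float(best[2]), float(best[3])) if with_error_terms else None
    return SaturationFit(n0=n0, V0=V0, r_half=rhalf_from_n0(n, n0),
                         sse=float(sse(best)), n=n, error_terms=terms)


def _fit_linear_origin(curve: RobustnessCurve) -> tuple[float, float]:
    """Through-origin least squares slope and its sse."""
    r, y = curve.r, curve.var_log_m
    slope = float((r * y).sum() / (r * r).sum())
    slope = max(slope, 0.0)
    return slope, float(((y - slope * r) ** 2).sum())


def _aicc(sse: float, n_pts: int, k: int) -> float:
    sse = max(sse, 1e-300)
    aic = n_pts * np.log(sse / n_pts) + 2 * k
    denom = n_pts - k - 1
    return aic + (2 * k * (k + 1) / denom if denom > 0 else np.inf)


def classify_robustness(curve: RobustnessCurve, seed: int = 0) -> str:
    """Label a variance curve r_robust, distributed, or indeterminate.

    Fits the saturating model against a through-origin linear model and
    compares small-sample-corrected AIC; differences below 2 (or an all-zero
    curve) are indeterminate.
    """
    if len(curve.r) < 6:
        raise ValueError("need at least 6 points to classify")
    if curve.var_log_m.max() <= 0.0:
        return "indeterminate"
    sat = fit_saturation(curve, seed=seed)
    _, sse_lin = _fit_linear_origin(curve)
    n_pts = len(curve.r)
    delta = _aicc(sse_lin, n_pts, 1) - _aicc(sat.sse, n_pts, 2)
    if abs(delta) < 2.0:
        return "indeterminate"
    return "r_robust" if delta > 0 else "distributed"


def bootstrap_n0(curve: RobustnessCurve, n_boot: int = 200, seed: int = 0,
                 **fit_kwargs) -> np.ndarray:
    """Bootstrap-over-points n0 estimates; a rough uncertainty utility."""
    rng = np.random.default_rng(seed)
    m = len(curve.r)
    out = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.sort(rng.choice(m, size=m, replace=True))
        idx = np.unique(idx)
        if len(idx) < 4:
            out[b] = np.nan
            continue
        sub = RobustnessCurve(curve.r[idx], curve.var_log_m[idx], curve.n)
        out[b] = fit_saturation(sub, seed=int(rng.integers(2**31)),
                                **fit_kwargs).n0
    return out
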