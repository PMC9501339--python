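"""Growth-curve fits and rank correlations for biofilm time series.

Two empirical relations are fitted by nonlinear least squares:

* the monoexponential roughness–biovolume relation
  ``SR(V) = SR_eq + A·exp(−V/V_c)`` — the surface-roughness coefficient of a
  developing biofilm saturates at SR_eq with characteristic biovolume V_c;
* the logistic coverage-versus-time curve
  ``f(t) = f_max / (1 + exp(−k (t − t0)))`` — substratum coverage rises after
  a lag and plateaus at f_max.

Spearman rank correlation links structural metrics to environmental indexes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "GrowthSeries",
    "FitResult",
    "fit_monoexponential",
    "fit_sigmoid_coverage",
    "spearman_rho",
]


@dataclass(frozen=True)
class GrowthSeries:
    """A sampled time series of one biofilm metric.

    ``t`` in days, strictly increasing, at least 4 samples.
    """

    t: np.ndarray
    y: np.ndarray
    metric: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=np.float64).ravel()
        y = np.asarray(self.y, dtype=np.float64).ravel()
        if len(t) != len(y) or len(t) < 4:
            raise ValueError("need matched t and y with at least 4 samples")
        if not np.all(np.diff(t) > 0):
            raise ValueError("t must be strictly increasing")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "y", y)


@dataclass(frozen=True)
class FitResult:
    """Nonlinear least-squares fit outcome.

    ``params``/``stderr`` map parameter names to estimates and asymptotic
    standard errors; ``r`` is the Pearson correlation between fitted and
    observed values; ``converged`` is False when the optimizer failed and
    ``warnings`` collects identifiability flags (e.g. an unidentifiable decay
    scale on constant data).
    """

    params: dict
    stderr: dict
    r: float
    converged: bool
    warnings: tuple = field(default_factory=tuple)


def _fit_quality(y: np.ndarray, y_fit: np.ndarray) -> float:
    if np.std(y) == 0 or np.std(y_fit) == 0:
        return math.nan
    return float(np.corrcoef(y, y_fit)[0, 1])


def _multistart_curve_fit(model, x, y, p0, bounds, rng, n_starts=3, jitter=0.2):
    """curve_fit from ``p0`` plus jittered restarts; best SSR solution wins."""
    best = None
    lo, hi = bounds
    starts = [np.asarray(p0, dtype=np.float64)]
    for _ in range(n_starts - 1):
        jittered = starts[0] * (1 + jitter * rng.standard_normal(len(p0)))
        starts.append(np.clip(jittered, np.asarray(lo) + 1e-12, hi))
    for start in starts:
        try:
            popt, pcov = optimize.curve_fit(
                model, x, y, p0=start, bounds=bounds, maxfev=20000
            )
        except (RuntimeError, ValueError):
            continue
        ssr = float(np.sum((model(x, *popt) - y) ** 2))
        if best is None or ssr < best[2]:
            best = (popt, pcov, ssr)
    return best


def fit_monoexponential(V, SR, *, rng_seed: int = 0) -> FitResult:
    """Fit SR(V) = SR_eq + A·exp(−V/V_c) by least squares.

    Initialization: SR_eq from the top-quartile mean of SR (the saturated
    tail), A from the first sample's offset, V_c from range(V)/3; V_c > 0 is
    enforced through bounds.  Three jittered restarts guard against local
    minima.  Non-convergence is reported via ``converged=False``, never
    silently worked around; near-constant SR flags V_c as unidentifiable.
    """
    V = np.asarray(V, dtype=np.float64).ravel()
    SR = np.asarray(SR, dtype=np.float64).ravel()
    if len(V) != len(SR) or len(V) < 5:
        raise ValueError("need matched V and SR with at least 5 points")
    if np.any(V < 0):
        raise ValueError("biovolumes must be non-negative")

    def model(v, sr_eq, a, v_c):
        return sr_eq + a * np.exp(-v / v_c)

    order = np.argsort(V)
    sr_sorted = SR[order]
    n_q = max(1, len(SR) // 4)
    sr_eq0 = float(np.mean(sr_sorted[-n_q:]))
    a0 = float(SR[order][0] - sr_eq0)
    v_range = float(V.max() - V.min())
    v_c0 = v_range / 3 if v_range > 0 else 1.0
    rng = np.random.default_rng(rng_seed)
    bounds = ([-np.inf, -np.inf, 1e-12], [np.inf, np.inf, np.inf])
    best = _multistart_curve_fit(model, V, SR, [sr_eq0, a0 if a0 != 0 else -0.1, v_c0], bounds, rng)
    if best is None:
        return FitResult(params={}, stderr={}, r=math.nan, converged=False)
    popt, pcov, _ = best
    names = ("SR_eq", "A", "V_c")
    stderr = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.full(3, np.nan)
    warnings = []
    # amplitude indistinguishable from zero => decay scale carries no information
    if abs(popt[1]) < 1e-8 or (np.isfinite(stderr[2]) and stderr[2] > 10 * abs(popt[2])) or not np.isfinite(stderr[2]):
        warnings.append("V_c unidentifiable (amplitude ~ 0 or unconstrained decay scale)")
    y_fit = model(V, *popt)
    return FitResult(
        params=dict(zip(names, popt.tolist())),
        stderr=dict(zip(names, stderr.tolist())),
        r=_fit_quality(SR, y_fit),
        converged=True,
        warnings=tuple(warnings),
    )


def fit_sigmoid_coverage(gs: GrowthSeries, *, rng_seed: int = 0) -> FitResult:
    """Fit a logistic coverage curve f(t) = f_max / (1 + exp(−k (t − t0))).

    Coverage values must lie in [0, 1]; f_max is constrained to (0, 1].
    A declining series yields k < 0, flagged in ``warnings``.
    """
    t, y = gs.t, gs.y
    if np.any(y < 0) or np.any(y > 1):
        raise ValueError("coverage values must lie in [0, 1]")

    def model(tt, f_max, k, t0):
        return f_max / (1 + np.exp(-k * (tt - t0)))

    f0 = min(max(float(y.max()), 1e-3), 1.0)
    half = f0 / 2
    t0_0 = float(t[np.argmin(np.abs(y - half))])
    rng = np.random.default_rng(rng_seed)
    bounds = ([1e-6, -np.inf, -np.inf], [1.0, np.inf, np.inf])
    best = _multistart_curve_fit(model, t, y, [f0, 1.0, t0_0], bounds, rng)
    if best is None:
        return FitResult(params={}, stderr={}, r=math.nan, converged=False)
    popt, pcov, _ = best
    names = ("f_max", "k", "t0")
    stderr = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.full(3, np.nan)
    warnings = []
    if popt[1] < 0:
        warnings.append("negative growth rate k: series is not an increasing sigmoid")
    y_fit = model(t, *popt)
    return FitResult(
        params=dict(zip(names, popt.tolist())),
        stderr=dict(zip(names, stderr.tolist())),
        r=_fit_quality(y, y_fit),
        converged=True,
        warnings=tuple(warnings),
    )


def spearman_rho(x, y) -> float:
    """Spearman rank correlation with average ranks for ties, in [−1, 1]."""
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length inputs with at least 3 values")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("rank correlation undefined for constant input")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)
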