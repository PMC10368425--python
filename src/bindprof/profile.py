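"""Profile-likelihood confidence intervals.

A profile scans one parameter over a grid while re-optimizing all other
(nuisance) parameters at each grid point; twice the log-likelihood
deficit, 2*(NLL_prof - NLL_min), is asymptotically chi-squared with one
degree of freedom, so the 95% confidence interval is read off where the
profile crosses the 0.95 quantile 3.84.

Scanning is adaptive in the parameter's transformed (log10 where
applicable) coordinate, targeting an increment of ~0.3 in 2*dNLL per
step; each side stops once the profile clears the threshold (plus a 0.5
margin for safe interpolation), hits a parameter bound, or exhausts the
step budget. Interval endpoints are linearly interpolated across the
threshold crossing. A side that never crosses before its bound is
reported as open (status ``hit_bound``) rather than extrapolated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .fitting import FitConfig, FitResult, local_minimize
from .likelihood import TitrationDataset, make_objective

__all__ = ["ProfilePoint", "ProfileResult", "chi2_threshold", "profile", "profile_objective"]

_STEP_MIN = 1e-4
_STEP_MAX = 0.5
_TARGET_INCREMENT = 0.3
_REFINE_TOL = 0.1  # bracket width in 2*dNLL before endpoint interpolation
_OVERSHOOT = 0.5


def chi2_threshold(level: float, df: int = 1) -> float:
    """Quantile of the chi-squared distribution: the 2*dNLL cutoff of a CI.

    chi2_threshold(0.95, 1) = 3.84 -- the likelihood-ratio threshold used
    for the 95% intervals on KD and EC50.
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"confidence level must be in (0, 1), got {level}")
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    return float(stats.chi2.ppf(level, df))


@dataclass(frozen=True)
class ProfilePoint:
    """One scan point: parameter value (natural scale), profiled NLL,
    2*dNLL, nuisance re-optimization convergence flag, and the full
    re-optimized vector (transformed scale)."""

    value: float
    nll: float
    two_delta_nll: float
    converged: bool
    x: np.ndarray


@dataclass
class ProfileResult:
    """Profile scan and the confidence interval it implies.

    ``lower``/``upper`` are on the parameter's natural scale;
    ``lower_status``/``upper_status`` are one of ``crossed`` (threshold
    passed, endpoint interpolated), ``hit_bound`` (open side: the scan
    reached a parameter bound below threshold; the bound itself is
    reported) or ``max_steps``.
    """

    param: str
    estimate: float
    level: float
    threshold: float
    points: list
    lower: float
    upper: float
    lower_status: str
    upper_status: str

    @property
    def ci(self) -> tuple:
        return (self.lower, self.upper)

    def to_dict(self) -> dict:
        return {
            "param": self.param,
            "estimate": self.estimate,
            "level": self.level,
            "threshold": self.threshold,
            "ci": [self.lower, self.upper],
            "lower_status": self.lower_status,
            "upper_status": self.upper_status,
            "scan": [
                {
                    "value": p.value,
                    "nll": p.nll,
                    "two_delta_nll": p.two_delta_nll,
                    "converged": p.converged,
                }
                for p in self.points
            ],
        }


def _natural(v: float, transform: str) -> float:
    return float(10.0**v) if transform == "log10" else float(v)


def _scan_side(objective, x_opt, nll_min, bounds, index, config, threshold,
               direction, max_steps, transform):
    """Walk one side of the profile; returns (points, endpoint, status)."""
    lo, hi = bounds[index]
    points = []
    x_warm = np.array(x_opt, dtype=float)
    ts = [float(x_opt[index])]
    deltas = [0.0]
    step = 0.005 * (hi - lo) if transform != "log10" else 0.01
    step = float(np.clip(step, _STEP_MIN, _STEP_MAX))
    status = "max_steps"
    for _ in range(max_steps):
        t_new = ts[-1] + direction * step
        at_bound = False
        if t_new <= lo:
            t_new, at_bound = lo, True
        elif t_new >= hi:
            t_new, at_bound = hi, True
        x0 = x_warm.copy()
        x0[index] = t_new
        x_sol, nll, ok = local_minimize(
            objective, x0, bounds, config, frozen={index: t_new}
        )
        delta = 2.0 * (nll - nll_min)
        points.append(ProfilePoint(_natural(t_new, transform), nll, delta, ok, x_sol))
        if ok:
            x_warm = x_sol
        increment = delta - deltas[-1]
        ts.append(float(t_new))
        deltas.append(float(delta))
        if delta >= threshold + _OVERSHOOT:
            status = "crossed"
            break
        if at_bound:
            status = "hit_bound"
            break
        # adapt the step towards the target per-step increment of 2*dNLL
        if increment > 1e-3:
            step *= float(np.clip(_TARGET_INCREMENT / increment, 0.3, 3.0))
        else:
            step *= 3.0
        step = float(np.clip(step, _STEP_MIN, _STEP_MAX))
    # locate and refine the bracket, then interpolate 2*dNLL linearly
    for i in range(1, len(deltas)):
        if deltas[i - 1] < threshold <= deltas[i]:
            t_in, d_in = ts[i - 1], deltas[i - 1]
            t_out, d_out = ts[i], deltas[i]
            # bisect until the bracket is tight enough for interpolation
            for _ in range(10):
                if d_out - d_in < _REFINE_TOL:
                    break
                t_mid = 0.5 * (t_in + t_out)
                x0 = x_warm.copy()
                x0[index] = t_mid
                x_sol, nll, ok = local_minimize(
                    objective, x0, bounds, config, frozen={index: t_mid}
                )
                d_mid = 2.0 * (nll - nll_min)
                points.append(
                    ProfilePoint(_natural(t_mid, transform), nll, d_mid, ok, x_sol)
                )
                if d_mid >= threshold:
                    t_out, d_out = t_mid, d_mid
                else:
                    t_in, d_in = t_mid, d_mid
            frac = (threshold - d_in) / (d_out - d_in)
            t_cross = t_in + frac * (t_out - t_in)
            return points, _natural(t_cross, transform), "crossed"
    # never crossed: report the furthest value reached, side stays open
    return points, _natural(ts[-1], transform), status


def profile_objective(
    objective,
    x_opt: np.ndarray,
    nll_min: float,
    bounds: np.ndarray,
    index: int,
    *,
    param: str = "x",
    transform: str = "linear",
    level: float = 0.95,
    config: FitConfig | None = None,
    max_steps: int = 100,
) -> ProfileResult:
    """Profile a single coordinate of an arbitrary NLL objective.

    This is the model-agnostic core; :func:`profile` wraps it for fitted
    titration models. ``x_opt`` must be the minimizer of ``objective``
    with minimum ``nll_min``.
    """
    config = config or FitConfig()
    threshold = chi2_threshold(level, 1)
    pts_lo, lower, st_lo = _scan_side(
        objective, x_opt, nll_min, bounds, index, config, threshold, -1.0,
        max_steps, transform,
    )
    pts_hi, upper, st_hi = _scan_side(
        objective, x_opt, nll_min, bounds, index, config, threshold, +1.0,
        max_steps, transform,
    )
    mle_point = ProfilePoint(
        _natural(x_opt[index], transform), nll_min, 0.0, True, np.array(x_opt)
    )
    points = list(reversed(pts_lo)) + [mle_point] + pts_hi
    return ProfileResult(
        param=param,
        estimate=_natural(x_opt[index], transform),
        level=level,
        threshold=threshold,
        points=points,
        lower=lower,
        upper=upper,
        lower_status=st_lo,
        upper_status=st_hi,
    )


def profile(
    fit: FitResult,
    data: TitrationDataset,
    param: str,
    level: float = 0.95,
    max_steps: int = 100,
) -> ProfileResult:
    """Profile-likelihood confidence interval for one fitted parameter.

    Re-optimizes all nuisance parameters at each scan value (warm-started
    from the neighbouring point) and interpolates the 2*dNLL = chi2
    crossing. ``param`` is a flat-vector name such as ``"KD"``, ``"EC50"``
    or ``"Fn_B[bio1]"``.
    """
    index = fit.layout.index_of(param)
    objective = make_objective(data, fit.layout)
    return profile_objective(
        objective,
        fit.best_x,
        fit.nll_min,
        fit.bounds,
        index,
        param=param,
        transform=fit.layout.transforms[index],
        level=level,
        config=fit.config,
        max_steps=max_steps,
    )
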