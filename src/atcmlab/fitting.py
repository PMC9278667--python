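"""Constrained fitting of the lookahead-WED exponential dose model.

The dose modulation curve is modelled as

    CTDIvol(z) = a * exp(b * f(WED; z, d)) + c

where f is a convex combination of four order statistics (maximum, third
quartile, median, minimum) of the WED profile over the d reconstruction
slices starting at z towards the scanning direction:

    f = w1*max + w2*Q3 + w3*median + w4*min,   w_i >= 0,  sum w_i = 1.

The lookahead depth d (a non-negative slice count) is found by grid search:
for each candidate d the continuous parameters (a, b, c, w) are estimated
by constrained nonlinear least squares — weights via a softmax
reparameterization on the probability simplex, a kept positive via a log
parameter — and the d minimizing the pooled RMSE is reported, with ties
broken towards smaller d. Multiple curves (e.g. both scanning directions)
can share a single parameter set by pooling their residuals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .atcm_sim import ModulationCurve, lookahead_stats, window_stat_matrix
from .wed import WEDProfile

#: Cap on the exponent b*f to avoid overflow in the model evaluation.
EXP_CAP = 50.0
#: Relative RMSE tolerance within which candidate depths count as tied.
TIE_RTOL = 1e-9


@dataclass(frozen=True)
class FitParams:
    """Parameters of the exponential lookahead model."""

    a: float
    b: float
    c: float
    d: int
    weights: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        if self.d < 0:
            raise ValueError("lookahead depth d must be non-negative")
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (4,):
            raise ValueError("need exactly four weights")
        if abs(w.sum() - 1.0) > 1e-6 or (w < -1e-9).any():
            raise ValueError("weights must be a convex combination")


@dataclass(frozen=True)
class FitResult:
    params: FitParams
    rmse: float
    r2: float
    per_curve_residuals: tuple[np.ndarray, ...]
    d_grid_profile: dict[int, float]
    degenerate: bool = False


def window_stats(profile: WEDProfile, z: float, d: int, direction: str,
                 slice_spacing: float) -> tuple[float, float, float, float]:
    """(max, Q3, median, min) of the WED over the lookahead window at z.

    The window holds the d profile samples starting at z and stepping
    ``slice_spacing`` mm towards the scanning direction (decreasing table
    position for HF, increasing for FH); positions beyond the profile
    contribute air (WED = 0). Quartiles interpolate linearly between order
    statistics.
    """
    if d < 1:
        raise ValueError("window depth d must be at least 1 (empty window)")
    if slice_spacing <= 0:
        raise ValueError("slice_spacing must be positive")
    step = -slice_spacing if direction == "HF" else slice_spacing
    positions = z + step * np.arange(d)
    vals = profile.interp(positions)
    return (float(vals.max()), float(np.quantile(vals, 0.75)),
            float(np.median(vals)), float(vals.min()))


def eval_model(params, f) -> np.ndarray | float:
    """Evaluate a*exp(b*f) + c with the exponent capped at +/-50."""
    if isinstance(params, FitParams):
        a, b, c = params.a, params.b, params.c
    else:
        a, b, c = params
    f = np.asarray(f, dtype=float)
    out = a * np.exp(np.clip(b * f, -EXP_CAP, EXP_CAP)) + c
    return float(out) if out.ndim == 0 else out


def _softmax(u: np.ndarray) -> np.ndarray:
    e = np.exp(np.concatenate([np.clip(u, -30.0, 30.0), [0.0]]))
    return e / e.sum()


def _solve_fixed_d(stats: np.ndarray, y: np.ndarray,
                   x0_list: list[np.ndarray]) -> tuple[np.ndarray, float]:
    """Least squares over x = (u1, u2, u3, log a, b, c) for one depth d."""

    def residual(x):
        w = _softmax(x[:3])
        f = stats @ w
        model = math.exp(x[3]) * np.exp(np.clip(x[4] * f, -EXP_CAP,
                                                EXP_CAP)) + x[5]
        return model - y

    best_x, best_cost = None, np.inf
    for x0 in x0_list:
        sol = least_squares(residual, x0, method="trf", xtol=1e-14,
                            ftol=1e-14, gtol=1e-14, max_nfev=400)
        if sol.cost < best_cost:
            best_x, best_cost = sol.x, sol.cost
    rmse = math.sqrt(2.0 * best_cost / y.size)
    return best_x, rmse


def _initial_guess(stats: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Heuristic start: uniform weights, log-linear regression for a, b."""
    f0 = stats @ np.full(4, 0.25)
    ypos = np.clip(y, 1e-9, None)
    b0, la0 = np.polyfit(f0, np.log(ypos), 1)
    return np.array([0.0, 0.0, 0.0, la0, b0, 0.0])


def _curve_stats(curve: ModulationCurve, profile: WEDProfile,
                 d: int) -> np.ndarray:
    return lookahead_stats(curve.z, profile, d, curve.direction,
                           curve.protocol.recon_thickness)


def fit_model(data, d_candidates=range(1, 41), shared: bool = True
              ) -> FitResult:
    """Fit the lookahead model to one or more (curve, profile) pairs.

    Parameters
    ----------
    data : list of (ModulationCurve, WEDProfile) pairs (a bare pair is
        accepted). Each profile is interpolated onto its curve's slice
        grid; air (WED = 0) pads positions beyond the profile.
    d_candidates : iterable of integer lookahead depths to grid-search.
    shared : pool residuals across all curves into a single parameter set
        (the default). With ``shared=False`` and several curves, a list of
        independent per-curve fits is returned.
    """
    if isinstance(data, tuple) and len(data) == 2 and isinstance(
            data[0], ModulationCurve):
        data = [data]
    data = list(data)
    if not data:
        raise ValueError("need at least one (curve, profile) pair")
    if not shared and len(data) > 1:
        return [fit_model([pair], d_candidates, shared=True)
                for pair in data]

    d_list = sorted({int(d) for d in d_candidates})
    if not d_list or d_list[0] < 1:
        raise ValueError("d candidates must be positive integers")

    ys = [np.asarray(curve.ctdi_vol, dtype=float) for curve, _ in data]
    y = np.concatenate(ys)
    sizes = [yi.size for yi in ys]

    if np.ptp(y) <= 1e-9 * max(1.0, np.abs(y).max()):
        # Flat curve: the exponential slope is unidentifiable; pin b ~ 0.
        d0 = d_list[0]
        params = FitParams(a=0.0, b=0.0, c=float(y.mean()), d=d0,
                           weights=(0.25, 0.25, 0.25, 0.25))
        res = tuple(yi - y.mean() for yi in ys)
        return FitResult(params=params, rmse=float(np.sqrt(np.mean(
            (y - y.mean()) ** 2))), r2=1.0, per_curve_residuals=res,
            d_grid_profile={d0: 0.0}, degenerate=True)

    grid: dict[int, float] = {}
    solutions: dict[int, np.ndarray] = {}
    warm: np.ndarray | None = None
    for d in d_list:
        stats = np.vstack([_curve_stats(curve, profile, d)
                           for curve, profile in data])
        inits = [_initial_guess(stats, y)]
        if warm is not None:
            inits.append(warm)
        x, rmse = _solve_fixed_d(stats, y, inits)
        grid[d] = rmse
        solutions[d] = x
        warm = x

    best_rmse = min(grid.values())
    tol = TIE_RTOL * max(best_rmse, 1e-300)
    best_d = min(d for d, r in grid.items() if r <= best_rmse + tol)
    x = solutions[best_d]
    w = _softmax(x[:3])
    params = FitParams(a=math.exp(x[3]), b=float(x[4]), c=float(x[5]),
                       d=best_d, weights=tuple(float(v) for v in w))

    stats = np.vstack([_curve_stats(curve, profile, best_d)
                       for curve, profile in data])
    model = eval_model((params.a, params.b, params.c), stats @ w)
    resid = model - y
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    per_curve = []
    start = 0
    for n in sizes:
        per_curve.append(resid[start:start + n])
        start += n
    return FitResult(params=params, rmse=grid[best_d], r2=r2,
                     per_curve_residuals=tuple(per_curve),
                     d_grid_profile=grid)


def detect_steps(curve: ModulationCurve, min_step: float
                 ) -> list[tuple[float, float]]:
    """Detect modulation steps in a piecewise-constant dose curve.

    Successive slices are grouped into plateaus by run-length grouping with
    tolerance ``min_step / 2``; an edge is reported wherever adjacent
    plateau levels differ by at least ``min_step``. Each edge is returned
    with the distance to the next edge (the width of the plateau it opens;
    the last edge gets the distance to the end of the scan). Edges are
    placed midway between the bounding slices. Returns an empty list for a
    flat curve.
    """
    if min_step <= 0:
        raise ValueError("min_step must be positive")
    y = np.asarray(curve.ctdi_vol, dtype=float)
    z = np.asarray(curve.z, dtype=float)
    tol = min_step / 2.0
    # run-length plateaus: start a new run when the value leaves the
    # current run's mean by more than tol
    run_means: list[float] = []
    run_last: list[int] = []
    mean, count, start = y[0], 1, 0
    for i in range(1, y.size):
        if abs(y[i] - mean) <= tol:
            count += 1
            mean += (y[i] - mean) / count
        else:
            run_means.append(mean)
            run_last.append(i - 1)
            mean, count = y[i], 1
    run_means.append(mean)
    run_last.append(y.size - 1)

    edges: list[float] = []
    for k in range(1, len(run_means)):
        if abs(run_means[k] - run_means[k - 1]) >= min_step:
            i = run_last[k - 1]
            edges.append(0.5 * (z[i] + z[i + 1]))
    if not edges:
        return []
    out = []
    for k, e in enumerate(edges):
        nxt = edges[k + 1] if k + 1 < len(edges) else z[-1]
        out.append((e, abs(nxt - e)))
    return out


def ctdi_vs_wed(curve: ModulationCurve, profile: WEDProfile) -> pd.DataFrame:
    """Per-slice (WED, CTDIvol) pairs, tagged with the scanning direction.

    The profile is interpolated onto the curve's slice positions when the
    sampling grids differ.
    """
    wed = profile.interp(curve.z)
    return pd.DataFrame({
        "table_position_mm": curve.z,
        "wed_mm": wed,
        "ctdi_vol_mGy": curve.ctdi_vol,
        "direction": curve.direction,
    })
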