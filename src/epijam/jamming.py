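"""Jamming-transition statistics.

Implements the rigid-pack scaling null model (T1 rate independent of
V_rms), the linear R_T1-vs-V_rms relation test with pairs-bootstrap
inference, four-parameter logistic (4PL) fitting for sigmoidal marker
transitions (EC50 reported in hours), and piecewise-linear change-point
estimation for the motility-decline onset.

The rigid-pack argument: if exchanges happen only at interfaces between
coherent packs of size L_c, the interface cell fraction scales as
f_int ~ 1/L_c ~ 1/V_rms while the relative speed of neighboring packs
scales as V_rel ~ V_rms, so R_T1 ~ f_int * V_rel is constant in V_rms. A
nonzero fitted slope of R_T1 on V_rms therefore rejects the rigid-pack
null in favor of distributed, fluid-like rearrangement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .core import T1Event, TrajectorySet
from .kinematics import field_from_vectors, trajectory_velocities, vrms
from .synthetic import four_param_logistic
from .topology import t1_rate

DEFAULT_N_BOOT = 2000


# ---------------------------------------------------------------------------
# rigid-pack null model
# ---------------------------------------------------------------------------

@dataclass
class NullModelPrediction:
    v_rms_grid: np.ndarray
    f_int: np.ndarray            # c1 / V_rms
    v_rel: np.ndarray            # c2 * V_rms
    predicted_rate: np.ndarray   # c1 * c2, constant across the grid
    c1: float
    c2: float


def rigid_pack_prediction(v_rms_grid: np.ndarray,
                          calibration: tuple[float, float],
                          l_c_reference_um: float | None = None) -> NullModelPrediction:
    """Rigid-pack prediction of R_T1 over a V_rms grid.

    The scaling argument fixes only products of constants; a single
    calibration pair (V_rms*, R_T1*) pins the proportionality so that the
    predicted rate equals R_T1* at every V_rms. When ``l_c_reference_um``
    is given, c1 is expressed through f_int = (V_rms*/L_c*)/V_rms so the
    interface fraction has a physical anchor; the prediction is unchanged.
    """
    v = np.asarray(v_rms_grid, dtype=float)
    if np.any(v <= 0):
        raise ValueError("V_rms values must be strictly positive")
    v_star, r_star = calibration
    if v_star <= 0 or r_star < 0:
        raise ValueError("calibration pair must have positive V_rms")
    c1 = (v_star / l_c_reference_um) * v_star if l_c_reference_um else v_star
    c2 = r_star / c1
    f_int = np.minimum(c1 / v, 1.0)  # interface fraction cannot exceed 1
    return NullModelPrediction(v, f_int, c2 * v, np.full_like(v, c1 * c2),
                               float(c1), float(c2))


# ---------------------------------------------------------------------------
# R_T1 vs V_rms relation
# ---------------------------------------------------------------------------

@dataclass
class RateSpeedRelation:
    pairs: pd.DataFrame          # columns v_rms, rate
    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    p_value: float
    n_boot: int
    seed: int
    degenerate: bool = False


def _ols_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    xm, ym = x.mean(), y.mean()
    sxx = np.sum((x - xm) ** 2)
    slope = np.sum((x - xm) * (y - ym)) / sxx
    return float(slope), float(ym - slope * xm)


def rate_speed_test(v_rms: np.ndarray, rate: np.ndarray,
                    n_boot: int = DEFAULT_N_BOOT, seed: int = 0,
                    alpha: float = 0.05) -> RateSpeedRelation:
    """OLS slope of R_T1 on V_rms with resampling-based inference.

    The confidence interval comes from a symmetric studentized pairs
    bootstrap (pairs resampled with replacement; slopes studentized by a
    heteroscedasticity-robust standard error), which is robust to the
    Poisson-like, heteroscedastic bin noise. The two-sided p-value for
    slope = 0 comes from a seeded permutation of the rate values against
    the speeds, which is exact under the no-association null.
    """
    x = np.asarray(v_rms, dtype=float)
    y = np.asarray(rate, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("v_rms and rate must be matching 1-D arrays")
    n = len(x)
    if n < 5:
        raise ValueError("need at least 5 paired observations")
    if np.ptp(x) == 0:
        return RateSpeedRelation(pd.DataFrame({"v_rms": x, "rate": y}),
                                 np.nan, np.nan, (np.nan, np.nan), np.nan,
                                 n_boot, seed, degenerate=True)
    slope, intercept = _ols_slope(x, y)
    xc = x - x.mean()
    sxx = np.sum(xc ** 2)
    resid = y - intercept - slope * x
    se = float(np.sqrt(np.sum(xc ** 2 * resid ** 2)) / sxx)

    rng = np.random.default_rng(seed)
    # symmetric studentized pairs-bootstrap CI
    idx = rng.integers(0, n, size=(n_boot, n))
    xb, yb = x[idx], y[idx]
    xm = xb.mean(axis=1, keepdims=True)
    ym = yb.mean(axis=1, keepdims=True)
    sxxb = np.sum((xb - xm) ** 2, axis=1)
    ok = sxxb > 0
    slopes_b = np.sum((xb - xm) * (yb - ym), axis=1)[ok] / sxxb[ok]
    resid_b = (yb[ok] - ym[ok]) - slopes_b[:, None] * (xb[ok] - xm[ok])
    se_b = np.sqrt(np.sum((xb[ok] - xm[ok]) ** 2 * resid_b ** 2, axis=1)) / sxxb[ok]
    good = se_b > 0
    t_abs = np.abs((slopes_b[good] - slope) / se_b[good])
    q = float(np.percentile(t_abs, 100.0 * (1.0 - alpha)))
    ci = (slope - q * se, slope + q * se)

    # permutation p-value for slope = 0
    perm_slopes = np.empty(n_boot)
    for b in range(n_boot):
        yp = y[rng.permutation(n)]
        perm_slopes[b] = np.sum(xc * (yp - yp.mean())) / sxx
    p = (np.sum(np.abs(perm_slopes) >= abs(slope)) + 1) / (n_boot + 1)
    return RateSpeedRelation(pd.DataFrame({"v_rms": x, "rate": y}),
                             slope, intercept, (float(ci[0]), float(ci[1])),
                             float(min(p, 1.0)), n_boot, seed)


def paired_rate_speed(traj: TrajectorySet, events: list[T1Event],
                      n_cells: int, bin_width_h: float = 3.0,
                      lag: int = 1) -> pd.DataFrame:
    """Time-aligned (V_rms, R_T1) pairs from one movie.

    V_rms per bin pools all per-cell forward-difference velocities whose
    interval starts inside the half-open bin; R_T1 per bin counts events
    per interior cell per hour.
    """
    t, vel = trajectory_velocities(traj, lag=lag)
    t_end = float(traj.times[-1])
    rates = t1_rate(events, n_cells, bin_width_h, t_start=0.0, t_end=t_end)
    rows = []
    for start, end, rate in zip(rates.bin_edges_h[:-1], rates.bin_edges_h[1:],
                                rates.rate):
        sel = (t >= start) & (t < end)
        if not sel.any():
            continue
        block = vel[sel].reshape(-1, 2)
        stats = vrms(field_from_vectors(block))
        rows.append({"t_start_h": start, "t_end_h": end,
                     "v_rms": stats.v_rms_raw, "rate": rate})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# sigmoidal transition fit
# ---------------------------------------------------------------------------

@dataclass
class SigmoidFit:
    bottom: float
    top: float
    logec50: float               # log10 of EC50 (EC50 in hours)
    hill: float
    residual_sd: float
    converged: bool
    extrapolated: bool           # EC50 outside the observed time range

    @property
    def ec50_h(self) -> float:
        return 10.0 ** self.logec50


def fit_sigmoid(times_h: np.ndarray, values: np.ndarray,
                n_starts: int = 8, seed: int = 0) -> SigmoidFit:
    """Four-parameter logistic fit on a log10 time axis.

    Multi-start nonlinear least squares: data-driven initial values for
    bottom/top/EC50 plus seeded jitter and a ladder of hill slopes. Raises
    on constant series (no transition to fit); returns with
    ``converged=False`` if every start fails.
    """
    t = np.asarray(times_h, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.ndim != 1 or t.shape != y.shape:
        raise ValueError("times and values must be matching 1-D arrays")
    if len(t) < 6:
        raise ValueError("need at least 6 points for a 4PL fit")
    if np.any(t <= 0):
        raise ValueError("times must be strictly positive (log-time model)")
    if np.ptp(y) == 0:
        raise ValueError("constant series: no transition to fit")

    order = np.argsort(t)
    t, y = t[order], y[order]
    increasing = y[-1] >= y[0]
    lo, hi = float(y.min()), float(y.max())
    half = 0.5 * (lo + hi)
    cross = np.flatnonzero(np.diff(np.sign(y - half)))
    ec50_guess = float(t[cross[0]]) if cross.size else float(np.median(t))

    rng = np.random.default_rng(seed)
    logt = np.log10(t)

    def resid(p):
        return four_param_logistic(t, *p) - y

    best, best_cost = None, np.inf
    hills = [1.0, 2.0, 4.0, 8.0]
    for s in range(n_starts):
        h0 = hills[s % len(hills)] * (1.0 if increasing else -1.0)
        jitter = rng.normal(0.0, 0.05, size=3) if s >= len(hills) else np.zeros(3)
        p0 = np.array([lo * (1 + jitter[0]), hi * (1 + jitter[1]),
                       np.log10(ec50_guess) + jitter[2], h0])
        try:
            sol = optimize.least_squares(resid, p0, method="lm",
                                         max_nfev=2000)
        except Exception:
            continue
        if sol.cost < best_cost:
            best, best_cost = sol, sol.cost
    if best is None:
        return SigmoidFit(np.nan, np.nan, np.nan, np.nan, np.nan,
                          converged=False, extrapolated=False)
    bottom, top, logec50, hill = best.x
    if hill < 0:  # flip to the canonical orientation
        bottom, top, hill = top, bottom, -hill
    dof = max(len(t) - 4, 1)
    rsd = float(np.sqrt(2 * best.cost / dof))
    extrapolated = not (logt.min() <= logec50 <= logt.max())
    return SigmoidFit(float(bottom), float(top), float(logec50), float(hill),
                      rsd, converged=True, extrapolated=extrapolated)


# ---------------------------------------------------------------------------
# motility-onset change point
# ---------------------------------------------------------------------------

@dataclass
class ChangePoint:
    onset_h: float
    slope_pre: float
    slope_post: float
    ci_h: tuple[float, float]
    at_boundary: bool
    n_boot: int
    seed: int


def _fit_piecewise(t: np.ndarray, y: np.ndarray,
                   candidates: np.ndarray):
    best = (np.inf, np.nan, None)
    for b in candidates:
        design = np.column_stack([np.ones_like(t), t, np.clip(t - b, 0, None)])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        res = y - design @ coef
        sse = float(res @ res)
        if sse < best[0]:
            best = (sse, float(b), coef)
    return best


def detect_onset(times_h: np.ndarray, values: np.ndarray,
                 n_boot: int = 200, seed: int = 0) -> ChangePoint:
    """Two-segment continuous piecewise-linear breakpoint of a time series.

    The breakpoint is found by grid search over interior sample times
    (two points excluded at each end); the CI comes from a seeded residual
    bootstrap. ``at_boundary`` flags best fits at the edge of the candidate
    grid (including effectively slope-less flat series).
    """
    t = np.asarray(times_h, dtype=float)
    y = np.asarray(values, dtype=float)
    if len(t) < 10:
        raise ValueError("need at least 10 points for onset detection")
    order = np.argsort(t)
    t, y = t[order], y[order]
    candidates = t[2:-2]
    sse, onset, coef = _fit_piecewise(t, y, candidates)
    design = np.column_stack([np.ones_like(t), t, np.clip(t - onset, 0, None)])
    fitted = design @ coef
    residuals = y - fitted

    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        yb = fitted + rng.choice(residuals, size=len(t), replace=True)
        _, ob, _ = _fit_piecewise(t, yb, candidates)
        boots.append(ob)
    lo, hi = np.percentile(boots, [2.5, 97.5]) if boots else (np.nan, np.nan)
    # flag fits with no meaningful slope change (e.g. flat series) and best
    # fits at the edge of the candidate grid
    span = float(t[-1] - t[0])
    scale = float(np.ptp(y))
    no_break = scale == 0.0 or abs(coef[2]) * span < 1e-9 * scale
    at_boundary = bool(no_break or onset in (candidates[0], candidates[-1]))
    return ChangePoint(onset, float(coef[1]), float(coef[1] + coef[2]),
                       (float(lo), float(hi)), at_boundary,
                       n_boot, seed)
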