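"""Velocity-field kinematics: PIV, V_rms, spatial velocity correlations and
the correlation length xi_v, and strain-rate decomposition.

V_rms is the root-mean-square of the instantaneous velocity over the field
of view, V_rms = sqrt(<|v|^2>) with <.> the spatial average over valid
vectors. The correlation length xi_v is the 1/e crossing of the normalized,
mean-subtracted, radially averaged velocity autocorrelation.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .core import TrajectorySet


class InsufficientDataError(ValueError):
    """Not enough valid data to compute the requested statistic."""


@dataclass
class VelocityField:
    """Gridded 2-D velocity vectors (µm/h) at one time point.

    ``vectors`` has shape (ny, nx, 2) ordered (vx, vy) in physical (y-up)
    coordinates; grid node (i, j) sits at origin + spacing * (j, i).
    """

    origin_um: tuple[float, float]
    spacing_um: float
    vectors: np.ndarray
    valid: np.ndarray
    time_h: float = 0.0

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.spacing_um <= 0:
            raise ValueError("grid spacing must be positive")
        if self.vectors.shape[:2] != self.valid.shape:
            raise ValueError("vectors and validity mask shapes differ")
        bad = ~np.isfinite(self.vectors).all(axis=-1)
        self.valid = self.valid & ~bad

    def node_positions(self) -> np.ndarray:
        ny, nx = self.valid.shape
        x = self.origin_um[0] + self.spacing_um * np.arange(nx)
        y = self.origin_um[1] + self.spacing_um * np.arange(ny)
        xx, yy = np.meshgrid(x, y)
        return np.stack([xx, yy], axis=-1)

    def valid_vectors(self) -> np.ndarray:
        return self.vectors[self.valid]


@dataclass
class VelocityStats:
    """Scalar motility measures of one velocity field."""

    v_rms: float                 # selected variant (see ``vrms``)
    v_rms_raw: float             # bare formula, no drift correction
    v_rms_mean_subtracted: float
    mean_speed: float
    n_valid: int
    time_h: float


def vrms(field: VelocityField, subtract_mean: bool = False) -> VelocityStats:
    """Root-mean-square velocity of a field.

    The bare statistic sqrt(<|v|^2>) and the drift-corrected variant (with
    the spatial mean velocity removed first) are always co-reported;
    ``subtract_mean`` selects which one ``v_rms`` carries.
    """
    v = field.valid_vectors()
    if v.shape[0] == 0:
        raise InsufficientDataError("no valid vectors")
    sq = np.einsum("ij,ij->i", v, v)
    raw = float(np.sqrt(sq.mean()))
    dv = v - v.mean(axis=0)
    sub = float(np.sqrt(np.einsum("ij,ij->i", dv, dv).mean()))
    return VelocityStats(
        v_rms=sub if subtract_mean else raw,
        v_rms_raw=raw,
        v_rms_mean_subtracted=sub,
        mean_speed=float(np.sqrt(sq).mean()),
        n_valid=int(v.shape[0]),
        time_h=field.time_h,
    )


# ---------------------------------------------------------------------------
# PIV
# ---------------------------------------------------------------------------

def _gaussian_subpixel(cm1: float, c0: float, cp1: float) -> float:
    """3-point Gaussian peak interpolation; parabolic fallback when the
    correlation values are not all positive."""
    if cm1 > 0 and c0 > 0 and cp1 > 0:
        denom = 2.0 * np.log(cm1) - 4.0 * np.log(c0) + 2.0 * np.log(cp1)
        if denom != 0:
            return (np.log(cm1) - np.log(cp1)) / denom
    denom = 2.0 * cm1 - 4.0 * c0 + 2.0 * cp1
    return (cm1 - cp1) / denom if denom != 0 else 0.0


def piv(frame_a: np.ndarray, frame_b: np.ndarray, window: int = 32,
        overlap: float = 0.5, dt_h: float = 1.0, um_per_px: float = 1.0,
        peak_ratio_min: float = 1.2, min_peak_ncc: float = 0.25) -> VelocityField:
    """Single-pass FFT cross-correlation PIV with Gaussian subpixel fit.

    The lag-dependent overlap normalization makes the correlation estimate
    unbiased across the search region. A window is valid only if (a) the
    primary-to-secondary correlation-peak ratio reaches ``peak_ratio_min``
    and (b) the normalized correlation at the peak reaches ``min_peak_ncc``
    (rejects windows that match nothing, e.g. pure noise). Displacements
    are converted from pixel (y-down) to physical y-up coordinates, µm/h.
    """
    a = np.asarray(frame_a, dtype=float)
    b = np.asarray(frame_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("frames must have the same shape")
    if window < 16:
        raise ValueError("window must be >= 16 px")
    if not 0 <= overlap < 1:
        raise ValueError("overlap must lie in [0, 1)")
    if window > min(a.shape):
        raise ValueError("window larger than image")

    step = max(1, int(round(window * (1.0 - overlap))))
    rows = range(0, a.shape[0] - window + 1, step)
    cols = range(0, a.shape[1] - window + 1, step)
    ny, nx = len(list(rows)), len(list(cols))
    vectors = np.zeros((ny, nx, 2))
    valid = np.zeros((ny, nx), dtype=bool)

    pad = 2 * window
    max_disp = window // 2
    # linear-correlation overlap counts, for unbiased normalization
    lag = np.arange(-max_disp, max_disp + 1)
    n_overlap = ((window - np.abs(lag))[:, None]
                 * (window - np.abs(lag))[None, :]).astype(float)
    excl = 3  # second-peak exclusion radius around the primary peak
    for i, r in enumerate(range(0, a.shape[0] - window + 1, step)):
        for j, c in enumerate(range(0, a.shape[1] - window + 1, step)):
            wa = a[r:r + window, c:c + window]
            wb = b[r:r + window, c:c + window]
            wa = wa - wa.mean()
            wb = wb - wb.mean()
            if wa.std() == 0 or wb.std() == 0:
                continue
            corr = np.fft.irfft2(
                np.conj(np.fft.rfft2(wa, s=(pad, pad)))
                * np.fft.rfft2(wb, s=(pad, pad)), s=(pad, pad))
            corr = np.fft.fftshift(corr)
            center = pad // 2
            sl = slice(center - max_disp, center + max_disp + 1)
            region = corr[sl, sl] / n_overlap
            pk = np.unravel_index(np.argmax(region), region.shape)
            peak_val = region[pk]
            if peak_val <= 0:
                continue
            masked = region.copy()
            r0, c0 = pk
            masked[max(0, r0 - excl):r0 + excl + 1,
                   max(0, c0 - excl):c0 + excl + 1] = -np.inf
            second = masked.max()
            ratio = peak_val / second if second > 0 else np.inf
            ncc = peak_val / (wa.std() * wb.std())
            dy = float(pk[0] - max_disp)
            dx = float(pk[1] - max_disp)
            if 0 < pk[0] < region.shape[0] - 1:
                dy += _gaussian_subpixel(region[pk[0] - 1, pk[1]], peak_val,
                                         region[pk[0] + 1, pk[1]])
            if 0 < pk[1] < region.shape[1] - 1:
                dx += _gaussian_subpixel(region[pk[0], pk[1] - 1], peak_val,
                                         region[pk[0], pk[1] + 1])
            vectors[i, j] = (dx * um_per_px / dt_h,
                             -dy * um_per_px / dt_h)  # y-down px -> y-up µm
            valid[i, j] = ratio >= peak_ratio_min and ncc >= min_peak_ncc

    origin = ((window / 2.0) * um_per_px, (window / 2.0) * um_per_px)
    return VelocityField(origin_um=origin, spacing_um=step * um_per_px,
                         vectors=vectors, valid=valid)


# ---------------------------------------------------------------------------
# velocity correlation and xi_v
# ---------------------------------------------------------------------------

class XiStatus(str, Enum):
    OK = "ok"
    NO_CROSSING = "no_crossing"
    INSUFFICIENT_DATA = "insufficient_data"


@dataclass
class CorrelationProfile:
    """Radially averaged velocity autocorrelation C(r) and its 1/e length."""

    r_um: np.ndarray
    c: np.ndarray
    counts: np.ndarray
    xi_v_um: float
    status: XiStatus

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"r_um": self.r_um, "c": self.c,
                             "n_pairs": self.counts})


def _pair_accumulate(points: np.ndarray, dv: np.ndarray, edges: np.ndarray,
                     chunk: int = 512):
    """Binned sums of dv_i . dv_j over all ordered pairs (incl. i = j)."""
    n_bins = len(edges) - 1
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    n = len(points)
    for start in range(0, n, chunk):
        p = points[start:start + chunk]
        d = dv[start:start + chunk]
        dist = np.hypot(p[:, None, 0] - points[None, :, 0],
                        p[:, None, 1] - points[None, :, 1])
        dots = d @ dv.T
        idx = np.searchsorted(edges, dist.ravel(), side="right") - 1
        ok = (idx >= 0) & (idx < n_bins)
        sums += np.bincount(idx[ok], weights=dots.ravel()[ok],
                            minlength=n_bins)
        counts += np.bincount(idx[ok], minlength=n_bins)
    return sums, counts


def velocity_correlation(fields, r_max: float | None = None,
                         bin_width: float | None = None,
                         min_filled_fraction: float = 0.5,
                         subtract_mean: bool = True) -> CorrelationProfile:
    """Radially averaged spatial autocorrelation of velocity fluctuations.

    C(r) = <dv(x) . dv(x + r)> / <|dv|^2>, with dv the per-field
    mean-subtracted velocity, accumulated over all ordered node pairs
    (including self-pairs, so the zero-distance bin is exactly 1). The
    correlation length xi_v is the linearly interpolated first crossing of
    C(r) = 1/e; if C never reaches 1/e within r_max the status is
    ``no_crossing``.
    """
    if isinstance(fields, VelocityField):
        fields = [fields]
    field0 = fields[0]
    extent = (max(field0.valid.shape) - 1) * field0.spacing_um
    if r_max is None:
        r_max = extent / 2.0
    if r_max > extent / 2.0 + 1e-9:
        raise ValueError("r_max must not exceed half the field extent")
    if bin_width is None:
        bin_width = field0.spacing_um / 2.0
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    n_bins = len(edges) - 1

    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    norm_sum, norm_n = 0.0, 0
    for field in fields:
        v = field.valid_vectors()
        if v.shape[0] < 2:
            continue
        pts = field.node_positions()[field.valid]
        dv = v - v.mean(axis=0) if subtract_mean else v
        s, c = _pair_accumulate(pts, dv, edges)
        sums += s
        counts += c
        norm_sum += float(np.einsum("ij,ij->", dv, dv))
        norm_n += dv.shape[0]

    centers = 0.5 * (edges[:-1] + edges[1:])
    if norm_n < 2 or norm_sum / max(norm_n, 1) < 1e-24:
        return CorrelationProfile(centers, np.full(n_bins, np.nan), counts,
                                  np.nan, XiStatus.INSUFFICIENT_DATA)
    norm = norm_sum / norm_n
    with np.errstate(invalid="ignore"):
        c_of_r = np.where(counts > 0, sums / np.maximum(counts, 1) / norm,
                          np.nan)
    if np.mean(counts > 0) < min_filled_fraction:
        return CorrelationProfile(centers, c_of_r, counts, np.nan,
                                  XiStatus.INSUFFICIENT_DATA)

    target = 1.0 / np.e
    xi, status = np.nan, XiStatus.NO_CROSSING
    filled = np.flatnonzero(counts > 0)
    for a, b in zip(filled[:-1], filled[1:]):
        if c_of_r[a] >= target >= c_of_r[b]:
            frac = (c_of_r[a] - target) / (c_of_r[a] - c_of_r[b])
            xi = float(centers[a] + frac * (centers[b] - centers[a]))
            status = XiStatus.OK
            break
    return CorrelationProfile(centers, c_of_r, counts, xi, status)


# ---------------------------------------------------------------------------
# strain rates
# ---------------------------------------------------------------------------

@dataclass
class StrainRateField:
    """Isotropic rate and deviatoric magnitude (1/h) on the velocity grid."""

    origin_um: tuple[float, float]
    spacing_um: float
    isotropic: np.ndarray        # 0.5 * tr(E)
    deviatoric: np.ndarray       # Frobenius norm of traceless E (default)
    valid: np.ndarray


def strain_rate(field: VelocityField, half_width: int = 1,
                min_points: int = 6,
                deviatoric_convention: str = "frobenius") -> StrainRateField:
    """Local least-squares velocity gradient and its decomposition.

    At each node the velocity gradient G is fitted over the
    (2*half_width+1)^2 neighborhood; E = (G + G^T)/2. The isotropic rate is
    tr(E)/2; the deviatoric magnitude is the Frobenius norm of the traceless
    part (convention ``frobenius``) or the maximum shear rate, the largest
    eigenvalue of the traceless part (convention ``max_shear``). Nodes with
    fewer than ``min_points`` valid neighbors are flagged invalid.
    """
    if deviatoric_convention not in ("frobenius", "max_shear"):
        raise ValueError("deviatoric_convention must be frobenius or max_shear")
    ny, nx = field.valid.shape
    pos = field.node_positions()
    iso = np.full((ny, nx), np.nan)
    dev = np.full((ny, nx), np.nan)
    out_valid = np.zeros((ny, nx), dtype=bool)
    h = half_width
    for i in range(ny):
        for j in range(nx):
            sl_i = slice(max(0, i - h), min(ny, i + h + 1))
            sl_j = slice(max(0, j - h), min(nx, j + h + 1))
            m = field.valid[sl_i, sl_j]
            if m.sum() < min_points:
                continue
            p = pos[sl_i, sl_j][m] - pos[i, j]
            v = field.vectors[sl_i, sl_j][m]
            design = np.column_stack([np.ones(len(p)), p[:, 0], p[:, 1]])
            coef, *_ = np.linalg.lstsq(design, v, rcond=None)
            grad = coef[1:].T          # G[a, b] = d v_a / d x_b
            e = 0.5 * (grad + grad.T)
            tr = e[0, 0] + e[1, 1]
            dev_t = e - 0.5 * tr * np.eye(2)
            iso[i, j] = 0.5 * tr
            if deviatoric_convention == "frobenius":
                dev[i, j] = float(np.sqrt((dev_t ** 2).sum()))
            else:
                dev[i, j] = float(np.abs(np.linalg.eigvalsh(dev_t)).max())
            out_valid[i, j] = True
    return StrainRateField(field.origin_um, field.spacing_um, iso, dev,
                           out_valid)


# ---------------------------------------------------------------------------
# trajectory-based velocities and V_rms time course
# ---------------------------------------------------------------------------

def trajectory_velocities(traj: TrajectorySet, lag: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Forward-difference velocities over ``lag`` frames.

    Returns (times at interval starts, velocities[n_frames - lag, n_cells, 2]).
    """
    times, _, pos = traj.position_array()
    if len(times) <= lag:
        raise InsufficientDataError("not enough frames for the requested lag")
    disp = traj.minimum_image(pos[lag:] - pos[:-lag])
    dt = (times[lag:] - times[:-lag])[:, None, None]
    return times[:-lag], disp / dt


def field_from_vectors(vectors: np.ndarray, time_h: float = 0.0,
                       spacing_um: float = 1.0) -> VelocityField:
    """Wrap an (n, 2) or (ny, nx, 2) vector array as a VelocityField."""
    vectors = np.asarray(vectors, dtype=float)
    if vectors.ndim == 2:
        vectors = vectors[None, :, :]
    return VelocityField((0.0, 0.0), spacing_um, vectors,
                         np.ones(vectors.shape[:2], dtype=bool), time_h)


def vrms_timecourse(traj: TrajectorySet, window: int = 4,
                    subtract_mean: bool = False, lag: int = 1):
    """Sliding-window V_rms over a trajectory, windows half-open [t, t+w).

    Returns a pandas DataFrame with window start/center times and V_rms.
    """
    import pandas as pd

    t, vel = trajectory_velocities(traj, lag=lag)
    n = len(t)
    if n < window:
        raise InsufficientDataError("fewer velocity frames than the window")
    rows = []
    for s in range(0, n - window + 1):
        block = vel[s:s + window].reshape(-1, 2)
        stats = vrms(field_from_vectors(block), subtract_mean=subtract_mean)
        rows.append({
            "t_start_h": t[s],
            "t_center_h": 0.5 * (t[s] + t[s + window - 1]),
            "v_rms": stats.v_rms,
            "v_rms_raw": stats.v_rms_raw,
            "v_rms_mean_subtracted": stats.v_rms_mean_subtracted,
            "mean_speed": stats.mean_speed,
            "n_valid": stats.n_valid,
        })
    return pd.DataFrame(rows)
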