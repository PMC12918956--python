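"""Fluorescence quantification: junction-to-cytoplasm contrast,
cytoplasmic-to-nuclear ratio, puncta density, and control-normalized
intensities.

Per-cell compartments (junction band, cytoplasm, nucleus) are derived from
a cell label mask and an optional nucleus mask; ratios default to
per-cell-then-average, with pooled-pixel aggregation available by flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

#: floor for background-corrected means, so ratios stay positive
EPS_INTENSITY = 1e-9
DEFAULT_JUNCTION_WIDTH_PX = 3


@dataclass
class CompartmentMasks:
    """Per-cell junction band / cytoplasm / nucleus pixel masks."""

    cell_ids: list
    junction: dict               # cell id -> boolean mask
    cytoplasm: dict
    nucleus: dict
    um_per_px: float

    def validate_disjoint(self) -> None:
        for cid in self.cell_ids:
            j = self.junction.get(cid)
            c = self.cytoplasm.get(cid)
            n = self.nucleus.get(cid)
            for a, b in ((j, c), (j, n), (c, n)):
                if a is not None and b is not None and (a & b).any():
                    raise ValueError(f"cell {cid}: compartments overlap")


def compartment_masks(label_mask: np.ndarray,
                      nucleus_mask: np.ndarray | None = None,
                      junction_width_px: int = DEFAULT_JUNCTION_WIDTH_PX,
                      um_per_px: float = 1.0) -> CompartmentMasks:
    """Split each labeled cell into junction band, cytoplasm, and nucleus.

    The junction band is the set of cell pixels within ``junction_width_px``
    of the cell boundary; the nucleus (where a mask is supplied) is removed
    from both band and cytoplasm so compartments are pairwise disjoint.
    """
    labels = [int(v) for v in np.unique(label_mask) if v > 0]
    junction, cytoplasm, nucleus = {}, {}, {}
    for lab in labels:
        cell = label_mask == lab
        dist_in = ndimage.distance_transform_edt(cell)
        band = cell & (dist_in <= junction_width_px)
        nuc = np.zeros_like(cell)
        if nucleus_mask is not None:
            nuc = cell & (np.asarray(nucleus_mask) > 0) & ~band
        junction[lab] = band
        nucleus[lab] = nuc
        cytoplasm[lab] = cell & ~band & ~nuc
    return CompartmentMasks(labels, junction, cytoplasm, nucleus, um_per_px)


# ---------------------------------------------------------------------------
# intensity ratios
# ---------------------------------------------------------------------------

@dataclass
class IntensityRatios:
    cell_ids: np.ndarray
    per_cell_ratio: np.ndarray
    mean_ratio: float            # mean of per-cell ratios (default summary)
    pooled_ratio: float          # ratio of pooled-pixel means
    background: float
    background_method: str
    n_excluded: int
    floored: bool                # a corrected mean hit the positivity floor


def estimate_background(image: np.ndarray,
                        background_mask: np.ndarray | None = None) -> tuple[float, str]:
    if background_mask is not None and np.asarray(background_mask).any():
        return float(np.median(image[np.asarray(background_mask) > 0])), "region_median"
    return float(np.percentile(image, 1.0)), "percentile_1"


def _compartment_ratio(image: np.ndarray, masks: CompartmentMasks,
                       num_key: str, den_key: str,
                       background_mask: np.ndarray | None) -> IntensityRatios:
    image = np.asarray(image, dtype=float)
    bg, method = estimate_background(image, background_mask)
    ids, ratios = [], []
    num_sum = den_sum = 0.0
    num_n = den_n = 0
    excluded = 0
    floored = False
    for cid in masks.cell_ids:
        num_mask = getattr(masks, num_key)[cid]
        den_mask = getattr(masks, den_key)[cid]
        if not num_mask.any() or not den_mask.any():
            excluded += 1
            continue
        num = image[num_mask].mean() - bg
        den = image[den_mask].mean() - bg
        if num <= 0 or den <= 0:
            floored = True
        num = max(num, EPS_INTENSITY)
        den = max(den, EPS_INTENSITY)
        ids.append(cid)
        ratios.append(num / den)
        num_sum += image[num_mask].sum() - bg * num_mask.sum()
        den_sum += image[den_mask].sum() - bg * den_mask.sum()
        num_n += int(num_mask.sum())
        den_n += int(den_mask.sum())
    if not ids:
        raise ValueError("no cell with both compartments nonempty")
    pooled = (max(num_sum / num_n, EPS_INTENSITY)
              / max(den_sum / den_n, EPS_INTENSITY))
    ratios = np.asarray(ratios)
    return IntensityRatios(np.asarray(ids), ratios, float(ratios.mean()),
                           float(pooled), bg, method, excluded, floored)


def junction_contrast(image: np.ndarray, masks: CompartmentMasks,
                      background_mask: np.ndarray | None = None) -> IntensityRatios:
    """Background-corrected junction-band / cytoplasm intensity ratio,
    per cell and pooled (E-cadherin junctional contrast)."""
    return _compartment_ratio(image, masks, "junction", "cytoplasm",
                              background_mask)


def cyto_nuclear_ratio(image: np.ndarray, masks: CompartmentMasks,
                       background_mask: np.ndarray | None = None,
                       invert: bool = False) -> IntensityRatios:
    """Background-corrected cytoplasmic-to-nuclear intensity ratio (as the
    YAP readout is printed); ``invert=True`` gives nuclear-to-cytoplasmic."""
    if invert:
        return _compartment_ratio(image, masks, "nucleus", "cytoplasm",
                                  background_mask)
    return _compartment_ratio(image, masks, "cytoplasm", "nucleus",
                              background_mask)


# ---------------------------------------------------------------------------
# puncta detection
# ---------------------------------------------------------------------------

@dataclass
class PunctaResult:
    centroids_px: np.ndarray     # (n, 2) as (row, col)
    count: int
    density_per_um2: float
    area_um2: float
    threshold: float
    spot_sigma_px: float
    saturated: bool


def puncta_density(image: np.ndarray, region_mask: np.ndarray | None = None,
                   spot_scale_px: float = 2.0, um_per_px: float = 1.0,
                   min_separation_px: int | None = None,
                   mad_factor: float = 5.0,
                   saturation_level: float | None = None) -> PunctaResult:
    """Scale-matched puncta (vesicle) detection and density.

    Band-passes the image with a difference of Gaussians at the spot scale,
    then keeps local maxima above median + ``mad_factor`` x MAD of the
    band-passed image (robust to cell-to-cell brightness variation).
    Density is count / analyzed area, exactly.
    """
    from skimage.feature import peak_local_max

    if spot_scale_px < 2:
        raise ValueError("spot scale must be >= 2 px")
    image = np.asarray(image, dtype=float)
    region = (np.ones(image.shape, dtype=bool) if region_mask is None
              else np.asarray(region_mask) > 0)
    saturated = False
    if saturation_level is not None and (image >= saturation_level).mean() > 0.001:
        saturated = True

    bandpass = (ndimage.gaussian_filter(image, spot_scale_px / np.sqrt(2.0))
                - ndimage.gaussian_filter(image, spot_scale_px * np.sqrt(2.0)))
    inside = bandpass[region]
    med = float(np.median(inside))
    mad = float(np.median(np.abs(inside - med)))
    threshold = med + mad_factor * max(mad, EPS_INTENSITY)
    if min_separation_px is None:
        min_separation_px = max(1, int(round(2 * spot_scale_px)))
    peaks = peak_local_max(bandpass, min_distance=min_separation_px,
                           threshold_abs=threshold, exclude_border=False,
                           labels=region.astype(int))
    area_um2 = float(region.sum()) * um_per_px ** 2
    return PunctaResult(np.asarray(peaks, dtype=float).reshape(-1, 2),
                        len(peaks), len(peaks) / area_um2, area_um2,
                        threshold, spot_scale_px, saturated)


# ---------------------------------------------------------------------------
# control normalization
# ---------------------------------------------------------------------------

@dataclass
class FoldChange:
    fold_change: float
    ci: tuple[float, float]
    n_treated: int
    n_control: int
    n_boot: int
    seed: int


def normalize_to_control(treated: np.ndarray, control: np.ndarray,
                         n_boot: int = 2000, seed: int = 0,
                         alpha: float = 0.05) -> FoldChange:
    """Ratio of group mean intensities with a seeded bootstrap CI."""
    treated = np.asarray(treated, dtype=float)
    control = np.asarray(control, dtype=float)
    if treated.size == 0 or control.size == 0:
        raise ValueError("both groups must be nonempty")
    if control.mean() == 0:
        raise ValueError("control group mean is zero")
    fc = float(treated.mean() / control.mean())
    rng = np.random.default_rng(seed)
    ti = rng.integers(0, treated.size, size=(n_boot, treated.size))
    ci_idx = rng.integers(0, control.size, size=(n_boot, control.size))
    boot = treated[ti].mean(axis=1) / control[ci_idx].mean(axis=1)
    lo, hi = np.percentile(boot, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return FoldChange(fc, (float(lo), float(hi)), treated.size, control.size,
                      n_boot, seed)
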