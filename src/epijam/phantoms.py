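"""Phantom images with exact ground truth.

Two kinds of fixture: textured phase-contrast-like frame pairs advected by
a known displacement field (for PIV validation), and fluorescence phantoms
with junction / cytoplasm / nucleus / puncta structure (for intensity-ratio
and puncta-density validation). Pixel arrays are y-down; ground truth is
stored in pixel units unless stated otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import TrajectorySet


# ---------------------------------------------------------------------------
# textured advection pairs (PIV fixtures)
# ---------------------------------------------------------------------------

def random_texture(shape: tuple[int, int], seed: int = 0,
                   smooth_px: float = 2.0, contrast: float = 50.0,
                   offset: float = 100.0) -> np.ndarray:
    """Smooth random texture emulating a speckled phase-contrast field."""
    rng = np.random.default_rng(seed)
    img = rng.normal(size=shape)
    img = ndimage.gaussian_filter(img, smooth_px)
    img = (img - img.mean()) / img.std()
    return offset + contrast * img


def advect_texture(texture: np.ndarray, displacement_px: np.ndarray,
                   noise_sigma: float = 0.0, seed: int = 0) -> np.ndarray:
    """Second frame of a pair: the texture advected by a per-pixel
    displacement field (dx, dy in pixel axes, shape (H, W, 2)).

    Integer uniform shifts are applied exactly (periodic roll); anything
    else is resampled with cubic splines.
    """
    disp = np.asarray(displacement_px, dtype=float)
    if disp.shape != texture.shape + (2,):
        raise ValueError("displacement field must be (H, W, 2)")
    dx, dy = disp[..., 0], disp[..., 1]
    if (np.ptp(dx) == 0 and np.ptp(dy) == 0
            and float(dx.flat[0]).is_integer() and float(dy.flat[0]).is_integer()):
        out = np.roll(texture, (int(dy.flat[0]), int(dx.flat[0])),
                      axis=(0, 1))
    else:
        yy, xx = np.mgrid[0:texture.shape[0], 0:texture.shape[1]]
        out = ndimage.map_coordinates(texture, [yy - dy, xx - dx],
                                      order=3, mode="wrap")
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        out = out + rng.normal(0.0, noise_sigma, size=out.shape)
    return out


def render_phantom_pair(traj: TrajectorySet, frame_a: int, frame_b: int,
                        um_per_px: float = 1.0, shape: tuple[int, int] | None = None,
                        texture_seed: int = 0, smooth_px: float = 2.0,
                        noise_sigma: float = 0.0,
                        piv_window_px: int = 32):
    """Frame pair whose second image is the first advected by the smoothed
    cell displacement field between two trajectory frames.

    Returns (image_a, image_b, displacement_px) where the last is the
    ground-truth per-pixel displacement in pixel axes (y-down). Refuses
    displacements exceeding a quarter of the PIV window.
    """
    if shape is None:
        npx = int(round(traj.box_size / um_per_px))
        shape = (npx, npx)
    ids_a, pa = traj.positions(frame_a)
    ids_b, pb = traj.positions(frame_b)
    if not np.array_equal(ids_a, ids_b):
        raise ValueError("frames must contain the same cells")
    disp_um = traj.minimum_image(pb - pa)
    max_disp_px = np.abs(disp_um).max() / um_per_px
    if max_disp_px > piv_window_px / 4.0:
        raise ValueError(
            f"max displacement {max_disp_px:.1f} px exceeds a quarter of the "
            f"PIV window ({piv_window_px} px); reduce the frame gap")

    # smooth displacement field on the pixel grid (y-down: row = box_y - y)
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]].astype(float)
    px = pa[:, 0] / um_per_px
    py = (traj.box_size - pa[:, 1]) / um_per_px
    disp_field = np.zeros(shape + (2,))
    sigma_px = 0.35 * traj.box_size / np.sqrt(len(ids_a)) / um_per_px
    for comp, sign, val in ((0, 1.0, disp_um[:, 0]),
                            (1, -1.0, disp_um[:, 1])):
        num = np.zeros(shape)
        den = np.zeros(shape)
        for x0, y0, v in zip(px, py, val):
            w = np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2) / (2 * sigma_px ** 2))
            num += w * sign * v / um_per_px
            den += w
        disp_field[..., comp] = num / np.maximum(den, 1e-12)

    img_a = random_texture(shape, seed=texture_seed, smooth_px=smooth_px)
    img_b = advect_texture(img_a, disp_field, noise_sigma=noise_sigma,
                           seed=texture_seed + 1)
    return img_a, img_b, disp_field


# ---------------------------------------------------------------------------
# fluorescence phantoms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FluorescencePhantomSpec:
    """Layout and intensity structure of a fluorescence phantom."""

    shape_px: tuple[int, int] = (256, 256)
    um_per_px: float = 0.5
    n_cells: int = 16
    background_margin_px: int = 6
    junction_width_px: int = 3
    background_level: float = 0.0
    cytoplasm_level: float = 100.0
    junction_level: float = 200.0
    nucleus_level: float = 0.0
    nucleus_radius_px: float = 10.0
    n_puncta: int = 0
    puncta_amplitude: float = 300.0
    puncta_sigma_px: float = 2.0
    puncta_min_sep_px: float = 8.0
    noise_sigma: float = 0.0
    seed: int = 0


@dataclass
class PhantomImage:
    """Rendered phantom plus its masks and recomputable ground truth."""

    image: np.ndarray
    label_mask: np.ndarray
    nucleus_mask: np.ndarray
    um_per_px: float
    truth: dict = field(default_factory=dict)


def _voronoi_labels(shape: tuple[int, int], n_cells: int,
                    rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Label mask from nearest-seed (Voronoi) assignment; labels 1..n."""
    from scipy.spatial import cKDTree

    m = int(np.ceil(np.sqrt(n_cells)))
    sy, sx = shape[0] / m, shape[1] / m
    sites = []
    for i in range(m):
        for j in range(m):
            sites.append(((i + 0.5) * sy, (j + 0.5) * sx))
    sites = np.asarray(sites)[:n_cells]
    sites = sites + rng.normal(0.0, 0.15 * min(sy, sx), size=sites.shape)
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    _, idx = cKDTree(sites).query(np.column_stack([yy.ravel(), xx.ravel()]))
    return (idx.reshape(shape) + 1).astype(np.int32), sites


def junction_band_masks(label_mask: np.ndarray,
                        width_px: int) -> np.ndarray:
    """Boolean mask of the junction band: pixels of each cell within
    ``width_px`` of that cell's boundary."""
    band = np.zeros(label_mask.shape, dtype=bool)
    for lab in np.unique(label_mask):
        if lab <= 0:
            continue
        cell = label_mask == lab
        dist_in = ndimage.distance_transform_edt(cell)
        band |= cell & (dist_in <= width_px)
    return band


def render_fluorescence_phantom(spec: FluorescencePhantomSpec) -> PhantomImage:
    """Render a junction/cytoplasm/nucleus/puncta phantom.

    The stored ground truth (intensity levels, expected ratios, puncta
    coordinates and density) is recomputable from the spec. Puncta that
    cannot be placed ``puncta_min_sep_px`` apart set a crowding warning
    flag in the truth record.
    """
    rng = np.random.default_rng(spec.seed)
    labels, sites = _voronoi_labels(spec.shape_px, spec.n_cells, rng)
    if spec.background_margin_px > 0:
        m = spec.background_margin_px
        labels[:m, :] = 0
        labels[-m:, :] = 0
        labels[:, :m] = 0
        labels[:, -m:] = 0
    band = junction_band_masks(labels, spec.junction_width_px)

    nucleus = np.zeros(spec.shape_px, dtype=bool)
    yy, xx = np.mgrid[0:spec.shape_px[0], 0:spec.shape_px[1]]
    for (cy, cx) in sites:
        nucleus |= ((yy - cy) ** 2 + (xx - cx) ** 2
                    <= spec.nucleus_radius_px ** 2)
    nucleus &= ~band  # compartments stay pairwise disjoint

    image = np.full(spec.shape_px, spec.background_level, dtype=float)
    image[labels > 0] = spec.cytoplasm_level
    image[band] = spec.junction_level
    if spec.nucleus_level:
        image[nucleus] = spec.nucleus_level

    puncta: list[tuple[float, float]] = []
    crowded = False
    if spec.n_puncta > 0:
        margin = 4 * spec.puncta_sigma_px
        for _ in range(spec.n_puncta):
            placed = False
            for _try in range(200):
                py = rng.uniform(margin, spec.shape_px[0] - margin)
                px = rng.uniform(margin, spec.shape_px[1] - margin)
                if all((py - q[0]) ** 2 + (px - q[1]) ** 2
                       >= spec.puncta_min_sep_px ** 2 for q in puncta):
                    puncta.append((py, px))
                    placed = True
                    break
            if not placed:
                crowded = True
                warnings.warn("puncta crowding limit reached", stacklevel=2)
                break
        for (py, px) in puncta:
            image += spec.puncta_amplitude * np.exp(
                -((yy - py) ** 2 + (xx - px) ** 2)
                / (2 * spec.puncta_sigma_px ** 2))

    if spec.noise_sigma > 0:
        image = image + rng.normal(0.0, spec.noise_sigma, size=image.shape)

    area_um2 = spec.shape_px[0] * spec.shape_px[1] * spec.um_per_px ** 2
    cyt = spec.cytoplasm_level - spec.background_level
    jun = spec.junction_level - spec.background_level
    nuc = spec.nucleus_level - spec.background_level
    truth = {
        "junction_level": spec.junction_level,
        "cytoplasm_level": spec.cytoplasm_level,
        "nucleus_level": spec.nucleus_level,
        "background_level": spec.background_level,
        "junction_cytoplasm_ratio": jun / cyt if cyt else np.nan,
        "cyto_nuclear_ratio": cyt / nuc if nuc else np.nan,
        "puncta_yx_px": [list(p) for p in puncta],
        "puncta_count": len(puncta),
        "puncta_density_per_um2": len(puncta) / area_um2,
        "crowding_warning": crowded,
    }
    return PhantomImage(image, labels, nucleus, spec.um_per_px, truth)
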