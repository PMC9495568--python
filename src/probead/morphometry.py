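"""Bead-micrograph morphometry.

Quantifies 8-bit grayscale micrographs of encapsulation beads the way an
ImageJ/FracLac workflow does: threshold binarization; size and shape
descriptors (area, perimeter, circularity, solidity) of the bead
silhouette; skeletonization of the internal network; gray-level
co-occurrence matrix (GLCM) texture features; box-counting fractal
dimension and gliding-box lacunarity of binary patterns; and the
shifting differential box-counting (SDBC) fractal dimension of the
grayscale intensity surface.

Feature definitions (G gray levels, symmetric normalised GLCM p):

    asm      = sum p^2
    contrast = sum (i - j)^2 p
    idm      = sum p / (1 + (i - j)^2)
    entropy  = -sum p ln p            (0 ln 0 := 0; log2 optional)
    corr     = sum (i - mu_i)(j - mu_j) p / (sigma_i sigma_j)
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage import measure, morphology

__all__ = [
    "ShapeDescriptors",
    "GLCMFeatures",
    "FractalFit",
    "LacunarityResult",
    "binarize_threshold",
    "shape_descriptors",
    "skeletonize_mask",
    "glcm_features",
    "boxcount_dimension",
    "gliding_box_lacunarity",
    "sdbc_dimension",
    "feature_row",
]

DEFAULT_ANGLES = (0.0, 45.0, 90.0, 135.0)
DEFAULT_LACUNARITY_SIZES = (2, 4, 8, 16)


@dataclass(frozen=True)
class ShapeDescriptors:
    area: float  # um^2
    perimeter: float  # um
    circularity: float  # 4*pi*A/P^2, capped at 1
    solidity: float  # area / convex hull area


@dataclass(frozen=True)
class GLCMFeatures:
    asm: float
    contrast: float
    correlation: float  # nan when undefined (constant image)
    idm: float
    entropy: float
    levels: int
    distance: int
    angles: tuple[float, ...]

    @property
    def correlation_defined(self) -> bool:
        return not np.isnan(self.correlation)


@dataclass(frozen=True)
class FractalFit:
    """A log-log box-count regression: N(s) ~ s^-D."""

    dimension: float
    sizes: tuple[int, ...]
    counts: tuple[float, ...]
    r2: float

    def __float__(self) -> float:
        return self.dimension


@dataclass(frozen=True)
class LacunarityResult:
    value: float  # mean of lambda(r) over sizes
    per_size: dict[int, float]

    def __float__(self) -> float:
        return self.value


# ---------------------------------------------------------------------------
# binarization and shape


def binarize_threshold(img: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Pixel true iff lo <= intensity <= hi."""
    if not 0 <= lo <= hi <= 255:
        raise ValueError("need 0 <= lo <= hi <= 255")
    img = np.asarray(img)
    return (img >= lo) & (img <= hi)


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(mask, structure=ndimage.generate_binary_structure(2, 2))
    if n == 0:
        raise ValueError("mask is empty")
    if n == 1:
        return mask.astype(bool)
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    return labels == (int(np.argmax(sizes)) + 1)


def _chain_perimeter(comp: np.ndarray) -> float:
    """Plain 8-neighbour boundary-chain length (1 axial, sqrt(2) diagonal)."""
    m = np.pad(comp, 1)
    if comp.sum() == 1:
        return 4.0  # degenerate: unit-square boundary
    bnd = m & ~ndimage.binary_erosion(m)
    ys, xs = np.nonzero(bnd)
    order = np.lexsort((xs, ys))
    start = (int(ys[order][0]), int(xs[order][0]))
    dirs = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]
    length = 0.0
    cur, prev_dir = start, 6
    for _ in range(8 * m.size):
        for k in range(8):
            d = (prev_dir + 6 + k) % 8
            ny, nx = cur[0] + dirs[d][0], cur[1] + dirs[d][1]
            if m[ny, nx]:
                length += 1.0 if d % 2 == 0 else np.sqrt(2.0)
                cur, prev_dir = (ny, nx), d
                break
        else:
            return 4.0  # isolated pixel fallback
        if cur == start:
            return length
    return length


def shape_descriptors(
    mask: np.ndarray,
    pixel_size: float = 1.0,
    perimeter_method: str = "crofton",
    fill_holes: bool = False,
) -> ShapeDescriptors:
    """Size/shape of the largest 8-connected component.

    Perimeter defaults to the 4-direction Crofton estimator, which is
    close to unbiased on rasterized discs (a plain boundary chain
    overestimates a digital circle's perimeter by ~5%, which would bias
    circularity low); ``perimeter_method="chain"`` gives the plain
    weighted chain.  ``fill_holes`` closes interior texture holes before
    measuring, the usual step when the mask comes from thresholding a
    textured micrograph.  Circularity ``4 pi A / P^2`` is capped at 1.
    """
    comp = _largest_component(np.asarray(mask, dtype=bool))
    if fill_holes:
        comp = ndimage.binary_fill_holes(comp)
    area_px = float(comp.sum())
    if perimeter_method == "crofton":
        perim_px = float(measure.perimeter_crofton(comp, directions=4))
    elif perimeter_method == "chain":
        perim_px = _chain_perimeter(comp)
    else:
        raise ValueError(f"unknown perimeter_method: {perimeter_method!r}")
    hull = morphology.convex_hull_image(comp)
    solidity = area_px / float(hull.sum())
    circ = 1.0 if perim_px == 0 else min(1.0, 4.0 * np.pi * area_px / perim_px**2)
    return ShapeDescriptors(
        area=area_px * pixel_size**2,
        perimeter=perim_px * pixel_size,
        circularity=circ,
        solidity=solidity,
    )


def skeletonize_mask(mask: np.ndarray) -> np.ndarray:
    """One-pixel-wide topology-preserving skeleton (iterative thinning)."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    return morphology.skeletonize(mask)


# ---------------------------------------------------------------------------
# GLCM texture


def _quantize(img: np.ndarray, levels: int) -> np.ndarray:
    return (np.asarray(img, dtype=np.int64) * levels) // 256


_ANGLE_OFFSETS = {0.0: (0, 1), 45.0: (-1, 1), 90.0: (-1, 0), 135.0: (-1, -1)}


def glcm_features(
    img: np.ndarray,
    mask: np.ndarray | None = None,
    levels: int = 8,
    distance: int = 1,
    angles: Sequence[float] = DEFAULT_ANGLES,
    log_base: str = "e",
) -> GLCMFeatures:
    """GLCM texture features of an 8-bit image.

    Intensities are quantized into ``levels`` equal-width bins over
    [0, 255]; a single symmetric co-occurrence matrix is accumulated over
    all requested angles at offset ``distance`` and normalised; when a
    mask is given only pixel pairs with both ends inside it count.
    Correlation is NaN (flagged undefined) for a constant image.
    """
    img = np.asarray(img)
    if levels < 2:
        raise ValueError("levels must be >= 2")
    if distance < 1:
        raise ValueError("distance must be >= 1")
    H, W = img.shape
    if H <= distance and W <= distance:
        raise ValueError("image smaller than offset distance")
    q = _quantize(img, levels)
    P = np.zeros((levels, levels), dtype=float)
    for ang in angles:
        if ang not in _ANGLE_OFFSETS:
            raise ValueError(f"unsupported angle {ang}; use 0/45/90/135")
        dr, dc = (d * distance for d in _ANGLE_OFFSETS[ang])
        r0, r1 = max(0, -dr), H - max(0, dr)
        c0, c1 = max(0, -dc), W - max(0, dc)
        if r1 <= r0 or c1 <= c0:
            continue
        a = q[r0:r1, c0:c1]
        b = q[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        if mask is not None:
            mk = np.asarray(mask, dtype=bool)
            valid = mk[r0:r1, c0:c1] & mk[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
            a, b = a[valid], b[valid]
        else:
            a, b = a.ravel(), b.ravel()
        np.add.at(P, (a, b), 1.0)
        np.add.at(P, (b, a), 1.0)
    total = P.sum()
    if total == 0:
        raise ValueError("no valid pixel pairs (mask too small?)")
    P /= total

    i = np.arange(levels, dtype=float)[:, None]
    j = np.arange(levels, dtype=float)[None, :]
    asm = float(np.sum(P * P))
    contrast = float(np.sum((i - j) ** 2 * P))
    idm = float(np.sum(P / (1.0 + (i - j) ** 2)))
    nz = P[P > 0]
    log = np.log2 if log_base == "2" else np.log
    entropy = float(-np.sum(nz * log(nz)))
    mu_i = float(np.sum(i * P))
    mu_j = float(np.sum(j * P))
    var_i = float(np.sum((i - mu_i) ** 2 * P))
    var_j = float(np.sum((j - mu_j) ** 2 * P))
    if var_i > 0 and var_j > 0:
        corr = float(np.sum((i - mu_i) * (j - mu_j) * P) / np.sqrt(var_i * var_j))
    else:
        corr = float("nan")
    return GLCMFeatures(asm, contrast, corr, idm, entropy, levels, distance, tuple(angles))


# ---------------------------------------------------------------------------
# fractal dimension and lacunarity


def _bbox_crop(mask: np.ndarray) -> np.ndarray:
    ys, xs = np.nonzero(mask)
    return mask[ys.min():ys.max() + 1, xs.min():xs.max() + 1]


def _count_boxes(mask: np.ndarray, s: int, oy: int = 0, ox: int = 0) -> int:
    m = mask[oy:, ox:]
    H, W = m.shape
    ph, pw = (-H) % s, (-W) % s
    if ph or pw:
        m = np.pad(m, ((0, ph), (0, pw)))
    H, W = m.shape
    blocks = m.reshape(H // s, s, W // s, s)
    return int(blocks.any(axis=(1, 3)).sum())


def _loglog_slope(sizes, counts):
    x = np.log(1.0 / np.asarray(sizes, dtype=float))
    y = np.log(np.asarray(counts, dtype=float))
    slope, intercept = np.polyfit(x, y, 1)
    pred = slope * x + intercept
    sst = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 if sst == 0 else float(1.0 - np.sum((y - pred) ** 2) / sst)
    return float(slope), r2


def _default_sizes(extent: int) -> list[int]:
    sizes = []
    s = 1
    while s <= max(2, extent // 2):
        sizes.append(s)
        s *= 2
    return sizes if len(sizes) >= 3 else [1, 2, 3]


def boxcount_dimension(
    mask: np.ndarray,
    sizes: Sequence[int] | None = None,
    multi_origin: bool = False,
) -> FractalFit:
    """Box-counting dimension of a binary pattern.

    ``N(s)`` counts the s-by-s grid cells containing any true pixel, with
    the grid anchored at the pattern's bounding-box origin; the dimension
    is the slope of ``log N`` vs ``log(1/s)``.  ``multi_origin`` averages
    counts over 4 grid origins (offset 0 and s//2 per axis).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    m = _bbox_crop(mask)
    if sizes is None:
        sizes = _default_sizes(min(m.shape))
    sizes = [int(s) for s in sizes]
    if len(sizes) < 3:
        raise ValueError("need at least 3 box sizes")
    counts = []
    for s in sizes:
        if multi_origin and s > 1:
            offs = [(0, 0), (s // 2, 0), (0, s // 2), (s // 2, s // 2)]
            counts.append(float(np.mean([_count_boxes(m, s, oy, ox) for oy, ox in offs])))
        else:
            counts.append(float(_count_boxes(m, s)))
    dim, r2 = _loglog_slope(sizes, counts)
    return FractalFit(dim, tuple(sizes), tuple(counts), r2)


def gliding_box_lacunarity(
    mask: np.ndarray, sizes: Sequence[int] = DEFAULT_LACUNARITY_SIZES
) -> LacunarityResult:
    """Gliding-box lacunarity ``lambda(r) = var(M)/mean(M)^2``.

    For each box size r the box mass M is recorded at every fully
    interior position (the box glides one pixel at a time); the returned
    scalar is the mean of ``lambda(r)`` over the sizes, with the per-size
    values exposed.
    """
    mask = np.asarray(mask, dtype=bool)
    if len(sizes) < 2:
        raise ValueError("need at least 2 box sizes")
    if not mask.any():
        raise ValueError("mask is empty (mean mass would be 0)")
    H, W = mask.shape
    per_size: dict[int, float] = {}
    ii = np.pad(np.cumsum(np.cumsum(mask, 0), 1), ((1, 0), (1, 0)))
    for r in sizes:
        r = int(r)
        if r > min(H, W):
            raise ValueError(f"box size {r} exceeds mask extent")
        M = ii[r:, r:] - ii[:-r, r:] - ii[r:, :-r] + ii[:-r, :-r]
        mean = M.mean()
        per_size[r] = float(M.var() / mean**2) if mean > 0 else float("inf")
    return LacunarityResult(float(np.mean(list(per_size.values()))), per_size)


def sdbc_dimension(img: np.ndarray, sizes: Sequence[int] | None = None) -> FractalFit:
    """Shifting differential box-counting dimension of a gray surface.

    The image is tiled with s-by-s cells; the box height is
    ``h = s * 256 / min(H, W)``.  Each cell's intensity span is covered
    by a stack of boxes starting at the cell's own minimum (the shift),
    contributing ``floor((max - min)/h) + 1`` boxes; the dimension is the
    slope of ``log N(s)`` vs ``log(1/s)`` and lies in [2, 3] for
    well-resolved surfaces.
    """
    img = np.asarray(img, dtype=float)
    H, W = img.shape
    if min(H, W) < 8:
        raise ValueError("image must be at least 8x8")
    if sizes is None:
        sizes = [s for s in (2, 4, 8, 16, 32) if s <= min(H, W) // 4]
    sizes = [int(s) for s in sizes]
    if len(sizes) < 3:
        raise ValueError("need at least 3 box sizes")
    counts = []
    for s in sizes:
        if s < 2:
            raise ValueError("box sizes must be >= 2")
        h = s * 256.0 / min(H, W)
        n_boxes = 0
        for y0 in range(0, H, s):
            for x0 in range(0, W, s):
                cell = img[y0:y0 + s, x0:x0 + s]
                n_boxes += int((cell.max() - cell.min()) // h) + 1
        counts.append(float(n_boxes))
    dim, r2 = _loglog_slope(sizes, counts)
    return FractalFit(dim, tuple(sizes), tuple(counts), r2)


def feature_row(
    img: np.ndarray,
    lo: float,
    hi: float,
    pixel_size: float = 1.0,
    glcm_levels: int = 8,
    glcm_distance: int = 1,
) -> dict[str, float]:
    """The full per-image feature vector used by the feature-table CSV."""
    mask = binarize_threshold(img, lo, hi)
    shape = shape_descriptors(mask, pixel_size=pixel_size, fill_holes=True)
    tex = glcm_features(img, mask=mask, levels=glcm_levels, distance=glcm_distance)
    skel = skeletonize_mask(mask)
    bc = boxcount_dimension(skel)
    lac_sizes = [r for r in DEFAULT_LACUNARITY_SIZES if r <= min(mask.shape)]
    lac = gliding_box_lacunarity(skel, sizes=lac_sizes)
    sdbc = sdbc_dimension(img)
    return {
        "area": shape.area,
        "perimeter": shape.perimeter,
        "circularity": shape.circularity,
        "solidity": shape.solidity,
        "asm": tex.asm,
        "contrast": tex.contrast,
        "correlation": tex.correlation,
        "idm": tex.idm,
        "entropy": tex.entropy,
        "boxcount_dimension": bc.dimension,
        "lacunarity": lac.value,
        "sdbc_dimension": sdbc.dimension,
        "threshold_lo": lo,
        "threshold_hi": hi,
        "glcm_levels": glcm_levels,
        "glcm_distance": glcm_distance,
        "pixel_size_um": pixel_size,
    }
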