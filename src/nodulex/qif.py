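"""Quantitative image features (QIF): 50 radiomic descriptors of a nodule.

All shape and texture features are 2-D, computed on the transverse slice
of maximal in-mask area.  The fixed feature order is given by
``QIF_FEATURE_NAMES``:

* the index of the maximal-area transverse plane;
* slice geometry: pixel count, area, x/y spans, perimeter, circularity,
  primary/secondary rotational moments and their ratio;
* first-order HU statistics (median, mean, sd, variance, skewness,
  kurtosis, entropy) and the same statistics (minus the median) of the
  horizontal difference image;
* gliding-box lacunarity at box sizes 2^1 .. 2^10;
* the five neighbourhood gray-tone difference matrix (NGTDM) textures --
  coarseness, contrast, busyness, complexity, texture strength -- at
  neighbourhood distances 1 and 2 pixels;
* distance-to-surface summaries, box-counting fractal dimensions of the
  area and of the perimeter, and the mean boundary gradient ("gradient
  margin").

Degenerate inputs are mapped to finite values (documented per function) so
downstream classifiers never see NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

from .volume import CTVolume

__all__ = [
    "QIF_FEATURE_NAMES",
    "SIZE_FEATURE_NAMES",
    "SegmentedNodule",
    "auto_segment",
    "max_area_slice",
    "geometry_features",
    "hu_statistics",
    "difference_image_statistics",
    "lacunarity",
    "ngtdm_features",
    "distance_features",
    "fractal_dimensions",
    "gradient_margin",
    "extract_qif",
]

_EPS = 1e-6  # guard for NGTDM zero denominators; coarseness capped at 1/_EPS
N_GRAY_LEVELS = 32  # NGTDM quantisation levels over the in-mask HU range
ENTROPY_BINS = 64  # equal-width HU histogram bins for entropy

QIF_FEATURE_NAMES: tuple[str, ...] = (
    ("max_area_plane", "n_pixels", "area", "span_x", "span_y", "perimeter",
     "circularity", "moment_primary", "moment_secondary", "moment_ratio",
     "hu_median", "hu_mean", "hu_sd", "hu_variance", "hu_skewness",
     "hu_kurtosis", "hu_entropy",
     "diff_mean", "diff_sd", "diff_variance", "diff_skewness",
     "diff_kurtosis", "diff_entropy")
    + tuple(f"lacunarity_{2**i}" for i in range(1, 11))
    + ("coarseness_d1", "coarseness_d2", "contrast_d1", "contrast_d2",
       "busyness_d1", "busyness_d2", "complexity_d1", "complexity_d2",
       "strength_d1", "strength_d2",
       "dist_summed", "dist_mean", "dist_summed_norm", "dist_mean_norm",
       "fd_area", "fd_perimeter", "gradient_margin")
)
assert len(QIF_FEATURE_NAMES) == 50

# "direct measures of size" excluded by the no-size Random-Forest variant
SIZE_FEATURE_NAMES: tuple[str, ...] = (
    "n_pixels", "area", "span_x", "span_y", "perimeter", "dist_summed",
)


@dataclass
class SegmentedNodule:
    """An HU region with its binary segmentation mask and voxel spacing."""

    hu: np.ndarray
    mask: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.hu = np.asarray(self.hu, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.hu.shape != self.mask.shape:
            raise ValueError("hu and mask shapes differ")
        if not self.mask.any():
            raise ValueError("segmentation mask is empty")


# ---------------------------------------------------------------------------
# automated segmentation for point-only regions
# ---------------------------------------------------------------------------

def _sphere_mask(shape, center, radius_vox: float) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return d2 <= radius_vox**2


def auto_segment(
    volume: CTVolume,
    seed_point: tuple[float, float, float],
    threshold_hu: float = -400.0,
    closing_radius: int = 1,
    fallback_radius_vox: float = 3.0,
) -> np.ndarray:
    """Segment the structure containing a seed point, without any contour.

    HU thresholding (>= ``threshold_hu``) followed by connected-component
    selection at the seed and morphological closing.  If the seed sits in
    background the result falls back to a small sphere around the seed, so
    the mask is never empty.  Such masks tend to be larger and rounder
    than hand contours, which is the accepted cost of automation.
    """
    if not volume.contains(seed_point):
        raise ValueError(f"seed point {seed_point} lies outside the volume")
    seed = tuple(int(np.floor(c + 0.5)) for c in seed_point)
    fg = volume.hu >= threshold_hu
    labels, _ = ndimage.label(fg)
    lab = labels[seed]
    if lab == 0:
        return _sphere_mask(volume.shape, seed, fallback_radius_vox)
    mask = labels == lab
    if closing_radius > 0:
        ball = _sphere_mask(
            (2 * closing_radius + 1,) * 3, (closing_radius,) * 3, closing_radius
        )
        mask = ndimage.binary_closing(mask, structure=ball)
    # closing can merge components; keep the one holding the seed
    labels, _ = ndimage.label(mask)
    mask = labels == labels[seed]
    if not mask.any():
        return _sphere_mask(volume.shape, seed, fallback_radius_vox)
    return mask


# ---------------------------------------------------------------------------
# per-slice features
# ---------------------------------------------------------------------------

def max_area_slice(nodule: SegmentedNodule) -> int:
    """Index of the transverse slice maximising in-mask area (ties: lowest)."""
    counts = nodule.mask.sum(axis=(0, 1))
    return int(np.argmax(counts))


def _boundary(mask2d: np.ndarray) -> np.ndarray:
    return mask2d & ~ndimage.binary_erosion(mask2d)


def _perimeter_mm(mask2d: np.ndarray, spacing2) -> float:
    """Marching-squares polygon length of the mask boundary, in mm.

    Vertices are smoothed with two passes of a closed (1,2,1)/4 moving
    average before measuring, which removes most of the staircase
    rasterisation bias (a rasterised disk then measures within ~2% of the
    true circle perimeter).  Very short rings (< 8 vertices, e.g. a
    single pixel's outline) are measured as drawn.
    """
    padded = np.pad(mask2d.astype(float), 1)
    total = 0.0
    for contour in measure.find_contours(padded, 0.5):
        ring = contour[:-1]  # closed: last vertex repeats the first
        if len(ring) >= 8:
            for _ in range(2):
                ring = (np.roll(ring, 1, axis=0) + 2 * ring
                        + np.roll(ring, -1, axis=0)) / 4.0
        d = np.diff(np.vstack([ring, ring[:1]]), axis=0)
        total += float(
            np.sqrt((d[:, 0] * spacing2[0]) ** 2 + (d[:, 1] * spacing2[1]) ** 2).sum()
        )
    return total


def geometry_features(mask2d: np.ndarray, spacing2=(1.0, 1.0)) -> dict[str, float]:
    """Slice geometry: counts, area, spans, perimeter, circularity, moments.

    Rotational moments are the eigenvalues (mm^2) of the second central
    moment matrix of the in-mask pixel *areas* (each pixel contributes its
    own inertia, so degenerate one-pixel-wide masks stay finite and a
    single square pixel has moment ratio exactly 1).
    """
    mask2d = np.asarray(mask2d, dtype=bool)
    if not mask2d.any():
        raise ValueError("empty slice mask")
    sx, sy = float(spacing2[0]), float(spacing2[1])
    xs, ys = np.nonzero(mask2d)
    n_pixels = int(mask2d.sum())
    area = n_pixels * sx * sy
    span_x = float((xs.max() - xs.min() + 1) * sx)
    span_y = float((ys.max() - ys.min() + 1) * sy)
    perimeter = _perimeter_mm(mask2d, (sx, sy))
    circularity = 4.0 * np.pi * area / perimeter**2 if perimeter > 0 else 0.0

    pts = np.stack([xs * sx, ys * sy], axis=1)
    centred = pts - pts.mean(axis=0)
    cov = centred.T @ centred / n_pixels
    cov[0, 0] += sx**2 / 12.0  # per-pixel inertia of an sx-by-sy rectangle
    cov[1, 1] += sy**2 / 12.0
    eig = np.linalg.eigvalsh(cov)
    moment_secondary, moment_primary = float(eig[0]), float(eig[1])
    moment_ratio = (
        moment_primary / moment_secondary if moment_secondary > 0 else 1.0
    )
    return dict(
        n_pixels=float(n_pixels),
        area=float(area),
        span_x=span_x,
        span_y=span_y,
        perimeter=perimeter,
        circularity=float(circularity),
        moment_primary=moment_primary,
        moment_secondary=moment_secondary,
        moment_ratio=float(moment_ratio),
    )


def _entropy_bits(values: np.ndarray, bins: int = ENTROPY_BINS) -> float:
    lo, hi = float(values.min()), float(values.max())
    if hi <= lo:
        return 0.0
    hist, _ = np.histogram(values, bins=bins, range=(lo, hi))
    p = hist[hist > 0] / values.size
    return float(-(p * np.log2(p)).sum())


def _moment_stats(values: np.ndarray) -> tuple[float, float, float, float, float]:
    """(mean, sd, variance, skewness, kurtosis) with population moments.

    Skewness and (non-excess) kurtosis of constant data are defined as 0.
    """
    mean = float(values.mean())
    centred = values - mean
    m2 = float((centred**2).mean())
    if m2 <= 0:
        return mean, 0.0, 0.0, 0.0, 0.0
    m3 = float((centred**3).mean())
    m4 = float((centred**4).mean())
    return mean, float(np.sqrt(m2)), m2, m3 / m2**1.5, m4 / m2**2


def hu_statistics(values) -> dict[str, float]:
    """First-order statistics of in-mask HU values."""
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("no HU values")
    mean, sd, var, skew, kurt = _moment_stats(values)
    return dict(
        hu_median=float(np.median(values)),
        hu_mean=mean,
        hu_sd=sd,
        hu_variance=var,
        hu_skewness=skew,
        hu_kurtosis=kurt,
        hu_entropy=_entropy_bits(values),
    )


def difference_image_statistics(hu2d: np.ndarray, mask2d: np.ndarray) -> dict[str, float]:
    """Statistics of the horizontal difference image inside the mask.

    The difference image is each pixel's HU minus its right (+x)
    neighbour's, defined where both pixels are in-mask.  All six values
    are 0 when no valid pair exists.
    """
    hu2d = np.asarray(hu2d, dtype=float)
    mask2d = np.asarray(mask2d, dtype=bool)
    valid = mask2d[:-1, :] & mask2d[1:, :]
    zeros = dict(diff_mean=0.0, diff_sd=0.0, diff_variance=0.0,
                 diff_skewness=0.0, diff_kurtosis=0.0, diff_entropy=0.0)
    if not valid.any():
        return zeros
    diffs = (hu2d[:-1, :] - hu2d[1:, :])[valid]
    mean, sd, var, skew, kurt = _moment_stats(diffs)
    return dict(
        diff_mean=mean, diff_sd=sd, diff_variance=var, diff_skewness=skew,
        diff_kurtosis=kurt, diff_entropy=_entropy_bits(diffs),
    )


def lacunarity(mask2d: np.ndarray, box_sizes=None) -> np.ndarray:
    """Gliding-box lacunarity at box sizes 2^1 .. 2^10.

    For each box size s, an s-by-s window glides (stride 1) over the
    mask's bounding box; with m_s the in-mask pixel count per window,
    Lambda(s) = var(m_s)/mean(m_s)^2 + 1.  Boxes exceeding the bounding
    box return the translation-invariant neutral value 1.
    """
    mask2d = np.asarray(mask2d, dtype=bool)
    if not mask2d.any():
        raise ValueError("empty slice mask")
    if box_sizes is None:
        box_sizes = [2**i for i in range(1, 11)]
    xs, ys = np.nonzero(mask2d)
    box = mask2d[xs.min():xs.max() + 1, ys.min():ys.max() + 1]
    # 2-D summed-area table for O(1) window sums
    sat = np.zeros((box.shape[0] + 1, box.shape[1] + 1), dtype=np.int64)
    sat[1:, 1:] = np.cumsum(np.cumsum(box, axis=0), axis=1)
    out = np.ones(len(box_sizes))
    for k, s in enumerate(box_sizes):
        if s > box.shape[0] or s > box.shape[1]:
            continue
        m = (
            sat[s:, s:] - sat[:-s, s:] - sat[s:, :-s] + sat[:-s, :-s]
        ).astype(float)
        mean = m.mean()
        out[k] = m.var() / mean**2 + 1.0 if mean > 0 else 1.0
    return out


def _quantize(hu2d: np.ndarray, mask2d: np.ndarray, levels: int) -> np.ndarray:
    vals = hu2d[mask2d]
    lo, hi = float(vals.min()), float(vals.max())
    q = np.zeros(hu2d.shape, dtype=np.int32)
    if hi > lo:
        q[mask2d] = np.minimum(
            ((hu2d[mask2d] - lo) / (hi - lo) * levels).astype(np.int32),
            levels - 1,
        )
    return q + 1  # gray levels 1..levels


def ngtdm_features(
    hu2d: np.ndarray, mask2d: np.ndarray, d: int = 1,
    levels: int = N_GRAY_LEVELS,
) -> dict[str, float]:
    """Neighbourhood gray-tone difference matrix textures at distance d.

    HU is quantised to ``levels`` gray tones over the in-mask range.  A
    pixel is valid when its full (2d+1)^2 neighbourhood lies inside the
    mask; for gray tone i, s(i) sums |i - A| over valid pixels of tone i,
    where A is the mean tone of the pixel's neighbours.  The five texture
    measures follow the standard coarseness / contrast / busyness /
    complexity / strength formulas with probability weights p_i and an
    epsilon guard on vanishing denominators; with no valid pixel all five
    are 0, and coarseness is capped at 1/epsilon.
    """
    mask2d = np.asarray(mask2d, dtype=bool)
    q = _quantize(np.asarray(hu2d, dtype=float), mask2d, levels)
    w = 2 * d + 1
    # validity: every neighbour within distance d is in-mask (and in-image)
    padded = np.zeros((mask2d.shape[0] + 2 * d, mask2d.shape[1] + 2 * d), bool)
    padded[d:-d or None, d:-d or None] = mask2d
    valid = np.ones(mask2d.shape, dtype=bool)
    neigh_sum = np.zeros(mask2d.shape, dtype=float)
    qpad = np.zeros(padded.shape, dtype=np.int32)
    qpad[d:-d or None, d:-d or None] = q
    for dx in range(-d, d + 1):
        for dy in range(-d, d + 1):
            shifted = padded[d + dx:d + dx + mask2d.shape[0],
                             d + dy:d + dy + mask2d.shape[1]]
            valid &= shifted
            if (dx, dy) != (0, 0):
                neigh_sum += qpad[d + dx:d + dx + mask2d.shape[0],
                                  d + dy:d + dy + mask2d.shape[1]]
    zeros = dict(coarseness=0.0, contrast=0.0, busyness=0.0,
                 complexity=0.0, strength=0.0)
    n = int(valid.sum())
    if n == 0:
        return zeros
    a_bar = neigh_sum[valid] / (w * w - 1)
    tones = q[valid]
    s = np.zeros(levels + 1)
    counts = np.zeros(levels + 1)
    np.add.at(s, tones, np.abs(tones - a_bar))
    np.add.at(counts, tones, 1.0)
    p = counts / n
    present = np.nonzero(p > 0)[0]
    i = present.astype(float)
    pi, si = p[present], s[present]
    n_p = len(present)

    coarseness = min(1.0 / (_EPS + float((pi * si).sum())), 1.0 / _EPS)
    if n_p > 1:
        dij2 = (i[:, None] - i[None, :]) ** 2
        contrast = (
            float((pi[:, None] * pi[None, :] * dij2).sum())
            / (n_p * (n_p - 1))
            * float(si.sum())
            / n
        )
        ipi = i * pi
        denom = float(np.abs(ipi[:, None] - ipi[None, :]).sum())
        busyness = float((pi * si).sum()) / denom if denom > _EPS else 0.0
        psum = pi[:, None] + pi[None, :]
        complexity = float(
            (np.abs(i[:, None] - i[None, :]) / (n * psum)
             * ((pi * si)[:, None] + (pi * si)[None, :])).sum()
        )
        strength = float((psum * dij2).sum()) / (_EPS + float(si.sum()))
    else:
        contrast = busyness = complexity = strength = 0.0
    return dict(coarseness=coarseness, contrast=contrast, busyness=busyness,
                complexity=complexity, strength=strength)


def distance_features(mask2d: np.ndarray, spacing2=(1.0, 1.0)) -> dict[str, float]:
    """Distance-to-surface summaries over in-mask pixels (mm).

    Distance is Euclidean to the nearest *boundary pixel* of the mask, so
    boundary pixels score 0.  Normalised variants divide by the maximum
    in-mask distance (0 when the maximum is 0).
    """
    mask2d = np.asarray(mask2d, dtype=bool)
    if not mask2d.any():
        raise ValueError("empty slice mask")
    dist = ndimage.distance_transform_edt(~_boundary(mask2d), sampling=spacing2)
    inside = dist[mask2d]
    summed = float(inside.sum())
    mean = summed / inside.size
    dmax = float(inside.max())
    return dict(
        dist_summed=summed,
        dist_mean=mean,
        dist_summed_norm=summed / dmax if dmax > 0 else 0.0,
        dist_mean_norm=mean / dmax if dmax > 0 else 0.0,
    )


def _box_count_dimension(points_mask: np.ndarray) -> float | None:
    xs, ys = np.nonzero(points_mask)
    if xs.size == 0:
        return None
    box = points_mask[xs.min():xs.max() + 1, ys.min():ys.max() + 1]
    max_extent = max(box.shape)
    sizes = [s for s in (2 ** np.arange(1, 11)) if s <= max_extent]
    if len(sizes) < 3:
        return None
    counts = []
    for s in sizes:
        nx = -(-box.shape[0] // s)
        ny = -(-box.shape[1] // s)
        padded = np.zeros((nx * s, ny * s), dtype=bool)
        padded[:box.shape[0], :box.shape[1]] = box
        blocks = padded.reshape(nx, s, ny, s).any(axis=(1, 3))
        counts.append(int(blocks.sum()))
    slope = np.polyfit(np.log(sizes), np.log(counts), 1)[0]
    return float(-slope)


def fractal_dimensions(mask2d: np.ndarray) -> tuple[float, float]:
    """Box-counting fractal dimensions of the filled area and its boundary.

    Least-squares slope of log N(s) against log(1/s) over dyadic box
    sizes; masks too small for three box sizes return (1, 1).
    """
    mask2d = np.asarray(mask2d, dtype=bool)
    if not mask2d.any():
        raise ValueError("empty slice mask")
    fd_area = _box_count_dimension(mask2d)
    fd_perimeter = _box_count_dimension(_boundary(mask2d))
    return (fd_area if fd_area is not None else 1.0,
            fd_perimeter if fd_perimeter is not None else 1.0)


def gradient_margin(
    hu2d: np.ndarray, mask2d: np.ndarray, spacing2=(1.0, 1.0)
) -> float:
    """Mean HU gradient magnitude (central differences, HU/mm) on the boundary."""
    mask2d = np.asarray(mask2d, dtype=bool)
    boundary = _boundary(mask2d)
    if not boundary.any():
        raise ValueError("mask has an empty boundary")
    gx, gy = np.gradient(np.asarray(hu2d, dtype=float), spacing2[0], spacing2[1])
    return float(np.sqrt(gx**2 + gy**2)[boundary].mean())


# ---------------------------------------------------------------------------
# full feature vector
# ---------------------------------------------------------------------------

def extract_qif(nodule: SegmentedNodule) -> np.ndarray:
    """Compute the 50-value QIF vector on the maximal-area transverse slice."""
    zi = max_area_slice(nodule)
    mask2d = nodule.mask[:, :, zi]
    hu2d = nodule.hu[:, :, zi]
    spacing2 = nodule.spacing[:2]

    values: dict[str, float] = {"max_area_plane": float(zi)}
    values.update(geometry_features(mask2d, spacing2))
    values.update(hu_statistics(hu2d[mask2d]))
    values.update(difference_image_statistics(hu2d, mask2d))
    for s, lam in zip((2 ** np.arange(1, 11)), lacunarity(mask2d)):
        values[f"lacunarity_{s}"] = float(lam)
    for d in (1, 2):
        tex = ngtdm_features(hu2d, mask2d, d=d)
        for name, v in tex.items():
            key = {"coarseness": "coarseness", "contrast": "contrast",
                   "busyness": "busyness", "complexity": "complexity",
                   "strength": "strength"}[name]
            values[f"{key}_d{d}"] = float(v)
    values.update(distance_features(mask2d, spacing2))
    fd_area, fd_perim = fractal_dimensions(mask2d)
    values["fd_area"] = fd_area
    values["fd_perimeter"] = fd_perim
    try:
        values["gradient_margin"] = gradient_margin(hu2d, mask2d, spacing2)
    except ValueError:  # boundary-free masks cannot occur for 2-D slices
        values["gradient_margin"] = 0.0
    vec = np.asarray([values[name] for name in QIF_FEATURE_NAMES], dtype=float)
    if not np.all(np.isfinite(vec)):
        bad = [QIF_FEATURE_NAMES[i] for i in np.nonzero(~np.isfinite(vec))[0]]
        raise AssertionError(f"non-finite QIF features: {bad}")
    return vec
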