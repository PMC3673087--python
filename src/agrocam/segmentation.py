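"""Greenness segmentation and orange-cardboard ROI extraction.

Vegetation is separated from soil/background by a single global threshold
on the green chromatic coordinate ``g = G / (R + G + B)``.  The threshold
is learned per image: RGB triplets are sampled from the image, a
two-class fuzzy c-means clustering estimates a vegetation and a
non-vegetation colour centre, and the threshold is the green fraction of
the vegetation centre.  A pixel is classified vegetation (white) when its
own ``g`` strictly exceeds the threshold; because ``g`` is a ratio this
decision is invariant to uniform intensity scaling.

The bright-orange cardboard that materialises the ground ROI in camera
arrangement surveys is extracted by an HSV colour gate (hue interval with
saturation/value floors) and its pixel count ``n`` is the resolution
measure of the arrangement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage import color as skcolor
from skimage import measure as skmeasure

__all__ = [
    "ClusterModel",
    "GreenThreshold",
    "OrangeBounds",
    "sample_features",
    "fit_fuzzy_clusters",
    "derive_threshold",
    "binarize_vegetation",
    "segment_orange_roi",
    "green_chromatic",
]

MAX_LEVEL = 255.0


@dataclass(frozen=True)
class ClusterModel:
    """Two RGB cluster centres with vegetation identified by greenness.

    ``centers`` is (2, 3); row 0 is the vegetation centre (the one with
    the larger green chromatic coordinate), row 1 the non-vegetation
    centre.
    """

    centers: np.ndarray
    fuzziness: float
    n_iter: int
    converged: bool

    @property
    def vegetation_center(self) -> np.ndarray:
        return self.centers[0]

    @property
    def background_center(self) -> np.ndarray:
        return self.centers[1]


@dataclass(frozen=True)
class GreenThreshold:
    """Global threshold on the green chromatic coordinate, in (0, 1)."""

    value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.value < 1.0:
            raise ValueError("threshold must lie in [0, 1)")


def green_chromatic(rgb: np.ndarray) -> np.ndarray:
    """g = G / (R + G + B) per pixel; 0 where the sum is 0."""
    arr = np.asarray(rgb, dtype=float)
    total = arr.sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        g = np.where(total > 0, arr[..., 1] / total, 0.0)
    return g


def sample_features(
    image: np.ndarray, n_samples: int, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Draw ``n_samples`` RGB triplets uniformly over the image, without
    replacement (``n_samples`` equal to the pixel count returns every
    pixel exactly once).  Reproducible for a fixed seed."""
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("image must be an (H, W, 3) RGB array")
    n_pixels = img.shape[0] * img.shape[1]
    if not 2 <= n_samples <= n_pixels:
        raise ValueError(
            f"n_samples must be in [2, {n_pixels}], got {n_samples}"
        )
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    flat = img.reshape(n_pixels, 3)
    idx = rng.choice(n_pixels, size=n_samples, replace=False)
    return flat[np.sort(idx)].astype(float)


def fit_fuzzy_clusters(
    samples: np.ndarray,
    fuzziness: float = 2.0,
    tol: float = 1e-4,
    max_iter: int = 300,
) -> ClusterModel:
    """Two-class fuzzy c-means on RGB triplets.

    Memberships and centres alternate until the largest centre movement
    falls below ``tol`` or ``max_iter`` is reached.  Centres are
    initialised deterministically from the per-channel 0.2 / 0.8
    quantiles of the samples ordered by greenness, so the fit does not
    depend on sample order.  The centre with the larger green chromatic
    coordinate is labelled vegetation.
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim != 2 or x.shape[1] != 3:
        raise ValueError("samples must be an (n, 3) array of RGB triplets")
    if len(x) < 2:
        raise ValueError("need at least two samples")
    if np.allclose(x, x[0]):
        raise ValueError("all samples identical: two clusters are undefined")
    if fuzziness <= 1.0:
        raise ValueError("fuzziness exponent must exceed 1")

    # deterministic, order-invariant init: per-channel 0.2/0.8 quantiles
    centers = np.quantile(x, [0.2, 0.8], axis=0)
    if np.allclose(centers[0], centers[1]):
        centers = np.vstack([x.min(axis=0), x.max(axis=0)]).astype(float)

    expo = 2.0 / (fuzziness - 1.0)
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        d2 = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        d2 = np.maximum(d2, 1e-12)
        ratio = (d2[:, :, None] / d2[:, None, :]) ** (expo / 2.0)
        u = 1.0 / ratio.sum(axis=2)
        w = u**fuzziness
        new_centers = (w.T @ x) / w.sum(axis=0)[:, None]
        shift = np.abs(new_centers - centers).max()
        centers = new_centers
        if shift < tol:
            converged = True
            break

    g_centers = green_chromatic(centers)
    if g_centers[0] < g_centers[1]:
        centers = centers[::-1]
    return ClusterModel(
        centers=centers,
        fuzziness=fuzziness,
        n_iter=n_iter,
        converged=converged,
    )


def derive_threshold(model: ClusterModel) -> GreenThreshold:
    """Green fraction of the vegetation centre: G / (R + G + B)."""
    veg = model.vegetation_center
    total = float(veg.sum())
    if total <= 0:
        raise ValueError("vegetation centre sums to zero")
    value = float(veg[1] / total)
    if value == 0.0:
        warnings.warn(
            "vegetation centre has zero green component; threshold "
            "degenerates to 0",
            stacklevel=2,
        )
    return GreenThreshold(value=value)


def binarize_vegetation(
    image: np.ndarray, threshold: GreenThreshold
) -> np.ndarray:
    """Boolean mask: True (white) where g strictly exceeds the threshold.

    Pixels with R + G + B = 0 are background.  Scale-invariant: scaling
    all channels of a pixel by a positive constant leaves its class
    unchanged.
    """
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("image must be an (H, W, 3) RGB array")
    return green_chromatic(img) > threshold.value


@dataclass(frozen=True)
class OrangeBounds:
    """HSV gate for the bright-orange cardboard.

    Hue in degrees on [0, 360); defaults keep hues between 15 and 40 deg
    with saturation and value at least 0.5 (on [0, 1] scales).
    """

    hue_min_deg: float = 15.0
    hue_max_deg: float = 40.0
    sat_min: float = 0.5
    val_min: float = 0.5

    def __post_init__(self) -> None:
        if self.hue_min_deg >= self.hue_max_deg:
            raise ValueError("empty hue interval")
        if not (0 <= self.sat_min <= 1 and 0 <= self.val_min <= 1):
            raise ValueError("saturation/value floors must be in [0, 1]")


def segment_orange_roi(
    image: np.ndarray,
    bounds: OrangeBounds = OrangeBounds(),
    largest_component_only: bool = False,
) -> tuple[np.ndarray, int]:
    """Mask of in-bound bright-orange pixels and their count ``n``.

    Optionally keeps only the largest connected component (8-connected),
    which suppresses stray matches away from the cardboard.
    """
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("image must be an (H, W, 3) RGB array")
    hsv = skcolor.rgb2hsv(img.astype(float) / MAX_LEVEL)
    hue_deg = hsv[..., 0] * 360.0
    mask = (
        (hue_deg >= bounds.hue_min_deg)
        & (hue_deg <= bounds.hue_max_deg)
        & (hsv[..., 1] >= bounds.sat_min)
        & (hsv[..., 2] >= bounds.val_min)
    )
    if largest_component_only and mask.any():
        labels = skmeasure.label(mask, connectivity=2)
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        mask = labels == counts.argmax()
    return mask, int(np.count_nonzero(mask))
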