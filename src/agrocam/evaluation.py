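"""Segmentation accuracy scoring: confusion counts, the PCC index, and
the 2 x 2 exposure-by-vignetting condition grid.

PCC (percentage of correct classification) scores a binary segmentation
against a ground-truth mask:

    PCC = (TW + TB) / (TW + TB + FW + FB)

where TW/TB are pixels correctly white/black and FW/FB the false whites
and blacks.  Field evaluations discard the top third of each image first
(it images the horizon, outside the treated strip); the same crop is
applied here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from agrocam import segmentation as seg
from agrocam.illumination import VignettingGains, vignetting_correct, vignetting_pattern

__all__ = [
    "ConfusionCounts",
    "PccScore",
    "confusion",
    "pcc",
    "crop_bottom_two_thirds",
    "condition_grid_report",
    "segment_image",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel counts by joint (truth, prediction) state."""

    tw: int
    tb: int
    fw: int
    fb: int

    def __post_init__(self) -> None:
        if min(self.tw, self.tb, self.fw, self.fb) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tw + self.tb + self.fw + self.fb


@dataclass(frozen=True)
class PccScore:
    """Fraction of correctly classified pixels, with a percent view."""

    value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0:
            raise ValueError("PCC must lie in [0, 1]")

    @property
    def percent(self) -> float:
        return 100.0 * self.value


def confusion(mask: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Exact confusion counts between a predicted and a truth mask."""
    m = np.asarray(mask, dtype=bool)
    t = np.asarray(truth, dtype=bool)
    if m.shape != t.shape:
        raise ValueError(
            f"mask shape {m.shape} does not match truth shape {t.shape}"
        )
    return ConfusionCounts(
        tw=int(np.count_nonzero(m & t)),
        tb=int(np.count_nonzero(~m & ~t)),
        fw=int(np.count_nonzero(m & ~t)),
        fb=int(np.count_nonzero(~m & t)),
    )


def pcc(counts: ConfusionCounts) -> PccScore:
    """PCC = (TW + TB) / (TW + TB + FW + FB)."""
    if counts.total == 0:
        raise ValueError("cannot score an empty region")
    return PccScore(value=(counts.tw + counts.tb) / counts.total)


def crop_bottom_two_thirds(image: np.ndarray) -> np.ndarray:
    """Drop the top third of the rows: keep rows floor(H/3) .. H-1."""
    arr = np.asarray(image)
    height = arr.shape[0]
    if height < 3:
        raise ValueError("image must have at least 3 rows")
    return arr[height // 3 :]


def segment_image(
    image: np.ndarray, n_samples: int = 2000, seed: int = 0
) -> np.ndarray:
    """Full greenness-segmentation chain on one image: sample features,
    fit the two-class fuzzy clustering, derive the green-fraction
    threshold, binarize."""
    n_pixels = image.shape[0] * image.shape[1]
    samples = seg.sample_features(image, min(n_samples, n_pixels), seed=seed)
    model = seg.fit_fuzzy_clusters(samples)
    threshold = seg.derive_threshold(model)
    return seg.binarize_vegetation(image, threshold)


def condition_grid_report(
    image_pairs: Sequence[tuple[np.ndarray, np.ndarray]],
    truths: Sequence[np.ndarray],
    gains: VignettingGains = VignettingGains(),
    crop_top_third: bool = True,
    n_samples: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean PCC over a batch for the 2 x 2 correction design.

    Each pair holds the image captured before exposure adjustment and the
    one captured after; each is segmented with and without vignetting
    correction, giving four binary images per pair, each scored against
    that pair's ground truth.  Returns one row per condition:
    ``exposure_adjusted`` x ``vignetting_corrected`` with the batch mean
    PCC in percent.
    """
    if len(image_pairs) == 0:
        raise ValueError("empty batch")
    if len(truths) != len(image_pairs):
        raise ValueError("need one ground truth per image pair")
    scores: dict[tuple[bool, bool], list[float]] = {
        (e, v): [] for e in (False, True) for v in (False, True)
    }
    pattern = None
    for i, ((under, adjusted), truth) in enumerate(zip(image_pairs, truths)):
        truth = np.asarray(truth, dtype=bool)
        for exposure_adjusted, img in ((False, under), (True, adjusted)):
            if img.shape[:2] != truth.shape:
                raise ValueError("image and truth dimensions differ")
            for vignetting_corrected in (False, True):
                if vignetting_corrected:
                    if pattern is None or pattern.values.shape != img.shape[:2]:
                        pattern = vignetting_pattern(
                            img.shape[1], img.shape[0]
                        )
                    proc = vignetting_correct(img, pattern, gains)
                else:
                    proc = img
                mask = segment_image(proc, n_samples=n_samples, seed=seed + i)
                m, t = mask, truth
                if crop_top_third:
                    m = crop_bottom_two_thirds(m)
                    t = crop_bottom_two_thirds(t)
                scores[(exposure_adjusted, vignetting_corrected)].append(
                    pcc(confusion(m, t)).percent
                )
    rows = [
        {
            "exposure_adjusted": e,
            "vignetting_corrected": v,
            "mean_pcc_percent": float(np.mean(scores[(e, v)])),
        }
        for e in (False, True)
        for v in (False, True)
    ]
    return pd.DataFrame(rows)
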