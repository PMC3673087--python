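"""Exposure-time feedback control and lens-vignetting correction.

Outdoor crop imaging runs under uncontrolled illumination with a fixed
iris, so the only handle on sensor excitation is the exposure time
``E_t``.  The controller samples the white quadrant of a reference panel
in the scene, computes the channel means (R, G, B averages) and their
maximum ``H``, and nudges ``E_t`` multiplicatively until ``H`` sits in a
band just below saturation: with 8-bit channels (``M = 255``) the target
band is ``[a*M, b*M)`` with ``a = 0.90`` and ``b = 0.98``.  The update is

* ``H < a*M``  ->  ``E_t := (1 + p) * E_t``   (raise)
* ``H > b*M``  ->  ``E_t := (1 - p) * E_t``   (lower)
* otherwise       ``E_t`` unchanged           (keep)

with adjustment fraction ``p = 0.20``.  Because a +/-20 % step can
overshoot a band whose width ratio is only 0.98/0.90 = 1.089, the loop
may oscillate on a static scene; it therefore carries an iteration cap
and a convergence flag rather than any guarantee of landing in band.

The UV/IR cut filter attenuates red off-axis, tinting image corners
toward green/blue.  The correction multiplies each channel by
``1 + K * P`` where ``P`` is a radial pattern that is 0 at the image
centre and 1 at the four corners, and the per-channel gains default to
``K_r = 0.3, K_g = 0, K_b = 0`` (only red needs correcting).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExposureState",
    "PanelSample",
    "ExposureLoopResult",
    "VignettingPattern",
    "VignettingGains",
    "sample_white_panel",
    "exposure_update",
    "exposure_control_loop",
    "vignetting_pattern",
    "vignetting_correct",
]


@dataclass(frozen=True)
class ExposureState:
    """Current exposure time plus the control band parameters."""

    exposure_time_us: float
    lower_frac: float = 0.90
    upper_frac: float = 0.98
    adjust_frac: float = 0.20
    max_level: float = 255.0

    def __post_init__(self) -> None:
        if self.exposure_time_us <= 0:
            raise ValueError("exposure_time_us must be positive")
        if not 0.0 < self.lower_frac < self.upper_frac <= 1.0:
            raise ValueError("band fractions must satisfy 0 < a < b <= 1")
        if not 0.0 < self.adjust_frac < 1.0:
            raise ValueError("adjust_frac p must be in (0, 1)")
        if self.max_level <= 0:
            raise ValueError("max_level must be positive")


@dataclass(frozen=True)
class PanelSample:
    """Channel means over the white reference region and their maximum."""

    mean_r: float
    mean_g: float
    mean_b: float

    @property
    def h_stat(self) -> float:
        return max(self.mean_r, self.mean_g, self.mean_b)


@dataclass
class ExposureLoopResult:
    """Outcome of the feedback loop: final state, per-iteration trace,
    and whether H landed inside the target band."""

    state: ExposureState
    trace: pd.DataFrame
    converged: bool


def sample_white_panel(
    image: np.ndarray, region: Sequence[int]
) -> PanelSample:
    """Average the RGB channels over a rectangular region (x, y, w, h).

    ``x, y`` index the top-left corner (column, row); the region must be
    non-empty and lie inside the image.
    """
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("image must be an (H, W, 3) RGB array")
    x, y, w, h = (int(v) for v in region)
    height, width = img.shape[:2]
    if w <= 0 or h <= 0:
        raise ValueError("panel region must be non-empty")
    if x < 0 or y < 0 or x + w > width or y + h > height:
        raise ValueError("panel region falls outside the image")
    patch = img[y : y + h, x : x + w].astype(float)
    means = patch.reshape(-1, 3).mean(axis=0)
    return PanelSample(mean_r=means[0], mean_g=means[1], mean_b=means[2])


def exposure_update(
    sample: PanelSample, state: ExposureState
) -> tuple[ExposureState, str]:
    """One control step; returns the new state and the branch taken
    ('raised', 'lowered' or 'kept').

    The branch inequalities are strict on both sides, so ``H`` exactly at
    ``b*M`` is kept (the update rule, not the band-membership test,
    decides).
    """
    h = sample.h_stat
    a, b, p, m = (
        state.lower_frac,
        state.upper_frac,
        state.adjust_frac,
        state.max_level,
    )
    if h < a * m:
        return replace(state, exposure_time_us=(1 + p) * state.exposure_time_us), "raised"
    if h > b * m:
        return replace(state, exposure_time_us=(1 - p) * state.exposure_time_us), "lowered"
    return state, "kept"


def exposure_control_loop(
    sensor: Callable[[float], np.ndarray],
    panel_region: Sequence[int],
    state: ExposureState,
    max_iter: int = 10,
) -> ExposureLoopResult:
    """Run capture -> sample -> update until H is in band or the
    iteration cap is hit.

    ``sensor`` maps an exposure time (us) to an RGB image.  The trace
    records one row per captured image: iteration index, exposure used,
    the measured H and the decision taken.
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    rows = []
    converged = False
    for it in range(max_iter):
        image = sensor(state.exposure_time_us)
        sample = sample_white_panel(image, panel_region)
        new_state, decision = exposure_update(sample, state)
        rows.append(
            {
                "iter": it,
                "exposure_us": state.exposure_time_us,
                "H": sample.h_stat,
                "decision": decision,
            }
        )
        if decision == "kept":
            converged = True
            break
        state = new_state
    trace = pd.DataFrame(rows, columns=["iter", "exposure_us", "H", "decision"])
    if not converged:
        logger.info(
            "exposure loop hit max_iter=%d without entering the target band",
            max_iter,
        )
    return ExposureLoopResult(state=state, trace=trace, converged=converged)


@dataclass(frozen=True)
class VignettingPattern:
    """Radial weight pattern: 0 at the centre, 1 at the four corners."""

    values: np.ndarray
    center: tuple[float, float]


@dataclass(frozen=True)
class VignettingGains:
    """Per-channel correction strengths (dimensionless, >= 0)."""

    k_r: float = 0.3
    k_g: float = 0.0
    k_b: float = 0.0

    def __post_init__(self) -> None:
        if min(self.k_r, self.k_g, self.k_b) < 0:
            raise ValueError("gains must be non-negative")


def vignetting_pattern(
    width: int, height: int, center: tuple[float, float] | None = None
) -> VignettingPattern:
    """Build the radial pattern P(x, y) for a width x height image.

    ``P`` is the Euclidean distance from the centre, normalised by the
    largest centre-to-corner distance so that the centre maps to 0 and
    the farthest corner to exactly 1 (all four corners when the centre
    is the exact image centre).
    """
    if width < 1 or height < 1:
        raise ValueError("pattern dimensions must be >= 1")
    if center is None:
        center = ((width - 1) / 2.0, (height - 1) / 2.0)
    cx, cy = center
    x = np.arange(width, dtype=float)
    y = np.arange(height, dtype=float)
    dist = np.sqrt((x[None, :] - cx) ** 2 + (y[:, None] - cy) ** 2)
    corners = np.array(
        [
            np.hypot(0 - cx, 0 - cy),
            np.hypot(width - 1 - cx, 0 - cy),
            np.hypot(0 - cx, height - 1 - cy),
            np.hypot(width - 1 - cx, height - 1 - cy),
        ]
    )
    values = dist / corners.max()
    return VignettingPattern(values=values, center=(cx, cy))


def vignetting_correct(
    image: np.ndarray,
    pattern: VignettingPattern,
    gains: VignettingGains = VignettingGains(),
    max_level: int = 255,
) -> np.ndarray:
    """Multiplicative per-channel correction ``C = (1 + K * P) * channel``.

    Integer input is corrected in floating point and rounded half-up;
    values above ``max_level`` are clamped (clamp events are logged).
    With the default gains only the red plane changes.
    """
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("image must be an (H, W, 3) RGB array")
    if pattern.values.shape != img.shape[:2]:
        raise ValueError(
            f"pattern shape {pattern.values.shape} does not match image "
            f"shape {img.shape[:2]}"
        )
    was_integer = np.issubdtype(img.dtype, np.integer)
    out = img.astype(float).copy()
    for ch, k in enumerate((gains.k_r, gains.k_g, gains.k_b)):
        if k != 0.0:
            out[:, :, ch] *= 1.0 + k * pattern.values
    n_clamped = int(np.count_nonzero(out > max_level))
    if n_clamped:
        logger.debug("vignetting correction clamped %d values", n_clamped)
    np.clip(out, 0.0, float(max_level), out=out)
    if was_integer:
        out = np.floor(out + 0.5).astype(img.dtype)
    return out
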