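"""Synthetic field-scene renderer with a linear sensor model.

Renders a flat field seen through the package's camera model: soil
background, crop rows running in the direction of travel (75 cm apart,
as in maize), randomly scattered weed blobs between the rows, and
optionally a 1 x 1 m bright-orange cardboard (the resolution target) and
a four-colour reference panel whose white quadrant drives exposure
control.  Every frame comes with exact ground-truth masks rendered from
the same geometry, so segmentation and scoring are testable without
field data.

The sensor model is linear in exposure time: a pixel's digital level is
its scene colour scaled by ``E_t / base_exposure_us``, attenuated in the
red channel by division by ``(1 + K * P)`` (the radial vignetting whose
exact inverse is the package's multiplicative correction), perturbed by
additive Gaussian noise, then rounded and clipped to 8 bits.

Scene colours carry per-pixel variation: a seeded soil texture, and a
seeded per-pixel "dilution" of vegetation colour toward the soil colour
that emulates mixed boundary pixels, shading and senescent material.
The dilution is left-skewed (most canopy pixels nearly pure), which
gives the greenness histogram of vegetation the long low tail that real
crop images show; the learned global threshold then falls close to the
soil greenness, exactly the regime in which corner vignetting produces
false vegetation and insufficient exposure produces over-segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources

import numpy as np

from agrocam.geometry import (
    ArrangementTable,
    CameraModel,
    GroundROI,
    build_pose,
)
from agrocam.illumination import (
    ExposureLoopResult,
    ExposureState,
    exposure_control_loop,
)

__all__ = [
    "SceneSpec",
    "SensorSpec",
    "PanelSpec",
    "RenderedFrame",
    "render",
    "render_exposure_series",
    "render_condition_pairs",
    "white_panel_rect",
    "make_table1_fixture",
]

MAX_LEVEL = 255


@dataclass(frozen=True)
class PanelSpec:
    """Four-colour reference panel lying in view ahead of the vehicle.

    Quadrants (white, red, green, blue) split a ``width_m x depth_m``
    rectangle whose near edge is ``distance_m`` ahead; the white quadrant
    is the near-left one.
    """

    distance_m: float = 2.2
    width_m: float = 1.2
    depth_m: float = 0.8
    lateral_offset_m: float = 0.0
    colors: tuple = (
        (245.0, 245.0, 245.0),  # white
        (190.0, 60.0, 55.0),  # red
        (60.0, 160.0, 70.0),  # green
        (55.0, 75.0, 185.0),  # blue
    )


@dataclass(frozen=True)
class SceneSpec:
    """Scene content and colour statistics.

    Crop rows are spaced ``row_spacing_m`` (0.75 m, as in maize) and run
    in the direction of travel.  ``weed_density`` is the approximate
    fraction of inter-row ground covered by weed blobs.  Colours are
    nominal scene radiances on the 8-bit scale at the sensor's reference
    exposure; per-pixel texture and vegetation dilution are seeded by
    ``weed_seed``.
    """

    row_spacing_m: float = 0.75
    row_width_m: float = 0.14
    n_rows: int = 5
    weed_density: float = 0.10
    weed_seed: int = 0
    cardboard: GroundROI | None = None
    panel: PanelSpec | None = None
    soil_color: tuple = (115.0, 100.0, 78.0)
    crop_color: tuple = (72.0, 108.0, 62.0)
    weed_color: tuple = (82.0, 108.0, 66.0)
    cardboard_color: tuple = (240.0, 120.0, 30.0)
    sky_color: tuple = (200.0, 212.0, 235.0)
    soil_texture_sd: float = 4.0
    veg_dilution_beta: tuple[float, float] = (0.6, 1.4)
    field_half_width_m: float = 6.0
    far_limit_m: float = 30.0

    def __post_init__(self) -> None:
        if self.row_spacing_m <= 0:
            raise ValueError("row_spacing_m must be positive")
        if not 0.0 <= self.weed_density < 1.0:
            raise ValueError("weed_density must be in [0, 1)")
        for name in ("soil_color", "crop_color", "weed_color", "cardboard_color"):
            c = getattr(self, name)
            if min(c) < 0 or max(c) > MAX_LEVEL:
                raise ValueError(f"{name} must lie in [0, 255]^3")


@dataclass(frozen=True)
class SensorSpec:
    """Linear sensor response: level = colour * E_t / base_exposure_us,
    red channel divided by (1 + K_r * P), additive Gaussian noise,
    clipped to ``saturation_level``."""

    base_exposure_us: float = 30000.0
    saturation_level: int = 255
    vignetting_strength: tuple[float, float, float] = (0.3, 0.0, 0.0)
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_exposure_us <= 0:
            raise ValueError("base_exposure_us must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if min(self.vignetting_strength) < 0:
            raise ValueError("vignetting strengths must be non-negative")


@dataclass
class RenderedFrame:
    """One rendered capture plus exact ground truth.

    ``levels`` holds the noise-free, unquantised sensor response (after
    exposure scaling and in-sensor vignetting); it is exactly linear in
    the exposure time and is what linearity checks should use.
    """

    image: np.ndarray
    truth_vegetation: np.ndarray
    truth_cardboard: np.ndarray
    truth_panel_white: np.ndarray
    levels: np.ndarray
    metadata: dict


def _ground_intersections(camera: CameraModel) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel ground-plane (z = 0) intersection points.

    Returns (points, valid): points is (H, W, 2) world X, Y; valid flags
    pixels whose ray hits the ground ahead of the camera.  Raises if no
    pixel sees the ground.
    """
    intr = camera.intrinsics
    W, H = intr.sensor_width_px, intr.sensor_height_px
    cx, cy = intr.principal
    u = (np.arange(W) + 0.5) - cx
    v = (np.arange(H) + 0.5) - cy
    uu, vv = np.meshgrid(u, v)
    f_px = intr.focal_px
    if intr.projection == "rectilinear":
        dirs = np.stack([uu / f_px, vv / f_px, np.ones_like(uu)], axis=-1)
    else:  # equidistant: pixel radius r -> off-axis angle r / f
        rr = np.hypot(uu, vv)
        theta = rr / f_px
        sin_t = np.sin(theta)
        with np.errstate(invalid="ignore", divide="ignore"):
            scale = np.where(rr > 0, sin_t / rr, 0.0)
        dirs = np.stack([uu * scale, vv * scale, np.cos(theta)], axis=-1)
    pose = build_pose(camera.extrinsics)
    world_dirs = dirs @ pose.rotation  # R^T applied to each direction
    h_m = camera.extrinsics.height_m
    dz = world_dirs[..., 2]
    valid = dz < -1e-9
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(valid, -h_m / dz, np.nan)
    pts = world_dirs[..., :2] * t[..., None]
    if not valid.any():
        raise ValueError("camera sees no ground: horizon-only view")
    return pts, valid


def _in_rect(pts, x0, x1, y0, y1):
    return (
        (pts[..., 0] >= x0)
        & (pts[..., 0] < x1)
        & (pts[..., 1] >= y0)
        & (pts[..., 1] < y1)
    )


def _weed_blobs(scene: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Seeded random ellipses between the rows: (n, 5) of
    (cx, cy, rx, ry, angle)."""
    half_span = scene.row_spacing_m * scene.n_rows / 2.0
    x0, x1 = 0.5, scene.far_limit_m / 2.0
    area = (x1 - x0) * 2 * half_span * scene.weed_density
    mean_blob = np.pi * 0.12 * 0.08
    n = int(area / mean_blob)
    if n == 0:
        return np.zeros((0, 5))
    cxs = rng.uniform(x0, x1, n)
    cys = rng.uniform(-half_span, half_span, n)
    rxs = rng.uniform(0.06, 0.20, n)
    rys = rng.uniform(0.04, 0.14, n)
    angs = rng.uniform(0, np.pi, n)
    return np.column_stack([cxs, cys, rxs, rys, angs])


def render(
    scene: SceneSpec,
    camera: CameraModel,
    sensor: SensorSpec,
    exposure_time_us: float | None = None,
) -> RenderedFrame:
    """Render one frame and its ground-truth masks.

    ``exposure_time_us`` defaults to the sensor's reference exposure, at
    which nominal scene colours map to their own digital levels (before
    vignetting and noise).
    """
    if exposure_time_us is None:
        exposure_time_us = sensor.base_exposure_us
    if exposure_time_us <= 0:
        raise ValueError("exposure time must be positive")
    pts, valid = _ground_intersections(camera)
    H, W = valid.shape

    # region classification (highest priority first: panel, cardboard,
    # crop rows, weeds, soil)
    veg = np.zeros((H, W), dtype=bool)
    card = np.zeros((H, W), dtype=bool)
    panel_white = np.zeros((H, W), dtype=bool)
    radiance = np.empty((H, W, 3), dtype=float)
    radiance[:] = scene.sky_color
    soil = valid.copy()

    scene_rng = np.random.default_rng(
        np.random.SeedSequence([scene.weed_seed, 2024])
    )

    radiance[valid] = scene.soil_color
    if scene.soil_texture_sd > 0:
        tex = scene_rng.normal(0.0, scene.soil_texture_sd, (H, W, 1))
        radiance[valid] += np.broadcast_to(tex, (H, W, 3))[valid]

    # crop rows along X, centred laterally
    offsets = (np.arange(scene.n_rows) - (scene.n_rows - 1) / 2.0) * scene.row_spacing_m
    row_mask = np.zeros((H, W), dtype=bool)
    for off in offsets:
        row_mask |= valid & (
            np.abs(pts[..., 1] - off) <= scene.row_width_m / 2.0
        ) & (pts[..., 0] > 0) & (pts[..., 0] < scene.far_limit_m)
    veg |= row_mask

    weed_mask = np.zeros((H, W), dtype=bool)
    for cx_, cy_, rx_, ry_, ang in _weed_blobs(scene, scene_rng):
        dx = pts[..., 0] - cx_
        dy = pts[..., 1] - cy_
        ca, sa = np.cos(ang), np.sin(ang)
        xr = dx * ca + dy * sa
        yr = -dx * sa + dy * ca
        weed_mask |= valid & ((xr / rx_) ** 2 + (yr / ry_) ** 2 <= 1.0)
    weed_mask &= ~row_mask
    veg |= weed_mask

    radiance[row_mask] = scene.crop_color
    radiance[weed_mask] = scene.weed_color

    # mixed-pixel dilution: pull each vegetation pixel toward soil by a
    # left-skewed Beta fraction (most pixels nearly pure canopy)
    a_b, b_b = scene.veg_dilution_beta
    if a_b > 0 and b_b > 0 and veg.any():
        mix = scene_rng.beta(a_b, b_b, int(veg.sum()))[:, None]
        soil_c = np.asarray(scene.soil_color)
        radiance[veg] = radiance[veg] * (1 - mix) + soil_c[None, :] * mix

    if scene.cardboard is not None:
        cb = scene.cardboard
        card = valid & _in_rect(
            pts,
            cb.distance_d_m,
            cb.distance_d_m + cb.depth_m,
            cb.lateral_offset_m - cb.width_m / 2.0,
            cb.lateral_offset_m + cb.width_m / 2.0,
        )
        radiance[card] = scene.cardboard_color
        veg &= ~card

    if scene.panel is not None:
        p = scene.panel
        x_mid = p.distance_m + p.depth_m / 2.0
        y_mid = p.lateral_offset_m
        quads = [
            # (x0, x1, y0, y1, color); white = near-left
            (p.distance_m, x_mid, y_mid, y_mid + p.width_m / 2.0, p.colors[0]),
            (p.distance_m, x_mid, y_mid - p.width_m / 2.0, y_mid, p.colors[1]),
            (x_mid, p.distance_m + p.depth_m, y_mid, y_mid + p.width_m / 2.0, p.colors[2]),
            (x_mid, p.distance_m + p.depth_m, y_mid - p.width_m / 2.0, y_mid, p.colors[3]),
        ]
        for i, (x0, x1, y0, y1, col) in enumerate(quads):
            q = valid & _in_rect(pts, x0, x1, y0, y1)
            radiance[q] = col
            veg &= ~q
            card &= ~q
            if i == 0:
                panel_white = q

    # linear exposure response
    levels = radiance * (exposure_time_us / sensor.base_exposure_us)

    # in-sensor vignetting: per-channel division by (1 + K * P)
    if any(k > 0 for k in sensor.vignetting_strength):
        from agrocam.illumination import vignetting_pattern

        pat = vignetting_pattern(W, H).values
        for ch, k in enumerate(sensor.vignetting_strength):
            if k > 0:
                levels[:, :, ch] /= 1.0 + k * pat

    levels_clean = levels.copy()
    if sensor.noise_sd > 0:
        noise_rng = np.random.default_rng(
            np.random.SeedSequence([sensor.seed, 77])
        )
        levels = levels + noise_rng.normal(0.0, sensor.noise_sd, levels.shape)

    image = np.clip(np.floor(levels + 0.5), 0, sensor.saturation_level).astype(
        np.uint8
    )
    metadata = {
        "exposure_time_us": float(exposure_time_us),
        "camera": camera,
        "scene": scene,
        "sensor": sensor,
    }
    return RenderedFrame(
        image=image,
        truth_vegetation=veg,
        truth_cardboard=card,
        truth_panel_white=panel_white,
        levels=levels_clean,
        metadata=metadata,
    )


def render_exposure_series(
    scene: SceneSpec,
    camera: CameraModel,
    sensor: SensorSpec,
    exposures_us,
) -> list[RenderedFrame]:
    """Render the same scene (same seeds) at several exposure times."""
    exposures = list(exposures_us)
    if not exposures:
        raise ValueError("exposure list must be non-empty")
    if min(exposures) <= 0:
        raise ValueError("exposure times must be positive")
    return [render(scene, camera, sensor, e) for e in exposures]


def white_panel_rect(frame: RenderedFrame, shrink: float = 0.5) -> tuple[int, int, int, int]:
    """Axis-aligned rectangle (x, y, w, h) inside the white panel quadrant.

    Takes the quadrant's bounding box shrunk about its centre; ``shrink``
    is the retained linear fraction.  Raises if the frame has no white
    panel pixels.
    """
    mask = frame.truth_panel_white
    if not mask.any():
        raise ValueError("frame contains no white panel pixels")
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    y0, y1 = rows[0], rows[-1] + 1
    x0, x1 = cols[0], cols[-1] + 1
    cx, cy = (x0 + x1) / 2.0, (y0 + y1) / 2.0
    w = max(1, int((x1 - x0) * shrink))
    h = max(1, int((y1 - y0) * shrink))
    x = int(round(cx - w / 2.0))
    y = int(round(cy - h / 2.0))
    return (x, y, w, h)


def render_condition_pairs(
    scene: SceneSpec,
    camera: CameraModel,
    sensor: SensorSpec,
    n_pairs: int,
    seed: int = 0,
    under_h_frac_range: tuple[float, float] = (0.35, 0.60),
    exposure_state: ExposureState | None = None,
    max_iter: int = 10,
) -> tuple[list[tuple[np.ndarray, np.ndarray]], list[np.ndarray]]:
    """Generate (under-exposed, exposure-adjusted) image pairs with truths.

    Each pair renders a fresh scene variant (new weed layout and sensor
    noise, ambient illumination varied across 'days' by scaling the
    sensor's reference exposure).  The first image is captured at an
    exposure that puts the white-panel statistic H at a seeded fraction
    of saturation below the control band; the second is captured after
    running the exposure-control loop against the rendered sensor.
    Requires a scene with a reference panel.
    """
    if scene.panel is None:
        raise ValueError("condition pairs need a scene with a reference panel")
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4242]))
    pairs: list[tuple[np.ndarray, np.ndarray]] = []
    truths: list[np.ndarray] = []
    state0 = exposure_state or ExposureState(exposure_time_us=sensor.base_exposure_us)
    for i in range(n_pairs):
        ambient = rng.uniform(0.7, 1.3)
        scene_i = replace(scene, weed_seed=scene.weed_seed + 1000 * i + 1)
        sensor_i = replace(
            sensor,
            base_exposure_us=sensor.base_exposure_us / ambient,
            seed=sensor.seed + 1000 * i + 1,
        )

        def capture(e_t: float, _scene=scene_i, _sensor=sensor_i):
            return render(_scene, camera, _sensor, e_t).image

        # calibrate the under-exposure so H starts below the band
        probe = render(scene_i, camera, sensor_i, sensor_i.base_exposure_us)
        rect = white_panel_rect(probe)
        from agrocam.illumination import sample_white_panel

        h_ref = sample_white_panel(probe.image, rect).h_stat
        target = rng.uniform(*under_h_frac_range) * state0.max_level
        e_under = sensor_i.base_exposure_us * target / max(h_ref, 1.0)
        under = render(scene_i, camera, sensor_i, e_under)

        result: ExposureLoopResult = exposure_control_loop(
            capture,
            rect,
            replace(state0, exposure_time_us=e_under),
            max_iter=max_iter,
        )
        adjusted = render(
            scene_i, camera, sensor_i, result.state.exposure_time_us
        )
        pairs.append((under.image, adjusted.image))
        truths.append(under.truth_vegetation)
    return pairs, truths


def make_table1_fixture() -> ArrangementTable:
    """The packaged 125-record field survey of ROI pixel counts.

    Measured pixel counts of a 1 x 1 m ground target over the 5 x 5 x 5
    grid of pitch (10-50 deg), height (210-230 cm) and distance
    (3.0-5.0 m).  The five entries printed with decimal points in the
    d = 4.0 m, h = 225 cm row of the source table are thousands
    separators and are stored as such.
    """
    ref = resources.files("agrocam.data").joinpath("table1_arrangements.csv")
    with resources.as_file(ref) as path:
        return ArrangementTable.from_csv(path)
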