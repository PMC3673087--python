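"""YAML/JSON run configuration with strict validation.

Every block mirrors one module's parameter set; units are embedded in the
key names (``_mm``, ``_um``, ``_cm``, ``_m``, ``_us``) to keep the cm/m
mixing that plagues arrangement tables out of config files.  Unknown keys
are rejected.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from agrocam.geometry import (
    CameraExtrinsics,
    CameraIntrinsics,
    CameraModel,
    GroundROI,
)
from agrocam.illumination import ExposureState, VignettingGains
from agrocam.segmentation import OrangeBounds
from agrocam.synthscene import PanelSpec, SceneSpec, SensorSpec

__all__ = ["RunConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CameraConfig(_Strict):
    focal_length_mm: float = 10.0
    pixel_pitch_um: float = 5.5
    sensor_width_px: int = 2336
    sensor_height_px: int = 1752
    projection: str = "equidistant"
    pitch_alpha_deg: float = 20.0
    roll_theta_deg: float = 0.0
    yaw_beta_deg: float = 0.0
    height_h_cm: float = 220.0

    def intrinsics(self) -> CameraIntrinsics:
        return CameraIntrinsics(
            focal_length_mm=self.focal_length_mm,
            pixel_pitch_um=self.pixel_pitch_um,
            sensor_width_px=self.sensor_width_px,
            sensor_height_px=self.sensor_height_px,
            projection=self.projection,
        )

    def extrinsics(self) -> CameraExtrinsics:
        return CameraExtrinsics(
            pitch_alpha_deg=self.pitch_alpha_deg,
            height_h_cm=self.height_h_cm,
            roll_theta_deg=self.roll_theta_deg,
            yaw_beta_deg=self.yaw_beta_deg,
        )

    def model(self) -> CameraModel:
        return CameraModel(intrinsics=self.intrinsics(), extrinsics=self.extrinsics())


class RoiConfig(_Strict):
    distance_d_m: float = 3.0
    width_m: float = 1.0
    depth_m: float = 1.0
    lateral_offset_m: float = 0.0

    def roi(self) -> GroundROI:
        return GroundROI(**self.model_dump())


class SceneConfig(_Strict):
    row_spacing_m: float = 0.75
    row_width_m: float = 0.14
    n_rows: int = 5
    weed_density: float = Field(0.10, ge=0.0, lt=1.0)
    weed_seed: int = 0
    cardboard: RoiConfig | None = None
    with_panel: bool = True
    panel_distance_m: float = 2.2

    def scene(self) -> SceneSpec:
        return SceneSpec(
            row_spacing_m=self.row_spacing_m,
            row_width_m=self.row_width_m,
            n_rows=self.n_rows,
            weed_density=self.weed_density,
            weed_seed=self.weed_seed,
            cardboard=self.cardboard.roi() if self.cardboard else None,
            panel=PanelSpec(distance_m=self.panel_distance_m)
            if self.with_panel
            else None,
        )


class SensorConfig(_Strict):
    base_exposure_us: float = 30000.0
    noise_sd: float = Field(2.0, ge=0.0)
    vignetting_kr: float = Field(0.3, ge=0.0)
    vignetting_kg: float = Field(0.0, ge=0.0)
    vignetting_kb: float = Field(0.0, ge=0.0)
    seed: int = 0

    def sensor(self) -> SensorSpec:
        return SensorSpec(
            base_exposure_us=self.base_exposure_us,
            noise_sd=self.noise_sd,
            vignetting_strength=(
                self.vignetting_kr,
                self.vignetting_kg,
                self.vignetting_kb,
            ),
            seed=self.seed,
        )


class ExposureConfig(_Strict):
    a: float = Field(0.90, gt=0.0, lt=1.0)
    b: float = Field(0.98, gt=0.0, le=1.0)
    p: float = Field(0.20, gt=0.0, lt=1.0)
    max_level: float = 255.0
    max_iter: int = Field(10, ge=1)
    initial_exposure_us: float = 20000.0

    @model_validator(mode="after")
    def _band(self):
        if self.a >= self.b:
            raise ValueError("exposure band requires a < b")
        return self

    def state(self) -> ExposureState:
        return ExposureState(
            exposure_time_us=self.initial_exposure_us,
            lower_frac=self.a,
            upper_frac=self.b,
            adjust_frac=self.p,
            max_level=self.max_level,
        )


class VignettingConfig(_Strict):
    k_r: float = Field(0.3, ge=0.0)
    k_g: float = Field(0.0, ge=0.0)
    k_b: float = Field(0.0, ge=0.0)

    def gains(self) -> VignettingGains:
        return VignettingGains(k_r=self.k_r, k_g=self.k_g, k_b=self.k_b)


class SegmentationConfig(_Strict):
    n_samples: int = Field(2000, ge=2)
    seed: int = 0
    hue_min_deg: float = 15.0
    hue_max_deg: float = 40.0
    sat_min: float = Field(0.5, ge=0.0, le=1.0)
    val_min: float = Field(0.5, ge=0.0, le=1.0)

    def orange_bounds(self) -> OrangeBounds:
        return OrangeBounds(
            hue_min_deg=self.hue_min_deg,
            hue_max_deg=self.hue_max_deg,
            sat_min=self.sat_min,
            val_min=self.val_min,
        )


class EvaluationConfig(_Strict):
    crop_top_third: bool = True


class RunConfig(_Strict):
    """Top-level configuration binding all pipeline blocks."""

    camera: CameraConfig = CameraConfig()
    scene: SceneConfig = SceneConfig()
    sensor: SensorConfig = SensorConfig()
    exposure: ExposureConfig = ExposureConfig()
    vignetting: VignettingConfig = VignettingConfig()
    segmentation: SegmentationConfig = SegmentationConfig()
    evaluation: EvaluationConfig = EvaluationConfig()


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a YAML (or JSON) run configuration.

    ``None`` or an empty file yields the pure defaults.  Parse failures,
    invariant violations and unknown keys each raise with a distinct,
    field-naming message.
    """
    if path is None:
        return RunConfig()
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        return RunConfig()
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    return RunConfig.model_validate(data)
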