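"""Shared fixtures: cameras at survey scale and scaled-down render setups."""

import numpy as np
import pytest

from agrocam.geometry import CameraExtrinsics, CameraIntrinsics, CameraModel
from agrocam.synthscene import PanelSpec, SceneSpec, SensorSpec


@pytest.fixture
def intrinsics():
    """Full-resolution survey camera (equidistant default)."""
    return CameraIntrinsics()


@pytest.fixture
def rectilinear_intrinsics():
    return CameraIntrinsics(projection="rectilinear")


@pytest.fixture
def small_intrinsics():
    """Quarter-scale sensor with the same field of view (pixel pitch
    scaled up by the same factor)."""
    return CameraIntrinsics(
        sensor_width_px=584, sensor_height_px=438, pixel_pitch_um=22.0
    )


@pytest.fixture
def operating_camera(small_intrinsics):
    """The chosen operating arrangement (pitch 20 deg, height 220 cm) on
    the quarter-scale sensor."""
    return CameraModel(
        intrinsics=small_intrinsics,
        extrinsics=CameraExtrinsics(pitch_alpha_deg=20.0, height_h_cm=220.0),
    )


@pytest.fixture
def panel_scene():
    return SceneSpec(panel=PanelSpec())


@pytest.fixture
def quiet_sensor():
    """Noise-free, vignetting-free sensor for deterministic checks."""
    return SensorSpec(noise_sd=0.0, vignetting_strength=(0.0, 0.0, 0.0))


@pytest.fixture
def default_sensor():
    return SensorSpec()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
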