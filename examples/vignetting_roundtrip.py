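"""Vignetting correction and its exactness on synthetic imagery.

The UV/IR cut filter attenuates red toward the image corners.  The
renderer models this as division of the red channel by (1 + 0.3 * P)
with P the radial pattern (0 at the centre, 1 at the corners); the
correction multiplies by the same factor, so the round trip should
restore red to within integer rounding wherever nothing clipped.
"""

import numpy as np

from agrocam.geometry import CameraExtrinsics, CameraIntrinsics, CameraModel
from agrocam.illumination import VignettingGains, vignetting_correct, vignetting_pattern
from agrocam.synthscene import SceneSpec, SensorSpec, render

intr = CameraIntrinsics(sensor_width_px=584, sensor_height_px=438, pixel_pitch_um=22.0)
camera = CameraModel(intr, CameraExtrinsics(pitch_alpha_deg=20, height_h_cm=220))
scene = SceneSpec()

clean = render(scene, camera, SensorSpec(noise_sd=0.0, vignetting_strength=(0, 0, 0)))
shaded = render(scene, camera, SensorSpec(noise_sd=0.0, vignetting_strength=(0.3, 0, 0)))

corner_drop = (
    clean.image[..., 0].astype(int) - shaded.image[..., 0].astype(int)
)
print(f"red loss at the corners before correction: up to {corner_drop.max()} levels")

pattern = vignetting_pattern(intr.sensor_width_px, intr.sensor_height_px)
corrected = vignetting_correct(shaded.image, pattern, VignettingGains(k_r=0.3))

unclipped = (clean.image[..., 0] < 255) & (shaded.image[..., 0] < 255)
err = corrected[..., 0].astype(int) - clean.image[..., 0].astype(int)
print(
    f"after correction: max |red error| = {np.abs(err[unclipped]).max()} level "
    f"over {unclipped.sum():,} unclipped pixels"
)
print(
    "green/blue untouched:",
    bool((corrected[..., 1:] == shaded.image[..., 1:]).all()),
)
print("a corner pixel with R = 100 and P = 1 corrects to (1 + 0.3) * 100 = 130")
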