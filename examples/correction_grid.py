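"""The 2 x 2 illumination-correction experiment on synthetic pairs.

For several simulated 'field stops', an under-exposed frame and an
exposure-adjusted frame of the same scene are captured; each is
segmented with and without vignetting correction and scored against
exact ground truth.  Mean PCC should order
(no corrections) < (vignetting only), (no corrections) <
(exposure only) < (both) — the same qualitative pattern measured on
real field imagery.

A small batch keeps this example quick; the acceptance script runs the
full ten-pair version.
"""

from agrocam.evaluation import condition_grid_report
from agrocam.geometry import CameraExtrinsics, CameraIntrinsics, CameraModel
from agrocam.synthscene import PanelSpec, SceneSpec, SensorSpec, render_condition_pairs

intr = CameraIntrinsics(sensor_width_px=584, sensor_height_px=438, pixel_pitch_um=22.0)
camera = CameraModel(intr, CameraExtrinsics(pitch_alpha_deg=20, height_h_cm=220))
scene = SceneSpec(panel=PanelSpec())
sensor = SensorSpec()

pairs, truths = render_condition_pairs(scene, camera, sensor, n_pairs=4, seed=7)
report = condition_grid_report(pairs, truths, seed=7)
print(report.to_string(index=False))
print()
print("uncorrected frames lose accuracy two ways: sensor noise dominates the")
print("weak signal when under-exposed, and red attenuation drags corner soil")
print("past the greenness threshold; each correction removes one error source")
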