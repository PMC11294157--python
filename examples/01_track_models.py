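"""Track one drop-vertical-jump trial with all four trunk models.

Generates a single synthetic participant (static calibration pose plus a
noisy DVJ trial), calibrates each tracking model against the four-marker
Definition Model in the static trial, tracks trunk tilt through the jump
and prints the cycle metrics next to the generator's ground truth.
"""
import numpy as np

import trunktrack as tt

template = tt.SubjectTemplate.default(height_cm=168.6, sex="F")
static, _ = tt.generate_trial(template, tt.MotionProfile.static(),
                              tt.ArtifactConfig.none(), rng=0)
trial, truth = tt.generate_trial(
    template, tt.MotionProfile.dvj(peak_flexion_deg=45.0),
    tt.ArtifactConfig(noise_sigma_mm=0.5, sta_amplitude_mm=3.0,
                      bra_shift_mm=15.0), rng=1)

smoothed = tt.smooth_trial(trial, tt.SmoothingConfig(10.0))
print(f"DVJ cycle: initial contact frame {truth.annotation['initial_contact']},"
      f" take-off frame {truth.annotation['take_off']}")
print(f"{'model':<12} {'mean':>7} {'max':>7} {'min':>7} {'rom':>7}  (deg)")
for model in tt.TrunkModel:
    cal = tt.calibrate(static, tt.MODEL_SPECS[model])
    series = tt.track_trial(smoothed, cal)
    m = tt.compute_metrics(series, truth.annotation)
    print(f"{model.label:<12} {m.mean:7.2f} {m.max:7.2f} "
          f"{m.min:7.2f} {m.rom:7.2f}")
m = truth.metrics
print(f"{'truth':<12} {m.mean:7.2f} {m.max:7.2f} {m.min:7.2f} {m.rom:7.2f}")
print("\nPositive tilt = flexion (forward lean).  The 15 mm sports-bra shift "
      "of the XP\nmarker biases the Definition Model, which uses XP for "
      "tracking; the M-STRN model\n(tracking on the mid-sternum marker "
      "instead) stays closer to the truth.")
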