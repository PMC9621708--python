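"""Process one trial's marker table into cycles and acceleration-peak events.

The chain: find the circularly moving (pedal) marker among decoys, resample
its vertical coordinate to 100 Hz, low-pass at 10 Hz (zero phase), detect one
position peak per cycle, convert displacement to a 0-180 degree rotation
angle, differentiate twice, and detect the two acceleration peaks per cycle.
"""

import numpy as np

from limbspeech import TrialSpec, process_trial, simulate_biking_kinematics

spec = TrialSpec(
    "P01", "female", 1, "legMot",
    duration=60.0, cycle_duration_mean=1.07, cycle_duration_sd=0.12, seed=42,
)
markers, truth = simulate_biking_kinematics(spec)
kin = process_trial(markers)

print(f"pedal marker: {kin.marker_id} (ground truth {truth.pedal_marker_id})")
print(f"cycles detected: {kin.cycle_durations.size}, "
      f"mean duration {kin.cycle_durations.mean():.2f} s")
print(f"acceleration peaks: {kin.acc_peak_times.size} "
      f"({kin.acc_peak_times.size / kin.cycle_durations.size:.2f} per cycle)")
print(f"median peak magnitude: {np.median(kin.acc_peak_magnitudes):.2f} m/s^2")
print(f"rotation angle range: {kin.angle.min():.1f} .. {kin.angle.max():.1f} deg")

err = np.abs(kin.acc_peak_times[:, None] - truth.true_acc_peak_times[None, :]).min(axis=1)
print(f"timing: {np.mean(err < 0.03):.0%} of detected peaks within 30 ms of ground truth")
# Leg cycles of ~1.07 s with an ~8 cm crank give impulse magnitudes with a
# median near 3.5 m/s^2; arms (~1.3 s, smaller stroke) land near 2.
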