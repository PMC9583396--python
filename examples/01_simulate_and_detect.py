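"""Simulate one elbow-extension session and detect its movements.

Builds a synthetic limb session (minimum-jerk extensions, EMG with a planted
beta-band common drive), runs the kinematic preprocessing chain and compares
detected movement bounds with the generator's ground truth.
"""

import numpy as np

from imcoh import SynthConfig, simulate_session
from imcoh.preprocess import angular_velocity, detect_movement_bounds, preprocess_kinematics

sess = simulate_session(SynthConfig(n_trials=6, seed=1))
angle = preprocess_kinematics(sess.recording.angle)  # 6 Hz zero-lag low-pass
velocity = angular_velocity(angle)
bounds = detect_movement_bounds(velocity)  # 0.01 deg/s threshold
extensions = [b for b in bounds if b.direction == "extension"]

print(f"movements detected: {len(bounds)} ({len(extensions)} extensions)")
peak_err = [
    1000 * abs(b.peak_velocity_time - e.peak_velocity_time)
    for b, e in zip(extensions, sess.truth.events)
]
onset_shift = [
    1000 * (e.onset - b.onset) for b, e in zip(extensions, sess.truth.events)
]
print(f"mean peak-velocity timing error: {np.mean(peak_err):.1f} ms")
print(f"mean onset broadening from the 6 Hz filter: {np.mean(onset_shift):.0f} ms")
print(f"peak velocity: {extensions[0].peak_velocity:.1f} deg/s "
      "(minimum-jerk closed form: 15*70/8 = 131.25)")
# Every planted extension is recovered and the peak-velocity anchor (which
# positions the coherence window) is exact to a few ms.  The onsets sit
# ~150 ms early because the zero-phase 6 Hz low-pass spreads the velocity
# bell at the tiny 0.01 deg/s threshold; on unfiltered noiseless velocity the
# detector matches the analytic crossings within one kinematic sample.
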