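"""Trial-averaged wavelet coherence of a muscle pair and its beta-band volume.

Runs the full analysis for one simulated limb: preprocessing, trial
segmentation with 3 s pads, Morlet-wavelet magnitude-squared coherence
(350-bin grid, 0.23-79.97 Hz, wavenumber 10), the analytic significance mask
and the volume statistic in the 200 ms window before peak velocity.
"""

from imcoh import SynthConfig, simulate_session
from imcoh.pipeline import PipelineConfig, analyze_session

sess = simulate_session(SynthConfig(n_trials=8, seed=2))
rows, counts = analyze_session(sess.recording, sess.mvc_trials, PipelineConfig())

print(f"trials analyzed: {counts['trials_kept']}")
for row in rows:
    print(f"{row['muscle_pair']}: beta volume = {row['imc_volume']:.3f} coherence*Hz*s, "
          f"window angle = {row['mean_angle']:.1f} deg, "
          f"window velocity = {row['mean_velocity']:.1f} deg/s")
print(f"planted in-band MSC (both pairs): {sess.truth.theoretical_msc['BB-BR']:.2f}")
# The volume integrates significant coherence over the 13-31 Hz x 200 ms cell
# block; with unit coupling and equal source/noise power the planted in-band
# coherence is 0.25, so both pairs show clearly non-zero volumes.
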