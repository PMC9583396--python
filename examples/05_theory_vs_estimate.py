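"""Closed-form coherence of the common-drive model vs two estimators.

For x_i = a_i*s + n_i with a band-limited drive s, the in-band coherence is
(a1*a2*Ps)^2 / ((a1^2*Ps+P1)*(a2^2*Ps+P2)).  This script compares that value
with (a) scipy's Welch coherence on a long record and (b) the package's
trial-averaged wavelet estimator at K = 20 trials.
"""

import numpy as np
from scipy import signal

from imcoh import (
    WaveletParams,
    build_frequency_grid,
    generate_common_drive_emg,
    magnitude_squared_coherence,
    theoretical_msc,
    trial_averaged_spectra,
)

gains, ps, pn = (1.0, 1.0), 1.0, (1.0, 1.0)
truth = theoretical_msc(gains, ps, pn)

x1, x2, _ = generate_common_drive_emg(2**17, 1000, gains, seed=0)
f, c = signal.coherence(x1, x2, fs=1000, nperseg=4096)
welch = float(np.mean(c[(f >= 16) & (f <= 28)]))

rng = np.random.default_rng(1)
t1, t2 = [], []
for _ in range(20):
    a, b, _ = generate_common_drive_emg(2400, 1000, gains, seed=rng)
    t1.append(a)
    t2.append(b)
grid = build_frequency_grid(WaveletParams(), fs=1000)
a1, a2, cr = trial_averaged_spectra(t1, t2, 1000, grid)
msc = magnitude_squared_coherence(cr, a1, a2)
wavelet = float(np.nanmean(msc.values[(grid.freqs >= 16) & (grid.freqs <= 28)]))

print(f"theoretical in-band MSC : {truth:.3f}")
print(f"Welch estimate (n=2^17) : {welch:.3f}")
print(f"wavelet estimate (K=20) : {wavelet:.3f}")
# The wavelet estimate carries the usual finite-K positive bias of order
# (1-C)^2/K ~ 0.03 on top of the true 0.25; the long-record Welch estimate
# converges to the closed form.
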