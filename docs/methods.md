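# Methods

This note records the models, estimators, parameters and design choices
behind `imcoh`, in the spirit of a package methods appendix: what is
computed, under which assumptions, and what the synthetic-data tests do and
do not establish.

## Signals and preprocessing

One limb session consists of surface EMG from the long head of the triceps
brachii (TB, extensor/agonist), biceps brachii (BB) and brachioradialis (BR,
both flexors/antagonists during extension) sampled at 1000 Hz, and the elbow
angle at 125 Hz on a shared clock.  The chain is:

* elbow angle: fourth-order zero-lag (forward–backward) Butterworth low-pass
  at 6 Hz; angular velocity by central differences (zero-lag, second-order
  accurate — the literature convention for kinematic differentiation);
* movement detection: contiguous excursions of |v| above 0.01 °/s whose peak
  exceeds a 5 °/s gate (the micro-threshold alone would hang on any noise
  floor); onset/offset are found by searching outward from the velocity peak
  and refined to the sub-sample threshold crossing by linear interpolation,
  because at 125 Hz the nearest-sample rule alone can miss the analytic
  crossing by more than one sample.  On unfiltered noiseless minimum-jerk
  movements the recovered onset/offset are within 10 ms of the closed-form
  crossings; after the 6 Hz low-pass the detected window is systematically
  wider (≈ 150 ms per side at this threshold) — an inherent property of
  zero-phase filtering at a threshold five orders of magnitude below peak
  velocity, shared by any pipeline using this rule;
* EMG: 49–51 Hz band-stop (power line) then 3–100 Hz band-pass, both
  fourth-order zero-lag Butterworth; **no rectification** — coherence theory
  applies to the raw interference EMG, and rectification distorts power and
  coherence spectra;
* segmentation: each movement is cut with 3 s pads on both sides.  The pads
  exist solely to absorb wavelet edge effects and are cropped after the
  transform; kinematic event times are mapped to the EMG clock by
  nearest-sample conversion, and the signals themselves are never resampled
  (resampling EMG would distort its spectrum).

Only extension movements (angle increasing) are analyzed; the generator also
produces the slower return flexions, which the pipeline detects and
discards, exercising the direction rule.

## Wavelet coherence

The transform is a complex Morlet CWT with wavenumber ω₀ = 10, evaluated on
a **linear** grid of nvoice × J1 = 7 × 50 = 350 center frequencies
f_j = j·Δf with Δf = 79.97/350 ≈ 0.2285 Hz, i.e. 0.23–79.97 Hz in 0.23 Hz
steps (2 d.p.).  At 20 Hz this gives a time–frequency precision cell of
roughly 0.1 s × 3 Hz.  Scales follow the standard Morlet Fourier-factor
relation s = (ω₀ + √(2+ω₀²))/(4πf).

Implementation: per frequency in the Fourier domain,
ψ̂(sω) = π^(−1/4) √(2πs/dt) · exp(−(sω−ω₀)²/2) for ω > 0, applied by
FFT/IFFT.  Frequencies are grouped by their required zero-padding (six
e-folding times of their own wavelet), so low-frequency rows get long
unshared transforms while the many high-frequency rows batch at short ones;
the result equals a direct linear convolution with the sampled wavelet to
< 1e−6 (verified against an independent time-domain oracle).  Cells whose
distance to a segment edge is below the e-folding time √2·s are inside the
cone of influence; with 3 s pads every retained cell above ~1 Hz is safe.

For K movements aligned at their peak-velocity time (the anchor of the
quantification window) and cropped to the time span common to all trials,
the estimator is

    S_i(ω,u)  = (1/K) Σ_k |W_i^k(ω,u)|²          (auto-spectra)
    S_12(ω,u) = (1/K) Σ_k W_1^k(ω,u) · W_2^k(ω,u)*   (cross-spectrum)
    R²(ω,u)   = |S_12|² / (S_1 · S_2)  ∈ [0,1].

K ≥ 2 is enforced: the single-trial ratio is identically 1.  For display of
full-movement maps a percent-of-movement axis (onset → 0 %, offset → 100 %)
is provided; the statistic itself lives in absolute time because the 200 ms
window is defined in absolute time.

**Significance.**  The default rule is the analytic threshold for the
average of K independent spectra of Gaussian signals,
R² > 1 − α^(1/(K−1)) (α = 0.05 cellwise; 0.1459 at K = 20).  A surrogate
alternative re-pairs the trials of channel 2 by circular shifts of the trial
list and takes cellwise (1−α) quantiles; both rules are recorded in the
result metadata.  Monte-Carlo calibration shows the analytic rule marks
≈ α of cells within the EMG passband under independence; below the 3 Hz
high-pass edge the assumption of a complex-Gaussian cell fails (those
wavelets, with supports of seconds, carry no in-band energy there) and the
rule is conservative — the calibration check therefore evaluates the
fraction over grid rows ≥ 3 Hz.

**β-volume.**  IMC is quantified as the volume under significant coherence,
Σ R²·mask·Δf·Δt over 13–31 Hz × the 200 ms window ending at peak velocity
(units: coherence·Hz·s).  Raw R² is summed; subtracting the threshold first
is available behind a flag.  The same window yields the mean elbow angle and
mean angular velocity used as ANCOVA covariates.  The volume is additive
over disjoint bands/windows and homogeneous of degree 1 in R² under a fixed
mask (tested).

## Antagonist co-contraction

The MVC reference comes from three 5 s maximal isometric flexion trials; the
trial with the highest mean torque over its central 3 s plateau is selected
and the per-muscle reference RMS computed on that plateau (ramp-up/down
excluded).  MVC EMG passes through the same filters as movement EMG so the
ratio is not biased by the conditioning chain.  Per movement, each flexor's
RMS over [onset, offset] is divided by its reference; the per-muscle ratios
are averaged, then averaged across movements, and expressed in percent.
Ratio-before-average makes the index invariant to per-channel amplifier
gains (the alternative order is not, which is why it was chosen); RMS makes
it invariant to rectification.

## Synthetic sessions

The generator's defaults are the recording conditions the analysis targets:
20 extensions per limb, EMG at 1000 Hz and kinematics at 125 Hz on
independent clocks, rests uniform on 8–15 s, 90°→160° minimum-jerk
extensions of 1 s (peak velocity 15Δθ/8T = 131.25 °/s), a 2 s hold and a
slower (1.5 s) return flexion, plus three 5 s MVC trials with trapezoidal
torque, one designated +10 % maximal.

EMG is built as x_i = a_i·s + n_i, where s is white Gaussian noise filtered
into the 13–31 Hz drive band by the same fourth-order zero-lag band-pass
used in preprocessing (keeping band edges consistent) and rescaled to
variance P_s, and n_i is independent noise band-limited to the 3–100 Hz
analysis band.  **Powers are band-referenced**: `noise_power` is the noise
variance falling inside the drive band (empirically rescaled), so the
in-band coherence has the closed form

    MSC = (a₁a₂P_s)² / ((a₁²P_s + P₁)(a₂²P_s + P₂)),

e.g. 0.25 for unit gains and P_s = P.  Band-limiting the noise to 3–100 Hz
also makes the preprocessing band-pass near-transparent, so the planted
co-contraction RMS ratio survives filtering; the residual +0.5–0.7 point
bias on a 30 % ratio comes from the β drive passing the filters slightly
better than broadband noise, and stays well inside the ±2-point recovery
tolerance.

Muscle activity is envelope-gated: cosine ramps (0.1 s) outside a plateau
that extends 0.25 s past the analytic onset/offset — wide enough that the
filter-broadened detected window stays inside the plateau, where the signal
is stationary and the planted RMS ratio therefore holds over any sub-window.
Flexor amplitude in each movement is rescaled so that RMS over the movement
equals `cocontraction_ratio` × the planted MVC RMS, exactly by construction;
`amplitude_jitter` (default 0, i.e. off) adds movement-to-movement gain
variability if wanted.  The movement schedule (rest draws, MVC selection)
comes from a dedicated `event_seed` stream, so changing the noise seed
changes the noise but not a single event time — convenient for paired
comparisons.

Two-group cohorts (`CohortConfig`) draw a per-subject common-drive gain
(control ≈ 0.55 ± 0.10, "paretic" ≈ 0.85 ± 0.10) and give paretic subjects
a co-contraction ratio decreasing in their gain
(0.35 − 0.8·(gain − mean) ± 0.02), planting both the group coherence
difference and a negative within-group volume/co-contraction association.
The default of 16 subjects per group is a desk-scale version of the study
design this emulates (24 per group): a metrics-level Monte Carlo puts the
probability of recovering the planted association's sign at ≈ 0.90 for 8,
0.97 for 12 and 0.996 for 16 subjects per group.

What the generator does **not** emulate: motor-unit physiology (EMG is
Gaussian, not spike-driven), nonstationary drive strength within a movement,
electrode crosstalk, movement-time variability beyond the randomized rests,
kinematic sensor noise (off by default) and lesion anatomy.  Passing
recovery tests therefore establishes the correctness of the estimators and
plumbing under the model's assumptions, not robustness to every property of
clinical data.

## Group statistics

* **t-test**: pooled variance, df = n₁+n₂−2, Cohen's d on the pooled SD with
  a normal-approximation CI.
* **Box–Cox**: profile-ML λ (scipy).  Coherence volumes can be exactly zero
  (no significant cells), so when non-positive values occur an offset of
  half the smallest positive value is added first and recorded.
* **ANCOVA**: separate 2 (limb) × 2 (muscle pair) fits per limb contrast
  (not one three-limb model), with limb, pair, their interaction and four
  covariates; Type-III sums of squares with sum-to-zero factor coding
  (statsmodels OLS), per-term F, p and partial η² = SS/(SS+SS_err);
  balanced limb×pair cells are required and checked.  Significance at the
  corrected α = 0.017.  Under a null simulation the limb-term type-I rate is
  ≈ 0.017 (2000 replicates), and on covariate-free balanced data the fit
  reduces exactly to the textbook two-way ANOVA.
* **Partial Spearman**: rank-transform everything, regress the x- and
  y-ranks on covariate ranks, correlate the residuals; p from t with
  n−2−k df, CI by Fisher z.  The outlier variant removes points whose
  residual exceeds twice the residual SE in the x-model, y-model or either
  (default "either" — which model defines the rule is genuinely ambiguous,
  so both are exposed), then recomputes.
* **Demographics**: exact mean and sample SD (ddof = 1) plus
  "as-printed" integers by truncation toward zero, the printing convention
  adopted for clinical demographic tables in this package.

## Problem sizes and numerical choices

The test suite and the acceptance script scale simulations to desk size:
coherence calibration uses 2.4 s trial segments at K = 20 over 10–20 seeds,
the paired gain-sweep uses a fixed seed set across gains, co-contraction
recovery runs 10 full 20-movement sessions, the ANCOVA calibration 2000
null replicates at 24 subjects/group, and the end-to-end run 16 subjects per
group × 20 movements (12 in the test suite).  Wavelet padding (six
e-folding times per frequency), the 1e−6 oracle agreement, MSC clipping to
[0, 1] against rounding and NaN-masking of zero-power cells are the only
numerical tolerances in the chain; all randomness flows from explicit seeds.

## Known limitations

* The significance rule is a stated substitute: the analytic threshold and
  the trial-shuffling surrogate are standard, but the exact procedure behind
  published "significant coherence" contours varies between toolboxes.
* The volume statistic sums raw coherence over significant cells; summing
  exceedance (R² − threshold) is available but not the default.
* Very low frequency bins (< ~1 Hz) on short segments are
  edge-contaminated in any wavelet pipeline; they never enter the β-band
  statistic but appear in full maps, flagged by the cone of influence.
* The BB short/long heads are treated as one channel, as recorded by a
  single electrode pair.
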