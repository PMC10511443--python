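# Methods

This note documents the models, the synthetic data, the numerical choices,
and the limits of what the test suite demonstrates.

## Estimation model

Blood pressure is estimated per 10-s window (2-s shift) by a multilayer
perceptron with two hidden layers of 80 and 12 units, ReLU activations, a 20%
dropout layer after each hidden layer, a single linear output unit, MSE loss,
and the Adam optimizer at learning rate 10⁻³. SBP models take 11 inputs
(ΔDC, both contact pressures, both skin temperatures, HR, age, height,
weight, BMI, sex); DBP models take those plus the seven waveform-shape
features (CP, ST, DT, ST/DT, systolic/diastolic area ratio, K, AC/DC) — 18
inputs. Waveform features are read from the dorsal channel, the higher-SNR
site, and averaged over the window's accepted beats.

Training details the architecture does not fix were chosen for desk-scale
convergence and are exposed in `MLPConfig`: batch size 32, at most 500 epochs
(150 in the experiment drivers and acceptance script, which is past
convergence at these problem sizes), early stopping when validation MSE has
not improved for 30 epochs (15 in the drivers), best-validation weights
restored. Features are z-scored with statistics fitted on training rows only;
targets are internally z-scored for optimizer conditioning and predictions
mapped back to mmHg. One seed drives weight initialisation, shuffling and
dropout, so training is deterministic per seed. The network is implemented
directly on numpy: at ~1 600 weights this is fast, and it keeps dropout, the
externally supplied validation split and best-weights restoration under
explicit control.

A feature that is constant across a fold's training rows (e.g. `sex` when
every training subject in a tiny cohort happens to be male) is dropped for
that fold and recorded in the per-fold report.

## Signal conditioning

Pipeline order: zero-phase Butterworth low-pass (order 4, cutoff 10 Hz —
pulse energy lies below 10 Hz) → wavelet denoising (Daubechies-8, level 4 at
1 kHz, universal soft threshold σ̂·√(2 ln N) with σ̂ from the MAD of the
finest detail band) → baseline extraction (zero-phase Butterworth, order 2,
0.4 Hz — below the slowest plausible heart rate of ~0.5 Hz) → pulsatile =
denoised − baseline. The split is exact by construction. Filters use
reflection padding; windows overlapping the first or last baseline period
(2.5 s) of a session are excluded from feature extraction.

The baseline path is kept in absolute ADC counts: ΔDC is the method's key
feature and any per-channel standardization would destroy it.
Z-scoring applies to the pulsatile path only; since every beat-shape feature
is invariant to affine amplitude changes, whether it is applied per session
or per window has no effect on the features, and the exported standardized
representation is computed per channel over the session.

Downsampling (to the 500 Hz feature rate) is restricted to integer
decimation with an anti-alias FIR; arbitrary-ratio resampling is out of
scope.

## Beat delineation and features

Systolic peaks: `scipy.signal.find_peaks` with ≥ 0.3 s separation,
prominence ≥ 25% and height ≥ 55% of the robust (2nd–98th percentile) signal
amplitude — the height floor rejects dicrotic peaks, which stay well below
the percussion peak in this waveform family. Feet (beat onsets): walking back
from each peak, the last sample at or below the inter-beat minimum plus 5% of
the upstroke amplitude. Only complete foot-to-foot beats are used; detected
feet trail the true onsets by a few milliseconds (≈ 8–12 ms on the simulator,
within the 20 ms matching tolerance used throughout).

Dicrotic notch: the most prominent local minimum between the systolic peak
and 80% of the cardiac period; if none exists (merged single-lobe pulse), the
maximum of the second derivative in (peak + 0.1 CP, peak + 0.5 CP); failing
both, the beat is excluded from notch-dependent features. Feature
definitions: ST = onset→notch and DT = notch→end, so ST + DT = CP identically;
K = (mean − min)/(max − min) over the beat, computed on the baseline-removed
pulsatile beat (K is invariant to the constant DC offset, but computing it
after baseline removal also removes within-beat drift); areas above the beat
minimum by the trapezoid rule, split at the notch; AC/DC = peak-to-peak
pulsatile amplitude over the mean baseline of the beat. A window needs at
least 5 accepted beats to be valid.

Interface-sensor voltages are converted to pressure by monotone
piecewise-linear interpolation of a calibration-anchor table; the default
table matches the synthetic sensor's saturating response
V = V_sat(1 − e^(−P/p₀)) sampled every 250 Pa over 0–4 kPa. Out-of-range
voltages clamp with a warning.

Each window is labelled with the nearest-in-time cuff reference relative to
the window end (the estimate time) — reference timing against the continuous
estimate stream is otherwise underdetermined, and this is the convention used
throughout.

## Evaluation protocols and statistics

LOSO: one fold per subject; the remaining subjects' sessions are shuffled and
split 85/15 into train/validation at session level; the left-out subject's
sessions are the test set. Pooled: a single session-level 70/15/15 split with
subjects shared across sets. Test errors from all LOSO folds are concatenated
before computing ME/SD (one pooled scatter, not fold-averaged statistics).
Every report also carries the train-mean predictor evaluated under the
identical protocol as a floor baseline.

ME = mean(estimate − reference); SD uses the n−1 denominator. Bland–Altman
limits are the exact identities μ ± 1.96σ; rounding to two decimals happens
only at the reporting layer. AAMI: |ME| < 5 mmHg and SD < 8 mmHg, strict, so
ties fail. BHS: cumulative percentages of |error| ≤ 5/10/15 mmHg, graded A
(≥ 60/85/95), B (≥ 50/75/90), C (≥ 40/65/85), else D.

## The synthetic cohort

Reference conditions: 18 subjects × 4 sessions × 120 s. Profiles: age
N(25, 3) clipped to [18, 60], height N(170, 8) cm, BMI N(21.1, 2.6) with
weight derived, sex Bernoulli(0.7 male), resting HR N(70, 7) bpm.

Optical model per channel (ADC counts):

    signal = α_subj + β_ch·SV + γ·P_ch            DC level
           + A_drift · sin(2π f_r t + φ)          respiratory drift
           + amp_ch · g_subj · (template − mean)  AC pulses
           + white noise

with α_subj ~ N(50 000, 8 000) common to both channels, β_palmar = 2.0 and
β_dorsal = 3.5 counts/mL, γ = 0.005 counts/Pa, pulse amplitudes 400/600
counts with a per-subject log-normal gain (σ = 0.10), drift 150 counts at
0.25 Hz with the same phase on both channels (one respiration), and noise
σ = 15 counts (≈ 20 dB SNR against the AC component). DC ≫ AC, as in real
reflectance PPG. Because α and the drift are common-mode, the dorsal−palmar
DC difference reduces to (β_d − β_p)·SV + γ·(P_d − P_p) — differential
cancellation is exact by construction, which is what makes it testable. The
per-beat template (two positive Gaussian lobes; dicrotic amplitude
0.25 + 0.2·R and delay (0.45 + 0.05·R)·CP grow with peripheral resistance R)
is mean-centred before being added, so the constructed DC level is exactly
identifiable; the AC/DC split of a PPG is a convention, and this one makes
the ground truth unambiguous. A multiplicative-gain mode exists to stress the
additive-cancellation assumption.

Hemodynamics: per subject SV ~ N(70, 10) mL and R ~ N(1.0, 0.15); per session
SV and R jitter (σ = 5 mL, 0.05), HR ~ N(profile HR, 4), palmar contact
pressure U(0.5, 3) kPa with the dorsal pressure 200 Pa-correlated (one
strap), skin temperatures N(33, 1) °C. Blood pressure follows a linear
forward model — simulator choices, not published values:

    SBP = 40 + 0.8·SV + 0.2·HR − 1.5·(T̄ − 33) + 0.002·(P_p + P_d) + ε
    DBP = 20 + 40·R + 0.15·HR − 1.0·(T̄ − 33) + ε,     ε ~ N(0, 2) mmHg

encoding the qualitative physiology (SBP rises with stroke volume and heart
rate; DBP with peripheral resistance; both fall with skin temperature) with
recoverable structure. Cuff references are emitted every 2 s at the estimate
cadence — denser than a real cuff, which is acceptable because the
simulator's job is to exercise the pipeline. An optional per-subject BP
residual (`subject_bp_offset_sd`, default 0) adds inter-individual variance
that no measured feature explains, for stress-testing LOSO; under the
reference conditions the forward model is fully feature-recoverable and the
LOSO-vs-pooled gap that the experiments still show comes from genuine
cross-subject feature-range extrapolation.

**What passing tests do and do not show.** The simulator reproduces the
statistical structure the method assumes — additive subject offsets that
cancel differentially, beat morphology driven by peripheral resistance, a BP
signal linear in the latent state — but not real tissue optics (no
Beer–Lambert modelling), motion artifacts, arrhythmia, sparse/lagged cuff
references, or nonlinear physiology. Recovery results on synthetic cohorts
therefore validate the pipeline's correctness and its protocol-level
behaviour (e.g. LOSO error exceeding pooled-split error), not clinical
accuracy on real wrists.

## Numerical and edge-case choices

Zero wavelet threshold (noise-free input) skips shrinkage rather than divide
by zero. Sessions shorter than two baseline periods, cutoffs at or above
Nyquist, non-integer decimation factors, zero-variance standardization
inputs, and constant feature columns are rejected with named errors. Flat or
degenerate beats (zero amplitude, non-positive baseline) raise; windows with
fewer than 5 beats are flagged invalid, never raised. Fold-constant features
are dropped per fold. Session CSVs store values with `repr`, so 64-bit floats
round-trip exactly. All cohort generation flows from one `SeedSequence`;
pipeline stages draw named sub-seeds (< 2³¹) from the master seed.

## Known limitations

Beat segmentation assumes a constant-period, two-lobe pulse family; real PPG
with heart-rate variability, motion artifacts or flattened dicrotic waves
will lower sensitivity and may bias ST/DT. The dicrotic-notch fallback
(second-derivative maximum) is a heuristic. The pressure calibration assumes
a monotone sensor. The fusion model is a small MLP without uncertainty
estimates. DBP estimation is consistently less accurate than SBP in the LOSO
protocol — reflected-wave morphology generalizes less well across subjects
than the differential DC feature, which the evaluation surfaces rather than
hides. One published figure caption disagrees with its body text on the
pooled-protocol SBP mean error (−0.97 vs −0.81 mmHg); the limits-of-agreement
arithmetic supports −0.81, which is the value used in the worked examples.
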