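# dualppg

Cuffless continuous blood-pressure estimation from **dual-wrist
photoplethysmography** plus interface-sensor contact pressure and skin
temperature — a complete, tested pipeline for a wristwatch-style wearable that
measures PPG on both the palmar and dorsal sides of the wrist.

## The problem and the method

A PPG signal splits into a quasi-static **DC** component (absorption by skin,
tissue and non-pulsatile blood) and a pulsatile **AC** component. The DC level
carries stroke-volume information relevant to systolic pressure, but it is
swamped by subject-specific optics: skin tone, tissue, wearing tightness. The
method's key idea is **differential DC sensing**: two PPG sensors on opposite
sides of the same wrist share those subject-specific offsets, so the
dorsal-minus-palmar baseline difference

&nbsp;&nbsp;&nbsp;&nbsp;ΔDC = mean(DC_dorsal − DC_palmar) per 10-s window

cancels them and retains the stroke-volume-related signal. ΔDC, contact
pressures and skin temperatures from the interface sensors, and the subject's
physical characteristics (HR, age, height, weight, BMI, sex) feed an MLP that
estimates SBP (11 inputs). For DBP, seven waveform-shape features of the
dorsal pulse — cardiac period CP, systolic time ST, diastolic time DT, ST/DT,
systolic/diastolic area ratio, the K value (P̄−P_min)/(P_max−P_min), and the
AC/DC ratio — are appended (18 inputs), since reflected-wave morphology tracks
peripheral resistance, the main determinant of diastolic pressure.

Estimates are produced on 10-s windows shifted by 2 s. Generalization to
unseen people is judged by **leave-one-subject-out (LOSO)** cross-validation,
with mean error (ME), error SD, Bland–Altman limits of agreement
[μ − 1.96σ, μ + 1.96σ], the AAMI accuracy criterion (|ME| < 5 mmHg,
SD < 8 mmHg) and BHS cumulative-error grading.

No public recordings of this sensor configuration exist, so the package ships
a first-class **synthetic cohort generator** (`dualppg.synthesize`) with fully
known latent hemodynamics — every downstream stage is validated against exact
ground truth (see `docs/methods.md` for what the simulator does and does not
emulate).

## Worked example

```bash
python examples/03_train_and_evaluate.py
```

builds a synthetic cohort of 8 subjects × 3 sessions × 90 s, extracts window
features, and runs the LOSO and pooled experiments:

```
24 sessions -> 888 valid windows
SBP: LOSO +1.03 ± 6.28 mmHg (LOA [-11.28, 13.34], AAMI pass, BHS B); pooled split +6.10 ± 2.39 mmHg; mean-predictor SD 9.01 mmHg
DBP: LOSO -0.50 ± 4.95 mmHg (LOA [-10.19, 9.20], AAMI pass, BHS A); pooled split +1.08 ± 2.68 mmHg; mean-predictor SD 4.45 mmHg
```

Read: pooled LOSO errors are far below the mean-predictor baseline (the model
recovers the simulated pressure signal), and the LOSO SD exceeds the
pooled-split SD — estimating blood pressure for a subject the model has never
seen is the harder, more honest test. The other examples cover cohort
generation (`01`), conditioning and feature extraction against ground truth
(`02`), and the agreement statistics on their own (`04`).

The same stages are scriptable from the shell:

```bash
dualppg-bp simulate --out runs/demo --seed 1
dualppg-bp features --in runs/demo/manifest.csv --out runs/demo/features.csv
dualppg-bp evaluate --features runs/demo/features.csv --target sbp --mode loso --out runs/demo/report.json
dualppg-bp run --out runs/full --seed 1          # whole pipeline in one step
```

## Layout

| Module | Role |
| --- | --- |
| `dualppg.signal_model` | `TimeSeries`, `SensorSession`, validation, session directory I/O |
| `dualppg.synthesize` | synthetic cohorts with known hemodynamic ground truth |
| `dualppg.preprocess` | low-pass, wavelet denoise, baseline/pulsatile split, z-score, decimation, windows |
| `dualppg.features` | beat segmentation, fiducials, the 8 pulse features, ΔDC, pressure calibration |
| `dualppg.fusion` | the 80/12 MLP regressor (ReLU, dropout, Adam, early stopping) |
| `dualppg.evaluate` | LOSO / pooled splits, ME/SD, Bland–Altman, AAMI, BHS |
| `dualppg.pipeline` | end-to-end orchestration and the quickstart fixture |
| `dualppg.cli` | thin `dualppg-bp` command over the library |
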