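# polarppg

Analysis pipeline for **perfusion index (PI) from polarization-gated,
dual-wavelength wearable PPG**.

Reflectance photoplethysmography degrades with darker skin tones: melanin
absorbs and superficial layers scatter the probe light, weakening the
pulsatile (AC) signal relative to the nonpulsatile (DC) background.  One
optical remedy is polarization gating — illuminate with linearly polarized
light and detect either co-polarized (surface-weighted) or cross-polarized
(depth-weighted, multiply scattered) returns.  This package implements the
full analysis such a device needs, for sensor developers and researchers
studying pigmentation bias in optical vital-sign monitors:

* **synthetic cohorts** with analytically known ground truth (four-channel
  recordings at 655/940 nm × co/cross polarization, plus repeated
  colorimeter scans), so the whole pipeline is testable without hardware;
* **zero-phase FIR low-pass filtering** with the overall −3 dB point at
  5 Hz (single-pass symmetric FIR with exact group-delay compensation, not
  forward–backward filtering, which would halve the gain at cutoff);
* **segmentation** of each 2-min record into the three best 10-s windows,
* **per-beat PI extraction**: peaks/troughs by prominence, DC = preceding
  trough, AC = peak − trough, PI = 100·AC/DC (%), heart-rate plausibility
  checks against a 60–100 bpm band;
* **skin-tone classification** from CIELAB colorimetry via the individual
  typology angle, ITA = arctan((L* − 50)/b*)·180/π, with cutoffs
  light > 23° / medium −5…23° / brown < −5°;
* **generalized estimating equations** (implemented in-repo from the
  estimating equations) regressing per-segment PI on ITA, polarization
  condition and their interaction, clustered by participant, with
  cluster-robust sandwich standard errors, χ²₁ Wald tests and z-based CIs.

The central quantity is the marginal model, fitted separately per
wavelength:

```
PI_ij = β₀ + β₁·ITA_i + β₂·1[cross]_j + β₃·ITA_i·1[cross]_j + ε_ij
```

with participant `i` as the cluster.  A positive `β₂` means cross-polarized
detection raises PI; a negative `β₃` means that uplift shrinks as skin gets
lighter — i.e. polarization gating helps most where pigmentation hurts most.

## Worked example

```python
import polarppg as p

manifest = p.run_all(
    p.RunConfig(seed=1),                  # analysis parameters (defaults)
    cohort_config=p.CohortConfig(seed=1), # 8 participants, ITA -25..50 deg, 120 s
    out_dir="results",
)
```

This simulates the default cohort (cross-polarized uplift β₂ = 0.83% PI,
interaction β₃ = −0.015 %/deg), extracts PI per segment and fits both
GEEs.  `results/gee_655.csv` then contains:

```
       Coefficients  Estimate  Standard error         95% CI       Wald    Pr(>|W|)
          Intercept   0.67239         0.02631   0.621, 0.724     653.00 5.0e-144***
                ITA   0.00627         0.00065   0.005, 0.008      94.10  3.0e-22***
    Cross-polarized   0.82178         0.00082   0.820, 0.823 1003308.04  0.0e+00***
ITA*Cross-polarized  -0.01491         0.00004 -0.015, -0.015  154082.87  0.0e+00***
```

Reading it: baseline co-polarized PI is ≈ 0.67% for a mid-tone (ITA 0)
participant; PI rises ≈ 0.006% per degree ITA; switching to cross-polarized
detection adds ≈ 0.822% PI (generative truth 0.83), and that uplift shrinks
by ≈ 0.0149% per degree ITA (truth 0.015) — largest benefit at the darkest
tones.  The standard errors are far smaller than a real study's because the
synthetic within-participant noise is mild and the condition contrast
cancels the participant offsets; on real recordings expect SEs an order of
magnitude larger.  `results/ita_summary.csv` holds each participant's mean
ITA, scan SD and category, and `manifest.json` accounts for every
participant as analyzed or excluded-with-reason.

The same stages are available from the shell:

```sh
polarppg simulate --config cohort.yaml --out data/ --seed 1
polarppg ita --scans data/S01_scans.csv          # {"mean_ita_deg": ..., "category": ...}
polarppg run-all --seed 1 --out results/ [--no-exclusion] [--working-corr independence]
```

Real recordings are analysed by pointing `run-all --in DIR` (or
`p.run_all(..., input_dir=...)`) at CSVs with header
`time_s,ch655_co,ch655_cross,ch940_co,ch940_cross`, a YAML sidecar
(`participant_id`, `fs`, `duration_s`) and `<pid>_scans.csv` colorimeter
files.

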