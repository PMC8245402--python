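# tdnirs

Time-domain functional near-infrared spectroscopy (TD-fNIRS) simulation
and analysis for visual-stimulation studies of the occipital cortex, with
a complete statistical battery for discriminating glaucomatous from
healthy eyes.

## The problem

Glaucoma degrades not only the retina but the whole visual pathway.
TD-fNIRS measures, through the scalp, the full distribution of photon
times of flight (DTOFs) of picosecond laser pulses at two wavelengths
(687 and 826 nm, source-detector distance 3 cm) over the visual cortex.
From those histograms one can recover absolute baseline optical
properties (absorption `mu_a` and reduced scattering `mu_s'`), separate
superficial (scalp/skull) from cortical absorption changes with a
two-layer photon-migration model, and track the haemodynamic response —
an increase in oxygenated haemoglobin (ΔO₂Hb, peak amplitude
`A_O2Hb` > 0) with a concurrent decrease in deoxygenated haemoglobin
(ΔHHb, `A_HHb` < 0) — evoked by a checkerboard stimulus viewed with one
eye.  Glaucomatous eyes produce visibly weaker responses; the question is
whether the HRF amplitudes and latencies discriminate eye pathology.

Because no raw clinical recordings are available, the package ships a
physics-based synthetic-study generator whose ground truth scores every
stage of the analysis.

## What the package does

* **`tdnirs.forward`** — analytic time-resolved diffuse reflectance
  `R(ρ, t)` of semi-infinite homogeneous and two-layer media
  (extrapolated-boundary diffusion; the two-layer solution is a Hankel ×
  Fourier inversion of a closed-form spatial-frequency kernel),
  time-resolved partial pathlengths `l_j(t) = -∂ ln R/∂μ_a,j`, and IRF
  convolution.
* **`tdnirs.simulate`** — the study generator: 180-s protocol (30 s
  baseline + 5 × [10 s rest, 10 s stimulus, 10 s recovery]); an
  86-subject cohort (31 healthy, 43 glaucoma, 12 mixed → 172 eyes, 344
  eye-hemisphere recordings); per-cycle canonical-HRF ground truth with
  class-conditional amplitude distributions pinned to the reported group
  quantiles and a shared subject-level random effect correlating fellow
  eyes; DTOF stacks with TCSPC Poisson noise (~10⁶ counts per 1-s
  histogram).
* **`tdnirs.dtof`** — stage 1: Poisson-weighted fit of the IRF-convolved
  homogeneous model to the summed baseline DTOF (absolute `mu_a`,
  `mu_s'` per wavelength), quality gates (> 150 kcounts in the baseline,
  reduced χ² ≤ 2), time-gated attenuation changes, the two-layer
  pathlength inversion into superficial vs cortical `Δμ_a(t, λ)`, and
  the modified Beer-Lambert step to ΔO₂Hb/ΔHHb in µM.
* **`tdnirs.hrf`** — stage 2: per-cycle fits of the canonical response
  `h(t) = A (t/τ)^p e^{p(1-t/τ)}` (peak amplitude `A`, time-to-peak
  `τ`), exclusion of cycles with `τ > 20 s`, eye-hemisphere means.
* **`tdnirs.stats`** — stage 3: GEE logistic models at the single-eye
  level (fellow eyes clustered within subject, exchangeable working
  correlation, sandwich errors), odds ratios with Bonferroni-adjusted
  CIs and Wald tests, latency-difference / amplitude-ratio predictors,
  and the concordance index `c` (= area under the ROC curve) with
  clustered-bootstrap CIs — a battery of 16 single-predictor, 8
  two-hemisphere and 16 derived-predictor models.
* **`tdnirs.cli`** — `tdnirs simulate | process | hrf | stats | run-all |
  validate` over an HDF5 dataset layout and CSV report tables.

## Worked example

```python
import numpy as np
from tdnirs import (SimulationConfig, make_design, make_protocol,
                    simulate_study)
from tdnirs.dtof import process_recording
from tdnirs.hrf import fit_cycles, apply_latency_exclusion

cfg = SimulationConfig(seed=1)
study = simulate_study(cfg, make_design(1, 1, 0), make_protocol())

key = ("S001", "left", "left")          # subject, stimulated eye, hemisphere
stacks = {wl: study.dtofs[(*key, wl)] for wl in cfg.wavelengths}
tc, fits, verdict = process_recording(
    stacks, study.irfs, study.grid, cfg.rho_cm,
    study.protocol.sample_times, baseline_samples=30)

print(verdict.passed, {wl: (float(round(f.props.mu_a, 3)),
                            float(round(f.props.mu_sp, 2)))
                       for wl, f in fits.items()})
cyc = apply_latency_exclusion(fit_cycles(tc, study.protocol))
print(cyc[["cycle", "A_O2Hb", "tau_O2Hb", "A_HHb", "tau_HHb"]].round(3))
```

prints (healthy subject, seed 1):

```
True {687.0: (0.115, 10.1), 826.0: (0.164, 9.17)}
   cycle  A_O2Hb  tau_O2Hb  A_HHb  tau_HHb
0      1   0.888     4.348 -0.446    5.898
1      2   0.908     3.654 -0.364    5.778
2      3   1.004     4.130 -0.435    6.019
3      4   0.707     3.122 -0.374    5.931
4      5   1.460     3.718 -0.589    5.739
```

The quality gates pass, the recovered baseline properties sit near the
healthy-group values the generator samples around (`mu_a` 0.15 ± 0.04,
`mu_s'` 10 ± 1.5 per cm at 687 nm), and the five cycles show the
canonical pattern: ΔO₂Hb peaks near 1 µM a few seconds after stimulus
onset with ΔHHb dips around -0.4 µM.  This subject's true eye-level
parameters, stored in `study.truth_cycles`, are A_O2Hb ≈ 0.98 µM,
A_HHb ≈ -0.44 µM, τ_O2Hb ≈ 3.8 s, τ_HHb ≈ 6.1 s — the per-cycle fits
scatter around exactly those values.

A full synthetic study at the statistics level reproduces the expected
discrimination structure: amplitude odds ratios below 1 for A_O2Hb and
above 1 for A_HHb with c ≈ 0.7, and uninformative latencies (c ≈ 0.5) —
run `tdnirs run-all --config <yaml>` to get the three report tables.

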