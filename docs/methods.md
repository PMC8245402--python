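# Methods

This note documents the models, numerical choices and design decisions
behind `tdnirs`, and what the synthetic experiments do and do not show
about real recordings.

## Photon migration forward models

**Homogeneous medium.** Time-resolved diffuse reflectance of a
semi-infinite medium is the extrapolated-boundary diffusion solution
with an isotropic source at depth `z0 = 1/mu_s'` and a negative image at
`-(z0 + 2 zb)`:

    R(rho, t) = exp(-mu_a v t - rho^2/(4 D v t)) / (2 (4 pi D v)^{3/2} t^{5/2})
                * [ z0 exp(-z0^2/(4Dvt)) + (z0 + 2 zb) exp(-(z0+2zb)^2/(4Dvt)) ]

with `D = 1/(3 mu_s')` (absorption-independent convention, so
time-domain Beer-Lambert scaling `R -> R exp(-d v t)` under
`mu_a -> mu_a + d` is exact), `v = 29.9792458/n` cm/ns, and
`zb = 2 A(n) D` from the effective-reflection polynomial in `n`
(`A ≈ 3.25` at the default `n = 1.4`).  Reflectance is the outward Fick
current at the surface.

**Two-layer medium.** A finite top layer (scalp/skull, default
thickness 0.5 cm — a deliberately conservative value) over a cortical
half-space, both sharing `n` (one photon speed, which keeps the
total-pathlength identity exact).  The lateral Fourier transform reduces
the problem to a 1-d two-point boundary-value problem in depth solved in
closed form; eliminating the homogeneous (top-properties) part leaves a
layered correction

    corr(s, w) = (r/2) (e^{-k1(L-z0)} - e^{-k1(L+z0+2zb)})
                 e^{-k1 L} (1 + e^{-2 k1 zb}) / (1 + r e^{-2 k1 (L+zb)})

with `k_i^2 = s^2 + (mu_a,i + i w/v)/D_i` and interface mismatch
`r = (D1 k1 - D2 k2)/(D1 k1 + D2 k2)`.  The correction was verified
against a brute-force 3x3 linear solve of the depth problem; it vanishes
identically for equal layers, so the homogeneous-limit equivalence is
exact by construction, and it decays like `exp(-k1 (2L - z0))`, so its
zero-order Hankel inversion (composite Gauss-Legendre, default panels of
0.5/cm with 6 nodes, truncation `s_max = 40/(2L - z0)`) plus inverse FFT
over temporal frequency is cheap (~0.4 s per curve on 4096 x 10 ps bins)
and free of the slowly decaying singular source term.  All exponentials
are evaluated in decaying form (no overflow for any thickness); the FFT
period is extended until `mu_a v T >= 30` to suppress time aliasing.

**Partial pathlengths.** `l_j(t) = -d ln R(t)/d mu_a,j` at baseline.
The cortical (bottom) pathlength uses central finite differences with
step 1e-5/cm; the superficial one follows from the exact identity
`l_top + l_bottom = v t` (adding equal absorption to both layers
rescales the curve by `exp(-d v t)` even for unequal `D_i`, because the
perturbation enters each layer as `d/D_i`, exactly like the frequency
term).  Independent finite differences at step 1e-4/cm reproduce both
pathlengths to ~1e-6 relative.

**Convolution.** Plain discrete linear convolution truncated to the
model grid, zero-padded before t = 0; a unit single-bin IRF is the
identity and total counts are conserved when the IRF sums to one.

## Synthetic study generator

The generator emulates the acquisition design: two wavelengths (687,
826 nm), 3 cm separation, a 180-s session (30 s baseline + 5 cycles of
10 s rest / 10 s stimulus / 10 s recovery), one DTOF per second per
wavelength with ~1e6 counts (a typical TCSPC budget; the acquisition
rate and count rate are declared defaults, not reported values), and a
Gaussian-plus-exponential-tail IRF (FWHM 150 ps, tail 300 ps, 10%
weight) resembling a hybrid-PMT response.

Cohort: 31 healthy, 43 bilateral-glaucoma and 12 mixed subjects (each
mixed subject has one eye per class), two eyes x two hemispheres — 86
subjects, 172 eyes, 344 recordings.  Baseline optical properties are
sampled per (subject, eye, wavelength) around the class means (healthy:
0.15/10.0 at 687 nm, 0.14/8.7 at 826 nm; glaucoma: 0.13/9.9 and
0.13/8.7; SDs 0.03-0.04 and 1.4-1.8 per cm).

**Canonical HRF.** `h(t) = A (t/tau)^p exp(p (1 - t/tau))` for t > 0: a
gamma-family bump whose signed peak is exactly `A` (µM) and whose
time-to-peak is exactly `tau` (s) for any dispersion `p` (default 5,
giving a realistic ~4 s FWHM at tau = 5 s).  This parameterisation makes
the two reported quantities model-free.

**Class-conditional amplitudes.** Magnitudes follow a *two-piece*
log-normal pinned to the reported group quantiles — healthy A_O2Hb
0.65 (0.45, 1.13) µM, glaucoma 0.41 (0.18, 0.60); healthy |A_HHb|
0.24 (0.16, 0.38), glaucoma 0.14 (0.06, 0.21) — with separate log-scale
spreads below/above the median.  A single log-normal cannot reproduce
these quartiles (they are asymmetric on the log scale, the glaucomatous
ones left-skewed); matching only the IQR would inflate the glaucoma
upper tail far beyond anything the reported discrimination statistics
are consistent with.  The canonical signs are applied afterwards
(A_O2Hb > 0, A_HHb < 0).  Latencies are class-independent by default
(tau_O2Hb 5.0 s, tau_HHb 5.2 s, eye-level SD 0.8 s, cycle-level SD
0.3 s): discrimination in the default study rests on amplitude, which is
the reported pattern.

**Correlation structure.** The standard-normal deviate behind each
eye-level amplitude decomposes as `sqrt(rho_eye) u_subject +
sqrt(1-rho_eye) z_eye` with `rho_eye = 0.5` by default, so fellow eyes
share half the amplitude variance — the violation of independent
sampling that motivates GEE downstream.  Hemisphere- and cycle-level
multiplicative jitter (log-SD 0.20 and 0.15) sit on top.

**DTOF synthesis.** Per recording, the deep-layer absorption time course
is `dmua_deep(t, lambda) = ln(10) eps(lambda) dC(t) 1e-6` with the 2x2
decadic extinction matrix (HbO2/HHb: 271.8/2158.8 at 687 nm, 950.8/720.6
at 826 nm, 1/(M cm), interpolated from the standard compiled tabulation;
condition number ~3).  The baseline curve is attenuated per
time-of-flight bin by `exp(-dmua_deep l_bottom(t_bin))` (microscopic
Beer-Lambert; exact to second order at these dmua ~ 1e-3/cm),
IRF-convolved, scaled to the count budget and Poisson-sampled.  A
superficial-only term is available through the same entry point for
contamination experiments.  Full-DTOF synthesis is intended for cohorts
of order ten subjects; statistics-stage experiments use the
parameter-level ground truth directly (`with_dtofs=False`), which is
exact for that stage and runs the full 86-subject cohort in
milliseconds.

## DTOF processing

Baseline optical properties are fitted per recording and wavelength on
the summed 30-s baseline histogram: Poisson-weighted least squares
between the measured histogram and the amplitude-scaled IRF-convolved
homogeneous model, over the window from 80% of peak (rising edge) to 1%
of peak (falling edge) — standard TD practice; the window, like every
stage parameter, is configurable.  The amplitude is profiled out
analytically each iteration; `mu_a, mu_s'` are optimised in log space
(Levenberg-Marquardt).  The reduced chi-square over the window feeds the
quality gates: **pass iff baseline counts > 150 000 and chi2_red <= 2**
(strict boundary semantics on both).

Attenuation changes are computed per time gate as
`dA_g(t) = -ln(N_g(t)/<N_g>_baseline)` and inverted through the
gate-integrated two-layer pathlength matrix
`L[g, j] = sum_g IRF*(R0 l_j) / sum_g IRF*R0` (photon-weighted mean
pathlength *in measured time*, i.e. including IRF smearing) via
least squares for the two layer unknowns; the cortical pair at the two
wavelengths is then mapped to (ΔO₂Hb, ΔHHb) through the extinction
matrix.  The pathlength medium takes both layers at the fitted
homogeneous properties with the 0.5-cm superficial thickness, mirroring
the fit-homogeneous / invert-two-layer analysis chain.

**Gate design.** The default is seven contiguous gates covering
[0, 4] ns after the measured peak (0.5 ns wide up to +3 ns, one 1-ns
tail gate), inverted with inverse-variance (gate-count) weighting.  A
minimal early/late pair ([0, 1] and [1.5, 3.5] ns) satisfies the same
contract but its two-unknown inversion has ~2.7x the per-sample noise of
the full-histogram Cramér-Rao bound (σ(ΔO₂Hb) ≈ 0.32 µM per 1-s sample
at 1e6 counts), which is too noisy to resolve glaucoma-scale |A_HHb| ≈
0.14 µM at the per-cycle level; the seven-gate weighted inversion sits
within ~40% of the bound (σ(ΔO₂Hb) ≈ 0.16 µM, σ(ΔHHb) ≈ 0.07 µM) while
remaining a pure time-gating scheme with a reported condition number
(error above 1e3).  Samples with zero gate counts are masked, not
propagated as infinities.

## HRF analysis

Each cycle of each chromophore is fitted independently with
`offset + h(t - onset; A, tau)` by least squares over
[onset - 10 s, onset + 20 s]; the response is identically zero during
the rest period, so the rest samples anchor the offset inside the same
fit rather than letting offset and amplitude trade off (this roughly
halves the amplitude variance compared with fitting the response window
alone).  The latency search interval is (0.5, 30] s — wider than the
admissible range, so slow fits land above the exclusion cut instead of
piling up on a bound — and **cycles with tau > 20 s (strictly) in either
chromophore are excluded** afterwards, reproducing the exclusion
semantics of responses slower than the stimulation period.  Fits with
|A| below 3x the residual noise SD are flagged `low_signal` but kept;
exclusion is governed solely by the latency rule.  Non-excluded cycles
are averaged to eye-hemisphere means; a hemisphere with no surviving
cycle becomes a missing aggregate and is dropped listwise per model,
with counts logged.

## Discrimination statistics

The statistical unit is the eye (label 1 = glaucomatous).  Predictors
are eye-hemisphere mean parameters under two hemisphere
classifications: anatomical left/right and ipsilateral/contralateral
(ipsilateral = recording hemisphere on the stimulated eye's side).
Models are logistic regressions estimated by GEE with subjects as
clusters, exchangeable working correlation (robust sandwich errors make
the estimates structure-insensitive) and Wald chi-square tests.  The
battery:

* 16 single-predictor models ({tau_HHb, tau_O2Hb, A_HHb, A_O2Hb} x 4
  hemisphere classes), Bonferroni multiplicity m = 4 per parameter
  family (p_adj = min(1, m p); CI level 1 - alpha/m; p values capped at
  1 are rendered "> 0.999");
* 8 two-predictor models (same parameter at both hemispheres of one
  classification).  If the parameter showed no single-hemisphere
  association, the joint null (both slopes zero, df = 2) is tested once
  per model; otherwise each slope gets its own Wald test.  m is the
  number of Wald tests actually performed in the family — computed, not
  hard-coded;
* 16 derived-predictor models: tau_O2Hb - tau_HHb, |tau_O2Hb -
  tau_HHb|, A_O2Hb/A_HHb and |A_O2Hb/A_HHb| per hemisphere class (zero
  denominators become missing values, never exceptions).

Discrimination is the concordance index of the fitted linear predictor
(for one-predictor models this is the predictor itself up to a monotone
map), computed from midranks (ties count half, the Mann-Whitney
identity), with percentile CIs from a subject-level cluster bootstrap
(default 1000 resamples, seeded; degenerate one-class resamples are
skipped and counted) at the Bonferroni-adjusted level; discrimination is
declared significant when the adjusted CI excludes 0.5.  Models that
cannot be estimated (separation on tiny cohorts) produce logged gap rows
rather than aborting the battery.

## Problem sizes and what the experiments show

The validation battery (`tdnirs.experiments`, driven by both
`tests/test_acceptance.py` and `scripts/acceptance.py`) uses: 200
simulated cycles (40 five-cycle recordings, half at the healthy median
parameters, half at the glaucoma medians) for end-to-end recovery; 50
replicated 86-subject studies for amplitude-direction recovery; 100
replicated null studies (both classes drawn from the healthy
distributions) for the family-wise false-positive rate.  These sizes
give stable medians and rates while keeping the whole battery around
seven minutes on one CPU.

Passing them shows the pipeline is unbiased and appropriately precise
*under the generator's assumptions*: no motion artefacts, no cardiac or
respiratory oscillations, no stimulus-correlated superficial
haemodynamics (only an optional superficial step for contamination
tests), a known-correct HRF family, a literally two-layer head, and an
exactly known IRF.  Real recordings violate all of these to some
degree, so the numbers bound estimator noise, not clinical accuracy.
Within those assumptions: baseline properties are recovered to ~1% at
realistic counts, per-cycle amplitudes to a pooled median ~14% and
latencies to ~0.34 s, the amplitude odds-ratio directions (A_O2Hb
protective, A_HHb risk) are recovered in every replicate, and the
Bonferroni-corrected battery keeps every family's false-positive rate
at or below the nominal level.

## Known limitations

* A single refractive index across layers; no three-layer or
  heterogeneous (mesh-based) head models — the forward solver is
  analytic by design; Monte Carlo or finite-element transport is out of
  scope.
* The moments-based TD analysis route and short-separation regression
  are not implemented.
* The two-layer inversion assumes the superficial thickness (0.5 cm)
  rather than estimating it; errors in that assumption bias the
  partition between layers.
* GEE with ~86 clusters relies on large-sample sandwich variances; no
  small-sample correction is applied.
* SNIRF ingestion/export is not implemented; the HDF5 layout is
  package-specific.
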