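"""Synthetic TD-fNIRS study generator with full ground truth.

Builds complete synthetic visual-stimulation studies: a stimulation
protocol, a subject/eye/hemisphere design, per-cycle haemodynamic response
ground truth, and (optionally) raw photon time-of-flight histograms (DTOFs)
with TCSPC Poisson noise, so that every downstream estimator can be scored
against a stored true value.

The emulated experiment: occipital recordings at two wavelengths
(687/826 nm) and 3 cm source-detector distance while one eye views a
reversing pattern; a 180-s session of 30 s baseline plus five cycles of
10 s rest / 10 s stimulus / 10 s recovery.  Activation raises oxygenated
haemoglobin (positive peak amplitude A_O2Hb) and lowers deoxygenated
haemoglobin (negative A_HHb); glaucomatous eyes respond with smaller
magnitudes.  Fellow eyes of one subject are correlated through a shared
subject-level random effect, which is what motivates the clustered (GEE)
statistics downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .chromophores import DEFAULT_WAVELENGTHS, absorption_matrix
from .forward import (
    LayeredMedium,
    OpticalProperties,
    ReflectanceCurve,
    TimeGrid,
    convolve_with_irf,
    partial_pathlengths_two_layer,
    td_reflectance_two_layer,
)

__all__ = [
    "StimulationProtocol",
    "make_protocol",
    "canonical_hrf",
    "ClassEffect",
    "SimulationConfig",
    "make_design",
    "draw_ground_truth",
    "concentration_timecourses",
    "make_irf",
    "delta_irf",
    "simulate_homogeneous_dtof",
    "synthesize_dtof_stack",
    "SimulatedStudy",
    "simulate_study",
]

EYES = ("left", "right")
HEMISPHERES = ("left", "right")
CLASSES = ("NORM", "GLAUCOMA")


# ---------------------------------------------------------------------------
# Protocol
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StimulationProtocol:
    """Block-design session: baseline then repeated rest/stimulus/recovery."""

    baseline_s: float
    n_cycles: int
    rest_s: float
    stim_s: float
    recovery_s: float
    sampling_rate: float

    def __post_init__(self) -> None:
        if self.baseline_s < 0:
            raise ValueError(f"baseline_s must be >= 0, got {self.baseline_s}")
        if self.n_cycles < 0:
            raise ValueError(f"n_cycles must be >= 0, got {self.n_cycles}")
        for name in ("rest_s", "stim_s", "recovery_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.sampling_rate <= 0:
            raise ValueError(f"sampling_rate must be > 0, got {self.sampling_rate}")

    @property
    def cycle_s(self) -> float:
        return self.rest_s + self.stim_s + self.recovery_s

    @property
    def total_s(self) -> float:
        return self.baseline_s + self.n_cycles * self.cycle_s

    @property
    def onsets(self) -> np.ndarray:
        """Stimulus-onset times, s from acquisition start."""
        k = np.arange(self.n_cycles)
        return self.baseline_s + k * self.cycle_s + self.rest_s

    @property
    def sample_times(self) -> np.ndarray:
        """Low-rate haemodynamic sampling instants, s."""
        n = int(round(self.total_s * self.sampling_rate))
        return np.arange(n) / self.sampling_rate


def make_protocol(
    baseline_s: float = 30.0,
    n_cycles: int = 5,
    rest_s: float = 10.0,
    stim_s: float = 10.0,
    recovery_s: float = 10.0,
    sampling_rate: float = 1.0,
) -> StimulationProtocol:
    """Default protocol: 30 s baseline + 5 x (10 s rest, 10 s stimulus,
    10 s recovery) = 180 s total, stimulus onsets at 40, 70, ..., 160 s."""
    return StimulationProtocol(
        baseline_s, n_cycles, rest_s, stim_s, recovery_s, sampling_rate
    )


# ---------------------------------------------------------------------------
# Canonical haemodynamic response
# ---------------------------------------------------------------------------


def canonical_hrf(
    t_rel: np.ndarray | float, A: float, tau: float, shape: float = 5.0
) -> np.ndarray:
    """Gamma-family canonical haemodynamic response.

    ``h(t) = A (t/tau)^shape exp(shape (1 - t/tau))`` for t > 0, else 0.

    The parameterisation makes the two reported quantities exact by
    construction: the (signed) peak value equals ``A`` and the time-to-peak
    equals ``tau``, independent of the dimensionless dispersion ``shape``
    (larger shape = narrower response).
    """
    if tau <= 0:
        raise ValueError(f"tau must be > 0, got {tau}")
    if shape <= 0:
        raise ValueError(f"shape must be > 0, got {shape}")
    t = np.asarray(t_rel, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    x = t[pos] / tau
    out[pos] = A * x**shape * np.exp(shape * (1.0 - x))
    return out


# ---------------------------------------------------------------------------
# Study design and ground truth
# ---------------------------------------------------------------------------


def make_design(
    n_norm: int = 31, n_glaucoma: int = 43, n_mixed: int = 12
) -> pd.DataFrame:
    """Subject -> (2 eyes) -> (2 hemispheres) design table.

    One row per eye-hemisphere recording.  The default cohort mirrors a
    mid-size clinical study: 31 all-healthy subjects, 43 bilateral
    glaucoma patients and 12 mixed subjects whose two eyes differ in
    class, i.e. 86 subjects, 172 eyes, 344 hemisphere recordings.  Mixed
    subjects alternate which eye is the glaucomatous one.
    """
    rows = []
    idx = 0
    for n_subj, kind in ((n_norm, "NORM"), (n_glaucoma, "GLAUCOMA"), (n_mixed, "mixed")):
        for i in range(n_subj):
            idx += 1
            sid = f"S{idx:03d}"
            for eye in EYES:
                if kind == "mixed":
                    flip = i % 2 == 0
                    eye_class = (
                        "GLAUCOMA" if (eye == "right") == flip else "NORM"
                    )
                else:
                    eye_class = kind
                for hemi in HEMISPHERES:
                    rows.append((sid, eye, hemi, eye_class))
    return pd.DataFrame(
        rows, columns=["subject_id", "eye", "hemisphere", "eye_class"]
    )


_PROBIT_Q3 = 0.6744897501960817  # standard-normal upper quartile


@dataclass(frozen=True)
class ClassEffect:
    """Class-conditional amplitude/latency model for one chromophore.

    Amplitude magnitudes follow a two-piece log-normal pinned to the
    reported group quantiles: median ``amp_median`` and quartiles
    ``amp_q1 < amp_q3`` (all uM magnitudes), with separate log-scale
    spreads below and above the median.  A single log-normal cannot
    reproduce the reported quartiles, which are asymmetric on the log
    scale (the glaucomatous distributions are log-left-skewed).  The
    canonical sign is applied afterwards; latencies are normal around
    ``tau_s`` seconds.
    """

    amp_median: float
    amp_q1: float
    amp_q3: float
    sign: int
    tau_s: float

    def __post_init__(self) -> None:
        if not (0 < self.amp_q1 < self.amp_median < self.amp_q3):
            raise ValueError(
                "require 0 < q1 < median < q3, got "
                f"({self.amp_q1}, {self.amp_median}, {self.amp_q3})"
            )

    @property
    def sigma_lo(self) -> float:
        return float(np.log(self.amp_median / self.amp_q1) / _PROBIT_Q3)

    @property
    def sigma_hi(self) -> float:
        return float(np.log(self.amp_q3 / self.amp_median) / _PROBIT_Q3)

    def amplitude_from_z(self, z: float | np.ndarray) -> np.ndarray:
        """Signed amplitude via the two-piece quantile transform of a
        standard-normal deviate (monotone, so correlated z's yield
        correlated amplitudes with the exact marginal quantiles)."""
        z = np.asarray(z, dtype=float)
        mag = self.amp_median * np.exp(
            np.where(z < 0, self.sigma_lo * z, self.sigma_hi * z)
        )
        return self.sign * mag


def _default_effects() -> dict[str, dict[str, ClassEffect]]:
    # Medians and quartiles from reported group statistics; latencies are
    # class-independent by default: discrimination then rests on amplitude.
    return {
        "O2Hb": {
            "NORM": ClassEffect(0.65, 0.45, 1.13, +1, 5.0),
            "GLAUCOMA": ClassEffect(0.41, 0.18, 0.60, +1, 5.0),
        },
        "HHb": {
            "NORM": ClassEffect(0.24, 0.16, 0.38, -1, 5.2),
            "GLAUCOMA": ClassEffect(0.14, 0.06, 0.21, -1, 5.2),
        },
    }


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; ``seed`` is mandatory.

    Baseline optical properties are (mu_a, mu_sp) means and between-subject
    standard deviations per class and wavelength, in 1/cm.
    """

    seed: int
    wavelengths: tuple[float, float] = DEFAULT_WAVELENGTHS
    rho_cm: float = 3.0
    n_refractive: float = 1.4
    top_thickness_cm: float = 0.5
    counts_per_dtof: float = 1.0e6
    n_bins: int = 4096
    bin_width_ns: float = 0.010
    baseline_props: dict = field(
        default_factory=lambda: {
            "NORM": {687.0: (0.15, 10.0), 826.0: (0.14, 8.7)},
            "GLAUCOMA": {687.0: (0.13, 9.9), 826.0: (0.13, 8.7)},
        }
    )
    baseline_props_sd: dict = field(
        default_factory=lambda: {
            "NORM": {687.0: (0.04, 1.5), 826.0: (0.03, 1.4)},
            "GLAUCOMA": {687.0: (0.04, 1.8), 826.0: (0.03, 1.6)},
        }
    )
    effects: dict = field(default_factory=_default_effects)
    hrf_shape: float = 5.0
    rho_eye: float = 0.5  # share of log-amplitude variance at subject level
    hemi_sigma_log: float = 0.20  # hemisphere-level log-amplitude jitter
    cycle_sigma_log: float = 0.15  # cycle-level log-amplitude jitter
    tau_eye_sd: float = 0.8  # eye-level latency jitter, s
    tau_cycle_sd: float = 0.3  # cycle-level latency jitter, s
    irf_t0_ns: float = 0.5
    irf_fwhm_ns: float = 0.15
    irf_tail_ns: float = 0.30
    sample_props: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.rho_eye <= 1.0):
            raise ValueError(f"rho_eye must be in [0, 1], got {self.rho_eye}")
        if self.counts_per_dtof <= 0:
            raise ValueError("counts_per_dtof must be > 0")
        if self.top_thickness_cm <= 0:
            raise ValueError(
                f"top_thickness_cm must be > 0, got {self.top_thickness_cm}"
            )
        if self.rho_cm <= 0:
            raise ValueError(f"rho_cm must be > 0, got {self.rho_cm}")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    @property
    def grid(self) -> TimeGrid:
        return TimeGrid.regular(self.n_bins, self.bin_width_ns)

    def null_effects(self) -> "SimulationConfig":
        """A copy in which both classes share the NORM effect model
        (no class signal; for false-positive-rate experiments)."""
        eff = {
            ch: {cls: d["NORM"] for cls in d} for ch, d in self.effects.items()
        }
        return replace(self, effects=eff)


def draw_ground_truth(
    config: SimulationConfig,
    design: pd.DataFrame,
    protocol: StimulationProtocol,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-cycle true HRF parameters for every eye-hemisphere recording.

    Log-amplitudes decompose as subject effect (variance ``rho_eye`` of the
    class log-variance, shared by fellow eyes) + eye effect (the rest) +
    hemisphere and cycle jitter.  Returns one row per (recording, cycle)
    with columns A_O2Hb, A_HHb (uM, signed) and tau_O2Hb, tau_HHb (s).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    rows = []
    for sid, sdf in design.groupby("subject_id", sort=False):
        u_subj = {ch: rng.standard_normal() for ch in config.effects}
        for (eye, eye_class), edf in sdf.groupby(["eye", "eye_class"], sort=False):
            z_eye = rng.standard_normal()
            tau_eye = {
                ch: config.effects[ch][eye_class].tau_s
                + rng.standard_normal() * config.tau_eye_sd
                for ch in config.effects
            }
            for hemi in edf["hemisphere"]:
                for k in range(protocol.n_cycles):
                    row = {
                        "subject_id": sid,
                        "eye": eye,
                        "hemisphere": hemi,
                        "eye_class": eye_class,
                        "cycle": k + 1,
                    }
                    for ch, cls_eff in config.effects.items():
                        eff = cls_eff[eye_class]
                        z = (
                            np.sqrt(config.rho_eye) * u_subj[ch]
                            + np.sqrt(1.0 - config.rho_eye) * z_eye
                        )
                        jitter = np.exp(
                            rng.standard_normal() * config.hemi_sigma_log
                            + rng.standard_normal() * config.cycle_sigma_log
                        )
                        tau = max(
                            tau_eye[ch] + rng.standard_normal() * config.tau_cycle_sd,
                            1.0,
                        )
                        row[f"A_{ch}"] = float(eff.amplitude_from_z(z)) * jitter
                        row[f"tau_{ch}"] = tau
                    rows.append(row)
    return pd.DataFrame(rows)


def concentration_timecourses(
    truth: pd.DataFrame, protocol: StimulationProtocol, shape: float = 5.0
) -> dict[tuple, np.ndarray]:
    """True (dO2Hb, dHHb)(t) per recording, uM, at the protocol sampling.

    Returns {(subject_id, eye, hemisphere): array (n_samples, 2)}.
    """
    t = protocol.sample_times
    onsets = protocol.onsets
    out: dict[tuple, np.ndarray] = {}
    for key, g in truth.groupby(["subject_id", "eye", "hemisphere"], sort=False):
        conc = np.zeros((t.size, 2))
        for _, row in g.iterrows():
            onset = onsets[int(row["cycle"]) - 1]
            for j, ch in enumerate(("O2Hb", "HHb")):
                conc[:, j] += canonical_hrf(
                    t - onset, row[f"A_{ch}"], row[f"tau_{ch}"], shape
                )
        out[key] = conc
    return out


# ---------------------------------------------------------------------------
# Instrument response and DTOF synthesis
# ---------------------------------------------------------------------------


def make_irf(
    grid: TimeGrid,
    t0: float = 0.5,
    fwhm: float = 0.15,
    tail_tau: float = 0.30,
    tail_frac: float = 0.10,
) -> ReflectanceCurve:
    """Model instrument response: Gaussian peak plus exponential tail.

    Emulates a hybrid-photomultiplier TCSPC response (FWHM ~ 150 ps with a
    diffusion tail).  Normalised to unit sum, so convolving with it
    conserves histogram counts.
    """
    t = grid.t
    sigma = fwhm / 2.3548200450309493
    g = np.exp(-0.5 * ((t - t0) / sigma) ** 2)
    tail = np.where(t >= t0, np.exp(-(t - t0) / tail_tau), 0.0)
    v = (1.0 - tail_frac) * g / g.sum() + tail_frac * tail / tail.sum()
    return ReflectanceCurve(grid, v / v.sum())


def delta_irf(grid: TimeGrid) -> ReflectanceCurve:
    """Unit single-bin IRF (identity element of the convolution)."""
    v = np.zeros(len(grid))
    v[0] = 1.0
    return ReflectanceCurve(grid, v)


def simulate_homogeneous_dtof(
    props: OpticalProperties,
    rho: float,
    grid: TimeGrid,
    irf: ReflectanceCurve,
    total_counts: float,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Single DTOF from a homogeneous medium: IRF-convolved semi-infinite
    reflectance scaled to ``total_counts``, Poisson-sampled unless
    ``rng`` is None (noiseless expectation)."""
    from .forward import td_reflectance_semi_infinite

    r = td_reflectance_semi_infinite(rho, grid, props)
    m = convolve_with_irf(r, irf).value
    mean = total_counts * m / m.sum()
    if rng is None:
        return mean
    return rng.poisson(mean).astype(np.int64)


def synthesize_dtof_stack(
    r0: ReflectanceCurve,
    l_top: np.ndarray,
    l_bottom: np.ndarray,
    dmua_top: np.ndarray,
    dmua_deep: np.ndarray,
    irf: ReflectanceCurve,
    counts_per_dtof: float,
    rng: np.random.Generator | None,
) -> np.ndarray:
    """DTOF time series for one channel/wavelength.

    The baseline curve ``r0`` is attenuated per time-of-flight bin by the
    microscopic Beer-Lambert factor ``exp(-dmua_top l_top - dmua_deep
    l_bottom)`` for each low-rate sample, convolved with the IRF, scaled so
    the baseline histogram integrates to ``counts_per_dtof``, and Poisson
    sampled (``rng=None`` returns noiseless expectations).

    Returns an (n_samples, n_bins) array.
    """
    m0 = convolve_with_irf(r0, irf).value
    scale = counts_per_dtof / m0.sum()
    att = np.exp(
        -np.multiply.outer(dmua_top, l_top) - np.multiply.outer(dmua_deep, l_bottom)
    )
    modulated = att * r0.value[None, :]
    # convolve every sample with the IRF along the bin axis
    n = len(r0.grid)
    nf = 1 << int(np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(modulated, n=nf, axis=1) * np.fft.rfft(irf.value, n=nf)
    mean = scale * np.fft.irfft(spec, n=nf, axis=1)[:, :n]
    np.clip(mean, 0.0, None, out=mean)
    if rng is None:
        return mean
    return rng.poisson(mean).astype(np.int64)


# ---------------------------------------------------------------------------
# Full study
# ---------------------------------------------------------------------------


@dataclass
class SimulatedStudy:
    """A complete synthetic dataset plus every ground-truth table."""

    config: SimulationConfig
    protocol: StimulationProtocol
    design: pd.DataFrame
    truth_cycles: pd.DataFrame
    truth_baseline: pd.DataFrame  # per (subject, eye, wavelength) true props
    irfs: dict[float, ReflectanceCurve]
    dtofs: dict[tuple, np.ndarray]  # (subject, eye, hemisphere, wavelength)

    @property
    def grid(self) -> TimeGrid:
        return self.config.grid


def _sample_props(
    config: SimulationConfig, eye_class: str, wl: float, rng: np.random.Generator
) -> OpticalProperties:
    mu_a, mu_sp = config.baseline_props[eye_class][wl]
    if config.sample_props:
        sd_a, sd_s = config.baseline_props_sd[eye_class][wl]
        mu_a = max(mu_a + rng.standard_normal() * sd_a, 0.02)
        mu_sp = max(mu_sp + rng.standard_normal() * sd_s, 3.0)
    return OpticalProperties(mu_a, mu_sp, config.n_refractive)


def simulate_study(
    config: SimulationConfig,
    design: pd.DataFrame | None = None,
    protocol: StimulationProtocol | None = None,
    with_dtofs: bool = True,
) -> SimulatedStudy:
    """Generate a full synthetic study with known ground truth.

    With ``with_dtofs=False`` only the design and true HRF parameter tables
    are produced (sufficient, and much cheaper, for statistics-stage
    experiments at full cohort size).  DTOF synthesis costs a two-layer
    pathlength evaluation per (subject, eye, wavelength) and is intended
    for cohorts of order ten subjects.
    """
    if design is None:
        design = make_design()
    if protocol is None:
        protocol = make_protocol()
    rng = np.random.default_rng(config.seed)
    truth = draw_ground_truth(config, design, protocol, rng)
    grid = config.grid
    irfs = {
        wl: make_irf(grid, config.irf_t0_ns, config.irf_fwhm_ns, config.irf_tail_ns)
        for wl in config.wavelengths
    }
    dtofs: dict[tuple, np.ndarray] = {}
    base_rows = []
    if with_dtofs:
        kmat = absorption_matrix(config.wavelengths)
        conc = concentration_timecourses(truth, protocol, config.hrf_shape)
        for (sid, eye), edf in design.groupby(["subject_id", "eye"], sort=False):
            eye_class = edf["eye_class"].iloc[0]
            for i, wl in enumerate(config.wavelengths):
                props = _sample_props(config, eye_class, wl, rng)
                medium = LayeredMedium(props, props, config.top_thickness_cm)
                r0 = td_reflectance_two_layer(config.rho_cm, grid, medium)
                l_top, l_bottom = partial_pathlengths_two_layer(
                    config.rho_cm, grid, medium, base=r0
                )
                base_rows.append(
                    {
                        "subject_id": sid,
                        "eye": eye,
                        "wavelength": wl,
                        "mu_a": props.mu_a,
                        "mu_sp": props.mu_sp,
                    }
                )
                for hemi in edf["hemisphere"].unique():
                    c = conc[(sid, eye, hemi)]
                    dmua_deep = kmat[i, 0] * c[:, 0] + kmat[i, 1] * c[:, 1]
                    dtofs[(sid, eye, hemi, wl)] = synthesize_dtof_stack(
                        r0,
                        l_top,
                        l_bottom,
                        np.zeros_like(dmua_deep),
                        dmua_deep,
                        irfs[wl],
                        config.counts_per_dtof,
                        rng,
                    )
    truth_baseline = pd.DataFrame(
        base_rows, columns=["subject_id", "eye", "wavelength", "mu_a", "mu_sp"]
    )
    return SimulatedStudy(
        config, protocol, design, truth, truth_baseline, irfs, dtofs
    )
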