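"""Stage 1: from raw DTOF histograms to cortical haemoglobin time courses.

Per eye-hemisphere recording the stage

1. sums the histograms of the initial baseline period and fits the
   IRF-convolved semi-infinite homogeneous diffusion model to recover
   absolute baseline optical properties per wavelength;
2. applies the acquisition quality gates (total baseline counts and
   reduced chi-square of the fit);
3. computes time-gated attenuation changes relative to the baseline,
   separating early photons (mostly superficial) from late photons
   (deeper penetration);
4. inverts the gate attenuations through two-layer partial pathlengths
   into layer absorption changes, taking the deep (cortical) layer as the
   signal of interest and the superficial layer as the systemic
   contamination channel; and
5. maps the two-wavelength cortical absorption changes to oxy-/deoxy-
   haemoglobin concentration changes (modified Beer-Lambert).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .chromophores import absorption_matrix
from .forward import (
    LayeredMedium,
    OpticalProperties,
    ReflectanceCurve,
    TimeGrid,
    convolve_with_irf,
    partial_pathlengths_two_layer,
    td_reflectance_semi_infinite,
    td_reflectance_two_layer,
)

__all__ = [
    "DTOFHistogram",
    "BaselineFit",
    "QualityVerdict",
    "HaemoTimeCourse",
    "fit_baseline_optical_properties",
    "quality_check",
    "default_gates",
    "time_gated_attenuation",
    "gate_pathlength_matrix",
    "invert_layered_mua",
    "mbll_concentrations",
    "process_recording",
]

MIN_BASELINE_COUNTS = 150_000
MAX_REDUCED_CHI2 = 2.0


@dataclass(frozen=True)
class DTOFHistogram:
    """Photon arrival-time histogram for one channel/wavelength/sample."""

    grid: TimeGrid
    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        object.__setattr__(self, "counts", c)
        if c.shape != self.grid.t.shape:
            raise ValueError("counts and grid shapes differ")
        if np.any(c < 0):
            raise ValueError("histogram counts must be non-negative")

    @property
    def total_counts(self) -> int:
        return int(self.counts.sum())


@dataclass
class BaselineFit:
    """Recovered baseline optical properties for one wavelength."""

    props: OpticalProperties
    amplitude: float
    chi2_red: float
    total_counts: int
    fit_range_ns: tuple[float, float]
    n_points: int
    converged: bool


@dataclass
class QualityVerdict:
    passed: bool
    reasons: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        assert self.passed == (len(self.reasons) == 0)


@dataclass
class HaemoTimeCourse:
    """Cortical haemoglobin concentration changes for one recording."""

    time_s: np.ndarray
    dO2Hb: np.ndarray  # uM
    dHHb: np.ndarray  # uM
    subject_id: str = ""
    eye: str = ""
    hemisphere: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "eye": self.eye,
                "hemisphere": self.hemisphere,
                "time_s": self.time_s,
                "dO2Hb_uM": self.dO2Hb,
                "dHHb_uM": self.dHHb,
            }
        )


def _fit_window(counts: np.ndarray, rise_frac: float, fall_frac: float) -> slice:
    """Index window from ``rise_frac`` of peak on the rising edge to
    ``fall_frac`` of peak on the falling edge."""
    peak = int(np.argmax(counts))
    peak_val = counts[peak]
    above = np.flatnonzero(counts[: peak + 1] >= rise_frac * peak_val)
    lo = int(above[0]) if above.size else 0
    below = np.flatnonzero(counts[peak:] < fall_frac * peak_val)
    hi = peak + int(below[0]) if below.size else counts.size
    return slice(lo, hi)


def fit_baseline_optical_properties(
    dtof_sum: DTOFHistogram,
    irf: DTOFHistogram,
    rho: float,
    n: float = 1.4,
    *,
    rise_frac: float = 0.80,
    fall_frac: float = 0.01,
    x0: tuple[float, float] = (0.1, 10.0),
) -> BaselineFit:
    """Fit (mu_a, mu_sp) to a baseline-summed DTOF.

    Minimises the Poisson-weighted residual between the measured histogram
    and an amplitude-scaled, IRF-convolved semi-infinite homogeneous model
    over the window from 80% of peak (rising) to 1% of peak (falling).
    The amplitude absorbs the unknown source power and coupling
    efficiency.  Reports the reduced chi-square used by the quality gate.
    """
    if not np.isclose(dtof_sum.grid.bin_width, irf.grid.bin_width, rtol=1e-9):
        raise ValueError("DTOF and IRF bin widths differ")
    counts = np.asarray(dtof_sum.counts, dtype=float)
    total = dtof_sum.total_counts
    if total <= 0:
        raise ValueError("empty histogram: no photons to fit")
    window = _fit_window(counts, rise_frac, fall_frac)
    idx = np.arange(counts.size)[window]
    if idx.size < 10:
        raise ValueError("fit range too small (degenerate histogram)")
    y = counts[window]
    sigma = np.sqrt(np.maximum(y, 1.0))
    grid = dtof_sum.grid
    irf_curve = ReflectanceCurve(irf.grid, np.asarray(irf.counts, dtype=float))

    def model(mu_a: float, mu_sp: float) -> np.ndarray:
        r = td_reflectance_semi_infinite(
            rho, grid, OpticalProperties(mu_a, mu_sp, n)
        )
        return convolve_with_irf(r, irf_curve).value

    def residuals(theta: np.ndarray) -> np.ndarray:
        mu_a, mu_sp = np.exp(theta)
        m = model(mu_a, mu_sp)[window]
        ms = m.sum()
        if ms <= 0 or not np.isfinite(ms):
            return np.full(idx.size, 1e6)
        amp = np.sum(y * m / sigma**2) / np.sum(m**2 / sigma**2)
        return (amp * m - y) / sigma

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # transient mu_sp <= 10 mu_a iterates
        sol = least_squares(
            residuals,
            np.log(np.asarray(x0, dtype=float)),
            method="lm",
            xtol=1e-10,
            ftol=1e-10,
        )
    mu_a, mu_sp = np.exp(sol.x)
    m = model(mu_a, mu_sp)[window]
    amp = float(np.sum(y * m / sigma**2) / np.sum(m**2 / sigma**2))
    dof = max(idx.size - 3, 1)
    chi2_red = float(np.sum(((amp * m - y) / sigma) ** 2) / dof)
    return BaselineFit(
        props=OpticalProperties(mu_a, mu_sp, n),
        amplitude=amp,
        chi2_red=chi2_red,
        total_counts=total,
        fit_range_ns=(float(grid.t[idx[0]]), float(grid.t[idx[-1]])),
        n_points=int(idx.size),
        converged=bool(sol.success),
    )


def quality_check(fit: BaselineFit) -> QualityVerdict:
    """Acquisition quality gates: baseline counts > 150 kcounts and
    reduced chi-square of the baseline fit <= 2."""
    reasons = []
    if not fit.total_counts > MIN_BASELINE_COUNTS:
        reasons.append("low_counts")
    if not fit.chi2_red <= MAX_REDUCED_CHI2:
        reasons.append("bad_fit")
    return QualityVerdict(passed=not reasons, reasons=reasons)


def default_gates(peak_t_ns: float) -> list[tuple[float, float]]:
    """Default time gates relative to the measured DTOF peak.

    Seven contiguous gates covering [0, 4] ns after the peak (0.5 ns wide
    up to +3 ns, then one 1-ns tail gate).  Finer gating with
    inverse-variance weighting keeps the layered inversion within ~40% of
    the full-histogram Cramer-Rao bound, versus ~3x for a minimal
    early/late pair, while remaining a pure time-gating scheme.
    """
    edges = peak_t_ns + np.array([0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 4.0])
    return list(zip(edges[:-1], edges[1:]))


def _gate_slices(grid: TimeGrid, gates: list[tuple[float, float]]) -> list[slice]:
    out = []
    for lo, hi in gates:
        if hi <= lo:
            raise ValueError(f"empty gate ({lo}, {hi})")
        i0 = int(np.searchsorted(grid.t, lo - 1e-12, side="left"))
        i1 = int(np.searchsorted(grid.t, hi - 1e-12, side="left"))
        if i1 <= i0:
            raise ValueError(f"gate ({lo}, {hi}) ns contains no bins")
        out.append(slice(i0, i1))
    return out


def time_gated_attenuation(
    dtof_series: np.ndarray,
    grid: TimeGrid,
    gates: list[tuple[float, float]],
    baseline_samples: int,
) -> np.ndarray:
    """Gate attenuation changes dA[g, sample] = -ln(N_g / <N_g>_baseline).

    ``dtof_series`` is (n_samples, n_bins); gate counts sum the bins with
    t in [lo, hi).  The reference is the mean gate count over the first
    ``baseline_samples`` samples.  Samples with zero gate counts are
    masked (NaN) with a warning rather than propagating -inf.
    """
    if len(gates) < 2:
        raise ValueError("need at least 2 gates to separate layers")
    slices = _gate_slices(grid, gates)
    ng = np.stack([dtof_series[:, s].sum(axis=1) for s in slices])  # (G, S)
    ref = ng[:, :baseline_samples].mean(axis=1)
    if np.any(ref <= 0):
        raise ValueError("zero baseline counts in a gate; widen the gate")
    with np.errstate(divide="ignore"):
        da = -np.log(ng / ref[:, None])
    bad = ~np.isfinite(da)
    if bad.any():
        warnings.warn(f"{bad.sum()} zero-count gate samples masked")
        da[bad] = np.nan
    return da


def gate_pathlength_matrix(
    r0: ReflectanceCurve,
    l_top: np.ndarray,
    l_bottom: np.ndarray,
    irf: ReflectanceCurve,
    gates: list[tuple[float, float]],
) -> np.ndarray:
    """Mean partial pathlengths of detected photons per measured-time gate.

    Linearising the gate counts in the layer absorptions gives
    ``dA_g = sum_j L[g, j] dmua_j`` with ``L[g, j]`` the photon-weighted
    mean of ``l_j`` over the gate *in measured time*, i.e. including IRF
    smearing: L[g, j] = sum_g IRF*(R0 l_j) / sum_g IRF*R0.
    """
    m0 = convolve_with_irf(r0, irf).value
    grid = r0.grid
    slices = _gate_slices(grid, gates)
    L = np.zeros((len(gates), 2))
    for j, l in enumerate((l_top, l_bottom)):
        pj = convolve_with_irf(
            ReflectanceCurve(grid, r0.value * l), irf
        ).value
        for g, s in enumerate(slices):
            denom = m0[s].sum()
            if denom <= 0:
                raise ValueError(f"gate {g} has no model photons")
            L[g, j] = pj[s].sum() / denom
    return L


def invert_layered_mua(
    da: np.ndarray,
    L: np.ndarray,
    weights: np.ndarray | None = None,
    max_condition: float = 1e3,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Solve dA[g, t] = sum_j L[g, j] dmua[j, t] for the two layers.

    Least-squares when more than two gates are supplied; ``weights`` are
    per-gate inverse variances (for Poisson counting, the gate counts
    themselves, since var dA_g ~ 1/N_g).  Returns (dmua_top(t),
    dmua_deep(t), condition_number); NaN attenuation samples yield NaN
    absorptions.
    """
    L = np.asarray(L, dtype=float)
    if L.ndim != 2 or L.shape[1] != 2 or L.shape[0] < 2:
        raise ValueError(f"pathlength matrix must be (>=2, 2), got {L.shape}")
    cond = float(np.linalg.cond(L))
    if cond > max_condition:
        raise ValueError(
            f"gate pathlength matrix condition number {cond:.1f} > "
            f"{max_condition}: choose gates with better depth contrast"
        )
    da = np.asarray(da, dtype=float)
    if weights is not None:
        w = np.sqrt(np.asarray(weights, dtype=float))
        if w.shape != (L.shape[0],) or np.any(w < 0):
            raise ValueError("weights must be non-negative, one per gate")
        L = L * w[:, None]
        da = da * w[:, None]
    ok = np.all(np.isfinite(da), axis=0)
    sol = np.full((2, da.shape[1]), np.nan)
    if ok.any():
        sol[:, ok], *_ = np.linalg.lstsq(L, da[:, ok], rcond=None)
    return sol[0], sol[1], cond


def mbll_concentrations(
    dmua_deep: np.ndarray,
    wavelengths: tuple[float, float],
    kmat: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Map deep-layer absorption changes at two wavelengths to (dO2Hb,
    dHHb) in uM.

    ``dmua_deep`` is (2, n_samples) ordered as ``wavelengths``.  Solves
    the 2x2 extinction system per sample (modified Beer-Lambert).
    """
    if kmat is None:
        kmat = absorption_matrix(wavelengths)
    kmat = np.asarray(kmat, dtype=float)
    if kmat.shape != (2, 2) or np.linalg.cond(kmat) > 1e6:
        raise ValueError("extinction matrix must be 2x2 and non-singular")
    dmua_deep = np.asarray(dmua_deep, dtype=float)
    if dmua_deep.shape[0] != 2:
        raise ValueError("expected absorption changes at exactly 2 wavelengths")
    conc = np.linalg.solve(kmat, dmua_deep)
    return conc[0], conc[1]


def process_recording(
    dtofs: dict[float, np.ndarray],
    irfs: dict[float, ReflectanceCurve],
    grid: TimeGrid,
    rho: float,
    sample_times: np.ndarray,
    baseline_samples: int,
    *,
    n: float = 1.4,
    top_thickness: float = 0.5,
    gates: list[tuple[float, float]] | None = None,
    meta: dict | None = None,
    baseline_fits: dict[float, BaselineFit] | None = None,
) -> tuple[HaemoTimeCourse, dict[float, BaselineFit], QualityVerdict]:
    """Full stage-1 chain for one eye-hemisphere recording.

    ``dtofs`` maps wavelength -> (n_samples, n_bins) histogram stack.
    Baseline optical properties are fitted per wavelength from the summed
    baseline histograms (unless precomputed fits are passed, e.g. shared
    between the two hemispheres of one acquisition), quality is the AND of
    the per-wavelength gates, and concentrations use two-layer pathlengths
    with the superficial layer fixed at ``top_thickness`` cm.
    """
    meta = meta or {}
    wavelengths = tuple(sorted(dtofs))
    fits: dict[float, BaselineFit] = dict(baseline_fits or {})
    dmua = []
    verdicts = []
    for wl in wavelengths:
        stack = dtofs[wl]
        baseline_sum = DTOFHistogram(grid, stack[:baseline_samples].sum(axis=0))
        irf_hist = DTOFHistogram(grid, irfs[wl].value)
        if wl not in fits:
            fits[wl] = fit_baseline_optical_properties(
                baseline_sum, irf_hist, rho, n
            )
        fit = fits[wl]
        verdicts.append(quality_check(fit))
        medium = LayeredMedium(fit.props, fit.props, top_thickness)
        r0 = td_reflectance_two_layer(rho, grid, medium)
        l_top, l_bottom = partial_pathlengths_two_layer(
            rho, grid, medium, base=r0
        )
        m0 = convolve_with_irf(r0, irfs[wl]).value
        peak_t = float(grid.t[int(np.argmax(m0))])
        wl_gates = gates if gates is not None else default_gates(peak_t)
        da = time_gated_attenuation(stack, grid, wl_gates, baseline_samples)
        L = gate_pathlength_matrix(r0, l_top, l_bottom, irfs[wl], wl_gates)
        slices = _gate_slices(grid, wl_gates)
        ref_counts = np.array(
            [stack[:baseline_samples, s].sum() / baseline_samples for s in slices]
        )
        _, deep, _ = invert_layered_mua(da, L, weights=ref_counts)
        dmua.append(deep)
    do2, dhhb = mbll_concentrations(np.vstack(dmua), wavelengths)
    reasons = sorted({r for v in verdicts for r in v.reasons})
    verdict = QualityVerdict(passed=not reasons, reasons=reasons)
    tc = HaemoTimeCourse(
        time_s=np.asarray(sample_times, dtype=float),
        dO2Hb=do2,
        dHHb=dhhb,
        **meta,
    )
    return tc, fits, verdict
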