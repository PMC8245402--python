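"""Analytic time-domain photon-migration forward models.

Implements time-resolved diffuse reflectance of a semi-infinite homogeneous
medium and of a two-layer medium (superficial scalp/skull layer over a
semi-infinite cortical layer), plus time-resolved partial pathlengths and
instrument-response-function (IRF) convolution.

Conventions
-----------
* Lengths in cm, times in ns, absorption ``mu_a`` and reduced scattering
  ``mu_sp`` in 1/cm.
* The diffusion coefficient is ``D = 1/(3 mu_sp)`` (absorption-independent
  convention), so the time-domain Beer-Lambert scaling
  ``R(t; mu_a + d) = R(t; mu_a) exp(-d v t)`` is exact.
* The boundary condition is the extrapolated boundary: the fluence vanishes
  on a plane at distance ``z_b = 2 A D`` outside the physical surface, with
  the internal-reflection parameter ``A`` derived from the refractive index.
* Reflectance is the normal component of the Fick current at the surface,
  ``R = D dPhi/dz | z=0`` (photon flux per unit area per unit time, for a
  unit-energy pulse injected at the isotropic-source depth ``z0 = 1/mu_sp``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "C_LIGHT_CM_PER_NS",
    "OpticalProperties",
    "LayeredMedium",
    "TimeGrid",
    "ReflectanceCurve",
    "td_reflectance_semi_infinite",
    "td_reflectance_two_layer",
    "partial_pathlengths_two_layer",
    "convolve_with_irf",
]

C_LIGHT_CM_PER_NS = 29.9792458
"""Speed of light in vacuum, cm/ns."""


class NumericalFailure(RuntimeError):
    """Raised when a transform/series fails to produce a usable curve."""


def internal_reflection_parameter(n: float) -> float:
    """Boundary parameter ``A = (1 + R_eff) / (1 - R_eff)``.

    ``R_eff`` is the effective Fresnel reflection coefficient for diffuse
    light at a tissue-air interface, from the standard polynomial fit in
    the relative refractive index (valid for n between 1 and about 1.6).
    """
    if n < 1:
        raise ValueError(f"refractive index must be >= 1, got {n}")
    r_eff = -1.440 / n**2 + 0.710 / n + 0.668 + 0.0636 * n
    return (1.0 + r_eff) / (1.0 - r_eff)


@dataclass(frozen=True)
class OpticalProperties:
    """Bulk optical properties of a turbid medium.

    Parameters
    ----------
    mu_a : float
        Absorption coefficient, 1/cm.
    mu_sp : float
        Reduced scattering coefficient, 1/cm.
    n : float
        Refractive index (>= 1), default 1.4 (soft tissue).
    """

    mu_a: float
    mu_sp: float
    n: float = 1.4

    def __post_init__(self) -> None:
        if self.mu_a < 0:
            raise ValueError(f"mu_a must be >= 0, got {self.mu_a}")
        if self.mu_sp <= 0:
            raise ValueError(f"mu_sp must be > 0, got {self.mu_sp}")
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        if self.mu_sp <= 10 * self.mu_a:
            warnings.warn(
                f"mu_sp={self.mu_sp} <= 10*mu_a={10 * self.mu_a}: "
                "diffusion approximation may be inaccurate",
                stacklevel=2,
            )

    @property
    def diffusion_coefficient(self) -> float:
        """D = 1/(3 mu_sp), cm."""
        return 1.0 / (3.0 * self.mu_sp)

    @property
    def v(self) -> float:
        """Speed of light in the medium, cm/ns."""
        return C_LIGHT_CM_PER_NS / self.n


@dataclass(frozen=True)
class LayeredMedium:
    """Two-layer semi-infinite medium: finite top layer over a half-space.

    Both layers share the refractive index of the top layer (a documented
    restriction: a single ``n`` defines one photon speed, which keeps the
    total-pathlength identity ``l_top + l_bottom = v t`` exact).
    """

    top: OpticalProperties
    bottom: OpticalProperties
    top_thickness: float

    def __post_init__(self) -> None:
        if self.top_thickness <= 0:
            raise ValueError(
                f"top_thickness must be > 0, got {self.top_thickness}"
            )
        if self.top.n != self.bottom.n:
            raise ValueError(
                "both layers must share the refractive index "
                f"(got {self.top.n} and {self.bottom.n})"
            )
        z0 = 1.0 / self.top.mu_sp
        if z0 >= self.top_thickness:
            raise ValueError(
                f"isotropic source depth 1/mu_sp = {z0:.3f} cm must lie "
                f"inside the top layer (thickness {self.top_thickness} cm)"
            )

    @property
    def n(self) -> float:
        return self.top.n

    @property
    def v(self) -> float:
        return C_LIGHT_CM_PER_NS / self.n


@dataclass(frozen=True)
class TimeGrid:
    """Uniform time axis for histograms and model curves, in ns."""

    t: np.ndarray
    bin_width: float

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        object.__setattr__(self, "t", t)
        if t.ndim != 1 or t.size < 2:
            raise ValueError("time grid must be a 1-d array with >= 2 points")
        if t[0] < 0:
            raise ValueError(f"time grid must start at t >= 0, got {t[0]}")
        dt = np.diff(t)
        if not np.allclose(dt, self.bin_width, rtol=1e-9, atol=0):
            raise ValueError("time grid must be uniform with spacing bin_width")

    @classmethod
    def regular(cls, n_bins: int = 4096, bin_width: float = 0.010) -> "TimeGrid":
        """Default TCSPC-like axis: ``n_bins`` bins of ``bin_width`` ns (10 ps)."""
        return cls(np.arange(n_bins) * bin_width, bin_width)

    def __len__(self) -> int:
        return self.t.size


@dataclass
class ReflectanceCurve:
    """Non-negative time-resolved curve (model reflectance or IRF) on a grid."""

    grid: TimeGrid
    value: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.value = np.asarray(self.value, dtype=float)
        if self.value.shape != self.grid.t.shape:
            raise ValueError("value and grid shapes differ")
        if np.any(self.value < 0):
            raise ValueError("reflectance values must be non-negative")

    @property
    def area(self) -> float:
        """Time integral, value * bin_width summed."""
        return float(np.sum(self.value) * self.grid.bin_width)


def td_reflectance_semi_infinite(
    rho: float, grid: TimeGrid, props: OpticalProperties
) -> ReflectanceCurve:
    """Time-resolved reflectance of a homogeneous semi-infinite medium.

    Extrapolated-boundary solution with an isotropic source at depth
    ``z0 = 1/mu_sp`` and its negative image at ``-(z0 + 2 z_b)``:

    ``R(rho, t) = exp(-mu_a v t - rho^2/(4 D v t)) / (2 (4 pi D v)^{3/2} t^{5/2})
    * [z0 exp(-z0^2/(4 D v t)) + (z0 + 2 z_b) exp(-(z0 + 2 z_b)^2/(4 D v t))]``

    The curve is exactly zero at t <= 0 (causality).
    """
    if rho <= 0:
        raise ValueError(f"source-detector distance must be > 0, got {rho}")
    v = props.v
    D = props.diffusion_coefficient
    z0 = 1.0 / props.mu_sp
    zb = 2.0 * internal_reflection_parameter(props.n) * D
    t = grid.t
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    with np.errstate(over="ignore", under="ignore"):
        four_dvt = 4.0 * D * v * tp
        common = np.exp(-props.mu_a * v * tp - rho**2 / four_dvt) / (
            2.0 * (4.0 * np.pi * D * v) ** 1.5 * tp**2.5
        )
        z1 = z0
        z2 = z0 + 2.0 * zb
        out[pos] = common * (
            z1 * np.exp(-(z1**2) / four_dvt) + z2 * np.exp(-(z2**2) / four_dvt)
        )
    return ReflectanceCurve(grid, out)


# ---------------------------------------------------------------------------
# Two-layer medium: spatial-frequency (Hankel) expansion, FFT time inversion
# ---------------------------------------------------------------------------


def _gauss_panels(s_max: float, panel_width: float, order: int = 6):
    """Composite Gauss-Legendre nodes/weights on [0, s_max]."""
    nodes, weights = np.polynomial.legendre.leggauss(order)
    n_panels = max(int(np.ceil(s_max / panel_width)), 1)
    edges = np.linspace(0.0, s_max, n_panels + 1)
    lo, hi = edges[:-1], edges[1:]
    half = 0.5 * (hi - lo)
    mid = 0.5 * (hi + lo)
    s = (mid[:, None] + half[:, None] * nodes[None, :]).ravel()
    w = (half[:, None] * weights[None, :]).ravel()
    return s, w


def _cexp(z: np.ndarray) -> np.ndarray:
    """exp(z) with the real part clipped so underflow goes straight to 0.

    Avoids denormal intermediates, which carry a large arithmetic penalty.
    """
    return np.exp(np.where(z.real < -708.0, -746.0 + 0j, z))


def _two_layer_sw_correction(
    s: np.ndarray, omega: np.ndarray, medium: LayeredMedium
) -> np.ndarray:
    """Layered correction to the homogeneous reflectance in (s, omega) space.

    The lateral Fourier transform reduces the diffusion equation to a 1-d
    two-point problem in depth z with an extrapolated boundary at
    ``z = -z_b``, continuity of fluence and normal current at the layer
    interface, and decay at infinity.  Eliminating the layer-2 amplitude
    yields, for the surface current ``R = D1 dPhi/dz | z=0``,

    ``R = R_homog(top properties) + correction``

    with the closed form (r is the diffuse interface mismatch coefficient)

    ``correction = (r/2) (e^{-k1(L - z0)} - e^{-k1(L + z0 + 2 zb)})
                   e^{-k1 L} (1 + e^{-2 k1 zb}) / (1 + r e^{-2 k1 (L + zb)})``

    which vanishes identically for equal layers and decays like
    ``exp(-k1 (2L - z0))`` in spatial frequency, so its Hankel inversion is
    cheap and free of the slowly-decaying singular source term.

    Parameters are broadcast: ``s`` shape (Ns, 1), ``omega`` shape (1, Nw).
    """
    v = medium.v
    D1 = medium.top.diffusion_coefficient
    D2 = medium.bottom.diffusion_coefficient
    L = medium.top_thickness
    z0 = 1.0 / medium.top.mu_sp
    zb = 2.0 * internal_reflection_parameter(medium.n) * D1

    s2 = s**2
    k1 = np.sqrt(s2 + (medium.top.mu_a + 1j * omega / v) / D1)
    k2 = np.sqrt(s2 + (medium.bottom.mu_a + 1j * omega / v) / D2)

    alpha = D1 * k1
    beta = D2 * k2
    r = (alpha - beta) / (alpha + beta)

    x = _cexp(-k1 * (L - z0)) - _cexp(-k1 * (L + z0 + 2.0 * zb))
    num = _cexp(-k1 * L) * (1.0 + _cexp(-2.0 * k1 * zb))
    den = 1.0 + r * _cexp(-2.0 * k1 * (L + zb))
    return 0.5 * r * x * num / den


def td_reflectance_two_layer(
    rho: float,
    grid: TimeGrid,
    medium: LayeredMedium,
    *,
    s_max: float | None = None,
    s_panel_width: float = 0.5,
    gauss_order: int = 6,
) -> ReflectanceCurve:
    """Time-resolved reflectance of a two-layer semi-infinite medium.

    Evaluated as the homogeneous solution for the top-layer properties plus
    a layered correction, whose spatial-frequency form is inverted with a
    composite Gauss-Legendre zero-order Hankel quadrature and an inverse
    FFT over temporal frequency.  With equal layer properties the
    correction vanishes and the result reduces exactly to
    :func:`td_reflectance_semi_infinite`.

    Parameters
    ----------
    rho : float
        Source-detector separation, cm.
    s_max : float, optional
        Spatial-frequency truncation, 1/cm.  Default scales with the
        correction-term decay ``exp(-s (2L - z0))`` so the truncated tail
        is below ~1e-16 of the integral.
    s_panel_width, gauss_order :
        Quadrature refinement; the default resolves the J0(s rho)
        oscillation with >10 nodes per period for rho up to ~5 cm.
    """
    if rho <= 0:
        raise ValueError(f"source-detector distance must be > 0, got {rho}")
    dt = grid.bin_width
    t0 = grid.t[0]
    if abs(t0 / dt - round(t0 / dt)) > 1e-6:
        raise ValueError("grid start time must be an integer number of bins")

    homog = td_reflectance_semi_infinite(rho, grid, medium.top)
    if medium.top == medium.bottom:
        return homog

    n_need = int(round(grid.t[-1] / dt)) + 1
    n_fft = 1 << max(int(np.ceil(np.log2(max(n_need, 2)))), 4)
    # Extend the FFT period until the curve has decayed (time aliasing):
    # require mu_a_min * v * T >= 30.
    v = medium.v
    mu_min = min(medium.top.mu_a, medium.bottom.mu_a)
    while mu_min > 0 and mu_min * v * n_fft * dt < 30:
        n_fft *= 2
        if n_fft > 1 << 22:
            raise NumericalFailure(
                "cannot reach a non-aliased FFT period; mu_a too small "
                f"(n_fft={n_fft}, mu_a_min={mu_min})"
            )

    z0 = 1.0 / medium.top.mu_sp
    if s_max is None:
        s_max = 40.0 / (2.0 * medium.top_thickness - z0)

    s, w = _gauss_panels(s_max, s_panel_width, gauss_order)
    omega = 2.0 * np.pi * np.fft.rfftfreq(n_fft, d=dt)

    # Hankel inversion: R(rho, w) = 1/(2 pi) * int_0^inf R(s, w) J0(s rho) s ds
    from scipy.special import j0

    hankel_w = (w * s * j0(s * rho)) / (2.0 * np.pi)

    # Chunk over spatial frequency to bound memory at ~ (chunk x Nw) complexes.
    spectrum = np.zeros(omega.size, dtype=complex)
    chunk = max(1, int(4e6 // omega.size))
    for i in range(0, s.size, chunk):
        sl = slice(i, i + chunk)
        block = _two_layer_sw_correction(s[sl, None], omega[None, :], medium)
        spectrum += hankel_w[sl] @ block

    corr = np.fft.irfft(spectrum, n=n_fft) / dt
    idx = (np.round(grid.t / dt)).astype(int)
    out = homog.value + corr[idx]
    out[grid.t <= 0] = 0.0
    np.clip(out, 0.0, None, out=out)
    if not np.all(np.isfinite(out)):
        raise NumericalFailure("two-layer transform produced non-finite values")
    return ReflectanceCurve(grid, out)


def partial_pathlengths_two_layer(
    rho: float,
    grid: TimeGrid,
    medium: LayeredMedium,
    *,
    delta_mua: float = 1e-5,
    floor_rel: float = 1e-12,
    base: ReflectanceCurve | None = None,
    **solver_kwargs,
) -> tuple[np.ndarray, np.ndarray]:
    """Time-resolved mean partial pathlengths (l_top(t), l_bottom(t)), cm.

    Defined as the absorption sensitivity of the log reflectance,
    ``l_j(t) = -d ln R(t) / d mu_a_j`` at the baseline properties.  The
    bottom-layer pathlength is computed by central finite differences with
    step ``delta_mua``; the top-layer one follows from the exact
    total-pathlength identity ``l_top + l_bottom = v t`` (adding the same
    absorption to both layers rescales the curve by ``exp(-d v t)``).

    Values at times where the reflectance is below ``floor_rel`` times its
    peak are set to the causal limits (l_bottom = 0, l_top = v t).

    ``base`` may pass a precomputed unperturbed curve to save one solve.
    """
    if base is None:
        base = td_reflectance_two_layer(rho, grid, medium, **solver_kwargs)

    def perturbed(d: float) -> np.ndarray:
        bottom = OpticalProperties(
            medium.bottom.mu_a + d, medium.bottom.mu_sp, medium.bottom.n
        )
        m = LayeredMedium(medium.top, bottom, medium.top_thickness)
        return td_reflectance_two_layer(rho, grid, m, **solver_kwargs).value

    r_plus = perturbed(delta_mua)
    r_minus = perturbed(-delta_mua)

    vt = medium.v * grid.t
    peak = base.value.max()
    ok = (base.value > floor_rel * peak) & (r_plus > 0) & (r_minus > 0)
    l_bottom = np.zeros_like(base.value)
    l_bottom[ok] = -(np.log(r_plus[ok]) - np.log(r_minus[ok])) / (2.0 * delta_mua)
    np.clip(l_bottom, 0.0, vt, out=l_bottom)
    l_top = vt - l_bottom
    return l_top, l_bottom


def convolve_with_irf(
    model: ReflectanceCurve, irf: ReflectanceCurve
) -> ReflectanceCurve:
    """Discrete linear convolution of a model curve with an IRF.

    Both curves must share the bin width.  The model is zero-padded before
    t = 0, and the full convolution is truncated to the model grid, so the
    output lives on the same axis as the input.  Total area is conserved:
    ``area(out) = area(model) * sum(irf)``.
    """
    if not np.isclose(model.grid.bin_width, irf.grid.bin_width, rtol=1e-9):
        raise ValueError(
            "model and IRF bin widths differ: "
            f"{model.grid.bin_width} vs {irf.grid.bin_width}"
        )
    full = np.convolve(model.value, irf.value)
    return ReflectanceCurve(model.grid, full[: len(model.grid)])
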