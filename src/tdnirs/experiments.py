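"""Self-contained validation experiments for the whole pipeline.

Each function regenerates its own synthetic inputs, runs the relevant
pipeline stages and returns summary metrics.  They back both the
acceptance test suite and ``scripts/acceptance.py``, so problem sizes are
chosen once, here: large enough for stable summary statistics, small
enough that the full battery runs on a single CPU in minutes.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .chromophores import absorption_matrix
from .dtof import (
    DTOFHistogram,
    fit_baseline_optical_properties,
    process_recording,
)
from .forward import (
    LayeredMedium,
    OpticalProperties,
    TimeGrid,
    partial_pathlengths_two_layer,
    td_reflectance_semi_infinite,
    td_reflectance_two_layer,
)
from .hrf import aggregate_hemisphere_means, apply_latency_exclusion, fit_cycles
from .simulate import (
    SimulationConfig,
    canonical_hrf,
    delta_irf,
    draw_ground_truth,
    make_design,
    make_irf,
    make_protocol,
    simulate_homogeneous_dtof,
    synthesize_dtof_stack,
)
from .stats import (
    HEMI_CLASSES,
    build_eye_records,
    fit_gee_logistic,
    run_model_battery,
)

__all__ = [
    "protocol_enumeration",
    "forward_oracle_metrics",
    "baseline_recovery_metrics",
    "cycle_recovery_metrics",
    "direction_recovery",
    "null_family_wise_error",
]


def protocol_enumeration() -> dict:
    """Design arithmetic: protocol length/onsets and cohort enumeration."""
    p = make_protocol()
    d = make_design()
    eyes = d.drop_duplicates(["subject_id", "eye"])
    return {
        "protocol_total_s": float(p.total_s),
        "first_onset_s": float(p.onsets[0]),
        "last_onset_s": float(p.onsets[-1]),
        "n_subjects": int(d["subject_id"].nunique()),
        "n_eyes": int(len(eyes)),
        "n_hemisphere_recordings": int(len(d)),
    }


def forward_oracle_metrics() -> dict:
    """Forward-model identities on the default TCSPC grid.

    * two-layer vs homogeneous closed form with equal layer properties
      (max relative error where the curve exceeds 1e-6 of its peak);
    * time-domain Beer-Lambert scaling of the homogeneous model;
    * pathlength-sum identity l_top + l_bottom = v t on t in [0.2, 4] ns.
    """
    grid = TimeGrid.regular(4096, 0.010)
    props = OpticalProperties(0.15, 10.0, 1.4)
    medium = LayeredMedium(props, OpticalProperties(0.15, 10.0, 1.4), 0.5)
    rho = 3.0

    homog = td_reflectance_semi_infinite(rho, grid, props)
    two = td_reflectance_two_layer(rho, grid, medium)
    mask = homog.value > 1e-6 * homog.value.max()
    eq_err = float(
        np.max(np.abs(two.value[mask] - homog.value[mask]) / homog.value[mask])
    )

    delta = 0.01
    shifted = td_reflectance_semi_infinite(
        rho, grid, OpticalProperties(props.mu_a + delta, props.mu_sp, props.n)
    )
    expected = homog.value * np.exp(-delta * props.v * grid.t)
    bl_err = float(
        np.max(np.abs(shifted.value[mask] - expected[mask]) / expected[mask])
    )

    hetero = LayeredMedium(props, OpticalProperties(0.20, 8.0, 1.4), 0.5)
    base = td_reflectance_two_layer(rho, grid, hetero)
    l_top, l_bottom = partial_pathlengths_two_layer(rho, grid, hetero, base=base)
    sel = (grid.t >= 0.2) & (grid.t <= 4.0)
    vt = hetero.v * grid.t[sel]
    sum_err = float(np.max(np.abs((l_top + l_bottom)[sel] - vt) / vt))

    return {
        "two_layer_homogeneous_limit_max_rel_err_pct": eq_err * 100.0,
        "beer_lambert_scaling_max_rel_err": bl_err,
        "pathlength_sum_identity_max_rel_err_pct": sum_err * 100.0,
    }


def baseline_recovery_metrics(seed: int) -> dict:
    """Optical-property recovery from simulated baseline DTOFs.

    Noiseless with an ideal delta IRF at 1e7 counts, and Poisson-noisy
    with a realistic IRF at 1e6 counts, both at the glaucoma-group
    baseline values (mu_a 0.13, mu_sp 9.9 at the red wavelength).
    """
    grid = TimeGrid.regular(4096, 0.010)
    props = OpticalProperties(0.13, 9.9, 1.4)
    rho = 3.0

    ideal = delta_irf(grid)
    mean = simulate_homogeneous_dtof(props, rho, grid, ideal, 1e7, None)
    fit = fit_baseline_optical_properties(
        DTOFHistogram(grid, mean), DTOFHistogram(grid, ideal.value), rho
    )
    noiseless = {
        "mu_a": abs(fit.props.mu_a - props.mu_a) / props.mu_a,
        "mu_sp": abs(fit.props.mu_sp - props.mu_sp) / props.mu_sp,
    }

    rng = np.random.default_rng(seed)
    irf = make_irf(grid)
    errs_a, errs_s = [], []
    for _ in range(5):
        counts = simulate_homogeneous_dtof(props, rho, grid, irf, 1e6, rng)
        f = fit_baseline_optical_properties(
            DTOFHistogram(grid, counts), DTOFHistogram(grid, irf.value), rho
        )
        errs_a.append(abs(f.props.mu_a - props.mu_a) / props.mu_a)
        errs_s.append(abs(f.props.mu_sp - props.mu_sp) / props.mu_sp)
    return {
        "baseline_mua_rel_err_noiseless_pct": noiseless["mu_a"] * 100.0,
        "baseline_musp_rel_err_noiseless_pct": noiseless["mu_sp"] * 100.0,
        "baseline_mua_rel_err_noisy_pct": float(np.max(errs_a)) * 100.0,
        "baseline_musp_rel_err_noisy_pct": float(np.max(errs_s)) * 100.0,
    }


def cycle_recovery_metrics(seed: int, n_recordings: int = 40) -> dict:
    """End-to-end per-cycle HRF parameter recovery at reported medians.

    ``n_recordings`` five-cycle recordings (half at the healthy-group
    median amplitudes/latencies, half at the glaucoma ones) are simulated
    as full DTOF stacks at default noise, pushed through baseline
    fitting, gating, the layered inversion, the spectral inversion and
    the cycle fits.  Returns pooled median absolute errors: amplitudes
    relative to the true A per chromophore, latencies in seconds.
    """
    grid = TimeGrid.regular(4096, 0.010)
    protocol = make_protocol()
    t_s = protocol.sample_times
    rho = 3.0
    rng = np.random.default_rng(seed)
    irf = make_irf(grid)
    wls = (687.0, 826.0)
    kmat = absorption_matrix(wls)
    cfg = SimulationConfig(seed=seed)

    groups = {
        "NORM": {"A": (0.65, -0.24), "tau": (5.0, 5.2)},
        "GLAUCOMA": {"A": (0.41, -0.14), "tau": (4.0, 4.6)},
    }
    fields: dict[str, dict] = {}
    for cls in groups:
        fields[cls] = {}
        for wl in wls:
            mu_a, mu_sp = cfg.baseline_props[cls][wl]
            props = OpticalProperties(mu_a, mu_sp, cfg.n_refractive)
            med = LayeredMedium(props, props, cfg.top_thickness_cm)
            r0 = td_reflectance_two_layer(rho, grid, med)
            lt, lb = partial_pathlengths_two_layer(rho, grid, med, base=r0)
            fields[cls][wl] = (r0, lt, lb)

    rel_a, abs_tau, n_excluded = [], [], 0
    for rec in range(n_recordings):
        cls = "NORM" if rec % 2 == 0 else "GLAUCOMA"
        A, tau = groups[cls]["A"], groups[cls]["tau"]
        conc = np.zeros((t_s.size, 2))
        for onset in protocol.onsets:
            conc[:, 0] += canonical_hrf(t_s - onset, A[0], tau[0])
            conc[:, 1] += canonical_hrf(t_s - onset, A[1], tau[1])
        dtofs = {}
        for i, wl in enumerate(wls):
            r0, lt, lb = fields[cls][wl]
            dmua = kmat[i, 0] * conc[:, 0] + kmat[i, 1] * conc[:, 1]
            dtofs[wl] = synthesize_dtof_stack(
                r0, lt, lb, np.zeros_like(dmua), dmua, irf,
                cfg.counts_per_dtof, rng,
            )
        tc, _, verdict = process_recording(
            dtofs, {w: irf for w in wls}, grid, rho, t_s,
            int(protocol.baseline_s),
        )
        fits = apply_latency_exclusion(fit_cycles(tc, protocol))
        for _, row in fits.iterrows():
            if row["excluded"]:
                n_excluded += 1
                continue
            rel_a.append(abs(row["A_O2Hb"] - A[0]) / abs(A[0]))
            rel_a.append(abs(row["A_HHb"] - A[1]) / abs(A[1]))
            abs_tau.append(abs(row["tau_O2Hb"] - tau[0]))
            abs_tau.append(abs(row["tau_HHb"] - tau[1]))
    return {
        "n_cycles": n_recordings * protocol.n_cycles,
        "n_cycles_excluded": n_excluded,
        "amplitude_recovery_mae_pct": float(np.median(rel_a)) * 100.0,
        "latency_recovery_mae_s": float(np.median(abs_tau)),
    }


def _stats_records(config: SimulationConfig) -> pd.DataFrame:
    """Eye-level records from a parameter-level synthetic study (full
    cohort; DTOF stage bypassed, which is exact for the statistics)."""
    design = make_design()
    protocol = make_protocol()
    truth = draw_ground_truth(config, design, protocol)
    truth["excluded"] = False
    agg = aggregate_hemisphere_means(truth)
    return build_eye_records(agg)


def direction_recovery(seed: int, n_replicates: int = 50) -> dict:
    """Sign of the amplitude odds ratios across seeded study replicates.

    For each replicate of the default 86-subject study, the eight
    single-predictor amplitude models (A_O2Hb and A_HHb at the four
    hemisphere classifications) are fitted; a replicate counts as correct
    when every A_O2Hb odds ratio is below 1 (larger oxygenation response
    protects) and every A_HHb odds ratio is above 1 (shallower HHb dip
    indicates glaucoma).
    """
    rng = np.random.default_rng(seed)
    ok = 0
    for _ in range(n_replicates):
        cfg = SimulationConfig(seed=int(rng.integers(2**31 - 1)))
        rec = _stats_records(cfg)
        good = True
        for pname, want in (("A_O2Hb", -1), ("A_HHb", +1)):
            for hemi in HEMI_CLASSES:
                r = fit_gee_logistic(rec, f"{pname}_{hemi}")
                if np.sign(r.coef[0]) != want:
                    good = False
        ok += good
    return {
        "direction_correct_fraction": ok / n_replicates,
        "n_replicates": n_replicates,
    }


def null_family_wise_error(seed: int, n_replicates: int = 100) -> dict:
    """Family-wise false-positive rate of the battery under the null.

    Replicated studies with no class effect (both classes drawn from the
    healthy distributions); for each parameter family (each with its own
    Bonferroni multiplicity) the fraction of replicates with any adjusted
    p < 0.05 is recorded.  Returns the worst family.
    """
    rng = np.random.default_rng(seed)
    hits: dict[tuple, list] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(n_replicates):
            cfg = SimulationConfig(seed=int(rng.integers(2**31 - 1))).null_effects()
            rec = _stats_records(cfg)
            tables = run_model_battery(rec, with_c_ci=False)
            for name, tab in tables.items():
                for fam, g in tab.groupby("parameter"):
                    hits.setdefault((name, fam), []).append(
                        bool((g["p_adj"] < 0.05).any())
                    )
    rates = {k: float(np.mean(v)) for k, v in hits.items()}
    worst = max(rates.values())
    return {
        "null_family_wise_error_max": worst,
        "n_replicates": n_replicates,
    }
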