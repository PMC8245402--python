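"""Stage 2: canonical-HRF fitting per stimulation cycle and aggregation.

Each rest/stimulus/recovery cycle of each chromophore time course is
fitted with the canonical gamma-family response plus a constant offset;
the fitted signed peak amplitude A (uM) and time-to-peak latency tau (s,
from stimulus onset) are the per-cycle parameters.  Cycles whose latency
exceeds the admissible window (longer than the stimulation period itself)
are excluded, and the surviving cycles are averaged to eye-hemisphere
means — the statistical unit of the discrimination stage.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .dtof import HaemoTimeCourse
from .simulate import StimulationProtocol, canonical_hrf

__all__ = [
    "fit_hrf_cycle",
    "fit_cycles",
    "apply_latency_exclusion",
    "aggregate_hemisphere_means",
    "map_laterality",
    "MAX_TAU_S",
]

MAX_TAU_S = 20.0
CHROMOPHORES = ("O2Hb", "HHb")

#: optimizer latency search interval, s; wider than the exclusion rule so
#: slow fits land above the cut and are counted as excluded, not clipped.
TAU_BOUNDS = (0.5, 30.0)


def fit_hrf_cycle(
    time_s: np.ndarray,
    signal: np.ndarray,
    onset: float,
    *,
    rest_s: float = 10.0,
    window_s: float = 20.0,
    shape: float = 5.0,
) -> dict:
    """Fit A, tau and a constant offset to one cycle of one chromophore.

    The fit spans [onset - rest_s, onset + window_s]: the canonical
    response is zero during the rest period, so the rest samples anchor
    the constant offset within the same least squares instead of leaving
    the offset and amplitude to trade off against each other inside the
    response window.  Returns a dict with the signed peak amplitude ``A``
    (uM), latency ``tau`` (s after onset), residual sum of squares
    ``rss``, the offset, a ``low_signal`` flag (|A| below 3x the residual
    noise level) and ``ok`` (optimizer converged).
    """
    time_s = np.asarray(time_s, dtype=float)
    signal = np.asarray(signal, dtype=float)
    win = (time_s >= onset - rest_s) & (time_s <= onset + window_s)
    t = time_s[win] - onset
    y = signal[win]
    good = np.isfinite(y)
    t, y = t[good], y[good]
    if np.sum(t >= 0) < 6:
        return dict(A=np.nan, tau=np.nan, rss=np.nan, offset=np.nan,
                    low_signal=True, ok=False)
    pre = t < 0
    c0 = float(np.mean(y[pre])) if pre.any() else 0.0

    yc = y - c0
    resp = t >= 0
    i0 = int(np.argmax(np.abs(yc * resp)))
    a0 = yc[i0] if yc[i0] != 0 else 1e-3
    tau0 = float(np.clip(t[i0], 2.0, 15.0))

    def resid(theta):
        a, tau, c = theta
        return canonical_hrf(t, a, tau, shape) + c - y

    sol = least_squares(
        resid,
        x0=[a0, tau0, c0],
        bounds=([-np.inf, TAU_BOUNDS[0], -np.inf], [np.inf, TAU_BOUNDS[1], np.inf]),
        xtol=1e-12,
        ftol=1e-12,
    )
    a, tau, c = sol.x
    rss = float(np.sum(sol.fun**2))
    noise_sd = float(np.sqrt(rss / max(t.size - 3, 1)))
    return dict(
        A=float(a),
        tau=float(tau),
        rss=rss,
        offset=float(c),
        low_signal=bool(abs(a) < 3.0 * noise_sd),
        ok=bool(sol.success),
    )


def fit_cycles(
    tc: HaemoTimeCourse,
    protocol: StimulationProtocol,
    shape: float = 5.0,
) -> pd.DataFrame:
    """Fit every stimulation cycle of both chromophores of one recording.

    Returns one row per cycle with columns ``A_O2Hb, A_HHb, tau_O2Hb,
    tau_HHb, rss_*, low_signal_*``, plus ``excluded``/``reason`` set by
    optimizer failures (latency exclusion is applied separately).
    """
    rows = []
    signals = {"O2Hb": tc.dO2Hb, "HHb": tc.dHHb}
    for k, onset in enumerate(protocol.onsets, start=1):
        row: dict = {
            "subject_id": tc.subject_id,
            "eye": tc.eye,
            "hemisphere": tc.hemisphere,
            "cycle": k,
            "excluded": False,
            "reason": "",
        }
        for ch in CHROMOPHORES:
            f = fit_hrf_cycle(
                tc.time_s,
                signals[ch],
                float(onset),
                rest_s=protocol.rest_s,
                window_s=protocol.stim_s + protocol.recovery_s,
                shape=shape,
            )
            row[f"A_{ch}"] = f["A"]
            row[f"tau_{ch}"] = f["tau"]
            row[f"rss_{ch}"] = f["rss"]
            row[f"low_signal_{ch}"] = f["low_signal"]
            if not f["ok"]:
                row["excluded"] = True
                row["reason"] = "fit_failure"
        rows.append(row)
    return pd.DataFrame(rows)


def apply_latency_exclusion(
    fits: pd.DataFrame, max_tau: float = MAX_TAU_S
) -> pd.DataFrame:
    """Exclude cycles whose latency exceeds ``max_tau`` seconds.

    The rule is a strict inequality: tau exactly at the limit is retained.
    A cycle is dropped if either chromophore's latency is out of range.
    Idempotent; already-excluded rows keep their original reason.
    """
    out = fits.copy()
    too_slow = (out["tau_O2Hb"] > max_tau) | (out["tau_HHb"] > max_tau)
    newly = too_slow & ~out["excluded"]
    out.loc[newly, "excluded"] = True
    out.loc[newly, "reason"] = "tau_gt_20s"
    return out


def aggregate_hemisphere_means(fits: pd.DataFrame) -> pd.DataFrame:
    """Eye-hemisphere means of the HRF parameters over non-excluded cycles.

    Returns one row per (subject_id, eye, hemisphere) with the arithmetic
    means of A and tau per chromophore and ``n_cycles_used``.  Groups in
    which every cycle is excluded yield NaN means (logged downstream as
    missing).
    """
    params = ["A_O2Hb", "A_HHb", "tau_O2Hb", "tau_HHb"]
    keys = ["subject_id", "eye", "hemisphere"]
    rows = []
    for key, g in fits.groupby(keys, sort=False):
        used = g[~g["excluded"]]
        row = dict(zip(keys, key))
        if "eye_class" in g.columns:
            row["eye_class"] = g["eye_class"].iloc[0]
        row["n_cycles_used"] = int(len(used))
        for p in params:
            row[p] = float(used[p].mean()) if len(used) else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def map_laterality(eye: str, hemisphere: str) -> str:
    """ipsilateral if the recording hemisphere is on the stimulated eye's
    side, contralateral otherwise."""
    sides = ("left", "right")
    if eye not in sides or hemisphere not in sides:
        raise ValueError(f"invalid side labels ({eye!r}, {hemisphere!r})")
    return "ipsilateral" if eye == hemisphere else "contralateral"
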