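"""Stage 3: discrimination statistics at the single-eye level.

The statistical unit is the eye (not the subject): each eye carries a
binary pathology label (1 = glaucomatous, 0 = healthy) and, as candidate
predictors, the eye-hemisphere mean HRF parameters under two hemisphere
classifications (anatomical left/right and stimulus-relative
ipsilateral/contralateral).  Because fellow eyes of one subject are
correlated, logistic models are estimated with Generalized Estimating
Equations (GEE, exchangeable working correlation, robust sandwich
errors), association is tested with Wald chi-square statistics and
Bonferroni multiplicity correction per parameter family, and
discrimination is quantified with the concordance index c (the area
under the ROC curve) with clustered-bootstrap confidence intervals at
the Bonferroni-adjusted level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from scipy.stats import rankdata

from .hrf import map_laterality

__all__ = [
    "build_eye_records",
    "derived_predictors",
    "fit_gee_logistic",
    "bonferroni_adjust",
    "concordance_index",
    "concordance_ci",
    "run_model_battery",
    "format_p",
    "GEEResult",
]

PARAMS = ("tau_HHb", "tau_O2Hb", "A_HHb", "A_O2Hb")
HEMI_CLASSES = ("left", "right", "ipsilateral", "contralateral")
DERIVED = ("tau_diff", "tau_absdiff", "A_ratio", "A_absratio")


# ---------------------------------------------------------------------------
# Eye-level table construction
# ---------------------------------------------------------------------------


def build_eye_records(aggregates: pd.DataFrame) -> pd.DataFrame:
    """Pivot hemisphere aggregates to one row per eye.

    Input: one row per (subject_id, eye, hemisphere) with ``eye_class``
    and the four mean HRF parameters.  Output columns are
    ``<param>_<hemisphere-classification>`` for all four parameters under
    both classifications, plus ``y`` (1 = GLAUCOMA).  Hemispheres whose
    aggregate is missing stay NaN (models drop them listwise).
    """
    rows = []
    for (sid, eye), g in aggregates.groupby(["subject_id", "eye"], sort=False):
        row: dict = {
            "subject_id": sid,
            "eye": eye,
            "y": int(g["eye_class"].iloc[0] == "GLAUCOMA"),
        }
        for _, r in g.iterrows():
            lat = map_laterality(eye, r["hemisphere"])
            for p in PARAMS:
                row[f"{p}_{r['hemisphere']}"] = r[p]
                row[f"{p}_{lat}"] = r[p]
        rows.append(row)
    return pd.DataFrame(rows)


def derived_predictors(records: pd.DataFrame) -> pd.DataFrame:
    """Add latency-difference and amplitude-ratio predictors per
    hemisphere classification.

    tau_diff = tau_O2Hb - tau_HHb; tau_absdiff = |tau_O2Hb - tau_HHb|;
    A_ratio = A_O2Hb / A_HHb; A_absratio = |A_O2Hb / A_HHb|.  A zero HHb
    amplitude yields a missing ratio (with a warning), not an exception.
    """
    out = records.copy()
    for h in HEMI_CLASSES:
        tau_d = out[f"tau_O2Hb_{h}"] - out[f"tau_HHb_{h}"]
        out[f"tau_diff_{h}"] = tau_d
        out[f"tau_absdiff_{h}"] = tau_d.abs()
        denom = out[f"A_HHb_{h}"]
        zero = denom == 0
        if zero.any():
            warnings.warn(f"{int(zero.sum())} zero A_HHb values: ratio set missing")
        ratio = out[f"A_O2Hb_{h}"] / denom.where(~zero)
        out[f"A_ratio_{h}"] = ratio
        out[f"A_absratio_{h}"] = ratio.abs()
    return out


# ---------------------------------------------------------------------------
# GEE logistic regression
# ---------------------------------------------------------------------------


@dataclass
class GEEResult:
    """One fitted eye-level logistic model (before multiplicity adjustment)."""

    predictors: list[str]
    coef: np.ndarray  # slopes only (intercept excluded)
    cov: np.ndarray  # robust covariance of the slopes
    wald_chi2: dict[str, float]  # per-predictor Wald statistics
    wald_p: dict[str, float]
    joint_chi2: float  # all slopes = 0
    joint_p: float
    joint_df: int
    n_obs: int
    n_clusters: int
    n_dropped: int
    linear_predictor: pd.Series = field(repr=False, default=None)
    labels: pd.Series = field(repr=False, default=None)
    clusters: pd.Series = field(repr=False, default=None)

    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.coef)

    def or_ci(self, level: float = 0.95) -> np.ndarray:
        """(k, 2) odds-ratio confidence limits at ``level``."""
        z = sps.norm.ppf(0.5 + level / 2.0)
        se = np.sqrt(np.diag(self.cov))
        return np.exp(
            np.stack([self.coef - z * se, self.coef + z * se], axis=1)
        )


def fit_gee_logistic(
    records: pd.DataFrame,
    predictors: list[str] | str,
    cluster: str = "subject_id",
    outcome: str = "y",
    corr: str = "exchangeable",
) -> GEEResult:
    """GEE logistic regression of eye pathology on 1-2 predictors.

    Rows with missing predictors are dropped (counted in ``n_dropped``).
    Robust (sandwich) standard errors; Wald chi-square per coefficient
    and jointly for all slopes.
    """
    if isinstance(predictors, str):
        predictors = [predictors]
    cols = [outcome, cluster, *predictors]
    d = records[cols].dropna()
    n_dropped = len(records) - len(d)
    y = d[outcome].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    if d[cluster].nunique() < 2:
        raise ValueError("need >= 2 clusters")
    X = sm.add_constant(d[predictors].to_numpy())
    cov_struct = {
        "exchangeable": sm.cov_struct.Exchangeable,
        "independence": sm.cov_struct.Independence,
    }[corr]()
    model = sm.GEE(
        y, X, groups=d[cluster].to_numpy(), family=sm.families.Binomial(),
        cov_struct=cov_struct,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(maxiter=200, ctol=1e-10)
    cov_full = np.asarray(res.cov_params())
    diverged = (
        not np.all(np.isfinite(res.params))
        or not np.all(np.isfinite(cov_full))
        or np.max(np.abs(res.params)) > 1e3
    )
    if diverged:
        # Diverging coefficients (separation) — a finite fit with a few
        # high-leverage observations is NOT flagged.
        raise RuntimeError(
            "GEE did not converge to a finite solution (possible separation); "
            f"params={res.params}"
        )
    coef = res.params[1:]
    cov = cov_full[1:, 1:]
    se = np.sqrt(np.diag(cov))
    wald = (coef / se) ** 2
    wald_p = sps.chi2.sf(wald, df=1)
    joint = float(coef @ np.linalg.solve(cov, coef))
    joint_df = len(coef)
    return GEEResult(
        predictors=list(predictors),
        coef=np.asarray(coef),
        cov=cov,
        wald_chi2=dict(zip(predictors, wald)),
        wald_p=dict(zip(predictors, wald_p)),
        joint_chi2=joint,
        joint_p=float(sps.chi2.sf(joint, df=joint_df)),
        joint_df=joint_df,
        n_obs=len(d),
        n_clusters=int(d[cluster].nunique()),
        n_dropped=n_dropped,
        linear_predictor=pd.Series(X @ res.params, index=d.index),
        labels=d[outcome],
        clusters=d[cluster],
    )


# ---------------------------------------------------------------------------
# Multiplicity and discrimination
# ---------------------------------------------------------------------------


def bonferroni_adjust(p: float | np.ndarray, m: int) -> np.ndarray | float:
    """p_adj = min(1, m p).  For confidence intervals use level
    ``1 - alpha/m`` instead."""
    if m < 1:
        raise ValueError(f"number of tests must be >= 1, got {m}")
    return np.minimum(np.asarray(p, dtype=float) * m, 1.0)[()]


def adjusted_ci_level(m: int, alpha: float = 0.05) -> float:
    if m < 1:
        raise ValueError(f"number of tests must be >= 1, got {m}")
    return 1.0 - alpha / m


def format_p(p: float) -> str:
    """Report convention: probabilities capped at 1 print as '> 0.999'."""
    return "> 0.999" if p >= 0.9995 else f"{p:.4f}"


def concordance_index(scores: np.ndarray, labels: np.ndarray) -> float:
    """Concordance index c = P(score_case > score_control) + 0.5 P(tie).

    Equivalent to the area under the ROC curve; computed from midranks
    (Mann-Whitney), ties counted half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same shape")
    n1 = int(np.sum(labels == 1))
    n0 = int(np.sum(labels == 0))
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present to compute c")
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def concordance_ci(
    scores: np.ndarray,
    labels: np.ndarray,
    clusters: np.ndarray,
    *,
    n_boot: int = 1000,
    level: float = 0.95,
    rng: np.random.Generator | int | None = 0,
) -> tuple[float, float, int]:
    """Cluster-bootstrap percentile CI for the concordance index.

    Subjects (clusters) are resampled with replacement; resamples missing
    one of the classes are skipped and counted.  Returns (lo, hi,
    n_skipped).
    """
    if n_boot < 500:
        raise ValueError("use at least 500 bootstrap replicates")
    rng = np.random.default_rng(rng)
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    clusters = np.asarray(clusters)
    uniq = np.unique(clusters)
    by_cluster = {c: np.flatnonzero(clusters == c) for c in uniq}
    cs = []
    skipped = 0
    for _ in range(n_boot):
        pick = rng.choice(uniq, size=uniq.size, replace=True)
        idx = np.concatenate([by_cluster[c] for c in pick])
        lab = labels[idx]
        if lab.min() == lab.max():
            skipped += 1
            continue
        cs.append(concordance_index(scores[idx], lab))
    if not cs:
        raise ValueError("all bootstrap resamples were degenerate")
    alpha = 1.0 - level
    lo, hi = np.quantile(cs, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi), skipped


# ---------------------------------------------------------------------------
# The full model battery
# ---------------------------------------------------------------------------


def _battery_row(
    name: str,
    hemi: str,
    res: GEEResult,
    pred: str,
    m: int,
    use_joint: bool,
    c: float | None,
    c_ci: tuple[float, float] | None,
) -> dict:
    i = res.predictors.index(pred)
    ci = res.or_ci(adjusted_ci_level(m))[i]
    chi2 = res.joint_chi2 if use_joint else res.wald_chi2[pred]
    p = res.joint_p if use_joint else res.wald_p[pred]
    df = res.joint_df if use_joint else 1
    return {
        "parameter": name,
        "hemisphere": hemi,
        "predictor": pred,
        "OR": float(np.exp(res.coef[i])),
        "OR_lo": float(ci[0]),
        "OR_hi": float(ci[1]),
        "df": df,
        "chi2": float(chi2),
        "p_adj": float(bonferroni_adjust(p, m)),
        "p_adj_fmt": format_p(float(bonferroni_adjust(p, m))),
        "m": m,
        "n_obs": res.n_obs,
        "n_dropped": res.n_dropped,
        "c": c,
        "c_lo": None if c_ci is None else c_ci[0],
        "c_hi": None if c_ci is None else c_ci[1],
    }


def run_model_battery(
    records: pd.DataFrame,
    *,
    with_c_ci: bool = True,
    n_boot: int = 1000,
    rng: np.random.Generator | int | None = 0,
    alpha: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """The full eye-level discrimination battery.

    Three report tables:

    * ``single``: 16 one-predictor models — each HRF parameter at each
      hemisphere classification; Bonferroni multiplicity m = 4 per
      parameter family (the four hemisphere classes).
    * ``two_hemisphere``: 8 two-predictor models — the same parameter at
      the two hemispheres of one classification (left+right,
      ipsi+contra).  Per family, if no single-hemisphere association was
      significant the joint null (both slopes zero) is tested once per
      model; otherwise each slope gets its own Wald test.  m is the
      number of Wald tests actually performed in the family.
    * ``derived``: 16 one-predictor models of the latency-difference /
      amplitude-ratio functions; m = 4 per function family.

    ``records`` must already contain the derived columns (see
    :func:`derived_predictors`); they are added if absent.
    """
    if "tau_diff_left" not in records.columns:
        records = derived_predictors(records)
    rng = np.random.default_rng(rng)

    def try_fit(predictors):
        """Partial-battery tolerance: a model that cannot be estimated
        (separation on tiny cohorts, degenerate predictors) yields a
        gap row instead of aborting the battery."""
        try:
            return fit_gee_logistic(records, predictors), None
        except (ValueError, RuntimeError) as e:
            warnings.warn(f"model {predictors} not estimable: {e}")
            return None, str(e)

    def gap_row(name, hemi, pred, m, err):
        return {
            "parameter": name, "hemisphere": hemi, "predictor": pred,
            "OR": np.nan, "OR_lo": np.nan, "OR_hi": np.nan, "df": 0,
            "chi2": np.nan, "p_adj": np.nan, "p_adj_fmt": f"failed: {err}",
            "m": m, "n_obs": 0, "n_dropped": 0,
            "c": np.nan, "c_lo": np.nan, "c_hi": np.nan,
        }

    def c_for(res: GEEResult):
        # c-index of the model's linear predictor (equals the single
        # predictor itself up to monotone transform for 1-predictor
        # models with positive slope; computed from the fit for
        # uniformity and for 2-predictor models)
        scores = res.linear_predictor.to_numpy()
        c = concordance_index(scores, res.labels.to_numpy())
        return c, scores

    single_rows = []
    single_signif: dict[str, bool] = {}
    for pname in PARAMS:
        m = len(HEMI_CLASSES)
        any_sig = False
        for hemi in HEMI_CLASSES:
            res, err = try_fit(f"{pname}_{hemi}")
            if res is None:
                single_rows.append(gap_row(pname, hemi, f"{pname}_{hemi}", m, err))
                continue
            c, scores = c_for(res)
            ci = None
            if with_c_ci:
                ci = concordance_ci(
                    scores,
                    res.labels.to_numpy(),
                    res.clusters.to_numpy(),
                    n_boot=n_boot,
                    level=adjusted_ci_level(m, alpha),
                    rng=rng,
                )[:2]
            row = _battery_row(
                pname, hemi, res, f"{pname}_{hemi}", m, False, c, ci
            )
            any_sig = any_sig or row["p_adj"] < alpha
            single_rows.append(row)
        single_signif[pname] = any_sig
    single = pd.DataFrame(single_rows)

    two_rows = []
    pairs = (("left", "right"), ("ipsilateral", "contralateral"))
    for pname in PARAMS:
        use_joint = not single_signif[pname]
        # number of Wald tests in this family: 1 per model if joint,
        # else 1 per coefficient
        m = (1 if use_joint else 2) * len(pairs)
        for pair in pairs:
            preds = [f"{pname}_{h}" for h in pair]
            res, err = try_fit(preds)
            if res is None:
                for hemi, pred in zip(pair, preds):
                    two_rows.append(gap_row(pname, hemi, pred, m, err))
                continue
            c, scores = c_for(res)
            ci = None
            if with_c_ci:
                ci = concordance_ci(
                    scores,
                    res.labels.to_numpy(),
                    res.clusters.to_numpy(),
                    n_boot=n_boot,
                    level=adjusted_ci_level(m, alpha),
                    rng=rng,
                )[:2]
            for hemi, pred in zip(pair, preds):
                two_rows.append(
                    _battery_row(pname, hemi, res, pred, m, use_joint, c, ci)
                )
    two = pd.DataFrame(two_rows)

    derived_rows = []
    for fname in DERIVED:
        m = len(HEMI_CLASSES)
        for hemi in HEMI_CLASSES:
            res, err = try_fit(f"{fname}_{hemi}")
            if res is None:
                derived_rows.append(gap_row(fname, hemi, f"{fname}_{hemi}", m, err))
                continue
            c, scores = c_for(res)
            ci = None
            if with_c_ci:
                ci = concordance_ci(
                    scores,
                    res.labels.to_numpy(),
                    res.clusters.to_numpy(),
                    n_boot=n_boot,
                    level=adjusted_ci_level(m, alpha),
                    rng=rng,
                )[:2]
            derived_rows.append(
                _battery_row(fname, hemi, res, f"{fname}_{hemi}", m, False, c, ci)
            )
    derived = pd.DataFrame(derived_rows)

    return {"single": single, "two_hemisphere": two, "derived": derived}
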