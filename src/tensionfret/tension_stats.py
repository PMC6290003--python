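"""Grouped-difference statistics for tension readouts.

The workhorse is a linear mixed-effects model with a per-image random
intercept, which accounts for the statistical dependence of puncta from
the same image.  The reported difference uses the convention
delta = ctrl - sensor, so molecular tension (lower sensor FRET) gives a
positive delta.

Inference uses REML estimation with Wald confidence intervals and
normal-approximation p-values on the fixed effect.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm


@dataclass
class GroupedDifferenceResult:
    delta: float
    ci_low: float
    ci_high: float
    p_value: float
    group_var: float
    resid_var: float
    n_puncta: int
    n_images: int
    ci_level: float
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.ci_low <= self.delta <= self.ci_high:
            raise ValueError("CI must bracket the point estimate")


@dataclass
class InteractionResult:
    interaction_delta: float  # drug-induced change in (ctrl - sensor)
    coefficient: float  # raw model coefficient on the interaction term
    ci_low: float
    ci_high: float
    p_value: float
    n_puncta: int
    n_images: int
    ci_level: float
    flags: list[str] = field(default_factory=list)


@dataclass
class BoxplotStats:
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    fliers: np.ndarray


def _check_obs(obs: pd.DataFrame, value_col: str, arm_col: str, group_col: str) -> None:
    for col in (value_col, arm_col, group_col):
        if col not in obs.columns:
            raise ValueError(f"missing column {col!r}")
    if not np.isfinite(obs[value_col].to_numpy(dtype=float)).all():
        raise ValueError("values must be finite")
    arms = set(obs[arm_col].unique())
    if not arms.issuperset({0, 1}):
        raise ValueError("both arms (isTensionSensor 0 and 1) must be present")


def fit_grouped_difference(
    obs: pd.DataFrame,
    ci_level: float = 0.95,
    value_col: str = "value",
    arm_col: str = "isTensionSensor",
    group_col: str = "imageNumber",
) -> GroupedDifferenceResult:
    """Mixed-model arm difference with a per-image random intercept.

    Fits ``value ~ arm`` with a random intercept per image (REML) and
    reports delta = ctrl - sensor = -(coefficient on the arm indicator)
    with a Wald CI and p-value.  With a single image in total the model is
    degenerate and a pooled OLS fallback is used (flagged); a group
    variance estimated at the zero boundary is reported as 0 with a
    ``boundary_group_var`` flag.
    """
    _check_obs(obs, value_col, arm_col, group_col)
    y = obs[value_col].to_numpy(dtype=float)
    arm = obs[arm_col].to_numpy(dtype=float)
    groups = obs[group_col].to_numpy()
    n_images = len(np.unique(groups))
    n = len(y)
    z = sps.norm.ppf(0.5 + ci_level / 2.0)
    flags: list[str] = []

    exog = sm.add_constant(arm)
    ols = sm.OLS(y, exog).fit()
    ssr = float(ols.ssr)
    if ssr <= 1e-12 * max(1.0, float(np.dot(y, y))):
        # Noise-free data: exact difference, zero-width interval.
        delta = -float(ols.params[1])
        return GroupedDifferenceResult(
            delta=delta, ci_low=delta, ci_high=delta, p_value=0.0 if delta != 0 else 1.0,
            group_var=0.0, resid_var=0.0, n_puncta=n, n_images=n_images,
            ci_level=ci_level, flags=["noise_free"],
        )

    if n_images < 2:
        se = float(ols.bse[1])
        delta = -float(ols.params[1])
        flags.append("pooled_ols_fallback")
        p = 2.0 * sps.norm.sf(abs(delta) / se) if se > 0 else 0.0
        return GroupedDifferenceResult(
            delta=delta, ci_low=delta - z * se, ci_high=delta + z * se, p_value=p,
            group_var=0.0, resid_var=float(ols.mse_resid), n_puncta=n,
            n_images=n_images, ci_level=ci_level, flags=flags,
        )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, exog, groups=groups)
        fit = model.fit(reml=True)
    coef = float(fit.fe_params[1])
    se = float(fit.bse_fe[1])
    group_var = float(np.asarray(fit.cov_re)[0, 0])
    if group_var < 1e-10:
        group_var = 0.0
        flags.append("boundary_group_var")
    delta = -coef
    p = 2.0 * sps.norm.sf(abs(coef) / se) if se > 0 else 0.0
    return GroupedDifferenceResult(
        delta=delta,
        ci_low=delta - z * se,
        ci_high=delta + z * se,
        p_value=p,
        group_var=group_var,
        resid_var=float(fit.scale),
        n_puncta=n,
        n_images=n_images,
        ci_level=ci_level,
        flags=flags,
    )


def fit_drug_interaction(
    obs: pd.DataFrame,
    ci_level: float = 0.95,
    value_col: str = "value",
    arm_col: str = "isTensionSensor",
    drug_col: str = "isDrugWell",
    group_col: str = "imageNumber",
) -> InteractionResult:
    """Interaction contrast ``value ~ arm * drug`` with per-image random
    intercept.

    ``interaction_delta`` is the drug-induced change in the ctrl - sensor
    difference (the negated interaction coefficient); CI and p-value refer
    to that contrast.  All four arm x well cells must be populated.
    """
    _check_obs(obs, value_col, arm_col, group_col)
    if drug_col not in obs.columns:
        raise ValueError(f"missing column {drug_col!r}")
    for ts in (0, 1):
        for dw in (0, 1):
            if not ((obs[arm_col] == ts) & (obs[drug_col] == dw)).any():
                raise ValueError(
                    f"empty cell: {arm_col}={ts}, {drug_col}={dw}"
                )
    y = obs[value_col].to_numpy(dtype=float)
    arm = obs[arm_col].to_numpy(dtype=float)
    drug = obs[drug_col].to_numpy(dtype=float)
    groups = obs[group_col].to_numpy()
    exog = np.column_stack([np.ones_like(y), arm, drug, arm * drug])
    n_images = len(np.unique(groups))
    z = sps.norm.ppf(0.5 + ci_level / 2.0)

    ols = sm.OLS(y, exog).fit()
    if float(ols.ssr) <= 1e-12 * max(1.0, float(np.dot(y, y))):
        coef = float(ols.params[3])
        delta = -coef
        return InteractionResult(
            interaction_delta=delta, coefficient=coef, ci_low=delta, ci_high=delta,
            p_value=0.0 if delta != 0 else 1.0, n_puncta=len(y),
            n_images=n_images, ci_level=ci_level, flags=["noise_free"],
        )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.MixedLM(y, exog, groups=groups).fit(reml=True)
    coef = float(fit.fe_params[3])
    se = float(fit.bse_fe[3])
    delta = -coef
    p = 2.0 * sps.norm.sf(abs(coef) / se) if se > 0 else 0.0
    return InteractionResult(
        interaction_delta=delta,
        coefficient=coef,
        ci_low=delta - z * se,
        ci_high=delta + z * se,
        p_value=p,
        n_puncta=len(y),
        n_images=n_images,
        ci_level=ci_level,
    )


def grouped_mean(
    values: np.ndarray, groups: np.ndarray, ci_level: float = 0.95
) -> tuple[float, float, float]:
    """Mean with grouping-aware CI (intercept-only mixed model; falls back
    to a t interval over group means when degenerate)."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    gmeans = np.array([values[groups == g].mean() for g in uniq])
    if len(uniq) < 2 or np.ptp(values) == 0:
        m = float(values.mean())
        return m, m, m
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.MixedLM(values, np.ones((len(values), 1)), groups=groups).fit(reml=True)
        m = float(fit.fe_params[0])
        se = float(fit.bse_fe[0])
    except Exception:
        m = float(gmeans.mean())
        se = float(gmeans.std(ddof=1) / math.sqrt(len(gmeans)))
    z = sps.norm.ppf(0.5 + ci_level / 2.0)
    return m, m - z * se, m + z * se


def binned_delta(
    ts_tracks: pd.DataFrame,
    ctrl_pool: pd.DataFrame,
    bin_by: str = "d_r_um",
    edges: np.ndarray | None = None,
    ci_level: float = 0.68,
    value_col: str = "value",
    group_col: str = "imageNumber",
    orientation_col: str = "orientation",
    split_orientation: bool = False,
) -> dict:
    """Per-bin grouped differences of sensor puncta against the entire
    control pool.

    For each bin of ``bin_by`` (recoil distance or angle), the mixed
    grouped-difference model is refitted between that bin's sensor puncta
    and the full, unbinned control pool; per-bin deltas are reported with
    the requested CI (default 68%).  The control-pool mean is reported
    with a 95% CI.  Empty bins are skipped and listed.
    """
    if edges is None:
        edges = np.arange(0.0, 10.5, 2.5) if bin_by == "d_r_um" else np.arange(0.0, 91.0, 30.0)
    edges = np.asarray(edges, dtype=float)
    ctrl = ctrl_pool.copy()
    ctrl_vals = ctrl[value_col].to_numpy(dtype=float)
    ctrl_groups = ctrl[group_col].to_numpy()
    ctrl_mean, ctrl_lo, ctrl_hi = grouped_mean(ctrl_vals, ctrl_groups, ci_level=0.95)

    rows = []
    skipped = []
    combos = [("all", ts_tracks)]
    if split_orientation:
        combos = [
            (name, ts_tracks[ts_tracks[orientation_col] == name])
            for name in ("parallel", "perpendicular")
        ]
    for orient_name, subset in combos:
        for lo, hi in zip(edges[:-1], edges[1:]):
            in_bin = subset[(subset[bin_by] >= lo) & (subset[bin_by] < hi)]
            if in_bin.empty:
                skipped.append((orient_name, float(lo), float(hi)))
                continue
            ts_part = pd.DataFrame(
                {
                    "value": in_bin[value_col].to_numpy(dtype=float),
                    "isTensionSensor": 1,
                    "imageNumber": [f"ts_{g}" for g in in_bin[group_col]],
                }
            )
            ctrl_part = pd.DataFrame(
                {
                    "value": ctrl_vals,
                    "isTensionSensor": 0,
                    "imageNumber": [f"ctrl_{g}" for g in ctrl_groups],
                }
            )
            res = fit_grouped_difference(
                pd.concat([ctrl_part, ts_part], ignore_index=True), ci_level=ci_level
            )
            rows.append(
                {
                    "orientation": orient_name,
                    "bin_low": float(lo),
                    "bin_high": float(hi),
                    "bin_center": float((lo + hi) / 2.0),
                    "delta": res.delta,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "p_value": res.p_value,
                    "n_ts": len(in_bin),
                    "n_ctrl": len(ctrl),
                }
            )
    return {
        "bins": pd.DataFrame(rows),
        "ctrl_mean": ctrl_mean,
        "ctrl_ci": (ctrl_lo, ctrl_hi),
        "skipped_bins": skipped,
    }


def ks_compare(sample_a, sample_b) -> tuple[float, float]:
    """Two-sided two-sample Kolmogorov-Smirnov statistic and asymptotic
    p-value."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples must have size >= 2")
    res = sps.ks_2samp(a, b, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue)


def boxplot_stats(values) -> BoxplotStats:
    """Box statistics with whiskers at the last datum within 1.5 x IQR."""
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("empty sample")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    return BoxplotStats(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        fliers=v[(v < lo_fence) | (v > hi_fence)],
    )


def summarize_boxplot(values, groups) -> tuple[pd.Series, BoxplotStats]:
    """Per-image medians and box statistics over those medians."""
    s = pd.Series(np.asarray(values, dtype=float))
    g = pd.Series(np.asarray(groups))
    if s.empty:
        raise ValueError("empty sample")
    medians = s.groupby(g.values).median()
    return medians, boxplot_stats(medians.to_numpy())
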