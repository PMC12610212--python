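"""Genotype-group comparison of prediction metrics.

Input is a long table of metric records — one value per (video, stage, metric)
with a group label (wild-type enhancer reporter vs the Su(H)-site mutant).
Two complementary inferences on the group mean difference (mutant − wild-type):

* a stratified percentile bootstrap: records are resampled with replacement
  within each group (group sizes preserved), the mean difference is recomputed
  per replicate, and the CI is taken from the empirical quantiles;
* a linear mixed-effects model with a fixed group effect and random intercepts
  for video and for stage (crossed, via variance components), fitted with
  statsmodels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import GENOTYPES

#: Metric columns eligible for group comparison.
COMPARISON_METRICS: tuple[str, ...] = ("ap_mae", "dv_mae", "mean_mae")


@dataclass
class BootstrapResult:
    """Percentile-bootstrap summary of one metric's group mean difference."""

    metric: str
    B: int
    alpha: float
    point_estimate: float  # plain mean(mutant) - mean(wild-type), no resampling
    ci_low: float
    ci_high: float
    samples: np.ndarray = field(repr=False)


@dataclass
class EffectEstimate:
    """Mixed-effects fixed group difference for one metric."""

    metric: str
    estimate: float
    p_value: float
    converged: bool
    structure: str = "fixed: group; random intercepts: video, stage"


def metric_records(metrics: pd.DataFrame) -> pd.DataFrame:
    """Melt a wide per-(video, stage) metrics table into long records with
    columns (video_id, stage, group, metric, value)."""
    required = {"video_id", "stage", "genotype", *COMPARISON_METRICS}
    missing = required - set(metrics.columns)
    if missing:
        raise ValueError(f"metrics table missing columns {sorted(missing)}")
    long = metrics.melt(
        id_vars=["video_id", "stage", "genotype"],
        value_vars=list(COMPARISON_METRICS),
        var_name="metric",
        value_name="value",
    ).rename(columns={"genotype": "group"})
    if long.duplicated(["video_id", "stage", "metric"]).any():
        raise ValueError("expected one value per (video, stage, metric)")
    return long


def _group_values(
    records: pd.DataFrame, metric: str, group_order: tuple[str, str]
) -> tuple[np.ndarray, np.ndarray]:
    sub = records[records["metric"] == metric]
    wt, mut = group_order
    a = sub.loc[sub["group"] == wt, "value"].to_numpy(dtype=float)
    b = sub.loc[sub["group"] == mut, "value"].to_numpy(dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError(
            f"both groups must be non-empty for metric {metric!r} "
            f"(got {len(a)} {wt!r}, {len(b)} {mut!r})"
        )
    return a, b


def bootstrap_diff(
    records: pd.DataFrame,
    metric: str,
    B: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
    group_order: tuple[str, str] = GENOTYPES,
) -> BootstrapResult:
    """Stratified percentile bootstrap of mean(mutant) − mean(wild-type).

    Each replicate resamples the records of each group with replacement,
    preserving group sizes. The point estimate is the plain (unresampled)
    group mean difference; the CI is the empirical (alpha/2, 1−alpha/2)
    percentile interval of the replicate differences. Deterministic for a
    fixed seed.
    """
    if B < 100:
        raise ValueError(f"B must be >= 100, got {B}")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    wt_vals, mut_vals = _group_values(records, metric, group_order)
    rng = np.random.default_rng(seed)
    n_wt, n_mut = len(wt_vals), len(mut_vals)
    wt_means = wt_vals[rng.integers(0, n_wt, size=(B, n_wt))].mean(axis=1)
    mut_means = mut_vals[rng.integers(0, n_mut, size=(B, n_mut))].mean(axis=1)
    diffs = mut_means - wt_means
    lo, hi = np.percentile(diffs, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return BootstrapResult(
        metric=metric,
        B=B,
        alpha=alpha,
        point_estimate=float(mut_vals.mean() - wt_vals.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
        samples=diffs,
    )


def interpret_ci(result: BootstrapResult) -> bool:
    """True iff the CI excludes zero (closed-interval convention: a CI with an
    endpoint exactly at zero still includes it)."""
    return not (result.ci_low <= 0.0 <= result.ci_high)


def mixed_effects_diff(
    records: pd.DataFrame,
    metric: str,
    group_order: tuple[str, str] = GENOTYPES,
) -> EffectEstimate:
    """Mixed-effects group contrast for one metric.

    Model: value ~ 1 + group, with crossed random intercepts for video and for
    stage expressed as variance components (fitted by statsmodels MixedLM over
    a single grouping super-level). Returns the fixed group-difference
    coefficient (mutant − wild-type) and its Wald p-value; a non-converged fit
    is flagged rather than silently returning NaN.
    """
    import statsmodels.api as sm

    sub = records[records["metric"] == metric].copy()
    groups_present = set(sub["group"].unique())
    if not set(group_order) <= groups_present:
        raise ValueError(
            f"need both groups {group_order} present, got {sorted(groups_present)}"
        )
    if sub["stage"].nunique() < 2:
        raise ValueError("need >= 2 stages for the stage random effect")
    wt, mut = group_order
    sub["is_mutant"] = (sub["group"] == mut).astype(float)
    sub["_one"] = 1
    model = sm.MixedLM.from_formula(
        "value ~ is_mutant",
        data=sub,
        groups="_one",
        re_formula="0",
        vc_formula={"video": "0 + C(video_id)", "stage": "0 + C(stage)"},
    )
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        fit = model.fit(reml=True)
    converged = bool(getattr(fit, "converged", True))
    return EffectEstimate(
        metric=metric,
        estimate=float(fit.params["is_mutant"]),
        p_value=float(fit.pvalues["is_mutant"]),
        converged=converged,
    )


def compare_groups(
    records: pd.DataFrame,
    metrics: tuple[str, ...] = COMPARISON_METRICS,
    B: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
    group_order: tuple[str, str] = GENOTYPES,
) -> pd.DataFrame:
    """Bootstrap CI + mixed-effects contrast for each metric; one row each."""
    rows = []
    for i, metric in enumerate(metrics):
        boot = bootstrap_diff(
            records, metric, B=B, alpha=alpha, seed=seed + i, group_order=group_order
        )
        try:
            eff = mixed_effects_diff(records, metric, group_order=group_order)
            mixed_est, mixed_p, converged = eff.estimate, eff.p_value, eff.converged
        except (ValueError, np.linalg.LinAlgError):
            mixed_est, mixed_p, converged = float("nan"), float("nan"), False
        rows.append(
            {
                "metric": metric,
                "mean_diff": boot.point_estimate,
                "ci_low": boot.ci_low,
                "ci_high": boot.ci_high,
                "excludes_zero": interpret_ci(boot),
                "mixed_effect": mixed_est,
                "mixed_p_value": mixed_p,
                "mixed_converged": converged,
            }
        )
    return pd.DataFrame(rows)
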