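"""Comparisons of predicted epigenetic age between cellular states.

Three designs, matching how multi-dataset stem-cell panels are analysed:

* two cell stages in one dataset → two-sample t-test (Welch by default,
  since group variances of predicted ages differ between stages; the
  pooled-variance Student test is available by flag);
* three stages in one dataset → one-way ANOVA followed by Tukey HSD
  pairwise comparisons (Tukey–Kramer standard errors for unbalanced
  groups, adjusted p-values from the studentized-range distribution);
* several datasets → a linear mixed model pooling all samples,

      predicted_age_dpc ~ stage dummies + (1 | dataset_id)

  with iPSC (or any chosen reference) as the baseline, fitted by REML;
  fixed effects are tested with Wald z statistics. A dataset lacking a
  stage still informs the others through its random intercept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .datamodel import ValidationError


@dataclass
class StageContrastResult:
    """One contrast between two cell stages."""

    contrast: str  # e.g. "neuron-iPSC"
    delta_mean: float  # mean(b) − mean(a), dpc
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    method: str  # t_test | tukey_hsd | mixed_model
    flag: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValidationError(f"p-value {self.p_value} outside [0, 1]")


@dataclass
class MixedModelFit:
    """REML random-intercept fit of predicted age on stage dummies."""

    fixed_effects: dict[str, float]
    std_errors: dict[str, float]
    pvalues: dict[str, float]
    random_intercept_var: float
    residual_var: float
    n: int
    n_datasets: int
    converged: bool
    method: str = "reml_random_intercept"
    contrasts: list[StageContrastResult] = field(default_factory=list)


def two_sample_t(
    pred_a: np.ndarray,
    pred_b: np.ndarray,
    label_a: str = "a",
    label_b: str = "b",
    equal_var: bool = False,
) -> StageContrastResult:
    """Two-sided two-sample t-test; delta_mean = mean(b) − mean(a)."""
    a = np.asarray(pred_a, dtype=float)
    b = np.asarray(pred_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs n >= 2")
    delta = float(b.mean() - a.mean())
    flag = ""
    if a.std() == 0 and b.std() == 0:
        if delta == 0:
            stat, p = 0.0, 1.0
            flag = "degenerate: zero variance in both groups, equal means"
        else:
            stat, p = np.inf, 0.0
            flag = "degenerate: zero variance in both groups"
    else:
        res = stats.ttest_ind(b, a, equal_var=equal_var)
        stat, p = float(res.statistic), float(res.pvalue)
    return StageContrastResult(
        contrast=f"{label_b}-{label_a}",
        delta_mean=delta,
        statistic=stat,
        p_value=p,
        n_a=int(a.size),
        n_b=int(b.size),
        method="t_test",
        flag=flag,
    )


def anova_tukey(
    values: np.ndarray, stage: np.ndarray
) -> tuple[float, float, list[StageContrastResult]]:
    """One-way ANOVA F-test, then all pairwise Tukey HSD contrasts.

    Returns (F, anova_p, contrasts). Requires ≥ 2 observations in each of
    (at least) 3 stages; unbalanced groups use Tukey–Kramer standard
    errors via the studentized-range distribution.
    """
    values = np.asarray(values, dtype=float)
    stage = np.asarray(stage, dtype=object)
    levels = pd.unique(stage)
    if len(levels) < 3:
        raise ValidationError("anova_tukey needs >= 3 stages (use two_sample_t)")
    groups = [values[stage == lev] for lev in levels]
    for lev, g in zip(levels, groups):
        if g.size < 2:
            raise ValidationError(f"stage {lev!r} has fewer than 2 observations")
    counts = {lev: int((stage == lev).sum()) for lev in levels}
    if np.ptp(values) == 0:
        # fully degenerate: every observation identical in every stage
        contrasts = [
            StageContrastResult(
                contrast=f"{levels[j]}-{levels[i]}",
                delta_mean=0.0,
                statistic=0.0,
                p_value=1.0,
                n_a=counts[levels[i]],
                n_b=counts[levels[j]],
                method="tukey_hsd",
                flag="degenerate: zero variance",
            )
            for i in range(len(levels))
            for j in range(i + 1, len(levels))
        ]
        return 0.0, 1.0, contrasts
    F, anova_p = (float(x) for x in stats.f_oneway(*groups))
    tukey = pairwise_tukeyhsd(values, stage)
    contrasts: list[StageContrastResult] = []
    table = tukey.summary().data[1:]
    for row, p_adj, delta, stat_q in zip(
        table, tukey.pvalues, tukey.meandiffs, np.abs(tukey.meandiffs) / tukey.std_pairs
    ):
        g1, g2 = str(row[0]), str(row[1])
        contrasts.append(
            StageContrastResult(
                contrast=f"{g2}-{g1}",
                delta_mean=float(delta),
                statistic=float(stat_q * np.sqrt(2)),  # studentized range q
                p_value=float(p_adj),
                n_a=counts[g1],
                n_b=counts[g2],
                method="tukey_hsd",
            )
        )
    return F, anova_p, contrasts


def per_dataset_contrasts(
    table: pd.DataFrame,
    value_col: str = "predicted_age_dpc",
    stage_col: str = "group",
    dataset_col: str = "dataset_id",
    reference: str = "iPSC",
    equal_var: bool = False,
) -> pd.DataFrame:
    """Within each dataset: t-test when two stages are present, ANOVA +
    Tukey HSD when three or more are. Long-format result table."""
    rows = []
    for dataset, block in table.groupby(dataset_col):
        stages = [s for s in pd.unique(block[stage_col]) if pd.notna(s)]
        usable = [s for s in stages if (block[stage_col] == s).sum() >= 2]
        if len(usable) < 2:
            continue
        if len(usable) == 2:
            a_lab = reference if reference in usable else usable[0]
            b_lab = [s for s in usable if s != a_lab][0]
            res = [
                two_sample_t(
                    block.loc[block[stage_col] == a_lab, value_col].to_numpy(),
                    block.loc[block[stage_col] == b_lab, value_col].to_numpy(),
                    a_lab,
                    b_lab,
                    equal_var=equal_var,
                )
            ]
            anova_p = np.nan
        else:
            keep = block[stage_col].isin(usable)
            _, anova_p, res = anova_tukey(
                block.loc[keep, value_col].to_numpy(),
                block.loc[keep, stage_col].to_numpy(),
            )
        for r in res:
            rows.append(
                {
                    "dataset_id": dataset,
                    "contrast": r.contrast,
                    "delta_mean_dpc": r.delta_mean,
                    "statistic": r.statistic,
                    "p_value": r.p_value,
                    "n_a": r.n_a,
                    "n_b": r.n_b,
                    "method": r.method,
                    "anova_p": anova_p,
                }
            )
    return pd.DataFrame(rows)


def stage_meta_analysis(
    table: pd.DataFrame,
    value_col: str = "predicted_age_dpc",
    stage_col: str = "group",
    dataset_col: str = "dataset_id",
    reference: str = "iPSC",
    stages: list[str] | None = None,
) -> MixedModelFit:
    """Random-intercept mixed model pooling stage effects across datasets.

    Fixed effects are dummies for each non-reference stage (default
    coding: NPC vs iPSC and neuron vs iPSC); the random intercept absorbs
    between-dataset shifts. REML estimation, Wald z p-values. With a
    single dataset the model degenerates and an OLS fit is returned with
    a warning; a non-converged REML fit is flagged and should not be
    read as primary.
    """
    df = table[[value_col, stage_col, dataset_col]].dropna().copy()
    if stages is not None:
        df = df[df[stage_col].isin(stages)]
    levels = [s for s in pd.unique(df[stage_col])]
    if reference not in levels:
        raise ValidationError(f"reference stage {reference!r} absent")
    others = [s for s in levels if s != reference]
    if not others:
        raise ValidationError("only the reference stage present")
    y = df[value_col].to_numpy(dtype=float)
    X = np.column_stack(
        [np.ones(len(df))] + [(df[stage_col] == s).to_numpy(dtype=float) for s in others]
    )
    names = ["intercept"] + [f"{s}-{reference}" for s in others]
    n_datasets = df[dataset_col].nunique()

    if n_datasets < 2:
        warnings.warn("single dataset: falling back to OLS (no random intercept)")
        ols = sm.OLS(y, X).fit()
        fixed = dict(zip(names, map(float, ols.params)))
        se = dict(zip(names, map(float, ols.bse)))
        pv = dict(zip(names, map(float, ols.pvalues)))
        fit = MixedModelFit(
            fixed_effects=fixed,
            std_errors=se,
            pvalues=pv,
            random_intercept_var=0.0,
            residual_var=float(ols.mse_resid),
            n=len(df),
            n_datasets=int(n_datasets),
            converged=True,
            method="ols_fallback",
        )
    else:
        model = MixedLM(y, X, groups=df[dataset_col].to_numpy())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(reml=True)
        converged = bool(getattr(res, "converged", True))
        fixed = dict(zip(names, map(float, res.fe_params)))
        se = dict(zip(names, map(float, res.bse_fe)))
        z = {k: fixed[k] / se[k] for k in names}
        pv = {k: float(2 * stats.norm.sf(abs(z[k]))) for k in names}
        fit = MixedModelFit(
            fixed_effects=fixed,
            std_errors=se,
            pvalues=pv,
            random_intercept_var=float(np.asarray(res.cov_re)[0, 0]),
            residual_var=float(res.scale),
            n=len(df),
            n_datasets=int(n_datasets),
            converged=converged,
        )
        if not converged:
            warnings.warn("mixed model did not converge; estimates are not primary")
    for s in others:
        key = f"{s}-{reference}"
        fit.contrasts.append(
            StageContrastResult(
                contrast=key,
                delta_mean=fit.fixed_effects[key],
                statistic=fit.fixed_effects[key] / fit.std_errors[key],
                p_value=fit.pvalues[key],
                n_a=int((df[stage_col] == reference).sum()),
                n_b=int((df[stage_col] == s).sum()),
                method="mixed_model",
                flag="" if fit.converged else "not_converged",
            )
        )
    return fit
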