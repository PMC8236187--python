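"""Accuracy metrics and sensitivity analyses for clock predictions.

Two headline statistics per evaluation set: Pearson's correlation
between predicted and chronological age, and the root mean squared
error (plain mean, no degrees-of-freedom correction), both in the age
unit supplied (dpc throughout this package). A range-restricted variant
evaluates only samples whose chronological age falls within the
training range, since penalized clocks cannot extrapolate beyond the
ages they saw. The sex-interaction model tests whether a clock's age
trajectory differs between sexes:

    predicted ~ age + sex + age:sex        (OLS, Wald t on age:sex)

with female as the reference level (configurable) and an optional refit
excluding listed samples for outlier sensitivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .datamodel import ValidationError


@dataclass
class EvalReport:
    n: int
    pearson_r: float | None
    rmse: float
    age_min: float
    age_max: float
    subset_label: str = ""
    r_undefined_reason: str = ""

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "pearson_r": self.pearson_r,
            "rmse": self.rmse,
            "age_min": self.age_min,
            "age_max": self.age_max,
            "subset_label": self.subset_label,
            "r_undefined_reason": self.r_undefined_reason,
        }


@dataclass
class InteractionModelResult:
    """OLS fit of predicted ~ age + sex + age:sex."""

    n: int
    coef: dict[str, float]
    pvalues: dict[str, float]
    interaction_p: float
    reference_sex: str
    excluded: list[str] = field(default_factory=list)


def accuracy(pred_dpc: np.ndarray, true_dpc: np.ndarray, subset_label: str = "") -> EvalReport:
    """Pearson r and RMSE of predictions against chronological age."""
    pred = np.asarray(pred_dpc, dtype=float)
    true = np.asarray(true_dpc, dtype=float)
    if pred.shape != true.shape or pred.ndim != 1:
        raise ValidationError("pred/true must be 1-d vectors of equal length")
    if pred.size < 3:
        raise ValidationError("need at least 3 samples")
    if np.isnan(pred).any() or np.isnan(true).any():
        raise ValidationError("missing values in pred/true")
    rmse = float(np.sqrt(np.mean((pred - true) ** 2)))
    r: float | None
    reason = ""
    if np.ptp(pred) == 0 or np.ptp(true) == 0:
        r = None
        reason = "zero variance in " + ("predictions" if np.ptp(pred) == 0 else "ages")
    else:
        # n−1 sample covariance convention; scale-free either way
        r = float(np.corrcoef(pred, true)[0, 1])
    return EvalReport(
        n=pred.size,
        pearson_r=r,
        rmse=rmse,
        age_min=float(true.min()),
        age_max=float(true.max()),
        subset_label=subset_label,
        r_undefined_reason=reason,
    )


def range_restricted_accuracy(
    pred_dpc: np.ndarray, true_dpc: np.ndarray, max_dpc: float
) -> EvalReport:
    """Accuracy on the subset with chronological age ≤ ``max_dpc``."""
    pred = np.asarray(pred_dpc, dtype=float)
    true = np.asarray(true_dpc, dtype=float)
    if max_dpc <= np.min(true):
        raise ValidationError("max_dpc at or below the youngest sample")
    keep = true <= max_dpc
    if keep.sum() < 3:
        raise ValidationError(
            f"only {int(keep.sum())} samples at or below {max_dpc} dpc"
        )
    return accuracy(pred[keep], true[keep], subset_label=f"true_age<={max_dpc:g}dpc")


def sex_interaction_test(
    pred_dpc: np.ndarray,
    true_dpc: np.ndarray,
    sex: np.ndarray,
    sample_ids: np.ndarray | None = None,
    exclude: list[str] | None = None,
    reference_sex: str = "female",
) -> InteractionModelResult:
    """Wald t-test for an age × sex interaction on predicted age.

    ``sex`` holds "male"/"female" labels; samples named in ``exclude``
    (by id) are dropped before fitting — the outlier-sensitivity refit.
    Both sexes must retain ≥ 3 samples.
    """
    pred = np.asarray(pred_dpc, dtype=float)
    true = np.asarray(true_dpc, dtype=float)
    sex = np.asarray(sex, dtype=object)
    n = pred.size
    ids = (
        np.asarray(sample_ids, dtype=object)
        if sample_ids is not None
        else np.array([f"s{i}" for i in range(n)], dtype=object)
    )
    keep = np.ones(n, dtype=bool)
    excluded: list[str] = []
    if exclude:
        excl = set(exclude)
        keep = np.array([i not in excl for i in ids])
        excluded = [i for i in ids if i in excl]
    pred, true, sex_k = pred[keep], true[keep], sex[keep]
    levels = set(sex_k)
    other = {"female": "male", "male": "female"}[reference_sex]
    if reference_sex not in levels or other not in levels:
        raise ValidationError("both sexes must be present")
    for level in (reference_sex, other):
        if (sex_k == level).sum() < 3:
            raise ValidationError(f"fewer than 3 {level} samples")
    dummy = (sex_k == other).astype(float)  # 1 = non-reference sex
    X = np.column_stack([true, dummy, true * dummy])
    X = sm.add_constant(X)
    fit = sm.OLS(pred, X).fit()
    names = ["intercept", "age", f"sex[{other}]", f"age:sex[{other}]"]
    coef = dict(zip(names, map(float, fit.params)))
    pvals = dict(zip(names, map(float, fit.pvalues)))
    return InteractionModelResult(
        n=int(pred.size),
        coef=coef,
        pvalues=pvals,
        interaction_p=pvals[f"age:sex[{other}]"],
        reference_sex=reference_sex,
        excluded=excluded,
    )


def youngest_oldest_predicted(
    pred_dpc: np.ndarray, sample_ids: np.ndarray
) -> list[str]:
    """Ids of the samples with the youngest and oldest predicted ages —
    the exclusion set of the standard outlier-sensitivity refit."""
    pred = np.asarray(pred_dpc, dtype=float)
    ids = np.asarray(sample_ids, dtype=object)
    return [str(ids[int(np.argmin(pred))]), str(ids[int(np.argmax(pred))])]


def evaluation_table(predictions: pd.DataFrame, max_dpc: float | None = None) -> pd.DataFrame:
    """Per-clock accuracy summary from a long-format prediction table
    (needs columns clock_name, predicted_age_dpc, chronological_age_dpc)."""
    rows = []
    for clock, block in predictions.groupby("clock_name"):
        block = block.dropna(subset=["predicted_age_dpc", "chronological_age_dpc"])
        rep = accuracy(
            block["predicted_age_dpc"].to_numpy(),
            block["chronological_age_dpc"].to_numpy(),
        )
        row = {"clock_name": clock, **rep.to_dict()}
        if max_dpc is not None:
            restricted = range_restricted_accuracy(
                block["predicted_age_dpc"].to_numpy(),
                block["chronological_age_dpc"].to_numpy(),
                max_dpc,
            )
            row["pearson_r_restricted"] = restricted.pearson_r
            row["rmse_restricted"] = restricted.rmse
            row["n_restricted"] = restricted.n
        rows.append(row)
    return pd.DataFrame(rows)
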