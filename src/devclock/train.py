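"""Elastic-net training of epigenetic age clocks.

A clock is a penalized linear regression of chronological age (in days
post-conception) on genome-wide methylation beta values. The objective
minimized is

    (1/2n) Σᵢ (yᵢ − b₀ − xᵢᵀβ)²  +  λ [ α Σⱼ|βⱼ| + (1−α)/2 Σⱼβⱼ² ]

with mixing parameter α (1 = lasso, 0 = ridge; default 0.5) and
shrinkage λ selected by k-fold cross-validation over a log-spaced grid
descending from λ_max, the smallest λ at which every coefficient is
zero. Predictors are standardized internally by default and the
coefficients returned on the original beta scale, matching the behaviour
of the reference coordinate-descent implementation this mirrors.

The coordinate-descent solve itself is delegated to scikit-learn's
``ElasticNet``; path construction, fold assignment, λ selection and
model assembly are defined here. ``kkt_max_violation`` evaluates the
subgradient optimality conditions of the objective directly from the
data — a solver-independent correctness diagnostic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import ElasticNet

from .datamodel import BetaMatrix, ClockModel, OutputUnit, Transform, ValidationError

# guards against an infinite lambda_max when alpha -> 0 (standard path convention)
_ALPHA_FLOOR_FOR_LAMBDA_MAX = 1e-3


@dataclass
class TrainConfig:
    """Settings for a clock fit.

    alpha: elastic-net mixing in [0, 1] (1 = lasso, 0 = ridge).
    n_folds: cross-validation folds for λ selection.
    lambda_grid: optional descending positive grid; constructed from the
        data when omitted: 100 log-spaced values from λ_max down to
        λ_max·lambda_min_ratio (ratio 1e-4, or 1e-2 when probes outnumber
        samples — the usual path convention in that regime).
    lambda_rule: "min" picks the CV-MSE minimizer, "one_se" the largest λ
        within one standard error of it.
    standardize: scale predictors to unit variance internally.
    """

    alpha: float = 0.5
    n_folds: int = 10
    lambda_grid: np.ndarray | None = None
    lambda_rule: str = "min"
    seed: int = 0
    standardize: bool = True
    n_lambda: int = 100
    lambda_min_ratio: float | None = None  # 1e-4, or 1e-2 when p >= n
    tol: float = 1e-8
    max_iter: int = 100000

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValidationError("alpha must be in [0, 1]")
        if self.n_folds < 2:
            raise ValidationError("n_folds must be >= 2")
        if self.lambda_rule not in ("min", "one_se"):
            raise ValidationError(f"unknown lambda_rule {self.lambda_rule!r}")


@dataclass
class FitDiagnostics:
    """Cross-validation path and the internals of the returned solution."""

    lambda_grid: np.ndarray
    cv_mse_mean: np.ndarray
    cv_mse_se: np.ndarray
    selected_lambda: float
    n_nonzero: int
    seed: int
    fold_assignment: np.ndarray = field(repr=False, default=None)
    # solution on the internal (possibly standardized) scale, for the
    # KKT optimality diagnostic
    coef_internal: np.ndarray = field(repr=False, default=None)
    intercept_internal: float = 0.0
    x_mean: np.ndarray = field(repr=False, default=None)
    x_scale: np.ndarray = field(repr=False, default=None)


def impute_missing(betas: BetaMatrix, strategy: str = "probe_mean") -> BetaMatrix:
    """Fill missing betas per probe ('probe_mean') or refuse ('fail')."""
    if strategy == "fail":
        if np.isnan(betas.values).any():
            n = int(np.isnan(betas.values).sum())
            raise ValidationError(f"{n} missing beta value(s) with strategy='fail'")
        return betas
    if strategy != "probe_mean":
        raise ValueError(f"unknown strategy {strategy!r}")
    values = betas.values.copy()
    mask = np.isnan(values)
    if not mask.any():
        return BetaMatrix(betas.probe_ids, betas.sample_ids, values)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        means = np.nanmean(values, axis=1)
    empty = np.isnan(means)
    if empty.any():
        probe = betas.probe_ids[int(np.where(empty)[0][0])]
        raise ValidationError(f"probe {probe!r} is missing in every sample")
    values[mask] = np.broadcast_to(means[:, None], values.shape)[mask]
    return BetaMatrix(betas.probe_ids, betas.sample_ids, values)


def lambda_max(X: np.ndarray, y: np.ndarray, alpha: float) -> float:
    """Smallest λ at which the elastic-net solution is identically zero:
    max_j |x_jᵀ (y − ȳ)| / (n · max(α, floor))."""
    yc = y - y.mean()
    a = max(alpha, _ALPHA_FLOOR_FOR_LAMBDA_MAX)
    return float(np.abs(X.T @ yc).max() / (X.shape[0] * a))


def _make_lambda_grid(X: np.ndarray, y: np.ndarray, cfg: TrainConfig) -> np.ndarray:
    lmax = lambda_max(X, y, cfg.alpha)
    if lmax <= 0:
        raise ValidationError("degenerate design: lambda_max is 0")
    ratio = cfg.lambda_min_ratio
    if ratio is None:
        # shallower path in the p >= n regime, the usual path convention
        ratio = 1e-2 if X.shape[1] >= X.shape[0] else 1e-4
    return np.geomspace(lmax, lmax * ratio, cfg.n_lambda)

def deal_folds(n: int, n_folds: int, seed: int) -> np.ndarray:
    """Shuffle sample indices under ``seed`` and deal them round-robin to
    folds — deterministic and balanced."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    fold = np.empty(n, dtype=int)
    fold[perm] = np.arange(n) % n_folds
    return fold


def _fit_path(
    X: np.ndarray, y: np.ndarray, lambdas: np.ndarray, cfg: TrainConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Coefficients and intercepts along a descending λ path (warm starts)."""
    model = ElasticNet(
        alpha=lambdas[0],
        l1_ratio=cfg.alpha,
        fit_intercept=True,
        warm_start=True,
        tol=cfg.tol,
        max_iter=cfg.max_iter,
    )
    coefs = np.empty((lambdas.size, X.shape[1]))
    intercepts = np.empty(lambdas.size)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # harmless convergence chatter at tiny λ
        for k, lam in enumerate(lambdas):
            model.set_params(alpha=lam)
            model.fit(X, y)
            coefs[k] = model.coef_
            intercepts[k] = model.intercept_
    return coefs, intercepts


def fit_elastic_net_clock(
    betas: BetaMatrix,
    ages_dpc: np.ndarray,
    cfg: TrainConfig | None = None,
    name: str = "clock",
) -> tuple[ClockModel, FitDiagnostics]:
    """Fit an elastic-net age clock with cross-validated λ selection.

    ``betas`` must be complete (intersect or impute first); ``ages_dpc``
    is the per-sample chronological age in days post-conception, aligned
    with ``betas.sample_ids``. Returns the clock (intercept + nonzero
    coefficients on the original beta scale, output in dpc) and the CV
    diagnostics.
    """
    cfg = cfg or TrainConfig()
    y = np.asarray(ages_dpc, dtype=float)
    if np.isnan(betas.values).any():
        raise ValidationError("missing betas: run impute_missing or intersect first")
    X = betas.values.T.copy()  # samples × probes
    n, p = X.shape
    if y.shape != (n,):
        raise ValidationError(f"ages length {y.shape} != n_samples {n}")
    if np.ptp(y) == 0:
        raise ValidationError("constant age vector")
    if n < cfg.n_folds:
        raise ValidationError(f"n_samples={n} < n_folds={cfg.n_folds}")

    x_mean = X.mean(axis=0)
    if cfg.standardize:
        x_scale = X.std(axis=0)
        x_scale[x_scale == 0] = 1.0
    else:
        x_scale = np.ones(p)
    Xi = (X - x_mean) / x_scale

    lambdas = (
        np.asarray(cfg.lambda_grid, dtype=float)
        if cfg.lambda_grid is not None
        else _make_lambda_grid(Xi, y, cfg)
    )
    if lambdas.ndim != 1 or lambdas.size == 0 or (np.diff(lambdas) > 0).any():
        raise ValidationError("lambda_grid must be a descending positive vector")

    fold = deal_folds(n, cfg.n_folds, cfg.seed)
    fold_mse = np.empty((cfg.n_folds, lambdas.size))
    for f in range(cfg.n_folds):
        test = fold == f
        coefs, intercepts = _fit_path(Xi[~test], y[~test], lambdas, cfg)
        pred = Xi[test] @ coefs.T + intercepts  # n_test × n_lambda
        fold_mse[f] = ((pred - y[test, None]) ** 2).mean(axis=0)
    cv_mean = fold_mse.mean(axis=0)
    cv_se = fold_mse.std(axis=0, ddof=1) / np.sqrt(cfg.n_folds)

    i_min = int(np.argmin(cv_mean))
    if cfg.lambda_rule == "min":
        i_sel = i_min
    else:  # one_se: largest λ (grid is descending, so smallest index) within 1 SE
        ok = cv_mean <= cv_mean[i_min] + cv_se[i_min]
        i_sel = int(np.where(ok)[0][0])
    selected = float(lambdas[i_sel])

    coefs, intercepts = _fit_path(Xi, y, lambdas[: i_sel + 1], cfg)
    coef_i, b0_i = coefs[-1], float(intercepts[-1])

    coef_orig = coef_i / x_scale
    intercept = b0_i - float(coef_orig @ x_mean)
    nz = np.flatnonzero(coef_i)
    coefficients = {betas.probe_ids[j]: float(coef_orig[j]) for j in nz}
    diagnostics = FitDiagnostics(
        lambda_grid=lambdas,
        cv_mse_mean=cv_mean,
        cv_mse_se=cv_se,
        selected_lambda=selected,
        n_nonzero=int(nz.size),
        seed=cfg.seed,
        fold_assignment=fold,
        coef_internal=coef_i,
        intercept_internal=b0_i,
        x_mean=x_mean,
        x_scale=x_scale,
    )
    if nz.size == 0:
        warnings.warn(
            f"selected λ={selected:g} shrank every coefficient to zero; "
            "returning the intercept-only model (intercept = mean age)"
        )
    model = ClockModel(
        name=name,
        intercept=intercept,
        coefficients=coefficients,
        output_unit=OutputUnit.DPC,
        transform=Transform.IDENTITY,
        training_meta={
            "alpha": cfg.alpha,
            "lambda": selected,
            "n_train": n,
            "train_age_min_dpc": float(y.min()),
            "train_age_max_dpc": float(y.max()),
        },
    )
    return model, diagnostics


def fit_at_lambda(
    betas: BetaMatrix,
    ages_dpc: np.ndarray,
    lam: float,
    cfg: TrainConfig | None = None,
    name: str = "clock",
) -> tuple[float, np.ndarray]:
    """Single elastic-net solve at a fixed λ (no CV); returns
    (intercept, dense coefficient vector) on the scale actually optimized
    (unit-variance columns if ``cfg.standardize``, raw betas otherwise).
    Mainly a building block for optimality checks and closed-form
    comparisons."""
    cfg = cfg or TrainConfig()
    X = betas.values.T.copy()
    y = np.asarray(ages_dpc, dtype=float)
    x_scale = X.std(axis=0) if cfg.standardize else np.ones(X.shape[1])
    if cfg.standardize:
        x_scale[x_scale == 0] = 1.0
    Xi = X / x_scale
    model = ElasticNet(
        alpha=lam, l1_ratio=cfg.alpha, fit_intercept=True,
        tol=cfg.tol, max_iter=cfg.max_iter,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(Xi, y)
    return float(model.intercept_), model.coef_.copy()


def kkt_max_violation(
    X: np.ndarray,
    y: np.ndarray,
    intercept: float,
    coef: np.ndarray,
    lam: float,
    alpha: float,
) -> float:
    """Largest violation of the elastic-net optimality conditions.

    For the objective (1/2n)||y − b₀ − Xβ||² + λ(α||β||₁ + (1−α)/2||β||²),
    stationarity requires, with r = y − b₀ − Xβ and gⱼ = xⱼᵀr/n − λ(1−α)βⱼ:

        βⱼ ≠ 0 :  gⱼ = λα·sign(βⱼ)
        βⱼ = 0 :  |gⱼ| ≤ λα
        intercept: mean(r) = 0

    Returns the max absolute violation across all conditions; computed
    directly from the data, independent of any solver.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    coef = np.asarray(coef, dtype=float)
    n = X.shape[0]
    r = y - intercept - X @ coef
    g = X.T @ r / n - lam * (1 - alpha) * coef
    active = coef != 0
    viol = np.abs(np.mean(r))
    if active.any():
        viol = max(viol, float(np.abs(g[active] - lam * alpha * np.sign(coef[active])).max()))
    if (~active).any():
        viol = max(viol, float(max(0.0, np.abs(g[~active]).max() - lam * alpha)))
    return float(viol)
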