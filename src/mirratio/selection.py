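"""Differential-ratio testing, the two selection strategies, and the
L1-penalised logistic signature fit.

Two screening strategies, both gated on the Benjamini–Hochberg adjusted
Mann–Whitney p-value:

* strategy 1 — adjusted p <= alpha AND fold change > 2 or < 0.5;
* strategy 2 — adjusted p <= alpha AND control coefficient of variation < 0.5
  (no fold-change criterion).

Ratios passing either gate are candidate features for a LASSO logistic
signature.  Features are log2-transformed and standardized to unit variance
before the penalised fit (the penalty is scale-sensitive, and log2 ratios are
directly comparable to the qPCR ΔCt scale); reported coefficients are
back-transformed to the original feature scale.  The penalty strength is the
glmnet-style lambda in ``(1/n) * neg-log-likelihood + lambda * ||beta||_1``
with an unpenalised intercept, chosen by minimum mean cross-validated
binomial deviance over a logarithmic grid unless given explicitly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.multitest import multipletests

from .core_io import RatioMatrix, SignatureModel, ValidationError
from .ratio_features import control_cv, fold_change

logger = logging.getLogger(__name__)


@dataclass
class TestResult:
    statistic: float  # Mann-Whitney U for the first sample
    pvalue: float
    adj_pvalue: float | None = None


@dataclass
class LassoConfig:
    """Configuration of the penalised logistic fit.

    ``lambda_`` is the glmnet-convention penalty; "auto" selects it by
    cross-validated deviance.  ``log2_transform`` should be True for raw
    count ratios and False for ΔCt features (already on the log2 scale).
    """

    lambda_: float | str = "auto"
    folds: int = 5
    seed: int = 0
    standardize: bool = True
    log2_transform: bool = False
    n_grid: int = 30
    grid_ratio: float = 1e-3  # lambda_min / lambda_max on the search grid
    tol: float = 1e-6
    max_iter: int = 20000

    def __post_init__(self) -> None:
        if self.lambda_ != "auto" and self.lambda_ < 0:
            raise ValidationError("lambda must be >= 0 or 'auto'")
        if self.folds < 2:
            raise ValidationError("need at least 2 CV folds")


# ---------------------------------------------------------------------------
# Rank tests and multiplicity
# ---------------------------------------------------------------------------


def mann_whitney(x, y) -> TestResult:
    """Two-sided Mann–Whitney U test of two independent samples.

    Uses the exact null distribution when the combined sample size is at
    most 12 and there are no ties; otherwise the normal approximation with
    tie and continuity corrections.  When every value is identical across
    both groups the test is degenerate and p = 1 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    if np.all(combined == combined[0]):
        return TestResult(statistic=x.size * y.size / 2.0, pvalue=1.0)
    has_ties = np.unique(combined).size < combined.size
    if x.size + y.size <= 12 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return TestResult(statistic=float(res.statistic),
                      pvalue=min(1.0, float(res.pvalue)))


def mann_whitney_matrix(values: np.ndarray, labels: np.ndarray
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Mann–Whitney (cases vs controls) for a feature matrix.

    Vectorised asymptotic test with tie and continuity corrections; intended
    for the ratio screen where sample sizes are far beyond the exact regime.
    Returns (U, p) arrays, U counted for the case group.
    """
    cases = values[:, labels == 1]
    controls = values[:, labels == 0]
    if cases.shape[1] == 0 or controls.shape[1] == 0:
        raise ValidationError("both classes must be non-empty")
    res = stats.mannwhitneyu(cases, controls, alternative="two-sided",
                             method="asymptotic", use_continuity=True, axis=1)
    p = np.minimum(1.0, np.nan_to_num(res.pvalue, nan=1.0))
    return np.asarray(res.statistic, dtype=float), p


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (original order kept)."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Ratio screening strategies
# ---------------------------------------------------------------------------


def score_ratios(rm: RatioMatrix) -> pd.DataFrame:
    """Populate and return the per-ratio statistics table.

    Columns: U, p, adj_p, FC (median cases / median controls), control_CV.
    Stored on ``rm.stats`` (indexed by ratio id) so strategies and report
    writers share one computation.
    """
    u, p = mann_whitney_matrix(rm.values, rm.labels)
    stats_df = pd.DataFrame(
        {
            "U": u,
            "p": p,
            "adj_p": bh_adjust(p),
            "FC": fold_change(rm),
            "control_CV": control_cv(rm),
        },
        index=rm.names,
    )
    rm.stats = stats_df
    return stats_df


def strategy1(rm: RatioMatrix, alpha: float = 0.01,
              fc_hi: float = 2.0, fc_lo: float = 0.5) -> list[str]:
    """Ratios with adjusted p <= alpha and fold change > fc_hi or < fc_lo."""
    s = rm.stats if not rm.stats.empty else score_ratios(rm)
    mask = (s["adj_p"] <= alpha) & ((s["FC"] > fc_hi) | (s["FC"] < fc_lo))
    rm.stats["strategy1"] = mask
    return list(s.index[mask])


def strategy2(rm: RatioMatrix, alpha: float = 0.01,
              cv_max: float = 0.5) -> list[str]:
    """Ratios with adjusted p <= alpha and control CV < cv_max."""
    s = rm.stats if not rm.stats.empty else score_ratios(rm)
    mask = (s["adj_p"] <= alpha) & (s["control_CV"] < cv_max)
    rm.stats["strategy2"] = mask
    return list(s.index[mask])


# ---------------------------------------------------------------------------
# LASSO logistic signature
# ---------------------------------------------------------------------------


def _prepare(X: np.ndarray, cfg: LassoConfig):
    """Apply log2 transform / standardization; identify constant features."""
    X = np.asarray(X, dtype=float)
    if cfg.log2_transform:
        if np.any(X <= 0):
            raise ValidationError("log2 transform requires positive features")
        X = np.log2(X)
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=0)
    constant = sds == 0
    if cfg.standardize:
        scales = np.where(constant, 1.0, sds)
        Xs = (X - means) / scales
    else:
        means = np.zeros(X.shape[1])
        scales = np.ones(X.shape[1])
        Xs = X
    return Xs, means, scales, constant


def fit_lasso_logistic(X, y, cfg: LassoConfig | None = None,
                       feature_names: list[str] | None = None
                       ) -> SignatureModel:
    """Fit an L1-penalised logistic regression and return the signature.

    The objective is ``(1/n) * sum(bernoulli nll) + lambda * ||beta||_1``
    with the intercept unpenalised.  Coefficients are returned on the
    original (pre-standardization) feature scale; zero-coefficient features
    are reported as unselected.  With lambda = 0 the fit reduces to ordinary
    maximum-likelihood logistic regression.
    """
    cfg = cfg or LassoConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if not np.all(np.isfinite(X)):
        raise ValidationError("features must be finite")
    if set(np.unique(y)) - {0, 1}:
        raise ValidationError("labels must be binary 0/1")
    n, d = X.shape
    if feature_names is None:
        feature_names = [f"x{i}" for i in range(d)]

    Xs, means, scales, constant = _prepare(X, cfg)
    if constant.any():
        for i in np.flatnonzero(constant):
            logger.warning("constant feature %r dropped from LASSO fit",
                           feature_names[i])
    active = ~constant

    lam = cfg.lambda_
    if lam == "auto":
        lam, _, _ = select_lambda(X, y, cfg)

    coef_std = np.zeros(d)
    prev = float(np.clip(y.mean(), 1e-12, 1 - 1e-12))
    # KKT at the all-zero solution: it is exactly optimal when the penalty
    # reaches the largest score-equation gradient, so skip the solver there
    grad0 = np.abs(Xs[:, active].T @ (y - y.mean())) / n if active.any() else \
        np.zeros(0)
    fully_shrunk = lam != 0 and (grad0.size == 0 or lam >= grad0.max())
    if active.any() and not fully_shrunk:
        Xa = Xs[:, active]
        if lam == 0:
            clf = LogisticRegression(C=np.inf, solver="lbfgs",
                                     tol=cfg.tol, max_iter=cfg.max_iter)
        else:
            clf = LogisticRegression(l1_ratio=1.0, C=1.0 / (n * lam),
                                     solver="saga", tol=cfg.tol,
                                     max_iter=cfg.max_iter, random_state=0)
        clf.fit(Xa, y)
        if clf.n_iter_[0] >= cfg.max_iter:
            if lam == 0:
                raise ValidationError(
                    "unpenalised fit failed to converge (separable data?)")
            logger.warning("LASSO solver hit max_iter=%d", cfg.max_iter)
        coef_std[active] = clf.coef_[0]
        intercept_std = float(clf.intercept_[0])
    else:
        # intercept-only model (all features constant or fully shrunk)
        intercept_std = float(np.log(prev / (1 - prev)))

    # back-transform to the original feature scale
    coef = coef_std / scales
    intercept = intercept_std - float(np.sum(coef_std * means / scales))
    return SignatureModel(
        feature_names=list(feature_names),
        coefficients=coef,
        intercept=intercept,
        penalty=float(lam),
        standardize_means=means,
        standardize_scales=scales,
        log2_transform=cfg.log2_transform,
    )


def _binomial_deviance(p_hat: np.ndarray, y: np.ndarray) -> float:
    eps = 1e-12
    p = np.clip(p_hat, eps, 1 - eps)
    return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def lambda_grid(X, y, cfg: LassoConfig) -> np.ndarray:
    """Logarithmic penalty grid from the full-shrinkage point downward.

    lambda_max = max_j |x_j . (y - ybar)| / n on the standardized scale is
    the smallest penalty at which every coefficient is exactly zero.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    Xs, _, _, constant = _prepare(X, cfg)
    resid = y - y.mean()
    grad = np.abs(Xs[:, ~constant].T @ resid) / len(y)
    lam_max = float(grad.max()) if grad.size else 1.0
    lam_max = max(lam_max, 1e-8)
    return np.geomspace(lam_max, lam_max * cfg.grid_ratio, cfg.n_grid)


def select_lambda(X, y, cfg: LassoConfig
                  ) -> tuple[float, np.ndarray, np.ndarray]:
    """Choose lambda by minimum mean CV binomial deviance.

    Stratified fold assignment controlled by ``cfg.seed``.  The solver is
    warm-started down the descending grid within each fold (the glmnet
    pathwise strategy), so the search costs little more than one fit.
    Returns the chosen lambda together with the grid and per-lambda mean
    deviances for audit.  Ties (within machine precision) resolve to the
    larger lambda, i.e. the sparser model.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n1, n0 = int(y.sum()), int((1 - y).sum())
    if min(n1, n0) < cfg.folds:
        raise ValidationError(
            f"cannot stratify {cfg.folds} folds with class counts {n1}/{n0}")
    grid = lambda_grid(X, y, cfg)
    skf = StratifiedKFold(n_splits=cfg.folds, shuffle=True,
                          random_state=cfg.seed)
    deviances = np.zeros((cfg.folds, len(grid)))
    path_tol = max(cfg.tol, 1e-4)
    for k, (tr, te) in enumerate(skf.split(X, y)):
        Xs_tr, means, scales, constant = _prepare(X[tr], cfg)
        Xa_tr = Xs_tr[:, ~constant]
        # standardize the held-out fold with the training parameters
        Xte = np.asarray(X[te], dtype=float)
        if cfg.log2_transform:
            Xte = np.log2(Xte)
        Xa_te = ((Xte - means) / scales)[:, ~constant]
        n_tr = len(tr)
        # liblinear is much faster than saga on these small dense problems;
        # its slight intercept penalisation (damped by intercept_scaling) is
        # immaterial for ranking lambdas.  Final fits use saga on the clean
        # objective.
        clf = LogisticRegression(l1_ratio=1.0, C=1.0, solver="liblinear",
                                 tol=path_tol, intercept_scaling=100.0,
                                 max_iter=min(cfg.max_iter, 1000),
                                 random_state=0)
        for g, lam in enumerate(grid):
            clf.C = 1.0 / (n_tr * lam)
            clf.fit(Xa_tr, y[tr])
            p_hat = clf.predict_proba(Xa_te)[:, 1]
            deviances[k, g] = _binomial_deviance(p_hat, y[te])
    mean_dev = deviances.mean(axis=0)
    best = int(np.argmin(mean_dev))  # grid is descending: first min = largest lambda
    return float(grid[best]), grid, mean_dev


def n_nonzero_path(X, y, cfg: LassoConfig, grid: np.ndarray) -> list[int]:
    """Number of selected features at each penalty on a fixed grid."""
    counts = []
    for lam in grid:
        fit_cfg = LassoConfig(**{**cfg.__dict__, "lambda_": float(lam)})
        counts.append(len(fit_lasso_logistic(X, y, fit_cfg).selected))
    return counts
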