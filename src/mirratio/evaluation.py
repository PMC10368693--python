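"""Model assessment: cross-validated calibration and discrimination metrics,
DeLong AUC inference, Youden cut-offs, univariate odds ratios and the
Cochran–Armitage trend test.

Calibration is quantified on the logit scale by refitting the outcome on the
logit of the predicted probability: the calibration intercept is the
intercept of that refit with the slope fixed at 1 (ideal value 0,
"calibration-in-the-large"); the calibration slope — Cox's measure of
spread — leaves the slope free (ideal value 1; below 1 means predictions
too extreme, above 1 too moderate).  Overall accuracy is the scaled Brier
score: the mean squared error of the predictions divided by that of the
uninformative constant-prevalence predictor, so 0 is perfect and 1 matches
the null model.  Discrimination is the AUC with DeLong confidence intervals,
and correlated AUCs are compared with the paired DeLong test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .core_io import SignatureModel, ValidationError
from .selection import LassoConfig, fit_lasso_logistic

logger = logging.getLogger(__name__)


@dataclass
class CvPerformance:
    """Fold-averaged CV metrics, with per-fold values retained."""

    calibration_intercept: float
    calibration_slope: float
    scaled_brier: float
    auc: float
    per_fold: dict[str, list[float]]


@dataclass
class ORResult:
    oddsratio: float
    ci_low: float
    ci_high: float
    pvalue: float
    note: str = ""


@dataclass
class RocComparison:
    auc1: float
    auc2: float
    z: float
    pvalue: float


@dataclass
class CutoffResult:
    cutoff: float
    sensitivity: float
    specificity: float
    youden_j: float


def _logit(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValidationError("predicted probabilities must lie in (0, 1)")
    return np.log(p / (1 - p))


def calibration_intercept(p_hat, y) -> float:
    """Intercept of logit P(y=1) = a + logit(p_hat), slope fixed at 1.

    Fitted as a binomial GLM with logit(p_hat) as a fixed offset; a = 0 when
    observed outcomes agree with predicted risk on average.
    """
    y = np.asarray(y, dtype=float)
    offset = _logit(p_hat)
    model = sm.GLM(y, np.ones((len(y), 1)), family=sm.families.Binomial(),
                   offset=offset)
    return float(model.fit().params[0])


def calibration_slope(p_hat, y) -> float:
    """Slope b of logit P(y=1) = a + b*logit(p_hat), both free (Cox)."""
    y = np.asarray(y, dtype=float)
    lp = _logit(p_hat)
    if np.all(lp == lp[0]):
        raise ValidationError("calibration slope undefined for constant predictions")
    X = sm.add_constant(lp)
    fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    return float(fit.params[1])


def scaled_brier(p_hat, y) -> float:
    """Brier score scaled by the null (constant-prevalence) Brier score.

    0 is a perfect prediction, 1 matches the uninformative predictor.  The
    complementary index of prediction accuracy, IPA = 1 - scaled Brier, can
    be derived directly from the returned value.
    """
    p_hat = np.asarray(p_hat, dtype=float)
    y = np.asarray(y, dtype=float)
    prev = y.mean()
    if prev in (0.0, 1.0):
        raise ValidationError("scaled Brier needs both classes present")
    brier = np.mean((p_hat - y) ** 2)
    brier_null = np.mean((prev - y) ** 2)
    return float(brier / brier_null)


# ---------------------------------------------------------------------------
# AUC and DeLong inference
# ---------------------------------------------------------------------------


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_components(scores: np.ndarray, y: np.ndarray):
    """Structural components V10 (per case) and V01 (per control)."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValidationError("AUC needs both classes present")
    all_ranks = _midrank(np.concatenate([pos, neg]))
    pos_ranks = _midrank(pos)
    neg_ranks = _midrank(neg)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (all_ranks[:m] - pos_ranks) / n          # per-case component
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m    # per-control component
    return float(auc), v10, v01


def auc(p_hat, y, ci: bool = True
        ) -> tuple[float, tuple[float, float]] | float:
    """AUC with ties counted 1/2, plus a DeLong 95% CI when ``ci``.

    Identical to the Mann–Whitney U statistic divided by n1*n0.
    """
    scores = np.asarray(p_hat, dtype=float)
    y = np.asarray(y, dtype=int)
    a, v10, v01 = _delong_components(scores, y)
    if not ci:
        return a
    m, n = len(v10), len(v01)
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + \
          (np.var(v01, ddof=1) / n if n > 1 else 0.0)
    half = 1.959963984540054 * np.sqrt(var)
    return a, (max(0.0, a - half), min(1.0, a + half))


def delong_paired_test(p1, p2, y) -> RocComparison:
    """Paired DeLong test for the difference of two correlated AUCs.

    Both score vectors must be computed on the same samples.  Z is for
    auc1 - auc2; identical score vectors give Z = 0, p = 1.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    y = np.asarray(y, dtype=int)
    if p1.shape != p2.shape or p1.shape != y.shape:
        raise ValidationError("paired test needs aligned score/label vectors")
    a1, v10_1, v01_1 = _delong_components(p1, y)
    a2, v10_2, v01_2 = _delong_components(p2, y)
    if np.array_equal(p1, p2):
        return RocComparison(a1, a2, 0.0, 1.0)
    m, n = len(v10_1), len(v01_1)
    s10 = np.cov(np.vstack([v10_1, v10_2]), ddof=1)
    s01 = np.cov(np.vstack([v01_1, v01_2]), ddof=1)
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var_diff <= 0:
        return RocComparison(a1, a2, 0.0, 1.0)
    z = (a1 - a2) / np.sqrt(var_diff)
    p = 2 * stats.norm.sf(abs(z))
    return RocComparison(a1, a2, float(z), float(p))


def youden_cutoff(p_hat, y) -> CutoffResult:
    """Cut-off maximising Youden's J = sensitivity + specificity - 1.

    Candidate cut-offs are midpoints between adjacent sorted unique
    predictions (plus the extremes); ties in J break toward the larger
    cut-off (higher specificity).  A sample is classified positive when its
    prediction exceeds the cut-off.
    """
    scores = np.asarray(p_hat, dtype=float)
    y = np.asarray(y, dtype=int)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValidationError("Youden cut-off needs both classes present")
    uniq = np.unique(scores)
    mids = (uniq[:-1] + uniq[1:]) / 2 if len(uniq) > 1 else np.array([])
    candidates = np.concatenate([[uniq[0] - 1e-12], mids, [uniq[-1] + 1e-12]])
    best = None
    for c in candidates:  # ascending: later (larger) cutoff wins ties
        pred = scores > c
        sens = float((pred & (y == 1)).sum() / n1)
        spec = float((~pred & (y == 0)).sum() / n0)
        j = sens + spec - 1
        if best is None or j >= best.youden_j:
            best = CutoffResult(float(c), sens, spec, float(j))
    return best


# ---------------------------------------------------------------------------
# Univariate associations
# ---------------------------------------------------------------------------


def or_from_2x2(a: int, b: int, c: int, d: int) -> ORResult:
    """Odds ratio from a 2x2 table with a Wald CI on the log scale.

    Layout: a = exposed cases, b = reference cases, c = exposed controls,
    d = reference controls; OR = (a*d)/(b*c).  A zero cell is reported with
    a note, never silently continuity-corrected.
    """
    note = ""
    if 0 in (a, b, c, d):
        note = "zero cell: OR/CI degenerate, no continuity correction applied"
        logger.warning(note)
    orr = (a * d) / (b * c) if b * c > 0 else np.inf
    if 0 in (a, b, c, d):
        return ORResult(orr, 0.0, np.inf, 1.0, note)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = np.log(orr)
    z = log_or / se
    return ORResult(
        oddsratio=float(orr),
        ci_low=float(np.exp(log_or - 1.959963984540054 * se)),
        ci_high=float(np.exp(log_or + 1.959963984540054 * se)),
        pvalue=float(2 * stats.norm.sf(abs(z))),
        note=note,
    )


def univariate_or(exposure, y, reference=None) -> dict | ORResult:
    """Univariate logistic odds ratio(s) for one exposure.

    Categorical exposure (``reference`` level declared, default the smallest
    level): one ORResult per non-reference level versus the reference,
    computed as the 2x2 cross-product ratio with a Wald CI.  Continuous
    exposure (``reference=None`` and floating values): a single per-unit
    ORResult from a maximum-likelihood logistic fit.
    """
    exposure = np.asarray(exposure)
    y = np.asarray(y, dtype=int)
    levels = np.unique(exposure)
    categorical = reference is not None or (
        exposure.dtype.kind in "iUOb" and len(levels) <= 10
    )
    if not categorical:
        x = exposure.astype(float)
        X = sm.add_constant(x)
        fit = sm.Logit(y, X).fit(disp=0)
        beta, se = fit.params[1], fit.bse[1]
        return ORResult(
            float(np.exp(beta)),
            float(np.exp(beta - 1.959963984540054 * se)),
            float(np.exp(beta + 1.959963984540054 * se)),
            float(fit.pvalues[1]),
        )
    ref = levels[0] if reference is None else reference
    if ref not in levels:
        raise ValidationError(f"reference level {ref!r} not present")
    out: dict = {}
    b = int(((exposure == ref) & (y == 1)).sum())   # reference cases
    d = int(((exposure == ref) & (y == 0)).sum())   # reference controls
    for lev in levels:
        if lev == ref:
            continue
        a = int(((exposure == lev) & (y == 1)).sum())
        c = int(((exposure == lev) & (y == 0)).sum())
        out[lev] = or_from_2x2(a, b, c, d)
    return out


def cochran_armitage(ordinal_exposure, y, scores=None) -> float:
    """Two-sided Cochran–Armitage test for linear trend in proportions.

    Levels receive equally spaced integer scores unless ``scores`` overrides
    them.  The statistic is the usual chi-square-for-trend z-score.
    """
    x = np.asarray(ordinal_exposure)
    y = np.asarray(y, dtype=int)
    levels = np.unique(x)
    if len(levels) < 2:
        raise ValidationError("trend test needs at least 2 exposure levels")
    if scores is None:
        scores = np.arange(len(levels), dtype=float)
    scores = np.asarray(scores, dtype=float)
    n_i = np.array([(x == lev).sum() for lev in levels], dtype=float)
    r_i = np.array([((x == lev) & (y == 1)).sum() for lev in levels],
                   dtype=float)
    N = n_i.sum()
    pbar = r_i.sum() / N
    num = np.sum(scores * (r_i - n_i * pbar))
    var = pbar * (1 - pbar) * (
        np.sum(scores ** 2 * n_i) - np.sum(scores * n_i) ** 2 / N
    )
    if var <= 0:
        return 1.0
    z = num / np.sqrt(var)
    return float(2 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------


def _fold_metrics(p_hat: np.ndarray, y_te: np.ndarray) -> dict[str, float]:
    out: dict[str, float] = {}
    if len(np.unique(y_te)) < 2:
        raise ValidationError(
            "evaluation fold contains a single class; re-stratify")
    if np.all(p_hat == p_hat[0]):
        # intercept-only prediction: no discrimination, slope undefined
        out["auc"] = 0.5
        out["calibration_slope"] = np.nan
    else:
        out["auc"] = auc(p_hat, y_te, ci=False)
        out["calibration_slope"] = calibration_slope(p_hat, y_te)
    out["calibration_intercept"] = calibration_intercept(p_hat, y_te)
    out["scaled_brier"] = scaled_brier(p_hat, y_te)
    return out


def kfold_cv(X, y, cfg: LassoConfig | None = None, k: int = 5,
             seed: int = 0, fit_fn=None) -> CvPerformance:
    """Stratified k-fold CV of the penalised logistic signature.

    For each fold the model is fitted on the remaining k-1 folds (by
    ``fit_fn(X_train, y_train) -> callable(X_test) -> p_hat`` when given,
    otherwise a LASSO fit under ``cfg``) and the four performance measures
    are computed on the held-out fold; fold values are averaged (NaN slopes
    from degenerate constant-prediction folds are excluded from the mean).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    cfg = cfg or LassoConfig()
    if fit_fn is None:
        def fit_fn(X_tr, y_tr, _cfg=cfg):
            model = fit_lasso_logistic(X_tr, y_tr, _cfg)
            return model.predict_proba
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    per_fold: dict[str, list[float]] = {
        "calibration_intercept": [], "calibration_slope": [],
        "scaled_brier": [], "auc": [],
    }
    for tr, te in skf.split(X, y):
        predict = fit_fn(X[tr], y[tr])
        p_hat = np.clip(np.asarray(predict(X[te]), dtype=float),
                        1e-12, 1 - 1e-12)
        for name, value in _fold_metrics(p_hat, y[te]).items():
            per_fold[name].append(value)
    slopes = [s for s in per_fold["calibration_slope"] if not np.isnan(s)]
    return CvPerformance(
        calibration_intercept=float(np.mean(per_fold["calibration_intercept"])),
        calibration_slope=float(np.mean(slopes)) if slopes else float("nan"),
        scaled_brier=float(np.mean(per_fold["scaled_brier"])),
        auc=float(np.mean(per_fold["auc"])),
        per_fold=per_fold,
    )


# ---------------------------------------------------------------------------
# Combined model
# ---------------------------------------------------------------------------

COVARIATE_COLUMNS = ["tabar", "wcrf", "bmi_class", "menopause", "bmi_x_menopause"]


def build_covariate_design(covariates) -> np.ndarray:
    """Design columns for the combined model, in COVARIATE_COLUMNS order.

    Tabar density class and WCRF score enter as continuous scores; BMI as a
    >= 30 indicator; menopausal status as an indicator; plus their product.
    """
    tabar = np.asarray(covariates["tabar"], dtype=float)
    wcrf = np.asarray(covariates["wcrf"], dtype=float)
    bmi_class = np.asarray(covariates["bmi_class"], dtype=float)
    menopause = np.asarray(covariates["menopause"], dtype=float)
    return np.column_stack([tabar, wcrf, bmi_class, menopause,
                            bmi_class * menopause])


def fit_combined_model(ratio_features, ratio_names, covariates, y,
                       cfg: LassoConfig | None = None) -> SignatureModel:
    """LASSO fit of ratio features together with the clinical covariates.

    Rows with any missing covariate are dropped (complete-case analysis; the
    count of dropped rows is logged).  Ratio features are used as given
    (ΔCt values are already on the log2 scale), covariates as coded by
    :func:`build_covariate_design`.
    """
    cfg = cfg or LassoConfig()
    ratio_features = np.asarray(ratio_features, dtype=float)
    y = np.asarray(y, dtype=int)
    cov = build_covariate_design(covariates)
    if np.all(cov < 0, axis=0).any():
        j = int(np.flatnonzero(np.all(cov < 0, axis=0))[0])
        raise ValidationError(f"covariate {COVARIATE_COLUMNS[j]!r} is all-missing")
    complete = ~np.any(cov < 0, axis=1)  # MISSING sentinel is negative
    dropped = int((~complete).sum())
    if dropped:
        logger.warning("combined model: %d incomplete rows dropped", dropped)
    X = np.hstack([ratio_features, cov])[complete]
    names = list(ratio_names) + COVARIATE_COLUMNS
    return fit_lasso_logistic(X, y[complete], cfg, feature_names=names)
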