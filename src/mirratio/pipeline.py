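"""End-to-end orchestration of the study flow: discovery on sequencing
counts, cross-platform qPCR validation, and combined clinical modelling.

Discovery: count filter -> profile deduplication -> all-pairs ratios ->
Mann-Whitney/BH screen -> strategy 1 and 2 gates -> per-strategy LASSO
signature -> stratified 5-fold CV of calibration and discrimination.  By
default the screen and the LASSO are re-run inside every CV training fold,
so the reported CV metrics are free of selection-induced optimism; the
selection-then-CV variant is available for comparison.

Validation: triplicate QC -> per-sample ΔCt ratios for the assay panel
mapped from the sequencing-selected ratios -> per-ratio univariate OR and
AUC -> Spearman concordance against the sequencing log2 ratios.

Combined stage: three LASSO models (ratios only / ratios + clinical
covariates / covariates only) with AUC, Youden cut-off and pairwise DeLong
comparisons, all on the complete-case sample set shared by the models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import CountMatrix, CtPlate, RatioMatrix
from .evaluation import (CvPerformance, auc, delong_paired_test, kfold_cv,
                         univariate_or, youden_cutoff)
from .qpcr import (cross_platform_concordance, delta_ct_table,
                   map_sequencing_ratios_to_assays)
from .ratio_features import (build_ratio_matrix, deduplicate_profiles,
                             filter_mirs)
from .selection import (LassoConfig, bh_adjust, fit_lasso_logistic,
                        mann_whitney_matrix, score_ratios, strategy1,
                        strategy2)

logger = logging.getLogger(__name__)


@dataclass
class PipelineParams:
    """Stage parameters; defaults are the study's stated values."""

    min_mean_count: float = 20.0
    pseudocount: float = 1.0
    dedup_tolerance: float = 0.0
    manual_exclusions: tuple[str, ...] = ()
    alpha: float = 0.01
    fc_hi: float = 2.0
    fc_lo: float = 0.5
    cv_max: float = 0.5
    folds: int = 5
    seed: int = 0
    lasso_lambda: float | str = "auto"
    refit_selection_in_cv: bool = True
    concordance_alpha: float = 0.01

    def lasso_cfg(self, log2_transform: bool) -> LassoConfig:
        return LassoConfig(lambda_=self.lasso_lambda, folds=self.folds,
                           seed=self.seed, log2_transform=log2_transform,
                           tol=1e-4)


@dataclass
class DiscoveryResult:
    ratio_matrix: RatioMatrix
    dedup_map: dict[str, str]
    strategy_selected: dict[str, list[str]]
    lasso_selected: dict[str, list[str]]
    cv: dict[str, CvPerformance]
    dimensions: dict[str, int] = field(default_factory=dict)


def _screen_arrays(values: np.ndarray, labels: np.ndarray,
                   params: PipelineParams
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Strategy masks straight from a (ratios x samples) array.

    Same statistics as :func:`mirratio.selection.score_ratios`, kept
    array-level so the per-fold re-screen inside CV stays cheap.
    """
    _, p = mann_whitney_matrix(values, labels)
    adj = bh_adjust(p)
    cases = labels == 1
    controls = labels == 0
    fc = (np.median(values[:, cases], axis=1)
          / np.median(values[:, controls], axis=1))
    ctrl = values[:, controls]
    cv = ctrl.std(axis=1, ddof=1) / ctrl.mean(axis=1)
    sig = adj <= params.alpha
    s1 = sig & ((fc > params.fc_hi) | (fc < params.fc_lo))
    s2 = sig & (cv < params.cv_max)
    return s1, s2


def _selection_aware_fit_fn(values: np.ndarray, params: PipelineParams,
                            which: str):
    """CV fit function that re-runs screen + LASSO on each training fold."""

    def fit(X_tr: np.ndarray, y_tr: np.ndarray):
        s1, s2 = _screen_arrays(X_tr.T, y_tr, params)
        mask = s1 if which == "strategy1" else s2
        if not mask.any():
            prev = float(np.clip(y_tr.mean(), 1e-6, 1 - 1e-6))
            return lambda X_te: np.full(len(X_te), prev)
        idx = np.flatnonzero(mask)
        model = fit_lasso_logistic(X_tr[:, idx], y_tr,
                                   params.lasso_cfg(log2_transform=True))
        return lambda X_te: model.predict_proba(X_te[:, idx])

    return fit


def run_discovery(cm: CountMatrix, params: PipelineParams | None = None,
                  compute_cv: bool = True) -> DiscoveryResult:
    """Full discovery stage on a count matrix with labels.

    ``compute_cv=False`` skips the fold-wise performance assessment and
    returns only the screening and signature-selection results.
    """
    params = params or PipelineParams()
    dims = {"samples": cm.n_samples, "mirs_detected": cm.n_mirs}
    filtered = filter_mirs(cm, params.min_mean_count)
    dims["mirs_filtered"] = filtered.n_mirs
    dedup, dmap = deduplicate_profiles(filtered, params.dedup_tolerance)
    dims["mirs_unique"] = dedup.n_mirs
    rm = build_ratio_matrix(dedup, params.pseudocount)
    dims["ratios"] = rm.n_ratios
    logger.info("discovery dimensions: %s", dims)

    score_ratios(rm)
    selected = {
        "strategy1": strategy1(rm, params.alpha, params.fc_hi, params.fc_lo),
        "strategy2": strategy2(rm, params.alpha, params.cv_max),
    }
    X = rm.values.T  # samples x ratios, raw scale
    y = rm.labels
    names = rm.names
    name_idx = {nm: i for i, nm in enumerate(names)}

    lasso_selected: dict[str, list[str]] = {}
    cv_results: dict[str, CvPerformance] = {}
    for strat, ratio_ids in selected.items():
        if ratio_ids:
            idx = [name_idx[r] for r in ratio_ids]
            model = fit_lasso_logistic(
                X[:, idx], y, params.lasso_cfg(log2_transform=True),
                feature_names=ratio_ids)
            lasso_selected[strat] = model.selected
        else:
            lasso_selected[strat] = []
        if not compute_cv:
            continue
        if params.refit_selection_in_cv:
            fit_fn = _selection_aware_fit_fn(rm.values, params, strat)
            cv_results[strat] = kfold_cv(X, y, k=params.folds,
                                         seed=params.seed, fit_fn=fit_fn)
        else:
            if ratio_ids:
                idx = [name_idx[r] for r in ratio_ids]
                cv_results[strat] = kfold_cv(
                    X[:, idx], y, params.lasso_cfg(log2_transform=True),
                    k=params.folds, seed=params.seed)
            else:
                fit_fn = _selection_aware_fit_fn(rm.values, params, strat)
                cv_results[strat] = kfold_cv(X, y, k=params.folds,
                                             seed=params.seed, fit_fn=fit_fn)
    return DiscoveryResult(rm, dmap, selected, lasso_selected, cv_results,
                           dims)


@dataclass
class ValidationResult:
    assay_ratios: list[str]
    assay_mirs: set[str]
    delta_ct: pd.DataFrame            # samples x assay ratios
    univariate: pd.DataFrame          # OR, CI, p, AUC per ratio
    concordance: pd.DataFrame


def run_validation(plates: list[CtPlate], selected_ratios: list[str],
                   rm: RatioMatrix, labels: pd.Series,
                   params: PipelineParams | None = None) -> ValidationResult:
    """Cross-platform validation of the sequencing-selected ratios.

    ``labels`` is indexed by sample id and covers the qPCR samples (which
    may be a subset of the sequencing cohort).
    """
    params = params or PipelineParams()
    assay_ratios, mirs = map_sequencing_ratios_to_assays(
        selected_ratios, params.manual_exclusions)
    logger.info("validation: %d sequencing ratios -> %d assay ratios over "
                "%d unique miRs", len(selected_ratios), len(assay_ratios),
                len(mirs))
    dct = delta_ct_table(plates, assay_ratios)
    y = labels.reindex(dct.index).to_numpy(dtype=int)

    records = []
    for rid in assay_ratios:
        vals = dct[rid].to_numpy(dtype=float)
        orr = univariate_or(vals, y)
        a, (lo, hi) = auc(vals, y)
        a = max(a, 0.0)
        records.append({
            "ratio_id": rid, "OR": orr.oddsratio,
            "or_ci_low": orr.ci_low, "or_ci_high": orr.ci_high,
            "p": orr.pvalue, "auc": a,
        })
    uni = pd.DataFrame(records).set_index("ratio_id")

    # sequencing log2 ratios under the assay ids, aligned orientation
    from .qpcr import collapse_ratio_id
    needed = set(assay_ratios)
    seq_cols = {}
    excl = set(params.manual_exclusions)
    for i, seq_id in enumerate(rm.names):
        if seq_id in excl:
            continue
        assay_id = collapse_ratio_id(seq_id)
        if assay_id in needed and assay_id not in seq_cols:
            seq_cols[assay_id] = np.log2(rm.values[i])
    seq_df = pd.DataFrame(seq_cols, index=rm.sample_ids)
    conc = cross_platform_concordance(seq_df, dct[list(seq_cols)],
                                      params.concordance_alpha)
    return ValidationResult(assay_ratios, mirs, dct, uni, conc)


def run_combined(dct: pd.DataFrame, covariates: pd.DataFrame,
                 labels: pd.Series, params: PipelineParams | None = None
                 ) -> dict:
    """Fit and compare the three models on the shared complete-case set."""
    from .evaluation import (COVARIATE_COLUMNS, build_covariate_design,
                             fit_combined_model)

    params = params or PipelineParams()
    shared = dct.index.intersection(covariates.index)
    cov = covariates.loc[shared]
    design = build_covariate_design(cov)
    complete = ~np.any(design < 0, axis=1)
    idx = shared[complete]
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.warning("combined stage: %d incomplete-covariate samples "
                       "dropped", n_dropped)
    X_ratio = dct.loc[idx].to_numpy(dtype=float)
    cov = cov.loc[idx]
    y = labels.reindex(idx).to_numpy(dtype=int)
    ratio_names = list(dct.columns)
    cfg = params.lasso_cfg(log2_transform=False)

    m_ratio = fit_lasso_logistic(X_ratio, y, cfg, feature_names=ratio_names)
    m_comb = fit_combined_model(X_ratio, ratio_names, cov, y, cfg)
    m_nonmol = fit_lasso_logistic(build_covariate_design(cov), y, cfg,
                                  feature_names=list(COVARIATE_COLUMNS))

    X_comb = np.hstack([X_ratio, build_covariate_design(cov)])
    preds = {
        "ratios": m_ratio.predict_proba(X_ratio),
        "combined": m_comb.predict_proba(X_comb),
        "nonmolecular": m_nonmol.predict_proba(build_covariate_design(cov)),
    }
    models = {"ratios": m_ratio, "combined": m_comb,
              "nonmolecular": m_nonmol}
    out: dict = {"n_samples": int(len(y)), "n_dropped": n_dropped}
    for name, p_hat in preds.items():
        a, ci = auc(p_hat, y)
        cut = youden_cutoff(p_hat, y)
        out[name] = {
            "selected": models[name].selected,
            "coefficients": dict(zip(models[name].feature_names,
                                     np.round(models[name].coefficients, 6))),
            "intercept": models[name].intercept,
            "auc": a, "auc_ci": list(ci),
            "cutoff": cut.cutoff, "sensitivity": cut.sensitivity,
            "specificity": cut.specificity, "youden_j": cut.youden_j,
        }
    out["delong"] = {}
    pairs = [("combined", "nonmolecular"), ("combined", "ratios"),
             ("ratios", "nonmolecular")]
    for a_name, b_name in pairs:
        cmp_res = delong_paired_test(preds[a_name], preds[b_name], y)
        out["delong"][f"{a_name}_vs_{b_name}"] = {
            "auc1": cmp_res.auc1, "auc2": cmp_res.auc2,
            "Z": cmp_res.z, "p": cmp_res.pvalue,
        }
    return out
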