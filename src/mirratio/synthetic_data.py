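"""Synthetic nested case–control cohorts with the statistical structure the
analysis assumes, so every pipeline stage runs with no external data.

The generator mirrors a two-platform circulating-miRNA screening study:

* a latent per-sample miR abundance layer (gamma-distributed biological
  variation around per-miR baseline means, overdispersion configurable);
* small-RNA-seq counts drawn as Poisson around the latent abundance times a
  log-normal per-sample library-size factor — a gamma-Poisson mixture, i.e.
  negative-binomial counts.  The library factor multiplies every count in a
  sample and therefore cancels exactly in every within-sample ratio;
* RT-qPCR triplicates from the same latent layer through a linear Ct model,
  Ct = intercept − slope·log2(abundance) + noise, with non-detects above a
  threshold and occasional injected outlier replicates;
* covariates (BMI class, menopausal status, WCRF lifestyle score, ordinal
  breast-density classes), Hardy–Weinberg SNP dosages with a weighted PRS,
  and case/control labels from a logistic model with configurable log-odds
  effects, sampled case–control style to hit the requested group sizes.

Differential signal is injected at the miR level: the numerator of each
chosen pair has its latent abundance shifted by ``effect_size_log2`` in
cases only, creating true differential ratios while marginal count
distributions stay realistic.  Ground truth (injected ratio ids, effects)
travels with the cohort for recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import (CASE, CONTROL, CountMatrix, CtPlate, ValidationError,
                      write_count_matrix)
from .ratio_features import canonical_pair

_TABAR_PROBS = (0.33, 0.38, 0.09, 0.20)  # ordinal classes 1..4 (IV-V grouped)
_BIRADS_PROBS = (0.32, 0.47, 0.21)       # ordinal classes 1..3 (3-4 grouped)


@dataclass
class GeneratorConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults emulate a screening cohort of 65 cases and 66 controls with a
    modest miR panel.  ``seed`` is mandatory: the same seed always yields a
    bit-identical cohort.
    """

    seed: int
    n_cases: int = 65
    n_controls: int = 66
    n_mirs: int = 50
    n_differential_pairs: int = 5
    effect_size_log2: float = 1.5       # shift of the numerator miR in cases
    dispersion: float = 0.1             # biological CV^2 of latent abundance
    libsize_log_sd: float = 0.5         # sd of log library-size factor
    n_duplicate_pairs: int = 2          # exact-copy miR rows to inject
    base_log2_mean_range: tuple[float, float] = (3.0, 12.0)
    # Ct model
    ct_slope: float = 1.0
    ct_intercept: float = 36.0
    ct_noise_sd: float = 0.25
    nondetect_ct: float = 40.0
    outlier_rate: float = 0.02          # per-triplicate outlier probability
    outlier_shift: float = 6.0
    # covariate log-odds effects
    bmi_class_log_or: float = 0.7
    menopause_log_or: float = 0.0
    interaction_log_or: float = 0.0
    wcrf_log_or: float = -0.39
    tabar_trend_log_or: float = 0.5
    prs_log_or: float = 0.0
    prevalence: float = 0.3             # sampling prevalence of the source pool
    # genotyping
    n_snps: int = 77
    maf_range: tuple[float, float] = (0.05, 0.5)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("generator seed is mandatory")
        for name in ("n_cases", "n_controls", "n_mirs"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if 2 * self.n_differential_pairs + 1 > self.n_mirs:
            raise ValidationError("too many differential pairs for n_mirs")


@dataclass
class SyntheticCohort:
    counts: CountMatrix
    latent: pd.DataFrame            # samples x miRs latent abundance
    plates: list[CtPlate]
    covariates: pd.DataFrame        # indexed by sample_id, includes label
    genotypes: pd.DataFrame
    snp_weights: dict[str, float]
    truth: dict = field(default_factory=dict)


def _labels(cfg: GeneratorConfig) -> np.ndarray:
    return np.array([CASE] * cfg.n_cases + [CONTROL] * cfg.n_controls)


def generate_counts(cfg: GeneratorConfig, rng: np.random.Generator | None = None
                    ) -> tuple[CountMatrix, pd.DataFrame, dict]:
    """Draw the count matrix; returns (counts, latent abundance, truth).

    The latent frame (samples x miRs, library-size free) is the shared layer
    the qPCR generator reads, so cross-platform concordance is built in.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    n = cfg.n_cases + cfg.n_controls
    labels = _labels(cfg)
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    mir_ids = [f"miR-{i + 1:03d}" for i in range(cfg.n_mirs)]

    lo, hi = cfg.base_log2_mean_range
    base = 2.0 ** rng.uniform(lo, hi, size=cfg.n_mirs)

    # injected differential pairs: numerator shifted up in cases; drawn from
    # well-expressed miRs so the mean>20 filter cannot remove the signal
    eligible = np.flatnonzero(base > 100)
    if len(eligible) < 2 * cfg.n_differential_pairs:
        eligible = np.argsort(base)[::-1][: max(2 * cfg.n_differential_pairs,
                                                1)]
    chosen = rng.choice(eligible, size=2 * cfg.n_differential_pairs,
                        replace=False)
    numerators = chosen[: cfg.n_differential_pairs]
    denominators = chosen[cfg.n_differential_pairs:]

    shift = np.ones((cfg.n_mirs, n))
    case_cols = labels == CASE
    for i in numerators:
        shift[i, case_cols] = 2.0 ** cfg.effect_size_log2

    disp = max(cfg.dispersion, 1e-9)
    bio = rng.gamma(shape=1.0 / disp, scale=disp, size=(cfg.n_mirs, n))
    latent = base[:, None] * shift * bio

    libsize = np.exp(rng.normal(0.0, cfg.libsize_log_sd, size=n))
    counts = rng.poisson(latent * libsize[None, :])

    # exact-copy duplicate rows exercise profile deduplication
    dup_sources = rng.choice(
        [i for i in range(cfg.n_mirs) if i not in set(chosen)],
        size=cfg.n_duplicate_pairs, replace=False)
    all_ids = list(mir_ids)
    all_counts = [counts]
    all_latent = [latent]
    for i in dup_sources:
        all_ids.append(f"{mir_ids[i]}-copy")
        all_counts.append(counts[i][None, :])
        all_latent.append(latent[i][None, :])

    cm = CountMatrix(all_ids, sample_ids, np.vstack(all_counts), labels)
    latent_df = pd.DataFrame(np.vstack(all_latent).T, index=sample_ids,
                             columns=all_ids)
    truth = {
        "injected_ratios": [
            "{}_{}".format(*canonical_pair(mir_ids[i], mir_ids[j]))
            for i, j in zip(numerators, denominators)
        ],
        "effect_size_log2": cfg.effect_size_log2,
        "duplicate_mirs": {f"{mir_ids[i]}-copy": mir_ids[i]
                           for i in dup_sources},
    }
    return cm, latent_df, truth


def generate_ct_plates(cfg: GeneratorConfig, latent: pd.DataFrame,
                       assays: list[str] | None = None,
                       rng: np.random.Generator | None = None
                       ) -> list[CtPlate]:
    """Triplicate Ct plates from the latent abundance layer.

    Ct = intercept − slope·log2(abundance) + N(0, noise_sd) per replicate;
    replicates above the non-detect threshold become NDs; with probability
    ``outlier_rate`` one replicate of a triplicate is shifted by
    ``outlier_shift`` (a pipetting-failure emulation the QC should catch).
    """
    rng = rng or np.random.default_rng(cfg.seed + 1)
    assays = assays if assays is not None else list(latent.columns)
    plates: list[CtPlate] = []
    for assay in assays:
        if assay not in latent.columns:
            raise ValidationError(f"no latent abundance for assay {assay!r}")
        conc = latent[assay].to_numpy()
        for s_idx, sid in enumerate(latent.index):
            ct_true = cfg.ct_intercept - cfg.ct_slope * np.log2(conc[s_idx])
            reps = ct_true + rng.normal(0.0, cfg.ct_noise_sd, size=3)
            if rng.random() < cfg.outlier_rate:
                reps[rng.integers(3)] += cfg.outlier_shift
            reps = [float("nan") if c > cfg.nondetect_ct else float(c)
                    for c in reps]
            plates.append(CtPlate(str(sid), str(assay), reps))
    return plates


def _draw_covariate_pool(cfg: GeneratorConfig, n_pool: int,
                         rng: np.random.Generator) -> pd.DataFrame:
    bmi = np.clip(rng.normal(26.5, 5.5, n_pool), 15, None)
    bmi_class = (bmi >= 30).astype(int)
    menopause = rng.binomial(1, 0.81, n_pool)
    wcrf = np.clip(rng.normal(5.3, 1.05, n_pool), 0, 7)
    tabar = rng.choice(np.arange(1, 5), p=_TABAR_PROBS, size=n_pool)
    birads = rng.choice(np.arange(1, 4), p=_BIRADS_PROBS, size=n_pool)
    return pd.DataFrame({
        "bmi": bmi, "bmi_class": bmi_class, "menopause": menopause,
        "wcrf": wcrf, "tabar": tabar, "birads": birads,
    })


def _draw_genotypes(cfg: GeneratorConfig, n: int, rng: np.random.Generator
                    ) -> tuple[pd.DataFrame, dict[str, float], np.ndarray]:
    snp_ids = [f"rs{900000 + i}" for i in range(cfg.n_snps)]
    mafs = rng.uniform(*cfg.maf_range, size=cfg.n_snps)
    dosages = rng.binomial(2, mafs[None, :], size=(n, cfg.n_snps))
    weights = {s: float(w)
               for s, w in zip(snp_ids, rng.normal(0.1, 0.05, cfg.n_snps))}
    geno = pd.DataFrame(dosages, columns=snp_ids)
    return geno, weights, mafs


def generate_cohort_covariates(cfg: GeneratorConfig,
                               rng: np.random.Generator | None = None,
                               sample_ids: list[str] | None = None,
                               labels: np.ndarray | None = None
                               ) -> tuple[pd.DataFrame, pd.DataFrame,
                                          dict[str, float]]:
    """Covariates, genotypes and PRS with labels from a logistic model.

    Draws a source pool, assigns outcomes from the configured log-odds
    effects (intercept centred so the pool prevalence matches
    ``cfg.prevalence``), then samples the requested numbers of cases and
    controls from the pool — the nested case–control design.  When
    ``sample_ids``/``labels`` are given the rows are matched to them, so the
    covariate table aligns with an already-generated count matrix.
    """
    rng = rng or np.random.default_rng(cfg.seed + 2)
    if labels is None:
        labels = _labels(cfg)
    n = len(labels)
    if sample_ids is None:
        sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    n_cases = int(np.sum(labels == CASE))
    n_controls = n - n_cases

    n_pool = max(40 * n, 4000)
    pool = _draw_covariate_pool(cfg, n_pool, rng)
    geno, weights, _ = _draw_genotypes(cfg, n_pool, rng)
    from .prs import compute_prs_table  # local import avoids cycle at import time
    prs = compute_prs_table(geno, weights)["prs"].to_numpy()
    prs_std = (prs - prs.mean()) / prs.std()

    eta = (cfg.bmi_class_log_or * pool["bmi_class"]
           + cfg.menopause_log_or * pool["menopause"]
           + cfg.interaction_log_or * pool["bmi_class"] * pool["menopause"]
           + cfg.wcrf_log_or * (pool["wcrf"] - 5.3)
           + cfg.tabar_trend_log_or * (pool["tabar"] - 1)
           + cfg.prs_log_or * prs_std).to_numpy()
    eta = eta - eta.mean() + np.log(cfg.prevalence / (1 - cfg.prevalence))
    outcome = rng.binomial(1, 1.0 / (1.0 + np.exp(-eta)))

    case_rows = np.flatnonzero(outcome == 1)
    control_rows = np.flatnonzero(outcome == 0)
    if len(case_rows) < n_cases or len(control_rows) < n_controls:
        raise ValidationError("source pool too small for requested cohort")
    take_cases = rng.choice(case_rows, n_cases, replace=False)
    take_controls = rng.choice(control_rows, n_controls, replace=False)

    rows = np.empty(n, dtype=int)
    rows[labels == CASE] = take_cases
    rows[labels == CONTROL] = take_controls
    cov = pool.iloc[rows].reset_index(drop=True)
    cov.insert(0, "sample_id", sample_ids)
    cov["prs"] = prs[rows]
    cov["label"] = labels
    cov = cov.set_index("sample_id")
    geno_out = geno.iloc[rows].reset_index(drop=True)
    geno_out.insert(0, "sample_id", sample_ids)
    return cov, geno_out.set_index("sample_id"), weights


def generate_cohort(cfg: GeneratorConfig) -> SyntheticCohort:
    """Generate a complete cohort: counts, plates, covariates, genotypes."""
    rng = np.random.default_rng(cfg.seed)
    counts, latent, truth = generate_counts(cfg, rng)
    plates = generate_ct_plates(cfg, latent, rng=rng)
    cov, geno, weights = generate_cohort_covariates(
        cfg, rng, sample_ids=counts.sample_ids, labels=counts.labels)
    truth["config"] = asdict(cfg)
    return SyntheticCohort(counts, latent, plates, cov, geno, weights, truth)


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> None:
    """Write the cohort as the TSV/JSON files the pipeline CLI consumes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_count_matrix(cohort.counts, out / "counts.tsv", out / "labels.tsv")
    rows = []
    for p in cohort.plates:
        for r, ct in enumerate(p.replicates):
            rows.append((p.sample_id, p.assay_id, r + 1,
                         "ND" if np.isnan(ct) else f"{ct:.4f}"))
    pd.DataFrame(rows, columns=["sample_id", "assay_id", "replicate", "ct"]
                 ).to_csv(out / "ct_plates.tsv", sep="\t", index=False)
    cov = cohort.covariates.copy()
    cov["label"] = np.where(cov["label"] == CASE, "case", "control")
    cov.to_csv(out / "covariates.tsv", sep="\t")
    cohort.genotypes.to_csv(out / "genotypes.tsv", sep="\t")
    pd.DataFrame({"snp_id": list(cohort.snp_weights),
                  "log_or": list(cohort.snp_weights.values())}
                 ).to_csv(out / "snp_weights.tsv", sep="\t", index=False)
    with open(out / "ground_truth.json", "w", encoding="utf-8") as fh:
        json.dump(cohort.truth, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
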