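"""RT-qPCR plate processing: triplicate QC, ΔCt ratios, cross-platform
concordance, and ratio–covariate association tests.

The Ct (cycle threshold) is inversely proportional to the log2 template
abundance, so the difference Ct_mean(Y) − Ct_mean(X) estimates the log2
abundance ratio X/Y within a sample — the qPCR analogue of the sequencing
count ratio, and like it free of any normalizer assay.

Triplicate QC, in a single pass: non-detect wells are first imputed to
Ct 40; then any replicate lying strictly more than one sample standard
deviation from the triplicate mean is excluded and the mean recomputed from
the survivors.  For three points the squared deviations sum to twice the
sample variance, so at most one replicate can ever qualify — the rule cannot
empty a triplicate.  Two-replicate groups skip the outlier step entirely
(each point of a pair always lies exactly one sd from the mean, so the rule
would always fire) and are flagged.
"""

from __future__ import annotations

import logging
import math
import re

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import CtPlate, NONDETECT_CT, ValidationError
from .ratio_features import canonical_pair

logger = logging.getLogger(__name__)

#: strips a trailing genomic-locus suffix ("-1", "-2", ...) from a miR id;
#: a single digit only, so arm labels ("-3p") and numeric family names stay
_LOCUS_SUFFIX = re.compile(r"-\d$")


def qc_triplicate(cts) -> tuple[float, list[int]]:
    """Apply the replicate QC rule; return (ct_mean, excluded indices).

    ``cts`` holds 1–3 replicate Ct values with NaN marking non-detects.
    All-non-detect groups yield ct_mean 40 with nothing excluded (the caller
    flags them via :func:`apply_qc`).
    """
    raw = [float(c) for c in cts]
    if not 1 <= len(raw) <= 3:
        raise ValidationError(f"expected 1-3 replicates, got {len(raw)}")
    vals = np.array([NONDETECT_CT if math.isnan(c) else c for c in raw])
    if len(vals) < 3:
        return float(vals.mean()), []
    mean = vals.mean()
    sd = vals.std(ddof=1)
    dev = np.abs(vals - mean)
    # strict "> one sd" with a relative guard so a deviation exactly equal
    # to the sd never tips over through floating-point rounding
    outliers = np.flatnonzero(dev > sd * (1 + 1e-9) + 1e-12)
    if outliers.size == 0:
        return float(mean), []
    assert outliers.size == 1, "triplicate QC can never flag two replicates"
    keep = np.delete(vals, outliers[0])
    return float(keep.mean()), [int(outliers[0])]


def apply_qc(plate: CtPlate) -> CtPlate:
    """Run triplicate QC on a plate record in place and return it."""
    plate.all_nondetect = all(math.isnan(c) for c in plate.replicates)
    if plate.all_nondetect:
        logger.warning("(%s, %s): all replicates non-detect; ct_mean = %g",
                       plate.sample_id, plate.assay_id, NONDETECT_CT)
    if len(plate.replicates) == 2:
        logger.warning("(%s, %s): doublet, outlier QC skipped",
                       plate.sample_id, plate.assay_id)
    plate.ct_mean, plate.qc_excluded = qc_triplicate(plate.replicates)
    return plate


def delta_ct_ratio(ct_mean_x: float, ct_mean_y: float) -> float:
    """ΔCt ratio of miR X over miR Y: Ct_mean(Y) − Ct_mean(X).

    Larger values mean more X relative to Y (Ct falls as abundance rises);
    the quantity is antisymmetric under swapping X and Y.
    """
    return ct_mean_y - ct_mean_x


def strip_locus_suffix(mir_id: str) -> str:
    """Collapse a locus-suffixed sequencing id to its mature miR id."""
    return _LOCUS_SUFFIX.sub("", mir_id)


def collapse_ratio_id(rid: str) -> str | None:
    """Map one sequencing ratio id to its assay-level mature-miR ratio id.

    Returns None when the two members collapse to the same mature miR (a
    degenerate self-ratio).  Dedup aliases ("a+b") map through their first
    member.
    """
    try:
        num, den = rid.split("_")
    except ValueError:
        raise ValidationError(f"unmappable ratio id {rid!r}") from None
    num = strip_locus_suffix(num.split("+")[0])
    den = strip_locus_suffix(den.split("+")[0])
    if num == den:
        return None
    return f"{num}_{den}"


def map_sequencing_ratios_to_assays(
    ratio_ids: list[str],
    manual_exclusions: tuple[str, ...] | list[str] = (),
) -> tuple[list[str], set[str]]:
    """Map sequencing-stage ratio ids to unique assay-level mature-miR ratios.

    Sequencing ids carry genomic-locus suffixes ("-1"/"-2") and may be
    merged dedup aliases ("a+b"); at the assay level both collapse to one
    mature miR, because the qPCR assay cannot distinguish loci producing the
    same mature sequence.  After collapsing, duplicate ratios are removed
    (first occurrence kept), entries listed in ``manual_exclusions``
    (sequencing-stage ids) are dropped, and degenerate self-ratios are
    rejected.  Returns the unique assay ratios and the mature miR set they
    require.
    """
    seen: set[tuple[str, str]] = set()
    assay_ratios: list[str] = []
    mirs: set[str] = set()
    excl = set(manual_exclusions)
    for rid in ratio_ids:
        if rid in excl:
            logger.info("ratio %s manually excluded from the assay panel", rid)
            continue
        assay_id = collapse_ratio_id(rid)
        if assay_id is None:
            raise ValidationError(
                f"ratio {rid!r} collapses to a self-ratio at the assay level")
        num, den = assay_id.split("_")
        pair = canonical_pair(num, den)
        if pair in seen:
            logger.info("ratio %s duplicates %s_%s after locus collapse",
                        rid, *pair)
            continue
        seen.add(pair)
        assay_ratios.append(f"{num}_{den}")
        mirs.update((num, den))
    return assay_ratios, mirs


def ct_mean_table(plates: list[CtPlate]) -> pd.DataFrame:
    """QC every plate and pivot to a samples x assays Ct-mean table."""
    rows = []
    for plate in plates:
        if plate.ct_mean is None:
            apply_qc(plate)
        rows.append((plate.sample_id, plate.assay_id, plate.ct_mean))
    df = pd.DataFrame(rows, columns=["sample_id", "assay_id", "ct_mean"])
    return df.pivot(index="sample_id", columns="assay_id", values="ct_mean")


def delta_ct_table(plates: list[CtPlate], assay_ratios: list[str]
                   ) -> pd.DataFrame:
    """Per-sample ΔCt value for each assay ratio (samples x ratios)."""
    ct = ct_mean_table(plates)
    out = {}
    for rid in assay_ratios:
        num, den = rid.split("_")
        for mir in (num, den):
            if mir not in ct.columns:
                raise ValidationError(f"no Ct data for assay {mir!r}")
        out[rid] = delta_ct_ratio(ct[num], ct[den])
    return pd.DataFrame(out, index=ct.index)


def cross_platform_concordance(
    seq_log_ratios: pd.DataFrame,
    dct_ratios: pd.DataFrame,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Spearman concordance between sequencing log2 ratios and ΔCt ratios.

    Both frames are samples x ratios; rows are aligned on the shared sample
    ids.  A ratio is flagged concordant when rho > 0 with p < alpha.
    Spearman is invariant to the (monotone) log2 transform, so the flag does
    not depend on the sequencing scale choice.
    """
    shared = seq_log_ratios.index.intersection(dct_ratios.index)
    if len(shared) < 3:
        raise ValidationError(
            f"need >= 3 paired samples, got {len(shared)}")
    records = []
    for rid in dct_ratios.columns:
        if rid not in seq_log_ratios.columns:
            raise ValidationError(f"ratio {rid!r} missing from sequencing data")
        rho, p = stats.spearmanr(seq_log_ratios.loc[shared, rid],
                                 dct_ratios.loc[shared, rid])
        records.append({
            "ratio_id": rid,
            "rho": float(rho),
            "p": float(p),
            "concordant": bool(p < alpha and rho > 0),
        })
    return pd.DataFrame(records).set_index("ratio_id")


def ratio_covariate_association(ratio_values, covariate,
                                kind: str = "auto") -> float:
    """Association p-value of a ratio with a covariate.

    Dispatches on covariate type: Mann–Whitney for 2 levels, Kruskal–Wallis
    for more, Spearman correlation for continuous; all two-sided.
    """
    v = np.asarray(ratio_values, dtype=float)
    cov = np.asarray(covariate)
    if kind == "auto":
        levels = np.unique(cov)
        if cov.dtype.kind in "fc" and len(levels) > 10:
            kind = "continuous"
        else:
            kind = "categorical"
    if kind == "continuous":
        _, p = stats.spearmanr(v, cov.astype(float))
        return float(p)
    levels = np.unique(cov)
    if len(levels) < 2:
        raise ValidationError("covariate has a single level")
    groups = [v[cov == lev] for lev in levels]
    if len(levels) == 2:
        res = stats.mannwhitneyu(groups[0], groups[1],
                                 alternative="two-sided",
                                 method="asymptotic", use_continuity=True)
        return float(min(1.0, res.pvalue))
    _, p = stats.kruskal(*groups)
    return float(p)
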