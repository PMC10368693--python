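"""Polygenic risk score from SNP dosages and published per-SNP log odds
ratios: PRS = sum over SNPs of log(OR) x genotype dosage, with dosage 0 for
wildtype, 1 for a heterozygous and 2 for a homozygous variant.

Missing genotypes contribute 0 by default and are counted alongside the
score; optional mean-dosage imputation (2 x risk allele frequency) is
available but off by default.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .core_io import ValidationError


def compute_prs(
    dosages: dict[str, float],
    weights: dict[str, float],
    allele_freqs: dict[str, float] | None = None,
) -> tuple[float, int]:
    """Weighted dosage sum for one sample; returns (prs, n_missing).

    Every non-missing dosage must be in {0, 1, 2} and have a weight.  When
    ``allele_freqs`` is given, a missing dosage is imputed to twice the risk
    allele frequency instead of contributing zero.
    """
    prs = 0.0
    n_missing = 0
    for snp, g in dosages.items():
        if g is None or (isinstance(g, float) and math.isnan(g)):
            n_missing += 1
            if allele_freqs is not None:
                if snp not in weights:
                    raise ValidationError(f"no weight for SNP {snp!r}")
                prs += weights[snp] * 2.0 * allele_freqs[snp]
            continue
        if g not in (0, 1, 2):
            raise ValidationError(
                f"dosage {g!r} for SNP {snp!r} not in {{0, 1, 2}}")
        if snp not in weights:
            raise ValidationError(f"no weight for SNP {snp!r}")
        prs += weights[snp] * g
    return prs, n_missing


def compute_prs_table(
    genotypes: pd.DataFrame,
    weights: dict[str, float],
    allele_freqs: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Per-sample PRS for a samples x SNPs dosage table.

    Returns a frame indexed like ``genotypes`` with columns ``prs`` and
    ``n_missing``, suitable for merging into the cohort table.
    """
    missing_w = [c for c in genotypes.columns if c not in weights]
    if missing_w:
        raise ValidationError(f"no weight for SNP {missing_w[0]!r}")
    arr = genotypes.to_numpy(dtype=float)
    ok = np.isnan(arr) | np.isin(arr, (0.0, 1.0, 2.0))
    if not ok.all():
        i, j = np.argwhere(~ok)[0]
        raise ValidationError(
            f"dosage {arr[i, j]} for SNP {genotypes.columns[j]!r} "
            "not in {0, 1, 2} or missing")
    w = np.array([weights[c] for c in genotypes.columns])
    miss = np.isnan(arr)
    if allele_freqs is not None:
        fill = 2.0 * np.array([allele_freqs[c] for c in genotypes.columns])
        filled = np.where(miss, fill[None, :], arr)
    else:
        filled = np.where(miss, 0.0, arr)
    return pd.DataFrame(
        {"prs": filled @ w, "n_missing": miss.sum(axis=1)},
        index=genotypes.index,
    )
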