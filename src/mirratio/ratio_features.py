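"""From raw counts to the deduplicated all-pairs ratio matrix.

The discovery stage uses ratios of raw miR counts within a sample as
features.  Any per-sample scaling (library size, plasma input volume)
multiplies every count in a sample by the same factor and therefore cancels
in every ratio — this is the whole point of the design: no normalizer gene
and no between-sample normalization is needed.

Stages, in order:

1. ``filter_mirs`` — keep miRs whose across-sample mean raw count is
   strictly greater than ``min_mean`` (default 20).
2. ``deduplicate_profiles`` — collapse miRs with identical count profiles
   (typically the same mature sequence annotated at two genomic loci) to a
   single row under a merged identifier.
3. ``build_ratio_matrix`` — one ratio per unordered pair, n(n-1)/2 in total,
   canonically oriented (lexicographically smaller miR id as numerator).
"""

from __future__ import annotations

import logging

import numpy as np

from .core_io import CountMatrix, RatioMatrix, ValidationError

logger = logging.getLogger(__name__)

DedupMap = dict[str, str]  # removed miR id -> retained (merged) alias


def filter_mirs(cm: CountMatrix, min_mean: float = 20.0) -> CountMatrix:
    """Retain miRs whose mean raw count across all samples exceeds ``min_mean``.

    The inequality is strict: a miR with mean exactly ``min_mean`` is dropped.
    """
    means = cm.counts.mean(axis=1)
    keep = np.flatnonzero(means > min_mean)
    if keep.size == 0:
        raise ValidationError(
            f"no miRs retained: no mean raw count exceeds {min_mean}"
        )
    logger.info("count filter: %d of %d miRs retained (mean > %g)",
                keep.size, cm.n_mirs, min_mean)
    return cm.subset_mirs(keep)


def deduplicate_profiles(
    cm: CountMatrix, tolerance: float = 0.0
) -> tuple[CountMatrix, DedupMap]:
    """Collapse miRs with identical count profiles to one row each.

    Rows within ``tolerance`` (max absolute difference; default 0 = exact
    equality) are grouped; the group is represented by a merged identifier
    joining the member ids with ``+`` so the alias records both, and the map
    from each removed id to its alias is returned.
    """
    n = cm.n_mirs
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    # group by row content; exact matching uses hashing, tolerant matching
    # falls back to pairwise comparison within equal-sum buckets
    if tolerance == 0.0:
        seen: dict[bytes, int] = {}
        for i in range(n):
            key = cm.counts[i].tobytes()
            if key in seen:
                parent[find(i)] = find(seen[key])
            else:
                seen[key] = i
    else:
        for i in range(n):
            for j in range(i + 1, n):
                if np.max(np.abs(cm.counts[i] - cm.counts[j])) <= tolerance:
                    parent[find(j)] = find(i)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    keep_rows: list[int] = []
    new_ids: list[str] = []
    dedup_map: DedupMap = {}
    for root in sorted(groups, key=lambda r: min(groups[r])):
        members = sorted(groups[root])
        rep = members[0]
        keep_rows.append(rep)
        if len(members) == 1:
            new_ids.append(cm.mir_ids[rep])
        else:
            alias = "+".join(cm.mir_ids[m] for m in members)
            new_ids.append(alias)
            for m in members:
                dedup_map[cm.mir_ids[m]] = alias
    out = cm.subset_mirs(keep_rows)
    out.mir_ids = new_ids
    if dedup_map:
        logger.info("deduplication: %d miRs collapsed into %d merged ids",
                    n - len(keep_rows) + len([g for g in groups.values() if len(g) > 1]),
                    sum(1 for g in groups.values() if len(g) > 1))
    return out, dedup_map


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Canonical ratio orientation: lexicographically smaller id is numerator."""
    return (a, b) if a < b else (b, a)


def build_ratio_matrix(cm: CountMatrix, pseudocount: float = 1.0) -> RatioMatrix:
    """Compute all n(n-1)/2 pairwise count ratios per sample.

    Each ratio value is (count_num + pseudocount) / (count_den + pseudocount).
    The pseudocount keeps ratios finite when a count is zero; on zero-free
    data it does not change within-ratio sample ranks, so rank-based
    downstream tests are unaffected by its value.
    """
    n = cm.n_mirs
    if n < 2:
        raise ValidationError("need at least 2 miRs to form a ratio")
    order = np.argsort(cm.mir_ids)
    shifted = cm.counts.astype(float) + pseudocount
    ratio_ids: list[tuple[str, str]] = []
    blocks: list[np.ndarray] = []
    for ii in range(n):
        i = order[ii]
        rest = order[ii + 1:]
        if rest.size == 0:
            continue
        ratio_ids.extend((cm.mir_ids[i], cm.mir_ids[j]) for j in rest)
        blocks.append(shifted[i][None, :] / shifted[rest])
    values = np.vstack(blocks)
    logger.info("ratio matrix: %d miRs -> %d ratios", n, values.shape[0])
    return RatioMatrix(
        ratio_ids=ratio_ids,
        values=values,
        sample_ids=list(cm.sample_ids),
        labels=cm.labels.copy(),
    )


def fold_change(rm: RatioMatrix) -> np.ndarray:
    """Per-ratio fold change: median over cases / median over controls."""
    cases = rm.labels == 1
    controls = rm.labels == 0
    if not cases.any() or not controls.any():
        raise ValidationError("fold change needs at least one case and one control")
    med_case = np.median(rm.values[:, cases], axis=1)
    med_ctrl = np.median(rm.values[:, controls], axis=1)
    return med_case / med_ctrl


def control_cv(rm: RatioMatrix) -> np.ndarray:
    """Per-ratio coefficient of variation among controls (sample sd / mean).

    Computed on the raw ratio scale with the n-1 standard deviation.
    """
    controls = rm.labels == 0
    if controls.sum() < 2:
        raise ValidationError("control CV needs at least 2 control samples")
    vals = rm.values[:, controls]
    return vals.std(axis=1, ddof=1) / vals.mean(axis=1)
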