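"""Domain types and tabular readers/writers shared by all pipeline stages.

The pipeline works with four kinds of tabular input: a miR raw-count matrix
with case/control labels (sequencing side), long-format RT-qPCR Ct plate
tables, a per-sample covariate table, and a genotype dosage table.  All files
are plain UTF-8 TSV/CSV with a header row; metrics are serialized as JSON
with sorted keys so identical results produce byte-identical files.

Case is encoded as 1 and control as 0 throughout the package; every odds
ratio and AUC reported downstream treats "case" as the positive class.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

CASE = 1
CONTROL = 0

#: sentinel for a missing covariate / genotype value (never silently dropped
#: at read time; complete-case handling is decided per model)
MISSING = -1

#: Ct value assigned to a non-detect well
NONDETECT_CT = 40.0


class ValidationError(ValueError):
    """Raised when an input file or in-memory object violates a contract.

    The message always names the offending row/column/sample so that a
    malformed file can be located without re-running with a debugger.
    """


@dataclass
class CountMatrix:
    """miR raw counts (miRs x samples) with per-sample case/control labels."""

    mir_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray  # (n_mirs, n_samples), non-negative integers
    labels: np.ndarray  # (n_samples,), 1 = case, 0 = control

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.labels = np.asarray(self.labels, dtype=int)
        n_mirs, n_samples = self.counts.shape
        if len(self.mir_ids) != n_mirs:
            raise ValidationError(
                f"count matrix has {n_mirs} rows but {len(self.mir_ids)} miR ids"
            )
        if len(self.sample_ids) != n_samples:
            raise ValidationError(
                f"count matrix has {n_samples} columns but "
                f"{len(self.sample_ids)} sample ids"
            )
        if len(set(self.mir_ids)) != n_mirs:
            seen: set[str] = set()
            dup = next(m for m in self.mir_ids if m in seen or seen.add(m))
            raise ValidationError(f"duplicated miR id: {dup!r}")
        if np.any(self.counts < 0):
            i, j = np.argwhere(self.counts < 0)[0]
            raise ValidationError(
                f"negative count at miR {self.mir_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )
        if self.labels.shape != (n_samples,):
            raise ValidationError("labels length does not match sample count")
        bad = set(np.unique(self.labels)) - {CASE, CONTROL}
        if bad:
            raise ValidationError(f"labels must be 0/1, got {sorted(bad)}")

    @property
    def n_mirs(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def subset_mirs(self, keep: Sequence[int]) -> "CountMatrix":
        keep = list(keep)
        return CountMatrix(
            mir_ids=[self.mir_ids[i] for i in keep],
            sample_ids=list(self.sample_ids),
            counts=self.counts[keep],
            labels=self.labels.copy(),
        )


@dataclass
class RatioMatrix:
    """All pairwise miR ratios per sample, with per-ratio statistics.

    ``ratio_ids`` are ordered (numerator, denominator) pairs; each unordered
    pair appears at most once.  The ``stats`` frame is populated lazily by the
    selection stage (raw p, BH-adjusted p, fold change, control CV).
    """

    ratio_ids: list[tuple[str, str]]
    values: np.ndarray  # (n_ratios, n_samples), all > 0
    sample_ids: list[str]
    labels: np.ndarray
    stats: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.shape != (len(self.ratio_ids), len(self.sample_ids)):
            raise ValidationError("ratio matrix dimensions do not match id lists")
        unordered = {frozenset(p) for p in self.ratio_ids}
        if len(unordered) != len(self.ratio_ids):
            raise ValidationError("an unordered miR pair appears more than once")
        if np.any(~(self.values > 0)):
            raise ValidationError("ratio values must be strictly positive")

    @property
    def names(self) -> list[str]:
        """Ratio ids in ``<numerator>_<denominator>`` format."""
        return [f"{a}_{b}" for a, b in self.ratio_ids]

    @property
    def n_ratios(self) -> int:
        return self.values.shape[0]


@dataclass
class CtPlate:
    """Triplicate Ct measurements for one (sample, assay) well group.

    ``replicates`` holds the raw values with non-detects as NaN; after QC,
    ``qc_excluded`` lists indices of removed replicates and ``ct_mean`` the
    mean of the survivors (non-detects imputed to 40 first).
    """

    sample_id: str
    assay_id: str
    replicates: list[float]  # NaN = non-detect
    qc_excluded: list[int] = field(default_factory=list)
    ct_mean: float | None = None
    all_nondetect: bool = False

    def __post_init__(self) -> None:
        if not 1 <= len(self.replicates) <= 3:
            raise ValidationError(
                f"({self.sample_id}, {self.assay_id}): expected 1-3 replicates, "
                f"got {len(self.replicates)}"
            )
        for ct in self.replicates:
            if not math.isnan(ct) and not 0 < ct <= 45:
                raise ValidationError(
                    f"({self.sample_id}, {self.assay_id}): Ct {ct} outside (0, 45]"
                )


@dataclass
class SignatureModel:
    """A fitted L1-penalised logistic signature.

    Coefficients are stored on the original feature scale (back-transformed
    from the standardization applied before fitting); features whose
    coefficient is exactly zero are reported as unselected.
    """

    feature_names: list[str]
    coefficients: np.ndarray
    intercept: float
    penalty: float  # lambda, glmnet convention: (1/n)*loss + lambda*||beta||_1
    standardize_means: np.ndarray
    standardize_scales: np.ndarray
    log2_transform: bool = False

    @property
    def selected(self) -> list[str]:
        return [
            name
            for name, c in zip(self.feature_names, self.coefficients)
            if c != 0.0
        ]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Probability of class 1 for a raw (untransformed) feature matrix."""
        X = np.asarray(X, dtype=float)
        if self.log2_transform:
            X = np.log2(X)
        eta = self.intercept + X @ self.coefficients
        return 1.0 / (1.0 + np.exp(-eta))


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep)


def read_count_matrix(path: str | Path, label_path: str | Path) -> CountMatrix:
    """Read a miR x sample count table plus a sample -> label map.

    The count file is TSV/CSV with miR ids in the first column and one column
    per sample; the label file has columns ``sample_id`` and ``label`` with
    labels in {case, control} (or 1/0).
    """
    df = _read_table(path)
    mir_col = df.columns[0]
    mir_ids = df[mir_col].astype(str).tolist()
    sample_ids = [str(c) for c in df.columns[1:]]
    counts = df.iloc[:, 1:].to_numpy()
    if not np.issubdtype(counts.dtype, np.number):
        raise ValidationError(f"{path}: non-numeric count values")

    labels_df = _read_table(label_path)
    if not {"sample_id", "label"} <= set(labels_df.columns):
        raise ValidationError(
            f"{label_path}: expected columns 'sample_id' and 'label'"
        )
    mapping = {"case": CASE, "control": CONTROL, "1": CASE, "0": CONTROL}
    label_map: dict[str, int] = {}
    for _, row in labels_df.iterrows():
        sid = str(row["sample_id"])
        raw = str(row["label"]).strip().lower()
        if raw not in mapping:
            raise ValidationError(
                f"{label_path}: unknown label {row['label']!r} for sample {sid}"
            )
        label_map[sid] = mapping[raw]

    unknown = sorted(set(label_map) - set(sample_ids))
    if unknown:
        raise ValidationError(
            f"{label_path}: labels given for unknown samples: {', '.join(unknown)}"
        )
    missing = sorted(set(sample_ids) - set(label_map))
    if missing:
        raise ValidationError(
            f"{label_path}: no label for samples: {', '.join(missing)}"
        )
    labels = np.array([label_map[s] for s in sample_ids])
    return CountMatrix(mir_ids, sample_ids, counts, labels)


def read_ct_plates(path: str | Path) -> list[CtPlate]:
    """Read a long-format Ct table: sample_id, assay_id, replicate, ct.

    ``ct`` is a real in (0, 45] or the string ``ND`` for a non-detect.  QC is
    NOT applied here; see :func:`mirratio.qpcr.qc_triplicate`.
    """
    df = _read_table(path)
    required = {"sample_id", "assay_id", "ct"}
    if not required <= set(df.columns):
        raise ValidationError(f"{path}: expected columns {sorted(required)}")
    plates: list[CtPlate] = []
    for (sid, aid), grp in df.groupby(["sample_id", "assay_id"], sort=True):
        reps: list[float] = []
        for raw in grp["ct"]:
            s = str(raw).strip()
            if s.upper() == "ND":
                reps.append(float("nan"))
            else:
                try:
                    ct = float(s)
                except ValueError:
                    raise ValidationError(
                        f"({sid}, {aid}): unparseable Ct value {raw!r}"
                    ) from None
                if not 0 < ct <= 45:
                    raise ValidationError(
                        f"({sid}, {aid}): Ct {ct} outside (0, 45]"
                    )
                reps.append(ct)
        plates.append(CtPlate(str(sid), str(aid), reps))
    return plates


def read_covariates(path: str | Path) -> pd.DataFrame:
    """Read the per-sample covariate table; missing values become MISSING."""
    df = _read_table(path)
    if "sample_id" not in df.columns:
        raise ValidationError(f"{path}: expected a 'sample_id' column")
    df = df.set_index("sample_id")
    return df.fillna(MISSING)


def read_genotypes(path: str | Path) -> pd.DataFrame:
    """Read a samples x SNPs dosage table; dosages in {0,1,2} or missing."""
    df = _read_table(path)
    if "sample_id" not in df.columns:
        raise ValidationError(f"{path}: expected a 'sample_id' column")
    df = df.set_index("sample_id")
    arr = df.to_numpy(dtype=float)
    ok = np.isnan(arr) | np.isin(arr, (0.0, 1.0, 2.0))
    if not ok.all():
        i, j = np.argwhere(~ok)[0]
        raise ValidationError(
            f"{path}: dosage {arr[i, j]} at sample {df.index[i]!r}, "
            f"SNP {df.columns[j]!r} not in {{0,1,2}} or missing"
        )
    return df


def read_snp_weights(path: str | Path) -> dict[str, float]:
    """Read a per-SNP log odds ratio weight table (snp_id, log_or)."""
    df = _read_table(path)
    if not {"snp_id", "log_or"} <= set(df.columns):
        raise ValidationError(f"{path}: expected columns snp_id, log_or")
    if df["snp_id"].duplicated().any():
        dup = df.loc[df["snp_id"].duplicated(), "snp_id"].iloc[0]
        raise ValidationError(f"{path}: duplicated SNP id {dup!r}")
    weights = dict(zip(df["snp_id"].astype(str), df["log_or"].astype(float)))
    for snp, w in weights.items():
        if not math.isfinite(w):
            raise ValidationError(f"{path}: non-finite weight for {snp!r}")
    return weights


# ---------------------------------------------------------------------------
# Writers (deterministic: sorted keys, fixed float format)
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.6g"


def write_count_matrix(cm: CountMatrix, path: str | Path, label_path: str | Path) -> None:
    df = pd.DataFrame(cm.counts, index=cm.mir_ids, columns=cm.sample_ids)
    df.index.name = "mir_id"
    df.to_csv(path, sep="\t")
    labels = pd.DataFrame(
        {
            "sample_id": cm.sample_ids,
            "label": ["case" if l == CASE else "control" for l in cm.labels],
        }
    )
    labels.to_csv(label_path, sep="\t", index=False)


def write_ratio_stats(rm: RatioMatrix, path: str | Path) -> None:
    """Write the per-ratio statistics table as TSV (header-only when empty)."""
    stats = rm.stats.copy()
    if stats.empty:
        stats = pd.DataFrame(
            columns=["ratio_id", "U", "p", "adj_p", "FC", "control_CV",
                     "strategy1", "strategy2"]
        )
    else:
        stats = stats.reset_index().rename(columns={"index": "ratio_id"})
    stats.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_metrics(metrics: Mapping, path: str | Path) -> None:
    """Write a metrics mapping as deterministic JSON."""

    def _clean(obj):
        if isinstance(obj, Mapping):
            return {str(k): _clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple, np.ndarray)):
            return [_clean(v) for v in obj]
        if isinstance(obj, (np.floating, float)):
            return float(f"{float(obj):.6g}")
        if isinstance(obj, np.integer):
            return int(obj)
        return obj

    with open(path, "w", encoding="utf-8") as fh:
        json.dump(_clean(metrics), fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_report(results: Mapping, out_dir: str | Path) -> list[Path]:
    """Write per-ratio statistics tables (TSV) and model metrics (JSON).

    ``results`` maps output names to either a RatioMatrix (written as a stats
    TSV) or a metrics mapping (written as JSON).  Writing the same results
    twice yields byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name in sorted(results):
        obj = results[name]
        if isinstance(obj, RatioMatrix):
            p = out_dir / f"{name}.tsv"
            write_ratio_stats(obj, p)
        else:
            p = out_dir / f"{name}.json"
            write_metrics(obj, p)
        written.append(p)
    return written
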