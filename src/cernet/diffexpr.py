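"""Differential expression between two developmental stages, and qPCR fold change.

The DE contrast is stage2 vs stage1 (e.g. adult vs embryo).  Fold changes are
computed on CPM-normalized counts with a pseudocount; p-values come from a
two-sided Welch t-test on log2(CPM + 1) across replicates.  Precomputed DE
tables (id, class, log2fc, pvalue) are accepted as first-class input so that
externally produced DE results can be threshold-filtered directly.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

RNA_CLASSES = ("lncRNA", "miRNA", "mRNA")
STAGES = ("stage1", "stage2")

#: fold-change thresholds used for DE selection: |log2FC| >= 4, relaxed to
#: >= 2 for mRNAs; combined with p < 0.001.
DEFAULT_FC_THRESHOLDS = {"lncRNA": 4.0, "miRNA": 4.0, "mRNA": 2.0}
DEFAULT_P_THRESHOLD = 0.001


@dataclass
class ExpressionMatrix:
    """Counts for all RNA classes over replicated samples of two stages.

    counts: DataFrame, rows = RNA ids, columns = sample ids.
    classes: Series mapping RNA id -> class in {lncRNA, miRNA, mRNA}.
    stages: Series mapping sample id -> stage in {stage1, stage2}.
    """

    counts: pd.DataFrame
    classes: pd.Series
    stages: pd.Series

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate RNA ids in count matrix")
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        present = set(self.stages.loc[self.counts.columns])
        if set(STAGES) - present:
            raise ValueError("need >=1 sample in each of stage1 and stage2")
        unknown = set(self.classes.unique()) - set(RNA_CLASSES)
        if unknown:
            raise ValueError(f"unknown RNA classes: {sorted(unknown)}")

    def samples_of(self, stage: str) -> list[str]:
        return [s for s in self.counts.columns if self.stages[s] == stage]


@dataclass(frozen=True)
class DERecord:
    """Differential-expression result for one RNA (stage2 vs stage1)."""

    id: str
    rna_class: str
    log2fc: float
    pvalue: float  # NaN when not computable (e.g. single replicate)

    @property
    def direction(self) -> str:
        return "up" if self.log2fc > 0 else "down"


@dataclass(frozen=True)
class QpcrMeasurement:
    sample_id: str
    group: str  # "test" or "calibrator"
    ct_target: float
    ct_reference: float

    def __post_init__(self) -> None:
        for v in (self.ct_target, self.ct_reference):
            if not math.isfinite(v) or v <= 0:
                raise ValueError("Ct values must be finite and positive")
        if self.group not in ("test", "calibrator"):
            raise ValueError(f"unknown group {self.group!r}")


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts per million by per-sample total; all-zero samples left as zero."""
    totals = counts.sum(axis=0)
    totals = totals.replace(0, 1)
    return counts / totals * 1e6


def compute_de(
    matrix: ExpressionMatrix,
    pseudocount: float = 1.0,
    normalize: str = "cpm",
) -> list[DERecord]:
    """Per-RNA log2 fold change (stage2 vs stage1) and Welch-t p-value.

    log2fc = log2((mean_2 + c) / (mean_1 + c)) on CPM (or raw values when
    ``normalize="none"`` for pre-normalized input).  The p-value is a
    two-sided Welch t-test on log2(value + 1) across replicates; with fewer
    than two replicates in either stage it is NaN.  RNAs with zero counts in
    every sample get log2fc = 0 and p = 1.  Zero within-group variance in
    both stages is resolved analytically: p = 0 if the group means differ,
    p = 1 otherwise.
    """
    if normalize == "cpm":
        values = cpm(matrix.counts)
    elif normalize == "none":
        values = matrix.counts.astype(float)
    else:
        raise ValueError(f"unknown normalization {normalize!r}")

    s1 = matrix.samples_of("stage1")
    s2 = matrix.samples_of("stage2")
    v1 = values[s1].to_numpy(dtype=float)
    v2 = values[s2].to_numpy(dtype=float)

    m1, m2 = v1.mean(axis=1), v2.mean(axis=1)
    log2fc = np.log2((m2 + pseudocount) / (m1 + pseudocount))

    all_zero = (matrix.counts[s1 + s2].to_numpy() == 0).all(axis=1)
    log2fc[all_zero] = 0.0

    if len(s1) >= 2 and len(s2) >= 2:
        l1, l2 = np.log2(v1 + 1.0), np.log2(v2 + 1.0)
        with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # constant rows handled below
            pvals = stats.ttest_ind(l2, l1, axis=1, equal_var=False).pvalue
        var1, var2 = l1.var(axis=1, ddof=1), l2.var(axis=1, ddof=1)
        both_const = (var1 == 0) & (var2 == 0)
        pvals = np.where(both_const, np.where(l2.mean(axis=1) == l1.mean(axis=1), 1.0, 0.0), pvals)
    else:
        pvals = np.full(len(log2fc), np.nan)
    pvals = np.where(all_zero, 1.0, pvals)

    ids = matrix.counts.index
    return [
        DERecord(id=i, rna_class=matrix.classes[i], log2fc=float(f), pvalue=float(p))
        for i, f, p in zip(ids, log2fc, pvals)
    ]


def filter_de(
    records: list[DERecord],
    fc_thresholds: dict[str, float] | None = None,
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> list[DERecord]:
    """Keep records with |log2fc| >= the class threshold and p < p_threshold."""
    fc_thresholds = fc_thresholds if fc_thresholds is not None else DEFAULT_FC_THRESHOLDS
    out = []
    for r in records:
        if r.rna_class not in fc_thresholds:
            raise ValueError(f"no fold-change threshold for class {r.rna_class!r}")
        if abs(r.log2fc) >= fc_thresholds[r.rna_class] and r.pvalue < p_threshold:
            out.append(r)
    return out


def delta_delta_ct(measurements: list[QpcrMeasurement]) -> dict[str, float]:
    """Relative quantification by the 2^-ddCt method.

    dCt = Ct_target - Ct_reference per sample; ddCt of a test sample is its
    dCt minus the mean dCt over calibrator samples; fold = 2^-ddCt.
    """
    cal = [m.ct_target - m.ct_reference for m in measurements if m.group == "calibrator"]
    if not cal:
        raise ValueError("at least one calibrator measurement is required")
    cal_mean = float(np.mean(cal))
    return {
        m.sample_id: 2.0 ** -((m.ct_target - m.ct_reference) - cal_mean)
        for m in measurements
        if m.group == "test"
    }


# ---------------------------------------------------------------------------
# I/O

def write_counts(matrix: ExpressionMatrix, path: str | Path, seed: int | None = None) -> None:
    """Counts TSV: id, class, then one column per sample; a second header row
    carries the stage label of each sample; optional seed comment first."""
    path = Path(path)
    with path.open("w") as fh:
        if seed is not None:
            fh.write(f"# rng_seed={seed}\n")
        samples = list(matrix.counts.columns)
        fh.write("id\tclass\t" + "\t".join(samples) + "\n")
        fh.write("#stage\t.\t" + "\t".join(matrix.stages[s] for s in samples) + "\n")
        for rid, row in matrix.counts.iterrows():
            vals = "\t".join(str(int(v)) if float(v).is_integer() else repr(float(v)) for v in row)
            fh.write(f"{rid}\t{matrix.classes[rid]}\t{vals}\n")


def read_counts(path: str | Path) -> ExpressionMatrix:
    path = Path(path)
    with path.open() as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    lines = [ln for ln in lines if not ln.startswith("# ")]
    header = lines[0].split("\t")
    stage_row = lines[1].split("\t")
    if header[:2] != ["id", "class"] or stage_row[0] != "#stage":
        raise ValueError(f"malformed counts header in {path}")
    samples = header[2:]
    stages = pd.Series(stage_row[2:], index=samples)
    ids, classes, data = [], [], []
    for ln in lines[2:]:
        parts = ln.split("\t")
        ids.append(parts[0])
        classes.append(parts[1])
        data.append([float(x) for x in parts[2:]])
    counts = pd.DataFrame(data, index=ids, columns=samples)
    return ExpressionMatrix(counts=counts, classes=pd.Series(classes, index=ids), stages=stages)


def write_de_table(records: list[DERecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "id": [r.id for r in records],
            "class": [r.rna_class for r in records],
            "log2fc": [r.log2fc for r in records],
            "pvalue": [r.pvalue for r in records],
            "direction": [r.direction for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_de_table(path: str | Path) -> list[DERecord]:
    df = pd.read_csv(path, sep="\t")
    required = {"id", "class", "log2fc", "pvalue"}
    if not required.issubset(df.columns):
        raise ValueError(f"DE table {path} must have columns {sorted(required)}")
    return [
        DERecord(id=str(r.id), rna_class=str(r["class"]), log2fc=float(r.log2fc), pvalue=float(r.pvalue))
        for _, r in df.iterrows()
    ]


def read_qpcr(path: str | Path) -> list[QpcrMeasurement]:
    df = pd.read_csv(path, sep="\t")
    return [
        QpcrMeasurement(
            sample_id=str(r.sample_id), group=str(r.group),
            ct_target=float(r.ct_target), ct_reference=float(r.ct_reference),
        )
        for _, r in df.iterrows()
    ]
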