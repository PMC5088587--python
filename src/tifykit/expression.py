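"""RPKM quantification, expression binning, stress-response calls and qPCR
fold changes.

RPKM = counts * 1e9 / (library size * gene length in bp).  Under control
conditions a gene is highly expressed at log2 RPKM > 4, moderately expressed
between 1 and 4 (both boundaries inclusive) and otherwise in the low/absent
bin.  A gene responds to a stress when the RPKM fold change against control
exceeds 2 at any treated timepoint (up), or falls below 1/2 without an up
call (down).  A small RPKM pseudocount keeps fold changes defined at
near-zero control expression.  qPCR fold changes use the 2^-ddCt method on
triplicate-mean Cq values against a reference gene.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .sequence_io import CountMatrix

LEVELS = ("high", "moderate", "low_or_absent")
RESPONSES = ("up", "down", "none")

DEFAULT_PSEUDOCOUNT = 0.01
DEFAULT_FOLD_THRESHOLD = 2.0
LEVEL_BINS = (1.0, 4.0)  # log2 RPKM boundaries, both assigned to 'moderate'


def rpkm(counts: CountMatrix) -> pd.DataFrame:
    """Reads per kilobase of exon model per million mapped reads, per gene
    and sample."""
    lib = counts.library_size.astype(float)
    length = counts.gene_length_bp.astype(float)
    return counts.counts.astype(float) * 1e9 / lib / length.values[:, None]


def classify_level(
    rpkm_control: float,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    bins: tuple[float, float] = LEVEL_BINS,
) -> str:
    """Expression-level bin from the control-sample RPKM."""
    if rpkm_control < 0:
        raise ValueError("RPKM must be non-negative")
    x = math.log2(rpkm_control + pseudocount)
    low, high = bins
    if x > high:
        return "high"
    if x >= low:
        return "moderate"
    return "low_or_absent"


def classify_response(
    rpkm_control: float,
    rpkm_treated_by_timepoint: Mapping[str, float],
    fold_threshold: float = DEFAULT_FOLD_THRESHOLD,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> tuple[str, dict[str, float]]:
    """Up/down/none call for one stress from per-timepoint fold changes.

    fold(t) = (rpkm_t + pc) / (rpkm_control + pc); up when the maximum fold
    over timepoints exceeds the threshold, down when the minimum falls below
    its reciprocal without an up call.
    """
    if not rpkm_treated_by_timepoint:
        raise ValueError("need at least one treated timepoint")
    folds = {
        t: (v + pseudocount) / (rpkm_control + pseudocount)
        for t, v in rpkm_treated_by_timepoint.items()
    }
    if max(folds.values()) > fold_threshold:
        return "up", folds
    if min(folds.values()) < 1.0 / fold_threshold:
        return "down", folds
    return "none", folds


@dataclass
class ExpressionCall:
    gene_id: str
    level: str
    response: dict[str, str] = field(default_factory=dict)  # condition -> up/down/none
    fold_changes: dict[str, dict[str, float]] = field(default_factory=dict)


def call_expression(
    rpkm_df: pd.DataFrame,
    control_samples: Sequence[str],
    treatments: Mapping[str, Mapping[str, Sequence[str]]],
    fold_threshold: float = DEFAULT_FOLD_THRESHOLD,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> list[ExpressionCall]:
    """Per-gene level and response calls from an RPKM matrix.

    ``treatments`` maps condition -> timepoint -> replicate sample ids;
    replicate RPKM values are averaged before fold-change computation.
    """
    control = rpkm_df[list(control_samples)].mean(axis=1)
    calls = []
    for gene in rpkm_df.index:
        level = classify_level(float(control[gene]), pseudocount)
        responses: dict[str, str] = {}
        folds: dict[str, dict[str, float]] = {}
        for condition, timepoints in treatments.items():
            treated = {
                tp: float(rpkm_df.loc[gene, list(samples)].mean())
                for tp, samples in timepoints.items()
            }
            responses[condition], folds[condition] = classify_response(
                float(control[gene]), treated, fold_threshold, pseudocount
            )
        calls.append(ExpressionCall(gene, level, responses, folds))
    return calls


def round_half_down(x: float) -> int:
    """Round with exact halves going down (9/24 = 37.5% prints as 37%)."""
    return math.ceil(x - 0.5)


@dataclass
class ProfileSummary:
    n_genes: int
    level_counts: dict[str, int]
    level_percent: dict[str, int]
    response_counts: dict[str, dict[str, int]]  # condition -> call -> count
    up_sets: dict[str, list[str]]  # condition -> up-regulated gene ids
    up_overlap: dict[tuple[str, str], int]  # condition pair -> |intersection|


def summarize_profile(calls: Sequence[ExpressionCall]) -> ProfileSummary:
    """Family-level summary: expression-level percentages and per-condition
    response counts, plus the overlap of up-regulated sets between
    conditions."""
    if not calls:
        raise ValueError("no expression calls to summarize")
    n = len(calls)
    level_counts = {lvl: 0 for lvl in LEVELS}
    for c in calls:
        level_counts[c.level] += 1
    level_percent = {
        lvl: round_half_down(100.0 * k / n) for lvl, k in level_counts.items()
    }
    conditions = sorted({cond for c in calls for cond in c.response})
    response_counts = {
        cond: {r: 0 for r in RESPONSES} for cond in conditions
    }
    up_sets: dict[str, list[str]] = {cond: [] for cond in conditions}
    for c in calls:
        for cond, resp in c.response.items():
            response_counts[cond][resp] += 1
            if resp == "up":
                up_sets[cond].append(c.gene_id)
    up_overlap = {}
    for i, c1 in enumerate(conditions):
        for c2 in conditions[i + 1 :]:
            up_overlap[(c1, c2)] = len(set(up_sets[c1]) & set(up_sets[c2]))
    return ProfileSummary(n, level_counts, level_percent, response_counts,
                          up_sets, up_overlap)


# ---------------------------------------------------------------------------
# qPCR


@dataclass
class QpcrRecord:
    """Triplicate Cq values of a target gene and the reference gene per
    sample."""

    gene_id: str
    cq_target: dict[str, list[float]]  # sample -> triplicate Cqs
    cq_reference: dict[str, list[float]]

    def __post_init__(self) -> None:
        for table in (self.cq_target, self.cq_reference):
            for sample, reps in table.items():
                if not reps or any(not math.isfinite(v) or v <= 0 for v in reps):
                    raise ValueError(
                        f"{self.gene_id}/{sample}: Cq values must be finite and > 0"
                    )

    def mean_cq(self, sample: str, reference: bool = False) -> float:
        table = self.cq_reference if reference else self.cq_target
        return float(np.mean(table[sample]))


def ddct_fold(record: QpcrRecord, control_sample: str, treated_sample: str) -> float:
    """Relative expression by the 2^-ddCt method (control normalized to 1).

    dCt = Cq_target - Cq_reference per sample (triplicate means);
    ddCt = dCt_treated - dCt_control; fold = 2^-ddCt.
    """
    for sample in (control_sample, treated_sample):
        if sample not in record.cq_reference or sample not in record.cq_target:
            raise ValueError(f"{record.gene_id}: missing Cq for sample {sample!r}")
    dct_control = record.mean_cq(control_sample) - record.mean_cq(control_sample, True)
    dct_treated = record.mean_cq(treated_sample) - record.mean_cq(treated_sample, True)
    return 2.0 ** (-(dct_treated - dct_control))


def read_qpcr(path) -> list[QpcrRecord]:
    """Read a qPCR TSV (gene_id, sample, replicate, cq_target, cq_ref)."""
    df = pd.read_csv(path, sep="\t")
    records = []
    for gene, sub in df.groupby("gene_id", sort=False):
        tgt: dict[str, list[float]] = {}
        ref: dict[str, list[float]] = {}
        for _, row in sub.iterrows():
            tgt.setdefault(row["sample"], []).append(float(row["cq_target"]))
            ref.setdefault(row["sample"], []).append(float(row["cq_ref"]))
        records.append(QpcrRecord(gene, tgt, ref))
    return records


def write_qpcr(records: Sequence[QpcrRecord], path) -> None:
    rows = []
    for rec in records:
        for sample, reps in rec.cq_target.items():
            for k, cq in enumerate(reps, start=1):
                rows.append(
                    {
                        "gene_id": rec.gene_id,
                        "sample": sample,
                        "replicate": k,
                        "cq_target": round(cq, 4),
                        "cq_ref": round(rec.cq_reference[sample][k - 1], 4),
                    }
                )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
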