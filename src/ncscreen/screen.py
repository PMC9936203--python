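"""CRISPRi candidate selection and screen readout analysis.

Candidate regions are the known and predicted non-coding RNAs with a
significant contrast, ranked by the largest absolute log2 fold change;
regions overlapping metabolic genes, or whose nearest same-strand operon
contains one, are filtered out with the reason recorded.  Screen readouts
are normalized to a gfp-control guide, yield changes are read against the
median-activity baseline with interquartile flags, and qPCR fold changes
use the 2^-ddCt method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .classify import NtrRecord
from .de import DEResults
from .intervals import AnnotatedFeature, AnnotationSet, GenomicInterval

KNOWN_NCRNA_CLASSES = frozenset({"sRNA", "asRNA", "potential_ncRNA"})


@dataclass
class CandidateRegion:
    """A ranked CRISPRi target region."""

    id: str
    region: GenomicInterval
    source: str  # ncRNA_prediction | known_structure
    score: float  # max |log2FC| among significant contrasts
    min_padj: float
    filtered_reason: str | None = None


def _nearest_operon(
    region: GenomicInterval, ann: AnnotationSet
) -> AnnotatedFeature | None:
    best, best_d = None, None
    for f in ann.on(region.seqid, region.strand):
        if f.feature_class != "operon_transcript":
            continue
        iv = f.interval
        d = max(iv.start - region.end, region.start - iv.end, 0)
        if best_d is None or d < best_d:
            best, best_d = f, d
    return best


def _metabolic_reason(region: GenomicInterval, ann: AnnotationSet) -> str | None:
    """Reason text when the region violates the metabolic-neighbourhood rule."""
    for f in ann.features:
        iv = f.interval
        if (
            f.metabolic
            and iv.seqid == region.seqid
            and min(iv.end, region.end) > max(iv.start, region.start)
        ):
            return f"overlaps metabolic gene {f.id}"
    operon = _nearest_operon(region, ann)
    if operon is not None:
        members = [
            f
            for f in ann.features
            if f.operon_id == operon.operon_id and f.feature_class == "coding_gene"
        ]
        for m in members:
            if m.metabolic:
                return f"nearest operon {operon.operon_id} contains metabolic gene {m.id}"
    return None


def select_candidates(
    de: DEResults,
    ntr_records: list[NtrRecord] | None,
    ann: AnnotationSet,
    alpha: float = 0.05,
    structure_logfc_min: float = 1.0,
) -> tuple[list[CandidateRegion], list[CandidateRegion]]:
    """Deterministic candidate selection from DE results.

    Known/predicted ncRNA regions with any significant contrast are ranked
    by descending max |log2FC| (ties: smaller adjusted p, then coordinate);
    RNA-structure features are appended when significant with |log2FC| > 1.
    Returns (selected, filtered-out) lists.
    """
    regions: list[tuple[str, GenomicInterval, str]] = []
    for f in ann.features:
        if f.feature_class in KNOWN_NCRNA_CLASSES:
            regions.append((f.id, f.interval, "ncRNA_prediction"))
        elif f.feature_class == "RNA_structure":
            regions.append((f.id, f.interval, "known_structure"))
    if ntr_records:
        for i, r in enumerate(ntr_records):
            if r.antisense_rrna and r.labels <= {"asRNA"}:
                continue  # antisense-to-rRNA records excluded from DE
            regions.append((f"ntr_{i:04d}", r.interval, "ncRNA_prediction"))

    selected: list[CandidateRegion] = []
    filtered: list[CandidateRegion] = []
    for rid, iv, source in regions:
        if rid not in de.significant.index:
            continue
        flags = de.significant.loc[rid]
        if not flags.any():
            continue
        lfc = de.logfc.loc[rid].abs().where(flags)
        score = float(lfc.max())
        padj = de.p_stagewise.loc[rid].where(flags)
        min_padj = float(padj.min())
        if source == "known_structure" and score <= structure_logfc_min:
            continue
        cand = CandidateRegion(
            id=rid, region=iv, source=source, score=score, min_padj=min_padj
        )
        reason = _metabolic_reason(iv, ann)
        if reason is not None:
            cand.filtered_reason = reason
            filtered.append(cand)
        else:
            selected.append(cand)

    def sort_key(c: CandidateRegion):
        return (
            0 if c.source == "ncRNA_prediction" else 1,
            -c.score,
            c.min_padj,
            c.region.seqid,
            c.region.start,
            c.region.end,
        )

    selected.sort(key=sort_key)
    return selected, filtered


def candidates_to_frame(candidates: list[CandidateRegion]) -> pd.DataFrame:
    rows = [
        {
            "id": c.id,
            "seqid": c.region.seqid,
            "start": c.region.start,
            "end": c.region.end,
            "strand": c.region.strand,
            "source": c.source,
            "max_abs_logfc": c.score,
            "min_padj": c.min_padj,
            "filtered_reason": c.filtered_reason,
        }
        for c in candidates
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# plate readout
# ---------------------------------------------------------------------------


def relative_activity(
    plate: pd.DataFrame, control_guide: str
) -> pd.DataFrame:
    """Per-guide replicate-mean activity normalized to the control guide.

    ``plate`` columns: guide, replicate, activity.  Returns a frame indexed
    by guide with ``relative_activity`` and propagated ``rel_sd``.
    """
    if control_guide not in set(plate["guide"]):
        raise ValueError(f"control guide {control_guide!r} absent from plate")
    grouped = plate.groupby("guide")["activity"]
    means = grouped.mean()
    sds = grouped.std(ddof=1).fillna(0.0)
    c = means[control_guide]
    if c == 0:
        raise ValueError("control guide mean activity is zero")
    return pd.DataFrame(
        {"relative_activity": means / c, "rel_sd": sds / c}
    )


@dataclass
class BaselineResult:
    median: float
    q1: float
    q3: float
    percent_change: pd.Series
    outside_iqr: pd.Series


def baseline_and_flags(relative_activities: pd.Series) -> BaselineResult:
    """Percent deviation from the median-activity baseline, with IQR flags.

    percent change = 100 * (activity - median) / median; a guide is flagged
    when its activity lies strictly outside [Q1, Q3] (linear-interpolation
    quartiles).
    """
    a = relative_activities.astype(float)
    if len(a) < 4:
        raise ValueError("need at least 4 guides for a meaningful baseline")
    med = float(np.median(a))
    q1, q3 = np.percentile(a, [25, 75])
    pct = 100.0 * (a - med) / med
    outside = (a < q1) | (a > q3)
    return BaselineResult(
        median=med, q1=float(q1), q3=float(q3),
        percent_change=pct, outside_iqr=outside,
    )


def od450_final(sample_well: float, blank_well: float) -> float:
    """Plate-reader OD correction: 2.51 x sample minus blank."""
    return 2.51 * sample_well - blank_well


def ddct_fold_change(
    ct_target_sample,
    ct_ref_sample,
    ct_target_control,
    ct_ref_control,
) -> float:
    """2^-ddCt fold change; replicate Ct values are averaged first."""
    t_s = float(np.mean(ct_target_sample))
    r_s = float(np.mean(ct_ref_sample))
    t_c = float(np.mean(ct_target_control))
    r_c = float(np.mean(ct_ref_control))
    ddct = (t_s - r_s) - (t_c - r_c)
    return float(2.0 ** (-ddct))


def batch_consistency(
    yields_batch1: np.ndarray, yields_batch2: np.ndarray
) -> tuple[float, float]:
    """Paired two-sided t-test between two screen batches."""
    a = np.asarray(yields_batch1, dtype=float)
    b = np.asarray(yields_batch2, dtype=float)
    if len(a) != len(b):
        raise ValueError("batches must be paired (equal length)")
    if len(a) < 2:
        raise ValueError("need at least two pairs")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d.mean(), 0.0):
            return 0.0, 1.0
        warnings.warn("zero variance of paired differences with nonzero mean")
        return float(np.inf) if d.mean() > 0 else float(-np.inf), 0.0
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)
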