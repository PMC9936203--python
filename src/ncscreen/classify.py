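"""Novel-transcribed-region extraction and interval-rule classification.

NTRs are the pieces of predicted transcribed regions that fall in
strand-specific annotation gaps (minimum 50 bp).  Each NTR is classified
by interval arithmetic against the reference annotation:

* **asRNA** — at least 90% of the NTR is covered by opposite-strand
  annotation;
* per genomic side, from the nearest same-strand feature: closer than
  100 bp contributes **UTR**, farther than 1000 bp (or no feature at all)
  contributes **sRNA**, and anything in between contributes **unclear**;
* any opposite-strand overlap with an rRNA gene, without cutoff, sets the
  ``antisense_rrna`` flag.

The two sides are evaluated independently, so dual labels such as
{UTR, sRNA} occur.  Boundary reading is literal: fraction exactly 0.90 is
asRNA; distance exactly 100 is not UTR; distance exactly 1000 is not sRNA.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import (
    AnnotationSet,
    GenomicInterval,
    nearest_same_strand_distance,
)


@dataclass
class NtrRecord:
    """A classified novel transcribed region."""

    interval: GenomicInterval
    labels: frozenset[str]
    antisense_rrna: bool
    asrna_overlap_fraction: float
    nearest_same_strand: tuple[int | None, int | None]

    @property
    def length(self) -> int:
        return len(self.interval)


def extract_ntrs(
    transcribed_regions: list[GenomicInterval],
    ann: AnnotationSet,
    min_length: int = 50,
) -> list[GenomicInterval]:
    """Intersect predictions with same-strand annotation gaps.

    Each returned piece has zero same-strand annotation overlap and length
    at least ``min_length``.
    """
    out: list[GenomicInterval] = []
    masks: dict[tuple[str, str], np.ndarray] = {}
    for region in transcribed_regions:
        key = (region.seqid, region.strand)
        if key not in masks:
            masks[key] = ann.strand_mask(*key)
        free = ~masks[key][region.start : region.end]
        # maximal free runs within the region
        padded = np.concatenate([[False], free, [False]])
        diff = np.diff(padded.astype(np.int8))
        for s, e in zip(np.flatnonzero(diff == 1), np.flatnonzero(diff == -1)):
            if e - s >= min_length:
                out.append(
                    GenomicInterval(
                        region.seqid, region.start + int(s), region.start + int(e), region.strand
                    )
                )
    return sorted(out, key=lambda iv: (iv.seqid, iv.strand, iv.start))


def classify(
    ntr: GenomicInterval,
    ann: AnnotationSet,
    asrna_min_frac: float = 0.90,
    utr_max_dist: int = 100,
    srna_min_dist: int = 1000,
) -> NtrRecord:
    """Classify one NTR by the interval rules described in the module docs."""
    same_mask = ann.strand_mask(ntr.seqid, ntr.strand)
    if same_mask[ntr.start : ntr.end].any():
        raise ValueError(
            f"NTR {ntr} overlaps same-strand annotation; it must come from "
            "extract_ntrs"
        )
    opp = "-" if ntr.strand == "+" else "+"
    opp_mask = ann.strand_mask(ntr.seqid, opp)
    frac = float(opp_mask[ntr.start : ntr.end].mean())
    rrna_mask = ann.strand_mask(ntr.seqid, opp, classes={"rRNA"})
    antisense_rrna = bool(rrna_mask[ntr.start : ntr.end].any())

    dists = nearest_same_strand_distance(ntr, ann)
    labels: set[str] = set()
    if frac >= asrna_min_frac:
        labels.add("asRNA")
    for d in dists:
        if d is None or d > srna_min_dist:
            labels.add("sRNA")
        elif d < utr_max_dist:
            labels.add("UTR")
        else:
            labels.add("unclear")
    return NtrRecord(
        interval=ntr,
        labels=frozenset(labels),
        antisense_rrna=antisense_rrna,
        asrna_overlap_fraction=frac,
        nearest_same_strand=dists,
    )


def classify_all(
    ntrs: list[GenomicInterval], ann: AnnotationSet, **kwargs
) -> list[NtrRecord]:
    return [classify(iv, ann, **kwargs) for iv in ntrs]


@dataclass
class ClassificationSummary:
    """Joint and marginal label counts plus a length histogram."""

    marginal: dict[str, int] = field(default_factory=dict)
    joint: dict[frozenset, int] = field(default_factory=dict)
    n_antisense_rrna: int = 0
    length_histogram: pd.Series | None = None


def classification_summary(
    records: list[NtrRecord],
    length_bins: list[int] | None = None,
) -> ClassificationSummary:
    """Count labels jointly and marginally and bin the NTR lengths."""
    marginal: Counter = Counter()
    joint: Counter = Counter()
    for r in records:
        joint[r.labels] += 1
        for lab in r.labels:
            marginal[lab] += 1
    if length_bins is None:
        length_bins = [0, 100, 200, 500, 1000, 10_000_000]
    lengths = [r.length for r in records]
    hist = pd.cut(pd.Series(lengths, dtype=float), bins=length_bins).value_counts().sort_index()
    return ClassificationSummary(
        marginal=dict(marginal),
        joint=dict(joint),
        n_antisense_rrna=sum(r.antisense_rrna for r in records),
        length_histogram=hist,
    )


def records_to_frame(records: list[NtrRecord]) -> pd.DataFrame:
    """Tabulate NTR records (one row per NTR) for TSV output."""
    rows = []
    for i, r in enumerate(records):
        rows.append(
            {
                "ntr_id": f"ntr_{i:04d}",
                "seqid": r.interval.seqid,
                "start": r.interval.start,
                "end": r.interval.end,
                "strand": r.interval.strand,
                "length": r.length,
                "labels": ",".join(sorted(r.labels)),
                "antisense_rrna": r.antisense_rrna,
                "asrna_overlap_fraction": round(r.asrna_overlap_fraction, 4),
                "dist_left": r.nearest_same_strand[0],
                "dist_right": r.nearest_same_strand[1],
            }
        )
    return pd.DataFrame(rows)
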