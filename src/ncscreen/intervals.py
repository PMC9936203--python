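"""Strand-aware genomic intervals and annotation containers.

Coordinates are 0-based half-open throughout ([start, end)), the BED
convention; GFF3 1-based inclusive coordinates are converted on I/O.
Every downstream stage (transcript calling, NTR classification,
candidate selection) builds on these types.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Closed vocabulary of annotation feature classes.
FEATURE_CLASSES = frozenset(
    {
        "coding_gene",
        "sRNA",
        "asRNA",
        "UTR",
        "rRNA",
        "tRNA",
        "tmRNA",
        "SRP",
        "RNaseP",
        "RNA_structure",
        "potential_ncRNA",
        "operon_transcript",
    }
)

STRANDS = ("+", "-")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval [start, end) on one strand of one sequence."""

    seqid: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}): need 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class AnnotatedFeature:
    """A reference annotation: an interval plus class and set labels.

    ``regulons``, ``go_terms`` and ``pathways`` hold the gene-set labels used
    by the enrichment stage; ``metabolic`` marks genes whose neighbourhood
    disqualifies a CRISPRi candidate region.
    """

    interval: GenomicInterval
    id: str
    feature_class: str
    regulons: frozenset[str] = frozenset()
    go_terms: frozenset[str] = frozenset()
    pathways: frozenset[str] = frozenset()
    metabolic: bool = False
    operon_id: str | None = None

    def __post_init__(self) -> None:
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(f"unknown feature class {self.feature_class!r}")
        self.regulons = frozenset(self.regulons)
        self.go_terms = frozenset(self.go_terms)
        self.pathways = frozenset(self.pathways)


@dataclass
class AnnotationSet:
    """Collection of features over sequences of known length."""

    features: list[AnnotatedFeature] = field(default_factory=list)
    seq_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [f.id for f in self.features]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate feature ids: {dup[:5]}")
        for f in self.features:
            length = self.seq_lengths.get(f.interval.seqid)
            if length is None:
                raise ValueError(f"feature {f.id}: unknown seqid {f.interval.seqid}")
            if f.interval.end > length:
                raise ValueError(
                    f"feature {f.id} extends past sequence end "
                    f"({f.interval.end} > {length})"
                )
        self._by_id = {f.id: f for f in self.features}

    def __len__(self) -> int:
        return len(self.features)

    def __getitem__(self, feature_id: str) -> AnnotatedFeature:
        return self._by_id[feature_id]

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self._by_id

    def on(self, seqid: str, strand: str) -> list[AnnotatedFeature]:
        """Features on one (seqid, strand), sorted by start."""
        return sorted(
            (
                f
                for f in self.features
                if f.interval.seqid == seqid and f.interval.strand == strand
            ),
            key=lambda f: (f.interval.start, f.interval.end),
        )

    def strand_mask(
        self, seqid: str, strand: str, classes: set[str] | None = None
    ) -> np.ndarray:
        """Boolean per-base occupancy for same-strand features (bitmap)."""
        if seqid not in self.seq_lengths:
            raise KeyError(f"unknown seqid {seqid!r}")
        mask = np.zeros(self.seq_lengths[seqid], dtype=bool)
        for f in self.on(seqid, strand):
            if classes is None or f.feature_class in classes:
                mask[f.interval.start : f.interval.end] = True
        return mask


def overlap_fraction(
    a: GenomicInterval, b: GenomicInterval, ignore_strand: bool = False
) -> float:
    """Fraction of ``a`` covered by ``b``, in [0, 1].

    Returns 0 for different seqids, and for different strands unless
    ``ignore_strand`` is set.
    """
    if a.seqid != b.seqid:
        return 0.0
    if not ignore_strand and a.strand != b.strand:
        return 0.0
    inter = min(a.end, b.end) - max(a.start, b.start)
    if inter <= 0:
        return 0.0
    return inter / len(a)


def merge_intervals(
    intervals: list[GenomicInterval], merge_abutting: bool = True
) -> list[GenomicInterval]:
    """Union-merge overlapping (and by default abutting) same-strand intervals.

    All inputs must share one (seqid, strand). Output is sorted and disjoint.
    """
    if not intervals:
        return []
    keys = {(iv.seqid, iv.strand) for iv in intervals}
    if len(keys) > 1:
        raise ValueError(f"intervals span multiple (seqid, strand): {sorted(keys)}")
    seqid, strand = keys.pop()
    ordered = sorted(intervals, key=lambda iv: (iv.start, iv.end))
    out: list[list[int]] = [[ordered[0].start, ordered[0].end]]
    for iv in ordered[1:]:
        last = out[-1]
        joined = iv.start <= last[1] if merge_abutting else iv.start < last[1]
        if joined:
            last[1] = max(last[1], iv.end)
        else:
            out.append([iv.start, iv.end])
    return [GenomicInterval(seqid, s, e, strand) for s, e in out]


def strand_gaps(ann: AnnotationSet, seqid: str, strand: str) -> list[GenomicInterval]:
    """Maximal intervals on (seqid, strand) covered by no same-strand feature.

    The returned gaps are sorted and disjoint, and together with the
    same-strand feature union they tile [0, seq_length).
    """
    if seqid not in ann.seq_lengths:
        raise KeyError(f"unknown seqid {seqid!r}")
    length = ann.seq_lengths[seqid]
    covered = merge_intervals([f.interval for f in ann.on(seqid, strand)])
    gaps: list[GenomicInterval] = []
    cursor = 0
    for iv in covered:
        if iv.start > cursor:
            gaps.append(GenomicInterval(seqid, cursor, iv.start, strand))
        cursor = max(cursor, iv.end)
    if cursor < length:
        gaps.append(GenomicInterval(seqid, cursor, length, strand))
    return gaps


def nearest_same_strand_distance(
    x: GenomicInterval, ann: AnnotationSet
) -> tuple[int | None, int | None]:
    """Edge-to-edge gap (bp) to the nearest same-strand feature on each side.

    Returns ``(upstream_gap, downstream_gap)`` in genomic orientation (left,
    right); ``None`` where no same-strand feature exists on that side. An
    abutting or overlapping feature gives distance 0 on the relevant side(s).
    """
    left: int | None = None
    right: int | None = None
    for f in ann.on(x.seqid, x.strand):
        iv = f.interval
        if iv.end <= x.start:
            d = x.start - iv.end
            left = d if left is None else min(left, d)
        elif iv.start >= x.end:
            d = iv.start - x.end
            right = d if right is None else min(right, d)
        else:  # overlapping feature: distance 0 on both covered flanks
            left = 0
            right = 0
    return left, right


def intervals_to_mask(intervals: list[GenomicInterval], length: int) -> np.ndarray:
    """Per-base bitmap of an interval list (test oracle helper)."""
    mask = np.zeros(length, dtype=bool)
    for iv in intervals:
        mask[iv.start : iv.end] = True
    return mask


def mask_to_intervals(
    mask: np.ndarray, seqid: str, strand: str
) -> list[GenomicInterval]:
    """Maximal runs of True in a bitmap as sorted disjoint intervals."""
    padded = np.concatenate([[False], mask.astype(bool), [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.nonzero(diff == 1)[0]
    ends = np.nonzero(diff == -1)[0]
    return [GenomicInterval(seqid, int(s), int(e), strand) for s, e in zip(starts, ends)]
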