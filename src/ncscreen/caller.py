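"""Transcribed-region calling from replicate coverage tracks.

A base is *supported* when at least ``min_replicates`` replicate tracks
reach the height cutoff there.  Runs of unsupported bases are bridged when
short enough: up to ``dip_tolerance_inside`` bp when the whole dip lies
inside a same-strand reference annotation, otherwise up to
``dip_tolerance_outside`` bp.  Maximal bridged runs become the predicted
transcribed regions.  Predictions from uniquely and multi-mapping coverage
are union-merged, and the (height, replicates) parameter grid can be
benchmarked against a reference annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import (
    AnnotationSet,
    GenomicInterval,
    mask_to_intervals,
    merge_intervals,
)


@dataclass
class CoverageTrack:
    """Per-base coverage for one (seqid, strand, replicate, mapping class)."""

    seqid: str
    strand: str
    replicate: str
    mapping_class: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("coverage values must be one-dimensional")
        if (self.values < 0).any():
            raise ValueError("coverage values must be non-negative")


@dataclass(frozen=True)
class CallerParams:
    """Height cutoff h, replicate support r, and dip tolerances (bp)."""

    height_cutoff: float = 5.0
    min_replicates: int = 2
    dip_tolerance_outside: int = 10
    dip_tolerance_inside: int = 50

    def __post_init__(self) -> None:
        if self.height_cutoff < 1:
            raise ValueError("height_cutoff must be >= 1")
        if self.min_replicates < 1:
            raise ValueError("min_replicates must be >= 1")
        if not (0 <= self.dip_tolerance_outside <= self.dip_tolerance_inside):
            raise ValueError("need 0 <= dip_tolerance_outside <= dip_tolerance_inside")


def call_regions(
    tracks: list[CoverageTrack],
    params: CallerParams,
    ann: AnnotationSet | None = None,
) -> list[GenomicInterval]:
    """Call transcribed regions from replicate tracks of one
    (seqid, strand, mapping class).

    ``ann`` supplies the same-strand reference mask used for the larger
    inside-annotation dip tolerance; with no annotation the outside
    tolerance applies everywhere.
    """
    if not tracks:
        return []
    keys = {(t.seqid, t.strand, t.mapping_class) for t in tracks}
    if len(keys) > 1:
        raise ValueError(f"tracks span multiple (seqid, strand, class): {sorted(keys)}")
    lengths = {len(t.values) for t in tracks}
    if len(lengths) > 1:
        raise ValueError(f"mismatched track lengths: {sorted(lengths)}")
    seqid, strand, _ = keys.pop()
    length = lengths.pop()

    support = np.zeros(length, dtype=np.int32)
    for t in tracks:
        support += t.values >= params.height_cutoff
    seed = support >= params.min_replicates
    if not seed.any():
        return []

    inside = (
        ann.strand_mask(seqid, strand)
        if ann is not None
        else np.zeros(length, dtype=bool)
    )
    bridged = _bridge_dips(
        seed, inside, params.dip_tolerance_outside, params.dip_tolerance_inside
    )
    return mask_to_intervals(bridged, seqid, strand)


def _bridge_dips(
    seed: np.ndarray, inside: np.ndarray, t_out: int, t_in: int
) -> np.ndarray:
    """Fill sub-threshold runs between supported runs when short enough."""
    out = seed.copy()
    edges = np.flatnonzero(np.diff(seed.astype(np.int8)))
    # runs of False strictly between True runs: pair (fall, rise) edges
    falls = edges[np.flatnonzero(seed[edges])]  # True -> False at index+1
    for fall in falls:
        rise = fall + 1
        while rise < len(seed) and not seed[rise]:
            rise += 1
        if rise >= len(seed):
            break  # trailing gap: never bridged
        gap_len = rise - (fall + 1)
        tol = t_in if inside[fall + 1 : rise].all() else t_out
        if gap_len <= tol:
            out[fall + 1 : rise] = True
    return out


def combine_mapping_classes(
    unique_regions: list[GenomicInterval],
    multi_regions: list[GenomicInterval],
) -> list[GenomicInterval]:
    """Union-merge predictions from the two mapping classes (same strand)."""
    merged = list(unique_regions) + list(multi_regions)
    if not merged:
        return []
    return merge_intervals(merged)


@dataclass
class BenchmarkCell:
    """Benchmark summary for one (height, replicates) parameter pair."""

    height_cutoff: float
    min_replicates: int
    recall_known: float
    novel_fraction: float
    n_predictions: int
    five_prime_offsets: np.ndarray = field(default_factory=lambda: np.array([]))
    three_prime_offsets: np.ndarray = field(default_factory=lambda: np.array([]))


def matched_end_offsets(
    predictions: list[GenomicInterval], reference: GenomicInterval
) -> tuple[int, int] | None:
    """Signed 5'/3' end offsets of the best-overlapping prediction.

    Negative means the predicted end lies upstream of the reference end
    (transcript orientation: upstream is lower coordinate on '+', higher
    on '-').
    """
    best, best_ov = None, 0
    for p in predictions:
        ov = min(p.end, reference.end) - max(p.start, reference.start)
        if ov > best_ov:
            best, best_ov = p, ov
    if best is None:
        return None
    if reference.strand == "+":
        return best.start - reference.start, best.end - reference.end
    return reference.end - best.end, reference.start - best.start


def benchmark_grid(
    tracks: list[CoverageTrack],
    ann: AnnotationSet,
    h_range: range | list[float] = range(1, 21),
    r_range: range | list[int] | None = None,
    dip_tolerance_outside: int = 10,
    dip_tolerance_inside: int = 50,
    reference_classes: set[str] | None = None,
) -> pd.DataFrame:
    """Benchmark every (height, replicates) pair against the annotation.

    ``recall_known`` is the fraction of reference features overlapped (>= 1
    bp, same strand) by a prediction; ``novel_fraction`` the fraction of
    predictions with no same-strand reference overlap.  End offsets are
    summarized by their medians.
    """
    n_reps = len({t.replicate for t in tracks})
    if r_range is None:
        r_range = range(1, n_reps + 1)
    refs = [
        f.interval
        for f in ann.features
        if reference_classes is None or f.feature_class in reference_classes
    ]
    groups: dict[tuple[str, str, str], list[CoverageTrack]] = {}
    for t in tracks:
        groups.setdefault((t.seqid, t.strand, t.mapping_class), []).append(t)

    rows = []
    for h in h_range:
        for r in r_range:
            params = CallerParams(
                height_cutoff=h,
                min_replicates=r,
                dip_tolerance_outside=dip_tolerance_outside,
                dip_tolerance_inside=dip_tolerance_inside,
            )
            by_strand: dict[tuple[str, str], dict[str, list[GenomicInterval]]] = {}
            for (seqid, strand, mc), grp in groups.items():
                by_strand.setdefault((seqid, strand), {})[mc] = call_regions(
                    grp, params, ann
                )
            preds: list[GenomicInterval] = []
            for classes in by_strand.values():
                preds.extend(
                    combine_mapping_classes(
                        classes.get("unique", []), classes.get("multi", [])
                    )
                )
            cell = _score_cell(preds, refs, h, r)
            rows.append(
                {
                    "height_cutoff": h,
                    "min_replicates": r,
                    "recall_known": cell.recall_known,
                    "novel_fraction": cell.novel_fraction,
                    "n_predictions": cell.n_predictions,
                    "median_5p_offset": (
                        float(np.median(cell.five_prime_offsets))
                        if cell.five_prime_offsets.size
                        else np.nan
                    ),
                    "median_3p_offset": (
                        float(np.median(cell.three_prime_offsets))
                        if cell.three_prime_offsets.size
                        else np.nan
                    ),
                }
            )
    return pd.DataFrame(rows)


def _score_cell(
    preds: list[GenomicInterval],
    refs: list[GenomicInterval],
    h: float,
    r: int,
) -> BenchmarkCell:
    def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
        return (
            a.seqid == b.seqid
            and a.strand == b.strand
            and min(a.end, b.end) > max(a.start, b.start)
        )

    recalled = 0
    offs5, offs3 = [], []
    for ref in refs:
        same = [p for p in preds if overlaps(p, ref)]
        if same:
            recalled += 1
            off = matched_end_offsets(same, ref)
            if off is not None:
                offs5.append(off[0])
                offs3.append(off[1])
    novel = sum(1 for p in preds if not any(overlaps(p, ref) for ref in refs))
    return BenchmarkCell(
        height_cutoff=h,
        min_replicates=r,
        recall_known=recalled / len(refs) if refs else 0.0,
        novel_fraction=novel / len(preds) if preds else 0.0,
        n_predictions=len(preds),
        five_prime_offsets=np.asarray(offs5),
        three_prime_offsets=np.asarray(offs3),
    )
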