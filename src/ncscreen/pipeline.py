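"""End-to-end drivers tying the stages together.

Used by the analysis scripts, the test suite and the acceptance script so
that every consumer runs the identical computation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import de, simulate
from .caller import CallerParams, CoverageTrack, call_regions, combine_mapping_classes
from .classify import NtrRecord, classify_all, extract_ntrs
from .intervals import AnnotationSet, GenomicInterval


def call_and_classify(
    tracks: list[CoverageTrack],
    ann: AnnotationSet,
    params: CallerParams | None = None,
    min_length: int = 50,
) -> tuple[list[GenomicInterval], list[NtrRecord]]:
    """Coverage tracks -> combined transcribed regions -> classified NTRs."""
    params = params or CallerParams()
    groups: dict[tuple[str, str, str], list[CoverageTrack]] = {}
    for t in tracks:
        groups.setdefault((t.seqid, t.strand, t.mapping_class), []).append(t)
    regions: list[GenomicInterval] = []
    for (seqid, strand) in sorted({(k[0], k[1]) for k in groups}):
        unique = call_regions(groups.get((seqid, strand, "unique"), []), params, ann)
        multi = call_regions(groups.get((seqid, strand, "multi"), []), params, ann)
        regions.extend(combine_mapping_classes(unique, multi))
    ntrs = extract_ntrs(regions, ann, min_length=min_length)
    return regions, classify_all(ntrs, ann)


def jaccard(a: GenomicInterval, b: GenomicInterval) -> float:
    inter = max(0, min(a.end, b.end) - max(a.start, b.start))
    return inter / (len(a) + len(b) - inter)


def ntr_recovery(
    records: list[NtrRecord],
    planted: list[tuple[GenomicInterval, str]],
    min_jaccard: float = 0.8,
) -> float:
    """Fraction of planted NTRs recovered with the intended class label."""
    hit = 0
    for iv, cls in planted:
        for r in records:
            if (
                r.interval.strand == iv.strand
                and jaccard(r.interval, iv) >= min_jaccard
                and cls in r.labels
            ):
                hit += 1
                break
    return hit / len(planted) if planted else 1.0


def stagewise_fdr_simulation(
    seed: int,
    n_genes: int = 2000,
    fraction_de: float = 0.10,
    alpha: float = 0.05,
    naive_alpha: float | None = None,
) -> dict[str, float]:
    """One replicate of the stage-wise FDR experiment on synthetic counts.

    Simulates the 2x2 design (2 replicates), runs the full DE pipeline at
    nominal overall FDR ``alpha``, and scores gene-level false discoveries
    against the planted truth.  Optionally also scores the naive
    per-contrast-BH-then-union comparator at ``naive_alpha``.
    """
    counts, design, truth = simulate.simulate_counts(
        n_genes=n_genes, fraction_de=fraction_de, seed=seed
    )
    res = de.run_de(counts, design, alpha=alpha)
    nulls = set(truth.null_genes())
    sig = res.table.index[res.table["significant_any"]]
    fp = sum(1 for g in sig if g in nulls)
    out = {
        "n_sig": float(len(sig)),
        "fdr": fp / max(len(sig), 1),
        "tp": float(len(sig) - fp),
        "n_null": float(len(nulls)),
    }
    if naive_alpha is not None:
        flags = de.naive_bh_union(res.p_raw, alpha=naive_alpha).any(axis=1)
        nsig = flags.index[flags]
        nfp = sum(1 for g in nsig if g in nulls)
        out["naive_fdr"] = nfp / max(len(nsig), 1)
        out["naive_tp"] = float(len(nsig) - nfp)
    return out


def fdr_experiment(
    seeds: list[int] | np.ndarray,
    n_genes: int = 2000,
    fraction_de: float = 0.10,
    alpha: float = 0.05,
    naive_alpha: float | None = None,
) -> pd.DataFrame:
    """Run :func:`stagewise_fdr_simulation` for every seed."""
    return pd.DataFrame(
        [
            stagewise_fdr_simulation(
                int(s), n_genes=n_genes, fraction_de=fraction_de,
                alpha=alpha, naive_alpha=naive_alpha,
            )
            for s in seeds
        ],
        index=list(seeds),
    )
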