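"""Synthetic inputs with planted ground truth.

Every input the pipeline consumes can be generated here: a bacterial-style
reference annotation (coding genes in operons, UTRs, structural RNAs,
regulon/GO/pathway labels), strand-specific per-base coverage tracks with
planted novel transcripts, a gene x sample count matrix for the
2-strain x 2-day fermentation design with negative-binomial noise and
planted contrast-specific fold changes, 96-well activity readings with a
gfp-control guide, and qPCR Ct tables.  All randomness flows from one
explicit seed through a single numpy Generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .caller import CoverageTrack
from .intervals import AnnotatedFeature, AnnotationSet, GenomicInterval

CONTRAST_NAMES = (
    "strain_day1",
    "strain_day3",
    "time_je1",
    "time_je1zyn",
    "interaction",
)

#: Map from GLM coefficients (strain, day, interaction) to the five
#: pairwise-contrast true log2 fold changes.
_COEF_TO_CONTRAST = np.array(
    [
        [1.0, 0.0, 0.0],  # strain @ day 1
        [1.0, 0.0, 1.0],  # strain @ day 3
        [0.0, 1.0, 0.0],  # time within je1
        [0.0, 1.0, 1.0],  # time within je1zyn
        [0.0, 0.0, 1.0],  # interaction
    ]
)


@dataclass
class SyntheticTruth:
    """Planted ground truth for one simulated data set."""

    planted_ntrs: list[tuple[GenomicInterval, str]] = field(default_factory=list)
    de_truth: dict[str, np.ndarray] = field(default_factory=dict)
    dispersions: dict[str, float] = field(default_factory=dict)
    size_factors: dict[str, float] = field(default_factory=dict)
    guide_effects: dict[str, float] = field(default_factory=dict)
    expressed_units: dict[str, str] = field(default_factory=dict)  # id -> mapping class

    def null_genes(self) -> list[str]:
        """Genes whose five true contrast log2FCs are all zero."""
        return [g for g, v in self.de_truth.items() if not np.any(v)]


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

_DEFAULT_REGULONS = {
    "RegA": 40,
    "RegB": 25,
    "RegC": 20,
    "RegD": 15,
    "RegE": 12,
}
_DEFAULT_PATHWAYS = {"path01": 25, "path02": 20, "path03": 18, "path04": 15}


def default_go_dag_spec(n_mid: int = 3, leaves_per_mid: int = 3) -> list[tuple[str, str]]:
    """Edge list (child, parent) of a small rooted GO-like DAG."""
    edges = []
    for i in range(n_mid):
        mid = f"GO:mid{i}"
        edges.append((mid, "GO:root"))
        for j in range(leaves_per_mid):
            edges.append((f"GO:leaf{i}{j}", mid))
    return edges


def make_go_dag(spec: list[tuple[str, str]] | None = None) -> nx.DiGraph:
    """Build the GO DAG (edges child -> parent) from an edge-list spec."""
    dag = nx.DiGraph()
    for child, parent in spec if spec is not None else default_go_dag_spec():
        dag.add_edge(child, parent)
    if not nx.is_directed_acyclic_graph(dag):
        raise ValueError("GO spec contains a cycle")
    return dag


def make_annotation(
    seed: int,
    n_genes: int = 200,
    genome_length: int = 320_000,
    fraction_metabolic: float = 0.3,
    regulon_spec: dict[str, int] | None = None,
    go_dag_spec: list[tuple[str, str]] | None = None,
    pathway_spec: dict[str, int] | None = None,
    n_deserts: int = 4,
    desert_length: int = 6_000,
    seqid: str = "chr",
) -> AnnotationSet:
    """Deterministically lay out a bacterial-style annotation.

    Coding genes are packed left to right with random lengths and intergenic
    gaps, grouped into operons (an ``operon_transcript`` feature spans each
    group); 5' UTRs precede some operons; rRNA/tRNA/tmRNA/SRP/RNaseP and a
    few RNA-structure features are interspersed.  ``n_deserts`` long empty
    stretches and occasional mid-size gaps are left so that independent
    sRNA-like and unclear-distance novel transcripts can later be planted.
    Regulon/GO/pathway labels and metabolic flags are drawn for coding genes.
    """
    rng = np.random.default_rng(seed)
    regulon_spec = regulon_spec if regulon_spec is not None else dict(_DEFAULT_REGULONS)
    pathway_spec = pathway_spec if pathway_spec is not None else dict(_DEFAULT_PATHWAYS)
    go_dag = make_go_dag(go_dag_spec)
    leaf_terms = [n for n in go_dag.nodes if go_dag.in_degree(n) == 0]

    features: list[AnnotatedFeature] = []
    cursor = 0
    placed_genes = 0
    gene_ids: list[str] = []
    operon_counter = 0
    # structural RNAs to intersperse: (class, length, count)
    structural = (
        [("rRNA", 1500)] * 2
        + [("tRNA", 80)] * 4
        + [("tmRNA", 350)]
        + [("SRP", 270)]
        + [("RNaseP", 400)]
        + [("RNA_structure", 150)] * 8
        + [("sRNA", 150)] * 3
        + [("potential_ncRNA", 200)] * 2
    )
    struct_slots = (
        sorted(rng.choice(max(n_genes, len(structural)), size=len(structural), replace=False))
        if n_genes > 0
        else []
    )
    desert_slots = (
        sorted(np.linspace(0, n_genes, n_deserts + 2, dtype=int)[1:-1]) if n_genes > 0 else []
    )
    struct_i = 0
    struct_slots_set = {int(s) for s in struct_slots}

    def emit(fclass: str, length: int, strand: str, fid: str, operon_id=None):
        nonlocal cursor
        if cursor + length > genome_length:
            raise ValueError(
                f"infeasible packing: genome_length={genome_length} too small "
                f"for the requested features (needed > {cursor + length})"
            )
        iv = GenomicInterval(seqid, cursor, cursor + length, strand)
        features.append(
            AnnotatedFeature(interval=iv, id=fid, feature_class=fclass, operon_id=operon_id)
        )
        cursor += length
        return iv

    while placed_genes < n_genes:
        if desert_slots and placed_genes >= desert_slots[0]:
            cursor += desert_length
            desert_slots.pop(0)
        if placed_genes in struct_slots_set and struct_i < len(structural):
            fclass, length = structural[struct_i]
            emit(fclass, length, rng.choice(["+", "-"]), f"{fclass.lower()}_{struct_i}")
            struct_i += 1
            cursor += int(rng.integers(80, 300))
        # every ~15 genes leave a mid-size gap (unclear-distance plant sites)
        if placed_genes > 0 and placed_genes % 15 == 0:
            cursor += int(rng.integers(800, 1300))
        strand = str(rng.choice(["+", "-"]))
        operon_size = min(int(rng.integers(1, 5)), n_genes - placed_genes)
        operon_id = f"op_{operon_counter}"
        operon_counter += 1
        operon_start = cursor
        # optional 5' UTR in front of the operon
        if rng.random() < 0.4:
            ulen = int(rng.integers(50, 150))
            emit("UTR", ulen, strand, f"utr5_{operon_id}", operon_id=operon_id)
        members = []
        for k in range(operon_size):
            glen = int(rng.integers(400, 1500))
            gid = f"gene_{placed_genes:04d}"
            emit("coding_gene", glen, strand, gid, operon_id=operon_id)
            gene_ids.append(gid)
            members.append(gid)
            placed_genes += 1
            if k < operon_size - 1:
                cursor += int(rng.integers(20, 60))  # small intra-operon spacer
        operon_end = cursor
        if operon_end > operon_start:
            iv = GenomicInterval(seqid, operon_start, operon_end, strand)
            features.append(
                AnnotatedFeature(
                    interval=iv,
                    id=f"tx_{operon_id}",
                    feature_class="operon_transcript",
                    operon_id=operon_id,
                )
            )
        cursor += int(rng.integers(170, 420))  # intergenic gap

    if struct_i < len(structural) and n_genes > 0:
        for fclass, length in structural[struct_i:]:
            emit(fclass, length, rng.choice(["+", "-"]), f"{fclass.lower()}_{struct_i}")
            struct_i += 1
            cursor += int(rng.integers(80, 300))

    if cursor > genome_length:
        raise ValueError("infeasible packing: ran past genome end")

    # --- labels on coding genes ------------------------------------------
    by_id = {f.id: f for f in features}
    if gene_ids:
        for reg, size in regulon_spec.items():
            if size > len(gene_ids):
                raise ValueError(f"regulon {reg} size {size} exceeds gene count")
            for gid in rng.choice(gene_ids, size=size, replace=False):
                f = by_id[gid]
                f.regulons = f.regulons | {reg}
        for pw, size in pathway_spec.items():
            chosen = set(rng.choice(gene_ids, size=min(size, len(gene_ids)), replace=False))
            for gid in chosen:
                f = by_id[gid]
                f.pathways = f.pathways | {pw}
        n_metab = int(round(fraction_metabolic * len(gene_ids)))
        for gid in rng.choice(gene_ids, size=n_metab, replace=False):
            by_id[gid].metabolic = True
        for gid in gene_ids:
            n_terms = int(rng.integers(0, 3))
            if n_terms and leaf_terms:
                terms = rng.choice(leaf_terms, size=min(n_terms, len(leaf_terms)), replace=False)
                f = by_id[gid]
                f.go_terms = f.go_terms | set(terms)

    return AnnotationSet(features=features, seq_lengths={seqid: genome_length})


# ---------------------------------------------------------------------------
# planting novel transcribed regions
# ---------------------------------------------------------------------------


def plant_ntrs(
    ann: AnnotationSet,
    seed: int,
    n_asrna: int = 5,
    n_utr: int = 5,
    n_srna: int = 3,
    n_unclear: int = 2,
    length_range: tuple[int, int] = (120, 250),
) -> list[tuple[GenomicInterval, str]]:
    """Choose planted NTR intervals whose class is unambiguous by geometry.

    asRNA plants lie fully inside an opposite-strand coding gene; UTR plants
    sit in a same-strand gap with both flank distances < 100 bp; sRNA plants
    sit in empty deserts (> 1000 bp clearance both sides, both strands);
    unclear plants have both flank distances in [100, 1000].  Every plant
    lies in a strand-specific annotation gap of ``ann``.
    """
    rng = np.random.default_rng(seed)
    (seqid,) = ann.seq_lengths
    masks = {s: ann.strand_mask(seqid, s) for s in "+-"}
    rrna_masks = {s: ann.strand_mask(seqid, s, classes={"rRNA"}) for s in "+-"}
    planted_mask = {s: np.zeros_like(masks[s]) for s in "+-"}
    plants: list[tuple[GenomicInterval, str]] = []

    def free(iv: GenomicInterval) -> bool:
        sl = slice(iv.start, iv.end)
        return not (masks[iv.strand][sl].any() or planted_mask[iv.strand][sl].any())

    def take(iv: GenomicInterval, cls: str) -> None:
        planted_mask[iv.strand][iv.start : iv.end] = True
        plants.append((iv, cls))

    opp = {"+": "-", "-": "+"}

    # asRNA: interior of an opposite-strand coding gene
    genes = [f for f in ann.features if f.feature_class == "coding_gene"]
    rng.shuffle(genes)
    placed = 0
    for g in genes:
        if placed >= n_asrna:
            break
        giv = g.interval
        L = int(rng.integers(*length_range))
        if len(giv) < L + 100:
            continue
        start = giv.start + 50
        iv = GenomicInterval(seqid, start, start + L, opp[giv.strand])
        if free(iv) and not rrna_masks[giv.strand][iv.start : iv.end].any():
            take(iv, "asRNA")
            placed += 1
    if placed < n_asrna:
        raise ValueError(f"could only plant {placed}/{n_asrna} asRNAs")

    # helper: gaps between consecutive same-strand features
    def bounded_gaps(strand: str) -> list[tuple[int, int]]:
        feats = ann.on(seqid, strand)
        out = []
        for a, b in zip(feats, feats[1:]):
            if b.interval.start > a.interval.end:
                out.append((a.interval.end, b.interval.start))
        return out

    for cls, n_wanted, side_lo, side_hi in (
        ("UTR", n_utr, 0, 99),
        ("unclear", n_unclear, 100, 1000),
    ):
        placed = 0
        for strand in rng.permutation(["+", "-"]):
            for gs, ge in rng.permutation(bounded_gaps(strand)).tolist():
                if placed >= n_wanted:
                    break
                glen = ge - gs
                Lmin, Lmax = length_range
                # both side distances in [side_lo, side_hi]
                lo_needed = 2 * max(side_lo, 20) + Lmin
                if glen < lo_needed or glen > 2 * side_hi + Lmax:
                    continue
                side = max(side_lo, 20, (glen - Lmax) // 2)
                if side > side_hi:
                    continue
                L = glen - 2 * side
                if not (Lmin <= L <= Lmax):
                    continue
                iv = GenomicInterval(seqid, gs + side, gs + side + L, strand)
                # keep the class crisp: no near-total antisense overlap
                opp_cov = masks[opp[strand]][iv.start : iv.end].mean()
                if free(iv) and opp_cov < 0.5 and not rrna_masks[opp[strand]][iv.start : iv.end].any():
                    take(iv, cls)
                    placed += 1
            if placed >= n_wanted:
                break
        if placed < n_wanted:
            raise ValueError(f"could only plant {placed}/{n_wanted} {cls} NTRs")

    # sRNA: deserts with > 1000 bp clearance on both sides, both strands
    both = masks["+"] | masks["-"] | planted_mask["+"] | planted_mask["-"]
    runs = np.flatnonzero(np.diff(np.concatenate([[1], both.astype(np.int8), [1]])))
    placed = 0
    for rs, re in zip(runs[::2], runs[1::2]):
        if placed >= n_srna:
            break
        L = int(rng.integers(*length_range))
        if re - rs < 2 * 1100 + L:
            continue
        mid = (rs + re) // 2
        iv = GenomicInterval(seqid, mid - L // 2, mid - L // 2 + L, str(rng.choice(["+", "-"])))
        if free(iv):
            take(iv, "sRNA")
            placed += 1
    if placed < n_srna:
        raise ValueError(f"could only plant {placed}/{n_srna} sRNAs")

    return plants


# ---------------------------------------------------------------------------
# coverage
# ---------------------------------------------------------------------------


def simulate_coverage(
    ann: AnnotationSet,
    planted_ntrs: list[tuple[GenomicInterval, str]],
    n_replicates: int = 2,
    mapping_classes: tuple[str, ...] = ("unique", "multi"),
    expression_level: float = 20.0,
    noise_model: str = "poisson",
    seed: int = 0,
    background: float = 0.2,
    expressed_fraction: float = 0.8,
    multi_fraction: float = 0.15,
) -> tuple[list[CoverageTrack], SyntheticTruth]:
    """Per-base strand-specific coverage with planted NTR plateaus.

    Coverage is a plateau of height ``expression_level`` over each expressed
    annotation feature and every planted NTR, near zero elsewhere; with
    ``noise_model='poisson'`` per-base values are Poisson draws around the
    plateau (or around ``background`` off-plateau), with ``'none'`` the exact
    step function.  Each expressed unit is assigned to one mapping class
    (``multi`` with probability ``multi_fraction``), so recovering all plants
    requires combining both mapping-class predictions.
    """
    if noise_model not in ("poisson", "none"):
        raise ValueError(f"unknown noise model {noise_model!r}")
    rng = np.random.default_rng(seed)
    (seqid,) = ann.seq_lengths
    length = ann.seq_lengths[seqid]
    truth = SyntheticTruth(planted_ntrs=list(planted_ntrs))

    units: list[tuple[str, GenomicInterval]] = []
    for f in ann.features:
        if f.feature_class == "operon_transcript":
            continue
        if rng.random() < expressed_fraction:
            units.append((f.id, f.interval))
    for i, (iv, cls) in enumerate(planted_ntrs):
        units.append((f"ntr_{i}_{cls}", iv))

    for uid, iv in units:
        mc = "multi" if (rng.random() < multi_fraction and "multi" in mapping_classes) else mapping_classes[0]
        truth.expressed_units[uid] = mc

    # plateau template per (strand, mapping class)
    template = {
        (s, mc): np.zeros(length) for s in "+-" for mc in mapping_classes
    }
    for uid, iv in units:
        mc = truth.expressed_units[uid]
        template[(iv.strand, mc)][iv.start : iv.end] = expression_level

    tracks: list[CoverageTrack] = []
    for strand in "+-":
        for mc in mapping_classes:
            base = template[(strand, mc)]
            for rep in range(1, n_replicates + 1):
                if noise_model == "none":
                    values = base.copy()
                else:
                    lam = np.where(base > 0, base, background)
                    values = rng.poisson(lam).astype(float)
                tracks.append(
                    CoverageTrack(
                        seqid=seqid,
                        strand=strand,
                        replicate=f"rep{rep}",
                        mapping_class=mc,
                        values=values,
                    )
                )
    return tracks, truth


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------


def make_design(n_reps: int = 2) -> pd.DataFrame:
    """Sample sheet for the 2-strain x 2-day fermentation design."""
    rows = []
    for strain in ("je1", "je1zyn"):
        for day in (1, 3):
            for rep in range(1, n_reps + 1):
                rows.append(
                    {
                        "sample": f"{strain}_d{day}_r{rep}",
                        "strain": strain,
                        "day": day,
                        "replicate": rep,
                    }
                )
    return pd.DataFrame(rows).set_index("sample")


def simulate_counts(
    n_genes: int = 2000,
    n_reps: int = 2,
    gene_ids: list[str] | None = None,
    baseline_mean_log2_range: tuple[float, float] = (3.0, 12.0),
    dispersion_range: tuple[float, float] = (0.01, 0.5),
    fraction_de: float = 0.10,
    effect_size_range: tuple[float, float] = (1.0, 3.0),
    size_factor_range: tuple[float, float] = (0.7, 1.4),
    coherent_groups: dict[str, list[str]] | None = None,
    coherent_effect_size_range: tuple[float, float] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Gene x sample NB counts for the 2x2 design with planted fold changes.

    Counts are NB(mean = s_j * q_gj, variance = mean + alpha_g * mean^2);
    per-gene dispersions alpha_g are log-uniform over ``dispersion_range``;
    a ``fraction_de`` subset of genes receives nonzero strain/day/interaction
    coefficients with |log2FC| in ``effect_size_range`` and random sign, from
    which the five pairwise-contrast truths follow.  Sample size factors are
    log-uniform over ``size_factor_range`` and recorded in the truth.

    ``coherent_groups`` (e.g. regulon id -> member gene ids) emulates
    co-regulation: all members of a group share one drawn coefficient
    pattern, so they form a coherent expression-profile cluster.

    Returns ``(counts, design, truth)``.
    """
    if n_reps < 2:
        raise ValueError("need n_reps >= 2")
    rng = np.random.default_rng(seed)
    design = make_design(n_reps)
    n_samples = len(design)
    if gene_ids is None:
        gene_ids = [f"g{i:05d}" for i in range(n_genes)]
    else:
        n_genes = len(gene_ids)

    base_log2 = rng.uniform(*baseline_mean_log2_range, size=n_genes)
    log_disp = rng.uniform(np.log(dispersion_range[0]), np.log(dispersion_range[1]), size=n_genes)
    alpha = np.exp(log_disp)

    coefs = np.zeros((n_genes, 3))  # strain, day, interaction (log2 scale)
    is_de = rng.random(n_genes) < fraction_de
    subsets = [(1, 0, 0), (0, 1, 0), (0, 0, 1), (1, 1, 0), (1, 0, 1), (0, 1, 1), (1, 1, 1)]
    for g in np.flatnonzero(is_de):
        pattern = subsets[rng.integers(len(subsets))]
        for k in range(3):
            if pattern[k]:
                coefs[g, k] = rng.uniform(*effect_size_range) * rng.choice([-1.0, 1.0])
    if coherent_groups:
        group_range = coherent_effect_size_range or effect_size_range
        index_of = {gid: i for i, gid in enumerate(gene_ids)}
        for name in sorted(coherent_groups):
            pattern = subsets[rng.integers(len(subsets))]
            shared = np.array(
                [
                    rng.uniform(*group_range) * rng.choice([-1.0, 1.0]) if on else 0.0
                    for on in pattern
                ]
            )
            for gid in coherent_groups[name]:
                if gid in index_of:
                    coefs[index_of[gid]] = shared

    s = np.exp(rng.uniform(np.log(size_factor_range[0]), np.log(size_factor_range[1]), size=n_samples))
    s /= np.exp(np.mean(np.log(s)))  # geometric mean 1

    strain_ind = (design["strain"] == "je1zyn").to_numpy().astype(float)
    day_ind = (design["day"] == 3).to_numpy().astype(float)
    design_3 = np.stack([strain_ind, day_ind, strain_ind * day_ind], axis=1)  # (n, 3)
    log2_q = base_log2[:, None] + coefs @ design_3.T  # (G, n)
    mu = s[None, :] * 2.0 ** log2_q

    counts = np.empty((n_genes, n_samples), dtype=np.int64)
    small = alpha < 1e-8
    for j in range(n_samples):
        n_param = 1.0 / np.maximum(alpha, 1e-8)
        p_param = n_param / (n_param + mu[:, j])
        col = rng.negative_binomial(n_param, p_param)
        if small.any():
            col[small] = rng.poisson(mu[small, j])
        counts[:, j] = col

    truth = SyntheticTruth(
        de_truth={
            gid: _COEF_TO_CONTRAST @ coefs[g] for g, gid in enumerate(gene_ids)
        },
        dispersions=dict(zip(gene_ids, alpha)),
        size_factors=dict(zip(design.index, s)),
    )
    counts_df = pd.DataFrame(counts, index=gene_ids, columns=design.index)
    return counts_df, design, truth


# ---------------------------------------------------------------------------
# plate + qPCR
# ---------------------------------------------------------------------------


def simulate_plate(
    guides: list[str],
    control_id: str,
    effects: dict[str, float],
    replicate_cv: float = 0.1,
    n_reps: int = 3,
    seed: int = 0,
    control_level: float = 100.0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Deep-well plate activities: lognormal noise around effect x control."""
    if control_id not in guides:
        raise ValueError(f"control guide {control_id!r} not among guides")
    rng = np.random.default_rng(seed)
    rows = []
    for g in guides:
        eff = effects.get(g, 1.0)
        for rep in range(1, n_reps + 1):
            noise = np.exp(rng.normal(0.0, replicate_cv)) if replicate_cv > 0 else 1.0
            rows.append({"guide": g, "replicate": rep, "activity": eff * control_level * noise})
    truth = SyntheticTruth(guide_effects={g: effects.get(g, 1.0) for g in guides})
    return pd.DataFrame(rows), truth


def simulate_qpcr(
    genes: list[str],
    conditions: list[str],
    true_fold_changes: dict[tuple[str, str], float],
    ct_noise_sd: float = 0.0,
    n_reps: int = 3,
    seed: int = 0,
    reference_gene: str = "citA",
    base_ct: float = 25.0,
    reference_ct: float = 20.0,
) -> pd.DataFrame:
    """Ct table satisfying fold change = 2^-ddCt in the noise-free limit.

    ``conditions[0]`` is the control condition; ``true_fold_changes`` maps
    (gene, condition) to the fold change relative to the control condition.
    The reference gene is constant across conditions.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for cond in conditions:
        for gene in list(genes) + [reference_gene]:
            if gene == reference_gene:
                ct = reference_ct
            else:
                fc = 1.0 if cond == conditions[0] else true_fold_changes.get((gene, cond), 1.0)
                ct = base_ct - np.log2(fc)
            for rep in range(1, n_reps + 1):
                noise = rng.normal(0.0, ct_noise_sd) if ct_noise_sd > 0 else 0.0
                rows.append(
                    {"gene": gene, "condition": cond, "replicate": rep, "ct": ct + noise}
                )
    return pd.DataFrame(rows)
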