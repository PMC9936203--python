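"""Expression profiles, PCA, k-means clustering and over-representation.

The variance-stabilizing transform is log2(normalized count + 1); PCA runs
on the most variable genes; the number of k-means clusters is chosen by
the elbow criterion (maximum perpendicular distance of the within-cluster
sum-of-squares curve from its end-point chord).  Over-representation uses
the one-sided hypergeometric/Fisher test; GO terms are de-correlated with
the elim scheme (genes of a significant specific term are removed from its
ancestors before those are tested); regulon enrichment is BH-adjusted and
reported with representation percentages 100 * overlap / regulon size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .de import bh_adjust

CONDITION_ORDER = ("je1@1", "je1@3", "je1zyn@1", "je1zyn@3")


def transform(
    counts: pd.DataFrame, sf: pd.Series, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Variance-stabilized expression: log2(count / s_j + pseudocount)."""
    if (sf <= 0).any():
        raise ValueError("size factors must be positive")
    return np.log2(counts / sf + pseudocount)


def condition_means(matrix: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Replicate means per condition, columns ordered je1@1..je1zyn@3."""
    cond = design["strain"].astype(str) + "@" + design["day"].astype(str)
    means = {}
    for name in CONDITION_ORDER:
        cols = cond.index[cond == name]
        means[name] = matrix[cols].mean(axis=1)
    return pd.DataFrame(means)[list(CONDITION_ORDER)]


def pca_top_variable(
    matrix: pd.DataFrame, n_top: int = 500, n_components: int | None = None
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples on the ``n_top`` most variable genes.

    Sign convention: each component's largest-magnitude gene loading is
    positive.  Returns (sample coordinates, fraction variance explained).
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least two samples")
    if n_top > len(matrix):
        warnings.warn(f"n_top={n_top} exceeds gene count {len(matrix)}; using all")
        n_top = len(matrix)
    var = matrix.var(axis=1)
    top = var.sort_values(ascending=False, kind="stable").index[:n_top]
    X = matrix.loc[top].to_numpy().T  # samples x genes
    k = n_components or min(X.shape[0] - 1, X.shape[1], 10)
    pca = PCA(n_components=k, svd_solver="full")
    coords = pca.fit_transform(X)
    for i, comp in enumerate(pca.components_):
        if comp[np.argmax(np.abs(comp))] < 0:
            pca.components_[i] = -comp
            coords[:, i] = -coords[:, i]
    cols = [f"PC{i + 1}" for i in range(k)]
    return (
        pd.DataFrame(coords, index=matrix.columns, columns=cols),
        pca.explained_variance_ratio_,
    )


@dataclass
class ElbowResult:
    k: int
    assignments: pd.Series
    centroids: pd.DataFrame
    inertia_curve: pd.Series


def kmeans_elbow(
    profiles: pd.DataFrame,
    k_range: range = range(2, 21),
    seed: int = 0,
    n_init: int = 25,
) -> ElbowResult:
    """k-means with elbow selection of k.

    For each k the best within-cluster sum of squares over ``n_init``
    restarts is kept; the elbow is the k maximizing perpendicular distance
    of the (k, WSS) curve from the chord joining its endpoints.
    """
    ks = list(k_range)
    if len(profiles) < max(ks):
        raise ValueError("need at least max(k_range) profiles")
    X = profiles.to_numpy(dtype=float)
    fits = {}
    inertia = []
    for k in ks:
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        km.fit(X)
        fits[k] = km
        inertia.append(km.inertia_)
    inertia = np.asarray(inertia)
    k_best = ks[_elbow_index(np.asarray(ks, dtype=float), inertia)]
    km = fits[k_best]
    return ElbowResult(
        k=k_best,
        assignments=pd.Series(km.labels_, index=profiles.index, name="cluster"),
        centroids=pd.DataFrame(km.cluster_centers_, columns=profiles.columns),
        inertia_curve=pd.Series(inertia, index=ks, name="wss"),
    )


def _elbow_index(x: np.ndarray, y: np.ndarray) -> int:
    """Index of maximal perpendicular distance from the end-point chord."""
    x0, y0, x1, y1 = x[0], y[0], x[-1], y[-1]
    norm = np.hypot(x1 - x0, y1 - y0)
    d = np.abs((y1 - y0) * x - (x1 - x0) * y + x1 * y0 - y1 * x0) / max(norm, 1e-300)
    return int(np.argmax(d))


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------


@dataclass
class EnrichmentRow:
    """One (gene set, cluster) over-representation result."""

    set_id: str
    cluster_id: str
    set_size: int
    cluster_size: int
    overlap: int
    representation_percent: float
    p_raw: float
    p_adj: float | None = None


def representation_percent(overlap: int, set_size: int) -> float:
    """100 * overlap / set size, rounded to 2 decimals."""
    return round(100.0 * overlap / set_size, 2)


def hypergeom_enrich(
    cluster_genes: set[str],
    gene_set: set[str],
    universe: set[str],
    min_size: int = 10,
    alpha: float = 0.01,
    set_id: str = "",
    cluster_id: str = "",
) -> EnrichmentRow | None:
    """One-sided hypergeometric over-representation test.

    P(X >= overlap) with X ~ Hypergeom(N=|universe|, K=|set|, n=|cluster|).
    Sets smaller than ``min_size`` (within the universe) are skipped
    (returns None).  ``alpha`` is informational; all tested rows are
    returned.
    """
    if not universe:
        raise ValueError("empty universe")
    cluster = set(cluster_genes) & set(universe)
    gset = set(gene_set) & set(universe)
    if len(gset) < min_size:
        return None
    overlap = len(cluster & gset)
    N, K, n = len(universe), len(gset), len(cluster)
    p = float(stats.hypergeom.sf(overlap - 1, N, K, n))
    return EnrichmentRow(
        set_id=set_id,
        cluster_id=cluster_id,
        set_size=K,
        cluster_size=n,
        overlap=overlap,
        representation_percent=representation_percent(overlap, K),
        p_raw=min(p, 1.0),
    )


def propagate_annotations(
    go_dag: nx.DiGraph, gene_to_terms: dict[str, set[str]]
) -> dict[str, set[str]]:
    """Term -> genes map with annotations propagated to all ancestors.

    ``go_dag`` edges point child -> parent.
    """
    if not nx.is_directed_acyclic_graph(go_dag):
        raise ValueError("GO graph is cyclic")
    term_genes: dict[str, set[str]] = {t: set() for t in go_dag.nodes}
    for gene, terms in gene_to_terms.items():
        for t in terms:
            if t not in term_genes:
                term_genes[t] = set()
            term_genes[t].add(gene)
            if t in go_dag:
                for anc in nx.descendants(go_dag, t):  # parents direction
                    term_genes[anc].add(gene)
    return term_genes


def go_elim(
    go_dag: nx.DiGraph,
    gene_to_terms: dict[str, set[str]],
    cluster: set[str],
    universe: set[str],
    alpha: float = 0.01,
    min_size: int = 10,
    cluster_id: str = "",
) -> list[EnrichmentRow]:
    """GO over-representation with elim de-correlation.

    Terms are processed most-specific first (levels by longest path to a
    root, descending); a term significant at ``alpha`` has its annotated
    genes removed from all its ancestors' gene sets before those are
    tested.
    """
    term_genes = propagate_annotations(go_dag, gene_to_terms)
    # longest path to a root (a node with no parent), child->parent edges
    depth: dict[str, int] = {}
    for node in reversed(list(nx.topological_sort(go_dag))):  # parents first
        parents = list(go_dag.successors(node))
        depth[node] = 1 + max(depth[p] for p in parents) if parents else 0
    order = sorted(term_genes, key=lambda t: -depth.get(t, 0))

    eliminated: dict[str, set[str]] = {t: set() for t in term_genes}
    rows: list[EnrichmentRow] = []
    for term in order:
        current = (term_genes[term] - eliminated[term]) & set(universe)
        row = hypergeom_enrich(
            cluster, current, universe, min_size=min_size, alpha=alpha,
            set_id=term, cluster_id=cluster_id,
        )
        significant = row is not None and row.p_raw <= alpha
        if significant:
            rows.append(row)
            if term in go_dag:
                for anc in nx.descendants(go_dag, term):
                    eliminated[anc] |= term_genes[term]
        elif row is not None:
            rows.append(row)
    return rows


def regulon_overrepresentation(
    clusters: dict[str, set[str]],
    regulons: dict[str, set[str]],
    background: set[str],
    min_size: int = 10,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """One-sided Fisher tests of regulon membership per cluster.

    ``background`` is the set of differentially expressed genes; regulons
    are intersected with it (with a warning when genes fall outside) and
    kept only when strictly larger than ``min_size``.  P-values are BH
    adjusted across all tested (regulon, cluster) pairs; rows with adjusted
    p <= alpha are returned with representation percentages.
    """
    background = set(background)
    rows = []
    for reg_id, reg in regulons.items():
        reg = set(reg)
        if reg - background:
            warnings.warn(f"regulon {reg_id}: {len(reg - background)} genes outside background; intersecting")
        reg &= background
        if len(reg) <= min_size:  # strictly greater than min_size required
            continue
        for cl_id, cl in clusters.items():
            cl = set(cl) & background
            overlap = len(cl & reg)
            table = [
                [overlap, len(cl) - overlap],
                [len(reg) - overlap, len(background) - len(cl) - len(reg) + overlap],
            ]
            _, p = stats.fisher_exact(table, alternative="greater")
            rows.append(
                {
                    "set_id": reg_id,
                    "cluster_id": cl_id,
                    "set_size": len(reg),
                    "cluster_size": len(cl),
                    "overlap": overlap,
                    "representation_percent": representation_percent(overlap, len(reg)),
                    "p_raw": float(p),
                }
            )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df["p_adj"] = bh_adjust(df["p_raw"].to_numpy())
    return df[df["p_adj"] <= alpha].sort_values("p_adj").reset_index(drop=True)


def enrichment_frame(rows: list[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in rows])
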