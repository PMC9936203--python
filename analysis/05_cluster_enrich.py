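#!/usr/bin/env python
"""Expression profiles, PCA, k-means clustering and over-representation.

Transforms counts to log2(normalized + 1), checks that samples group by
strain and day on the top-variable-gene PCA, clusters per-condition mean
profiles of the significant features with elbow-selected k, and tests the
clusters for regulon (Fisher/BH), GO (elim) and pathway (hypergeometric)
over-representation.
"""

import pandas as pd

import settings
from ncscreen import de, io, profiles, simulate

counts = pd.read_csv(settings.SCRATCH / "counts.tsv", sep="\t", index_col=0)
design = pd.read_csv(settings.SCRATCH / "design.tsv", sep="\t", index_col=0)
ann = io.read_gff3(settings.SCRATCH / "annotation.gff3")

res = de.run_de(counts, design, ann, alpha=0.05)
mat = profiles.transform(counts.loc[res.table.index], res.size_factors)

coords, var_ratio = profiles.pca_top_variable(mat, n_top=500)
coords.join(design).to_csv(settings.RESULTS / "pca_samples.tsv", sep="\t")

sig_ids = res.table.index[res.table["significant_any"]]
prof = profiles.condition_means(mat.loc[sig_ids], design)
prof = prof.sub(prof.mean(axis=1), axis=0)  # cluster by profile shape
elbow = profiles.kmeans_elbow(prof, k_range=range(2, 11), seed=settings.MASTER_SEED)
elbow.inertia_curve.to_csv(settings.RESULTS / "elbow_curve.tsv", sep="\t")
elbow.assignments.to_csv(settings.RESULTS / "cluster_assignments.tsv", sep="\t")

clusters = {
    f"cluster_{k}": set(elbow.assignments.index[elbow.assignments == k])
    for k in sorted(elbow.assignments.unique())
}
background = set(sig_ids)
regulons: dict[str, set] = {}
pathways: dict[str, set] = {}
gene_to_terms: dict[str, set] = {}
for f in ann.features:
    for r in f.regulons:
        regulons.setdefault(r, set()).add(f.id)
    for p in f.pathways:
        pathways.setdefault(p, set()).add(f.id)
    if f.go_terms:
        gene_to_terms[f.id] = set(f.go_terms)

reg_table = profiles.regulon_overrepresentation(clusters, regulons, background)
reg_table.to_csv(settings.RESULTS / "enrichment_regulons.tsv", sep="\t", index=False)

go_dag = simulate.make_go_dag()
universe = set(res.table.index[res.table["considered"]])
go_rows = []
for cid, genes in clusters.items():
    go_rows += profiles.go_elim(go_dag, gene_to_terms, genes, universe, cluster_id=cid)
go_table = profiles.enrichment_frame(go_rows)
go_hits = go_table[go_table.p_raw <= 0.01] if not go_table.empty else go_table
go_table.to_csv(settings.RESULTS / "enrichment_go.tsv", sep="\t", index=False)

pw_rows = []
for cid, genes in clusters.items():
    for pid, members in pathways.items():
        row = profiles.hypergeom_enrich(genes, members, universe,
                                        set_id=pid, cluster_id=cid)
        if row is not None:
            pw_rows.append(row)
pw_table = profiles.enrichment_frame(pw_rows)
pw_table.to_csv(settings.RESULTS / "enrichment_pathways.tsv", sep="\t", index=False)

print(f"PC1+PC2 explain {100 * var_ratio[:2].sum():.0f}% of sample variance")
print(f"k-means elbow chose k = {elbow.k} over {len(prof)} significant features")
print(f"regulon over-representation rows at FDR<=0.01: {len(reg_table)}")
if not reg_table.empty:
    print(reg_table[["set_id", "cluster_id", "overlap", "set_size",
                     "representation_percent", "p_adj"]].to_string(index=False))
print(f"GO elim terms tested: {len(go_table)}, enriched at 0.01: {len(go_hits)}")
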