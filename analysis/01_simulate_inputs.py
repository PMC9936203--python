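#!/usr/bin/env python
"""Generate every synthetic input with planted ground truth.

Emits the reference annotation (GFF3), the gene x sample count matrix and
sample sheet (TSV), one example coverage track (bedGraph) and the planted
truth (JSON) under scratch/synth/.  Coverage tracks themselves are
regenerated deterministically by later scripts from the shared seed.
"""

import json

import numpy as np

import settings
from ncscreen import io, simulate

settings.SCRATCH.mkdir(parents=True, exist_ok=True)

ann = simulate.make_annotation(**settings.ANNOTATION)
plants = simulate.plant_ntrs(ann, **settings.PLANTS)
io.write_gff3(settings.SCRATCH / "annotation.gff3", ann)

tracks, cov_truth = simulate.simulate_coverage(ann, plants, **settings.COVERAGE)
example = next(t for t in tracks if t.strand == "+" and t.mapping_class == "unique")
io.write_bedgraph(settings.SCRATCH / "coverage_plus_unique_rep1.bedgraph",
                  example.seqid, example.values)

feature_ids = [f.id for f in ann.features if f.feature_class != "operon_transcript"]
ntr_ids = [f"ntr_{i:04d}" for i in range(len(plants))]
# two regulons respond coherently, as co-regulated genes do under a shared
# regulator, so the clustering stage has recoverable structure
coherent = {
    reg: [f.id for f in ann.features if reg in f.regulons]
    for reg in settings.COHERENT_REGULONS
}
counts, design, de_truth = simulate.simulate_counts(
    gene_ids=feature_ids + ntr_ids, coherent_groups=coherent, **settings.COUNTS
)
counts.to_csv(settings.SCRATCH / "counts.tsv", sep="\t")
design.to_csv(settings.SCRATCH / "design.tsv", sep="\t")

truth = {
    "planted_ntrs": [
        {"start": int(iv.start), "end": int(iv.end), "strand": iv.strand, "class": cls}
        for iv, cls in plants
    ],
    "size_factors": {s: float(v) for s, v in de_truth.size_factors.items()},
    "n_null_genes": len(de_truth.null_genes()),
    "de_truth": {g: list(map(float, v)) for g, v in de_truth.de_truth.items()},
}
(settings.SCRATCH / "truth.json").write_text(json.dumps(truth, indent=1))

n_de = len(counts) - truth["n_null_genes"]
print(f"annotation: {len(ann)} features over {settings.ANNOTATION['genome_length']/1e3:.0f} kb")
print(f"planted NTRs: {len(plants)} "
      f"({', '.join(sorted({c for _, c in plants}))})")
print(f"counts: {counts.shape[0]} features x {counts.shape[1]} samples, "
      f"{n_de} with a planted effect")
print(f"inputs written to {settings.SCRATCH}")
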