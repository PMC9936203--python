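# ncscreen

From bacterial RNA-seq coverage to CRISPRi candidate regions — a tested
pipeline for strain-engineering transcriptomics, exercised end to end on
synthetic data with planted ground truth.

Industrial *Bacillus subtilis* production strains are screened for genomic
regions — especially non-coding RNAs — whose knockdown changes enzyme
yield. The computational path runs: call transcribed regions from
strand-specific coverage; extract and classify novel ncRNAs from
annotation gaps; test differential expression across a
2-strain × 2-day fermentation design; cluster expression profiles and test
gene-set over-representation; rank CRISPRi candidates and analyse the
screen readout. `ncscreen` implements every step as an importable library
(`src/ncscreen/`), with narrative drivers under `analysis/` and a thin CLI
(`ncscreen call|de|screen`).

## The statistics at the core

**Transcribed regions.** A base is called when ≥ r replicates have
coverage ≥ h (defaults h = 5, r = 2); sub-threshold dips are bridged up to
10 bp (50 bp inside annotation). Novel transcribed regions (NTRs) are the
≥ 50 bp pieces inside strand-specific annotation gaps, classified by
interval rules: asRNA (≥ 90% opposite-strand overlap), and per flank
UTR (< 100 bp to same-strand annotation), sRNA (> 1000 bp), unclear
(in between) — flanks evaluated independently, so dual labels occur.

**Differential expression.** Per gene a negative-binomial GLM,

```
K_gj ~ NB(μ_gj, α_g),   μ_gj = s_j exp(x_jᵀ β_g),   Var = μ + α μ²,
```

with design {intercept, strain, day, strain×day}, median-of-ratios size
factors s_j, trended dispersions with empirical-Bayes quasi-likelihood
moderation, and five contrasts (strain at each day, time in each strain,
interaction). Multiplicity is stage-wise: BH across an omnibus screening
test at overall FDR α, then per screened gene a Shaffer-modified Holm
correction of the five confirmation p-values with multipliers
(2, 2, 2, 2, 1), judged at the realized cutoff α·R/m. This controls the
gene-level FDR while rejecting strictly more than per-contrast-BH-then-union.

**Screen readout.** Guide activities are normalized to a gfp-control
guide; yield changes are percent deviations from the median-activity
baseline with interquartile flags; qPCR fold changes use 2^−ΔΔCt; plate
OD is corrected as 2.51 × sample − blank.

## Worked example

Simulate the 2×2 fermentation design with 10% planted effects and run the
full stage-wise pipeline:

```python
from ncscreen import simulate, de

counts, design, truth = simulate.simulate_counts(n_genes=2000, fraction_de=0.10, seed=7)
res = de.run_de(counts, design, alpha=0.05)

n_sig = int(res.table["significant_any"].sum())
nulls = set(truth.null_genes())
fp = sum(g in nulls for g in res.table.index[res.table["significant_any"]])
print(f"significant genes: {n_sig} of {len(counts)}")
print(f"false discoveries vs planted truth: {fp}  (FDR {fp/n_sig:.3f})")
```

prints

```
significant genes: 151 of 2000
false discoveries vs planted truth: 5  (FDR 0.033)
```

151 of the 2000 genes are confirmed in at least one contrast at overall
FDR 0.05; checking against the planted truth, 5 are false discoveries —
a realized FDR of 3.3%, inside the nominal 5%. `res.logfc`,
`res.p_stagewise` and `res.significant` hold the per-contrast log2 fold
changes, stage-wise adjusted p-values and flags.

The numbered scripts replay the whole study on one synthetic genome:

```
python analysis/01_simulate_inputs.py      # annotation, coverage, counts, plate, qPCR
python analysis/02_call_transcripts.py     # caller + (h, r) benchmark grid
python analysis/03_classify_ntrs.py        # NTR extraction + classification
python analysis/04_differential_expression.py
python analysis/05_cluster_enrich.py       # PCA, k-means elbow, enrichment
python analysis/06_screen_yield.py         # candidates, plate, ΔΔCt, batches
```

Each prints what it found (e.g. 100% planted-NTR recovery with correct
class labels; a regulon recovered at 100% cluster representation; a
planted 1.21× guide reported as +23.8% above the median baseline) and
writes its tables under `results/`.

## Layout

```
src/ncscreen/      library: intervals, io, simulate, caller, classify,
                   de, profiles, screen, pipeline, cli
analysis/          numbered narrative drivers (see above)
tests/             pytest suite incl. property tests and oracle checks
scripts/           acceptance.py
docs/methods.md    models, defaults, numerical choices, limitations
```
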