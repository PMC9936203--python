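"""Shared settings for the analysis scripts.

One fixed master seed drives every stage; the synthetic genome emulates a
compact bacterial chromosome with planted novel transcripts, and the count
matrix the 2-strain x 2-day duplicate fermentation design.
"""

from pathlib import Path

MASTER_SEED = 20240901

ANNOTATION = dict(seed=MASTER_SEED, n_genes=150, genome_length=300_000)
PLANTS = dict(seed=MASTER_SEED + 1, n_asrna=5, n_utr=5, n_srna=3, n_unclear=2)
COVERAGE = dict(
    seed=MASTER_SEED + 2, n_replicates=2, expression_level=20,
    noise_model="poisson",
)
# ~40% of features carry an effect, matching the prevalence of differential
# expression observed in fed-batch fermentation transcriptomes
COUNTS = dict(seed=MASTER_SEED + 3, n_reps=2, fraction_de=0.40,
              coherent_effect_size_range=(2.0, 3.0))
PLATE = dict(seed=MASTER_SEED + 4, replicate_cv=0.05, n_reps=3)

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "synth"
RESULTS = ROOT / "results"

# regulons whose members respond coherently in the simulated counts
COHERENT_REGULONS = ["RegA", "RegD"]
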