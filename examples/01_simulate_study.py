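"""Generate a synthetic allopolyploid small-RNA study and inspect its truth.

Builds parent 1 (An + Cn subgenomes), parent 2 (Ar, diverged from An) and a
triploid F1 (An + Ar + Cn) with planted miRNA loci, then prints what was
planted: how many loci, their conserved/novel split, the expression classes,
and which loci were deleted from or inserted into the hybrid genome.
"""

from polymir import SimulationConfig, simulate_genomes

cfg = SimulationConfig(
    seed=1, n_chrom_per_subgenome=2, chrom_length=50_000,
    n_mirna_loci=20, mean_depth=20_000,
)
sim = simulate_genomes(cfg)
truth = sim.truth.loci

print(f"chromosomes per genome: parent1={len(sim.genomes['parent1'])}, "
      f"parent2={len(sim.genomes['parent2'])}, f1={len(sim.genomes['f1'])}")
print(f"planted miRNA loci: {len(truth)}")
print("identity:", truth.identity.astype(str).value_counts().to_dict())
print("expression classes:", truth.expression_class.value_counts().to_dict())
print("lost in F1:", sim.truth.lost_ids, "| gained in F1:", sim.truth.gained_ids)
# Each row of `truth` records where a locus sits, its mature sequence, its
# true per-sample mean abundance, and the labels the analysis should recover.
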