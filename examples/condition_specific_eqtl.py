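"""Two-condition cis-eQTL scan with condition-specific classification.

Simulates a 110-sample paired cohort (control vs tunicamycin-induced ER
stress) with planted shared, control-only and TM-only genotype effects,
runs the nominal scan + BH-FDR in each condition, classifies each
variant-gene pair, and prints genotype-stratified expression for a
TM-only association.
"""

from ermotifs.eqtl import (
    cis_pairs,
    classify_conditions,
    fdr_adjust,
    genotype_summaries,
    nominal_scan,
)
from ermotifs.simulate import (
    SimulationConfig,
    default_motifs,
    simulate_cohort,
    simulate_genome,
)

config = SimulationConfig(
    seed=21,
    chrom_lengths=(("chr1", 400_000), ("chr2", 400_000)),
    n_genes=60,
    motif_counts=(("UPRE", 4),),
    n_eqtl_per_class=(("shared", 10), ("control_only", 10), ("tm_only", 10)),
    n_null_variants=40,
    n_samples=110,
)
sim = simulate_genome(config, default_motifs())
cohort = simulate_cohort(config, sim)

pairs = cis_pairs(sim.genes, cohort.genotypes.meta.reset_index(), 1_000_000)
assoc_c = fdr_adjust(nominal_scan(pairs, cohort.genotypes, cohort.expr_control))
assoc_t = fdr_adjust(nominal_scan(pairs, cohort.genotypes, cohort.expr_tm))
classes = classify_conditions(assoc_c, assoc_t, alpha=0.001)

counts = classes["class"].value_counts()
print(f"tested pairs: {len(pairs)}")
for cls in ("shared", "control_only", "tm_only", "neither"):
    print(f"  {cls:13} {counts.get(cls, 0)}")

truth = cohort.effects.merge(classes, on=["variant_id", "gene_id"])
planted = truth[truth["class_x"] != "null"]
agree = (planted["class_x"] == planted["class_y"]).mean()
print(f"\nplanted effects classified correctly: {100 * agree:.0f}%")

tm_hit = truth[(truth["class_x"] == "tm_only") & (truth["class_y"] == "tm_only")].iloc[0]
summary = genotype_summaries(
    tm_hit["variant_id"], tm_hit["gene_id"], cohort.genotypes,
    cohort.expr_control, cohort.expr_tm,
)
print(f"\ngenotype-stratified expression for {tm_hit['gene_id']} "
      f"({tm_hit['variant_id']}, TM-only):")
print(f"{'dosage':>6} {'mean ctrl':>10} {'mean TM':>9} {'fold change':>12}")
for row in summary.itertuples():
    print(f"{row.dosage:>6} {row.mean_control:>10.2f} {row.mean_tm:>9.2f} "
          f"{row.fold_change:>12.2f}")
print(
    "\nThe dosage-dependent TM means (flat under control) are the signature "
    "of a\nstress-specific regulatory variant."
)
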