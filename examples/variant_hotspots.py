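"""Variant enrichment within motifs: permutation null, positional
chi-squared hotspots, and benign-vs-pathogenic binomial tests.

Simulates eQTL-style and clinical-style variant sets with a 10x density
multiplier and a 0.95 benign probability at the CpG hotspot positions,
then recovers that structure with the three enrichment procedures.
"""

from ermotifs.enrichment import (
    benign_enrichment_table,
    permutation_enrichment,
    position_chisq_table,
    variant_motif_overlap,
)
from ermotifs.motifs import scan_genome, wobble_score
from ermotifs.simulate import (
    SimulationConfig,
    default_motifs,
    simulate_genome,
    simulate_variants,
)

config = SimulationConfig(
    seed=3,
    chrom_lengths=(("chr1", 60_000), ("chr2", 40_000)),
    n_genes=12,
    motif_counts=(("ERSEI", 6), ("ERSEII", 6), ("UPRE", 6), ("ATF4", 6)),
    n_motif_snvs=1_500,
    n_clinical_snvs=1_200,
    n_background_snvs=100,
)
motifs = default_motifs()
sim = simulate_genome(config, motifs)
clinical, gtex = simulate_variants(config, sim, motifs)

lpm = motifs["ERSEI"]
hits = scan_genome(sim.sequences, lpm, wobble_score(lpm))

res = permutation_enrichment(
    hits, gtex, config.chrom_sizes,
    spec=[(len(lpm.informative_positions), len(hits))],
    N=999, seed=3,
)
print(f"ERSEI x eQTL-variant overlap: n_real={res.n_real}, "
      f"null mean={res.draws.mean():.1f}, p_raw={res.p_raw:.4g}")

overlap = variant_motif_overlap(gtex, hits, motifs)
chisq = position_chisq_table(overlap, motifs)
top = chisq.nsmallest(3, "p_adj")
print("\ntop ERSEI positions by chi-squared (hotspots planted at 18, 19):")
for row in top.itertuples():
    print(f"  position {row.position:>2}: count={row.count:>4} "
          f"chi2={row.statistic:8.1f} p_adj={row.p_adj:.3g}")

clin_overlap = variant_motif_overlap(clinical, hits, motifs)
benign = benign_enrichment_table(clin_overlap, clinical, motifs)
flagged = benign[benign["enriched"]]
print("\npositions with benign overrepresentation (planted at 18, 19):")
for row in flagged.itertuples():
    print(f"  position {row.position:>2}: {row.benign}/{row.n} benign, "
          f"p_adj={row.p_adj:.3g}")
print(
    "\nVariants cluster at the CpG positions, and those same positions are "
    "depleted\nof pathogenic labels relative to the motif-wide benign "
    "fraction."
)
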