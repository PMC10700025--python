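"""The candidate-site filtering funnel: scan -> gene proximity -> conservation.

Scans a synthetic genome, keeps hits within 2 kb of a gene, then keeps
hits fully covered by the PhastCons-like track with mean score >= 0.5,
and prints the funnel counts plus the per-position PhyloP profile of one
motif (elevated at half-sites, near-neutral over the spacer).
"""

import pandas as pd

from ermotifs.conservation import conservation_filter, positional_profile
from ermotifs.intervals import window_filter
from ermotifs.motifs import scan_genome, wobble_score
from ermotifs.simulate import (
    SimulationConfig,
    default_motifs,
    simulate_genome,
    simulate_tracks,
)

config = SimulationConfig(
    seed=7,
    chrom_lengths=(("chr1", 100_000), ("chr2", 60_000)),
    n_genes=16,
    motif_counts=(("ERSEI", 8), ("ERSEII", 8), ("UPRE", 8), ("ATF4", 8)),
)
motifs = default_motifs()
sim = simulate_genome(config, motifs)
phastcons, phylop = simulate_tracks(config, sim, motifs)

hits = pd.concat(
    [scan_genome(sim.sequences, lpm, wobble_score(lpm)) for lpm in motifs.values()],
    ignore_index=True,
)
proximal, pairs, n_genes = window_filter(hits, sim.genes, window_bp=2000)
conserved = conservation_filter(proximal, phastcons, cutoff=0.5)

print(f"scan hits:                 {len(hits)}")
print(f"within 2 kb of a gene:     {len(proximal)}  ({n_genes} genes)")
print(f"conserved (mean >= 0.5):   {len(conserved)}")

profile = positional_profile(
    hits[hits["motif"] == "ERSEII"], phylop
).set_index("position")
print("\nERSEII per-position mean PhyloP (positions 1-11; 6 is the spacer):")
print("  " + "  ".join(f"{profile.loc[p, 'mean']:5.2f}" for p in range(1, 12)))
print(
    "\nThe funnel only narrows: each filter is a subset of the last. The "
    "spacer\nposition stays near 0 (neutral) while contact positions are "
    "elevated."
)
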