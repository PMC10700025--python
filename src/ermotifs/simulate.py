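"""Synthetic data with planted ground truth for every pipeline stage.

The generator emulates the structure of the real study inputs at desk
scale: an i.i.d. background genome with consensus or one-wobble motif
instances planted near genes; conservation tracks elevated over the planted
half-sites; motif variants concentrated at CpG hotspot positions with C->T
alternates and position-dependent benign/pathogenic labels; Hardy-Weinberg
genotypes; and log2-intensity expression with planted condition-specific
genotype effects plus Gaussian noise for a paired control/tunicamycin (TM)
cohort of 110 individuals.

Every random stream is a Philox counter-based generator keyed on
``(seed, stream id)`` so each output file can be regenerated independently
and byte-identically.  Ground truth is returned as plain tables; downstream
acceptance checks read only these, never regenerated randomness.

The LPMs shipped here are synthetic stand-ins built from the published
consensus layouts (ERSEI CCAAT-N9-CCACG, ERSEII ATTGG-N-CCACG, UPRE
(C/A)CACGTCA, ATF4 (A/C)TGA(T/C)GCAA(T/C)); they are not the
experimentally derived reference matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .conservation import ConservationTrack
from .eqtl import ExpressionMatrix, GenotypeMatrix
from .intervals import half_site_mask, motif_position_to_genomic
from .motifs import BASES, LetterProbabilityMatrix, reverse_complement

_STREAMS = {
    "genome": 1,
    "planting": 2,
    "tracks": 3,
    "variants": 4,
    "cohort": 5,
}

#: CpG hotspot positions per motif (the positions the positional tests target)
HOTSPOT_POSITIONS = {
    "ERSEI": (18, 19),
    "ERSEII": (10, 11),
    "UPRE": (4, 5),
    "ATF4": (5, 6),
}

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TISSUES = ("lung", "liver", "whole_blood", "muscle", "thyroid")


def stream(seed: int, name: str) -> np.random.Generator:
    """Philox generator for one named output stream of one simulation."""
    return np.random.Generator(np.random.Philox(key=[seed, _STREAMS[name]]))


def _strong_row(base: str) -> list[float]:
    """Consensus row: 0.88 main base, 0.08 its transition partner, 0.02 rest."""
    row = [0.02] * 4
    row[BASES.index(base)] = 0.88
    row[BASES.index(_TRANSITION[base])] = 0.08
    return row


def _degenerate_row(main: str, second: str) -> list[float]:
    row = [0.04] * 4
    row[BASES.index(main)] = 0.48
    row[BASES.index(second)] = 0.44
    return row


def default_motifs() -> dict[str, LetterProbabilityMatrix]:
    """Synthetic LPMs for the four ER-stress motifs.

    Built from the published consensus layouts, with the transition partner
    as the second-most-probable base at strong positions (so the "wobble"
    base of a consensus C is T, matching CpG deamination).  Synthetic
    stand-ins, not the experimentally derived matrices.
    """
    def build(name, layout, spacer=()):
        rows = []
        for sym in layout:
            if sym == "N":
                rows.append([0.25] * 4)
            elif isinstance(sym, tuple):
                rows.append(_degenerate_row(*sym))
            else:
                rows.append(_strong_row(sym))
        return LetterProbabilityMatrix(
            name, np.array(rows), spacer_positions=frozenset(spacer)
        )

    ersei = build(
        "ERSEI", list("CCAAT") + ["N"] * 9 + list("CCACG"), spacer=range(6, 15)
    )
    erseii = build("ERSEII", list("ATTGG") + ["N"] + list("CCACG"), spacer=(6,))
    upre = build("UPRE", [("C", "A")] + list("CACGTCA"))
    atf4 = build(
        "ATF4", [("A", "C")] + list("TGA") + [("C", "T")] + list("GCAA") + [("T", "C")]
    )
    return {m.name: m for m in (ersei, erseii, upre, atf4)}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic data set.

    Defaults are the desk-scale conditions all tests run under: two 500 kb
    chromosomes, 60 genes, 30 planted instances per motif within 1.5 kb of
    a gene, PhastCons-like baseline Beta(1,4) vs Beta(19,1) over half-sites,
    PhyloP-like N(0,1) vs N(2,0.5), a 10x variant multiplier and 0.95 benign
    probability at the CpG hotspots, Hardy-Weinberg genotypes at MAF
    U(0.05,0.5), and a 110-sample paired cohort with planted |beta| = 1
    condition-specific effects and residual SD 0.5.
    """

    seed: int = 0
    chrom_lengths: tuple[tuple[str, int], ...] = (
        ("chr1", 500_000), ("chr2", 500_000),
    )
    gc: float = 0.41
    n_genes: int = 60
    gene_length: int = 2_000
    motif_counts: tuple[tuple[str, int], ...] = (
        ("ERSEI", 30), ("ERSEII", 30), ("UPRE", 30), ("ATF4", 30),
    )
    wobble_fraction: float = 0.3
    max_gene_distance: int = 1_500
    # conservation model
    cons_baseline: tuple[float, float] = (1.0, 4.0)    # Beta, mean 0.2
    cons_elevated: tuple[float, float] = (19.0, 1.0)   # Beta, mean 0.95
    phylop_baseline: tuple[float, float] = (0.0, 1.0)  # Normal(mean, sd)
    phylop_elevated: tuple[float, float] = (2.0, 0.5)
    gap_rate: float = 0.01
    # variant model
    n_motif_snvs: int = 2_000
    n_clinical_snvs: int = 800
    n_background_snvs: int = 500
    n_spacer_indels: int = 20
    hotspot_multiplier: float = 10.0
    benign_p_hotspot: float = 0.95
    benign_p_base: float = 0.5
    # cohort model
    n_samples: int = 110
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_eqtl_per_class: tuple[tuple[str, int], ...] = (
        ("shared", 15), ("control_only", 15), ("tm_only", 15),
    )
    eqtl_beta: float = 1.0
    noise_sd: float = 0.5
    baseline_mean: float = 10.0
    baseline_sd: float = 1.0
    condition_effect_sd: float = 0.5
    n_null_variants: int = 100

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return dict(self.chrom_lengths)


@dataclass
class SimulatedGenome:
    sequences: dict[str, str]
    genes: pd.DataFrame       # gene_id, chrom, start, end, strand, tss
    truth: pd.DataFrame       # chrom, start, end, strand, motif, gene_id, wobble_pos


def _sample_motif_sequence(
    lpm: LetterProbabilityMatrix, rng: np.random.Generator, wobble: bool
) -> tuple[str, int]:
    """Consensus (or one-wobble) instance; spacer bases drawn uniformly.

    Returns the plus-strand motif sequence and the wobbled 1-based position
    (0 when none).
    """
    order = np.argsort(-lpm.probs, axis=1, kind="stable")
    letters = [BASES[order[i, 0]] for i in range(lpm.length)]
    for p in lpm.spacer_positions:
        letters[p - 1] = BASES[rng.integers(0, 4)]
    wobble_pos = 0
    if wobble:
        inf = lpm.informative_positions
        wobble_pos = int(inf[rng.integers(0, len(inf))])
        letters[wobble_pos - 1] = BASES[order[wobble_pos - 1, 1]]
    return "".join(letters), wobble_pos


def simulate_genome(
    config: SimulationConfig,
    motifs: Mapping[str, LetterProbabilityMatrix] | None = None,
) -> SimulatedGenome:
    """Background genome with genes and planted motif instances.

    Bases are i.i.d. at the configured GC content.  Genes are evenly spaced
    along the chromosomes; each planted instance is assigned to a gene
    round-robin and placed (random strand) within ``max_gene_distance`` of
    the gene body without overlapping previously planted instances.
    """
    if motifs is None:
        motifs = default_motifs()
    rng_g = stream(config.seed, "genome")
    p = np.array([(1 - config.gc) / 2, config.gc / 2,
                  config.gc / 2, (1 - config.gc) / 2])
    arrays = {
        chrom: rng_g.choice(4, size=size, p=p).astype(np.uint8)
        for chrom, size in config.chrom_lengths
    }

    # evenly spaced genes, proportional share per chromosome
    chroms = list(config.chrom_sizes)
    sizes = np.array([config.chrom_sizes[c] for c in chroms], dtype=float)
    shares = np.floor(config.n_genes * sizes / sizes.sum()).astype(int)
    while shares.sum() < config.n_genes:
        shares[int(np.argmax(sizes / (shares + 1)))] += 1
    rng_p = stream(config.seed, "planting")
    gene_rows = []
    gid = 0
    for chrom, n_c in zip(chroms, shares):
        size = config.chrom_sizes[chrom]
        slot = size // max(n_c, 1)
        if slot < config.gene_length + 2 * config.max_gene_distance:
            raise ValueError("infeasible packing: genes do not fit the genome")
        for k in range(n_c):
            start = k * slot + config.max_gene_distance + int(
                rng_p.integers(0, max(1, slot // 8))
            )
            gene_rows.append(
                {"gene_id": f"GENE{gid:04d}", "chrom": chrom, "start": start,
                 "end": start + config.gene_length,
                 "strand": "+" if rng_p.random() < 0.5 else "-"}
            )
            gid += 1
    genes = pd.DataFrame(gene_rows)
    genes["tss"] = np.where(genes["strand"] == "+", genes["start"] + 1, genes["end"])

    occupied: dict[str, set[int]] = {c: set() for c in chroms}
    truth_rows = []
    gene_cycle = 0
    for motif_name, count in config.motif_counts:
        lpm = motifs[motif_name]
        for _ in range(count):
            placed = False
            for _attempt in range(200):
                gene = genes.iloc[gene_cycle % len(genes)]
                lo = max(0, int(gene["start"]) - config.max_gene_distance)
                hi = min(
                    config.chrom_sizes[gene["chrom"]] - lpm.length,
                    int(gene["end"]) + config.max_gene_distance - lpm.length,
                )
                gene_cycle += 1
                if hi <= lo:
                    continue
                start = int(rng_p.integers(lo, hi + 1))
                span = range(start - 1, start + lpm.length + 1)
                if any(b in occupied[gene["chrom"]] for b in span):
                    continue
                strand = "+" if rng_p.random() < 0.5 else "-"
                wobble = rng_p.random() < config.wobble_fraction
                seq, wobble_pos = _sample_motif_sequence(lpm, rng_p, wobble)
                planted = seq if strand == "+" else reverse_complement(seq)
                codes = np.array([BASES.index(b) for b in planted], dtype=np.uint8)
                arrays[gene["chrom"]][start : start + lpm.length] = codes
                occupied[gene["chrom"]].update(span)
                truth_rows.append(
                    {"chrom": gene["chrom"], "start": start,
                     "end": start + lpm.length, "strand": strand,
                     "motif": motif_name, "gene_id": gene["gene_id"],
                     "wobble_pos": wobble_pos}
                )
                placed = True
                break
            if not placed:
                raise ValueError(
                    f"infeasible packing: could not place a {motif_name} instance"
                )
    base_lookup = np.array(list(BASES))
    sequences = {c: "".join(base_lookup[arr]) for c, arr in arrays.items()}
    truth = pd.DataFrame(truth_rows).sort_values(["chrom", "start"]).reset_index(
        drop=True
    )
    return SimulatedGenome(sequences=sequences, genes=genes, truth=truth)


def simulate_tracks(
    config: SimulationConfig,
    sim: SimulatedGenome,
    motifs: Mapping[str, LetterProbabilityMatrix] | None = None,
) -> tuple[ConservationTrack, ConservationTrack]:
    """PhastCons-like and PhyloP-like tracks over the simulated genome.

    Baseline values cover the whole genome; bases inside planted half-sites
    are drawn from the elevated component (spacer bases stay baseline);
    coverage gaps are inserted at ``gap_rate`` independently per track.
    """
    if motifs is None:
        motifs = default_motifs()
    rng = stream(config.seed, "tracks")
    phast: dict[str, np.ndarray] = {}
    phylop: dict[str, np.ndarray] = {}
    for chrom, size in config.chrom_lengths:
        phast[chrom] = rng.beta(*config.cons_baseline, size=size)
        phylop[chrom] = rng.normal(*config.phylop_baseline, size=size)
    for row in sim.truth.itertuples():
        for chrom, s, e in half_site_mask(row, motifs[row.motif]):
            phast[chrom][s:e] = rng.beta(*config.cons_elevated, size=e - s)
            phylop[chrom][s:e] = rng.normal(*config.phylop_elevated, size=e - s)
    if config.gap_rate > 0:
        for chrom, size in config.chrom_lengths:
            phast[chrom][rng.random(size) < config.gap_rate] = np.nan
            phylop[chrom][rng.random(size) < config.gap_rate] = np.nan
    return (
        ConservationTrack(phast, kind="phastcons"),
        ConservationTrack(phylop, kind="phylop"),
    )


def _draw_motif_snvs(
    config: SimulationConfig,
    sim: SimulatedGenome,
    motifs: Mapping[str, LetterProbabilityMatrix],
    rng: np.random.Generator,
    n: int,
) -> pd.DataFrame:
    """SNVs at informative motif positions, hotspot positions upweighted.

    Hotspot alternates follow the CpG deamination pattern: a genomic C
    becomes T (G becomes A on the minus-strand-facing copy).
    """
    slots = []
    weights = []
    for ti, row in enumerate(sim.truth.itertuples()):
        hot = HOTSPOT_POSITIONS.get(row.motif, ())
        for p in motifs[row.motif].informative_positions:
            slots.append((ti, p))
            weights.append(config.hotspot_multiplier if p in hot else 1.0)
    weights = np.asarray(weights)
    idx = rng.choice(len(slots), size=n, p=weights / weights.sum())
    rows = []
    for i in idx:
        ti, p = slots[i]
        t = sim.truth.iloc[ti]
        gpos = motif_position_to_genomic(p, t)
        ref = sim.sequences[t["chrom"]][gpos]
        hot = p in HOTSPOT_POSITIONS.get(t["motif"], ())
        if hot and ref in "CG":
            alt = _TRANSITION[ref]
        else:
            alt = BASES[(BASES.index(ref) + int(rng.integers(1, 4))) % 4]
        rows.append(
            {"chrom": t["chrom"], "pos": gpos + 1, "ref": ref, "alt": alt,
             "motif": t["motif"], "motif_position": p, "hotspot": hot,
             "gene_id": t["gene_id"]}
        )
    return pd.DataFrame(rows)


def _draw_background_snvs(
    config: SimulationConfig, sim: SimulatedGenome, rng: np.random.Generator, n: int
) -> pd.DataFrame:
    chroms = list(config.chrom_sizes)
    sizes = np.array([config.chrom_sizes[c] for c in chroms], dtype=np.int64)
    cum = np.cumsum(sizes)
    r = rng.integers(0, cum[-1], size=n)
    ci = np.searchsorted(cum, r, side="right")
    pos = r - (cum[ci] - sizes[ci])
    rows = []
    for c, g in zip(ci, pos):
        chrom = chroms[c]
        ref = sim.sequences[chrom][g]
        alt = BASES[(BASES.index(ref) + int(rng.integers(1, 4))) % 4]
        rows.append(
            {"chrom": chrom, "pos": int(g) + 1, "ref": ref, "alt": alt,
             "motif": None, "motif_position": np.nan, "hotspot": False,
             "gene_id": None}
        )
    return pd.DataFrame(rows)


def simulate_variants(
    config: SimulationConfig,
    sim: SimulatedGenome,
    motifs: Mapping[str, LetterProbabilityMatrix] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Clinical-style and eQTL-summary variant sets with planted structure.

    Returns ``(clinical, gtex)``.  ``clinical`` holds SNVs with
    benign/pathogenic significance labels (benign probability
    ``benign_p_hotspot`` at hotspot positions, ``benign_p_base`` elsewhere)
    plus deletions placed in ERSE spacers; ``gtex`` holds eQTL-style rows
    (variant_id, gene_id, tissue, pval_nominal) concentrated at the hotspot
    positions.  Both include uniform background variants.
    """
    if motifs is None:
        motifs = default_motifs()
    rng = stream(config.seed, "variants")

    clin_motif = _draw_motif_snvs(config, sim, motifs, rng, config.n_clinical_snvs)
    clin_bg = _draw_background_snvs(config, sim, rng, config.n_background_snvs)
    clinical = pd.concat([clin_motif, clin_bg], ignore_index=True)
    p_ben = np.where(
        clinical["hotspot"], config.benign_p_hotspot, config.benign_p_base
    )
    benign = rng.random(len(clinical)) < p_ben
    labels = np.where(
        benign,
        np.where(rng.random(len(clinical)) < 0.5, "Benign", "Likely_benign"),
        np.where(rng.random(len(clinical)) < 0.5, "Pathogenic", "Likely_pathogenic"),
    )
    clinical["significance"] = labels

    # spacer deletions: remove one spacer base of a random ERSE instance
    indel_rows = []
    erse = sim.truth[sim.truth["motif"].isin(["ERSEI", "ERSEII"])]
    for _ in range(config.n_spacer_indels):
        t = erse.iloc[int(rng.integers(0, len(erse)))]
        spacers = sorted(motifs[t["motif"]].spacer_positions)
        p = spacers[int(rng.integers(0, len(spacers)))]
        gpos = motif_position_to_genomic(p, t)
        ref2 = sim.sequences[t["chrom"]][gpos - 1 : gpos + 1]
        indel_rows.append(
            {"chrom": t["chrom"], "pos": gpos, "ref": ref2, "alt": ref2[0],
             "motif": t["motif"], "motif_position": p, "hotspot": False,
             "gene_id": t["gene_id"],
             "significance": "Pathogenic" if rng.random() < 0.5 else "Benign"}
        )
    if indel_rows:
        clinical = pd.concat([clinical, pd.DataFrame(indel_rows)], ignore_index=True)
    clinical["start"] = clinical["pos"] - 1
    clinical["end"] = clinical["start"] + clinical["ref"].str.len()
    clinical["var_class"] = np.where(
        (clinical["ref"].str.len() == 1) & (clinical["alt"].str.len() == 1),
        "SNV", "indel",
    )
    clinical["group"] = np.where(
        clinical["significance"].str.lower().str.contains("benign"),
        "BENIGN", "PATH",
    )

    gtex_motif = _draw_motif_snvs(config, sim, motifs, rng, config.n_motif_snvs)
    gtex_bg = _draw_background_snvs(
        config, sim, rng, config.n_background_snvs
    )
    gtex = pd.concat([gtex_motif, gtex_bg], ignore_index=True)
    gtex["variant_id"] = (
        gtex["chrom"].astype(str) + "_" + gtex["pos"].astype(str)
        + "_" + gtex["ref"] + "_" + gtex["alt"]
    )
    gtex["gene_id"] = gtex["gene_id"].fillna("GENE_NA")
    gtex["tissue"] = np.array(_TISSUES, dtype=object)[
        rng.integers(0, len(_TISSUES), size=len(gtex))
    ]
    gtex["pval_nominal"] = 10.0 ** (-rng.uniform(5, 12, size=len(gtex)))
    gtex["start"] = gtex["pos"] - 1
    gtex["end"] = gtex["pos"]
    gtex["var_class"] = "SNV"
    return clinical, gtex


@dataclass
class SimulatedCohort:
    genotypes: GenotypeMatrix
    expr_control: ExpressionMatrix
    expr_tm: ExpressionMatrix
    effects: pd.DataFrame  # gene_id, variant_id, class, beta, maf


def simulate_cohort(
    config: SimulationConfig, sim: SimulatedGenome
) -> SimulatedCohort:
    """Paired-condition cohort with planted condition-specific cis-eQTLs.

    One causal variant per effect gene, placed within 50 kb of the TSS;
    dosages are Hardy-Weinberg draws at MAF ~ U(maf_range); expression is
    ``mu_g + delta_g*[TM] + beta*dosage*[condition in class] + N(0, sd^2)``.
    Null variants near the remaining genes give the scan true negatives.
    """
    rng = stream(config.seed, "cohort")
    samples = [f"S{i:03d}" for i in range(config.n_samples)]
    genes = sim.genes
    classes = [c for c, n in config.n_eqtl_per_class for _ in range(n)]
    if len(classes) > len(genes):
        raise ValueError("more planted effects than genes")
    gene_order = rng.permutation(len(genes))
    effect_genes = gene_order[: len(classes)]
    null_genes = gene_order[len(classes):]

    var_rows, meta_rows, effects = [], [], []

    def add_variant(gene, beta_class=None, beta=0.0):
        pos = int(
            np.clip(
                gene["tss"] + int(rng.integers(-50_000, 50_001)),
                1, config.chrom_sizes[gene["chrom"]],
            )
        )
        maf = rng.uniform(*config.maf_range)
        dosage = rng.binomial(2, maf, size=config.n_samples).astype(float)
        vid = f"{gene['chrom']}_{pos}_A_G"
        while any(m["variant_id"] == vid for m in meta_rows):
            pos += 1
            vid = f"{gene['chrom']}_{pos}_A_G"
        var_rows.append(pd.Series(dosage, index=samples, name=vid))
        meta_rows.append(
            {"variant_id": vid, "chrom": gene["chrom"], "pos": pos,
             "ref": "A", "alt": "G", "maf": maf}
        )
        effects.append(
            {"gene_id": gene["gene_id"], "variant_id": vid,
             "class": beta_class or "null", "beta": beta, "maf": maf}
        )
        return vid, dosage

    mu = rng.normal(config.baseline_mean, config.baseline_sd, size=len(genes))
    delta = rng.normal(0.0, config.condition_effect_sd, size=len(genes))
    expr_c = np.empty((len(genes), config.n_samples))
    expr_t = np.empty((len(genes), config.n_samples))
    for gi in range(len(genes)):
        expr_c[gi] = mu[gi] + rng.normal(0, config.noise_sd, config.n_samples)
        expr_t[gi] = mu[gi] + delta[gi] + rng.normal(
            0, config.noise_sd, config.n_samples
        )

    for cls, gi in zip(classes, effect_genes):
        gene = genes.iloc[gi]
        _, dosage = add_variant(gene, beta_class=cls, beta=config.eqtl_beta)
        if cls in ("shared", "control_only"):
            expr_c[gi] += config.eqtl_beta * dosage
        if cls in ("shared", "tm_only"):
            expr_t[gi] += config.eqtl_beta * dosage

    for k in range(config.n_null_variants):
        gene = genes.iloc[int(null_genes[k % len(null_genes)])] if len(null_genes) \
            else genes.iloc[int(rng.integers(0, len(genes)))]
        add_variant(gene)

    dosages = pd.DataFrame(var_rows)
    meta = pd.DataFrame(meta_rows).set_index("variant_id")
    gene_meta = genes.set_index("gene_id")[["chrom", "tss", "strand"]]
    gm = GenotypeMatrix(dosages, meta)
    ec = ExpressionMatrix(
        pd.DataFrame(expr_c, index=genes["gene_id"], columns=samples),
        "control", gene_meta,
    )
    et = ExpressionMatrix(
        pd.DataFrame(expr_t, index=genes["gene_id"], columns=samples),
        "tm", gene_meta,
    )
    return SimulatedCohort(gm, ec, et, pd.DataFrame(effects))


# ---------------------------------------------------------------------------
# writers for the on-disk dialects the pipeline consumes
# ---------------------------------------------------------------------------

def write_fasta(path: str | Path, sequences: Mapping[str, str], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _contig_lines(chrom_sizes: Mapping[str, int] | None) -> str:
    if not chrom_sizes:
        return ""
    return "".join(
        f"##contig=<ID={c},length={n}>\n" for c, n in chrom_sizes.items()
    )


def write_clinical_vcf(
    path: str | Path,
    variants: pd.DataFrame,
    chrom_sizes: Mapping[str, int] | None = None,
) -> None:
    """Minimal VCF with the clinical significance under CLNSIG."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(_contig_lines(chrom_sizes))
        fh.write(
            '##INFO=<ID=CLNSIG,Number=1,Type=String,'
            'Description="Clinical significance">\n'
        )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        ordered = variants.sort_values(["chrom", "pos"])
        for row in ordered.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\t.\t"
                f"CLNSIG={row.significance}\n"
            )


def write_genotype_vcf(
    path: str | Path,
    gm: GenotypeMatrix,
    chrom_sizes: Mapping[str, int] | None = None,
) -> None:
    """Minimal VCF with GT calls reconstructed from dosages."""
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    samples = list(gm.dosages.columns)
    meta = gm.meta
    order = meta.sort_values(["chrom", "pos"]).index
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(_contig_lines(chrom_sizes))
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples) + "\n"
        )
        for vid in order:
            m = meta.loc[vid]
            calls = [
                gt_map.get(d, "./.") for d in gm.dosages.loc[vid].to_numpy(float)
            ]
            fh.write(
                f"{m['chrom']}\t{m['pos']}\t{vid}\t{m['ref']}\t{m['alt']}\t.\t.\t.\t"
                "GT\t" + "\t".join(calls) + "\n"
            )


def write_eqtl_tsv(path: str | Path, gtex: pd.DataFrame) -> None:
    gtex[["variant_id", "gene_id", "tissue", "pval_nominal"]].to_csv(
        path, sep="\t", index=False
    )


def write_expression_tsv(path: str | Path, em: ExpressionMatrix) -> None:
    em.values.to_csv(path, sep="\t", index_label="gene_id")
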