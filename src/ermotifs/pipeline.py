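"""Stage orchestration over an output directory with JSON manifests.

Each stage reads declared inputs from the run directory, writes its outputs
plus a ``<stage>.manifest.json`` recording inputs, parameter values, seed,
row counts and wall time.  Stages are idempotent given identical inputs.
The funnel (scan >= proximity-filtered >= conservation-filtered) can be
reconstructed from the manifests alone.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import conservation as cons
from . import enrichment, eqtl, intervals, motifs as mo, simulate as sim

STAGES = (
    "simulate", "scan", "filter-proximity", "filter-conservation",
    "positional", "permute", "clinvar", "eqtl", "classify", "report",
)

#: per-motif wobble p-value cutoffs reported for the reference matrices
DEFAULT_PVALUE_CUTOFFS = {
    "ERSEI": 1.6e-5, "ERSEII": 1.6e-5, "UPRE": 1.2e-4, "ATF4": 1.9e-5,
}


@dataclass
class PipelineConfig:
    """Parameters of a full pipeline run (defaults match the method)."""

    outdir: str = "ermotifs_run"
    seed: int = 0
    window_bp: int = 2000
    conservation_cutoff: float = 0.5
    pvalue_cutoffs: dict = field(default_factory=lambda: dict(DEFAULT_PVALUE_CUTOFFS))
    permutation_n: int = 9999
    fdr_alpha: float = 0.001
    cis_window: int = 1_000_000
    half_site: bool = True
    simulation: sim.SimulationConfig | None = None

    def __post_init__(self) -> None:
        for name in ("window_bp", "conservation_cutoff", "permutation_n",
                     "fdr_alpha", "cis_window"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.simulation is None:
            self.simulation = sim.SimulationConfig(seed=self.seed)


class PipelineError(RuntimeError):
    pass


def _require(path: Path) -> Path:
    if not path.exists():
        raise PipelineError(f"missing input file: {path}")
    return path


def _write_manifest(outdir: Path, stage: str, inputs, outputs, params, seed,
                    rows, t0) -> dict:
    manifest = {
        "stage": stage,
        "inputs": [str(p) for p in inputs],
        "outputs": [str(p) for p in outputs],
        "params": params,
        "seed": seed,
        "rows": rows,
        "wall_time_s": round(time.time() - t0, 3),
    }
    (outdir / f"{stage}.manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def run_stage(stage: str, config: PipelineConfig) -> dict:
    """Run one pipeline stage; returns its manifest."""
    if stage not in STAGES:
        raise PipelineError(f"unknown stage {stage!r}; choose from {STAGES}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    lpms = sim.default_motifs()
    lpm_path = outdir / "motifs.lpm"
    if lpm_path.exists():
        lpms = {m.name: m for m in mo.read_lpm_file(lpm_path)}

    if stage == "simulate":
        sc = config.simulation
        genome = sim.simulate_genome(sc, lpms)
        phast, phylop = sim.simulate_tracks(sc, genome, lpms)
        clinical, gtex = sim.simulate_variants(sc, genome, lpms)
        cohort = sim.simulate_cohort(sc, genome)
        mo.write_lpm_file(lpm_path, lpms.values())
        sim.write_fasta(outdir / "genome.fa", genome.sequences)
        intervals.write_chrom_sizes(outdir / "chrom.sizes", sc.chrom_sizes)
        intervals.write_genes_tsv(outdir / "genes.tsv", genome.genes)
        genome.truth.to_csv(outdir / "truth_motifs.tsv", sep="\t", index=False)
        phast.to_bedgraph(outdir / "phastcons.bedgraph")
        phylop.to_bedgraph(outdir / "phylop.bedgraph")
        sim.write_clinical_vcf(outdir / "clinical.vcf", clinical, sc.chrom_sizes)
        sim.write_eqtl_tsv(outdir / "gtex_eqtl.tsv", gtex)
        sim.write_genotype_vcf(
            outdir / "genotypes.vcf", cohort.genotypes, sc.chrom_sizes
        )
        sim.write_expression_tsv(outdir / "expr_control.tsv", cohort.expr_control)
        sim.write_expression_tsv(outdir / "expr_tm.tsv", cohort.expr_tm)
        cohort.effects.to_csv(outdir / "truth_effects.tsv", sep="\t", index=False)
        return _write_manifest(
            outdir, stage, [], sorted(p.name for p in outdir.iterdir()),
            {"simulation": asdict(sc)}, sc.seed,
            {"planted_motifs": len(genome.truth), "genes": len(genome.genes),
             "clinical_variants": len(clinical), "eqtl_variants": len(gtex)},
            t0,
        )

    if stage == "scan":
        from pyfaidx import Fasta

        fa = Fasta(str(_require(outdir / "genome.fa")))
        genome = {name: str(fa[name][:]) for name in fa.keys()}
        frames = []
        thresholds = {}
        for name, lpm in lpms.items():
            threshold = mo.wobble_score(lpm)
            thresholds[name] = threshold
            dist = mo.exact_score_distribution(lpm)
            frames.append(mo.scan_genome(genome, lpm, threshold, dist=dist))
        hits = pd.concat(frames, ignore_index=True)
        hits.to_csv(outdir / "hits.tsv", sep="\t", index=False)
        intervals.write_bed(outdir / "hits.bed", intervals.hits_to_bed(hits))
        return _write_manifest(
            outdir, stage, ["genome.fa", "motifs.lpm"], ["hits.tsv", "hits.bed"],
            {"thresholds_bits": thresholds,
             "pvalue_cutoffs": config.pvalue_cutoffs},
            config.seed,
            {"hits": len(hits),
             **{f"hits_{m}": int((hits['motif'] == m).sum()) for m in lpms}},
            t0,
        )

    if stage == "filter-proximity":
        hits = pd.read_csv(_require(outdir / "hits.tsv"), sep="\t")
        genes = intervals.read_genes_tsv(_require(outdir / "genes.tsv"))
        retained, pairs, n_genes = intervals.window_filter(
            hits, genes, config.window_bp
        )
        retained.to_csv(outdir / "hits_proximal.tsv", sep="\t", index=False)
        pairs.to_csv(outdir / "hit_gene_pairs.tsv", sep="\t", index=False)
        return _write_manifest(
            outdir, stage, ["hits.tsv", "genes.tsv"],
            ["hits_proximal.tsv", "hit_gene_pairs.tsv"],
            {"window_bp": config.window_bp}, config.seed,
            {"hits_in": len(hits), "hits_out": len(retained),
             "genes_with_hit": n_genes},
            t0,
        )

    if stage == "filter-conservation":
        hits = pd.read_csv(_require(outdir / "hits_proximal.tsv"), sep="\t")
        sizes = intervals.read_chrom_sizes(_require(outdir / "chrom.sizes"))
        track = cons.ConservationTrack.from_bedgraph(
            _require(outdir / "phastcons.bedgraph"), "phastcons", sizes
        )
        retained = cons.conservation_filter(hits, track, config.conservation_cutoff)
        retained.to_csv(outdir / "hits_conserved.tsv", sep="\t", index=False)
        return _write_manifest(
            outdir, stage, ["hits_proximal.tsv", "phastcons.bedgraph"],
            ["hits_conserved.tsv"],
            {"cutoff": config.conservation_cutoff}, config.seed,
            {"hits_in": len(hits), "hits_out": len(retained)},
            t0,
        )

    if stage == "positional":
        hits = pd.read_csv(_require(outdir / "hits.tsv"), sep="\t")
        gtex = enrichment.read_eqtl_tsv(_require(outdir / "gtex_eqtl.tsv"))
        sizes = intervals.read_chrom_sizes(_require(outdir / "chrom.sizes"))
        overlap = enrichment.variant_motif_overlap(
            gtex, hits, lpms, half_site=config.half_site
        )
        chisq = enrichment.position_chisq_table(overlap, lpms)
        chisq.to_csv(outdir / "positional_chisq.tsv", sep="\t", index=False)
        phylop = cons.ConservationTrack.from_bedgraph(
            _require(outdir / "phylop.bedgraph"), "phylop", sizes
        )
        profiles, anova_rows = [], []
        for name in lpms:
            sub = hits[hits["motif"] == name]
            if sub.empty:
                continue
            profiles.append(cons.positional_profile(sub, phylop))
            groups = cons.positional_values(sub, phylop)
            F, p = cons.anova_positions(groups)
            anova_rows.append({"motif": name, "F": F, "p": p})
        pd.concat(profiles, ignore_index=True).to_csv(
            outdir / "phylop_profile.tsv", sep="\t", index=False
        )
        pd.DataFrame(anova_rows).to_csv(
            outdir / "positional_anova.tsv", sep="\t", index=False
        )
        return _write_manifest(
            outdir, stage,
            ["hits.tsv", "gtex_eqtl.tsv", "phylop.bedgraph"],
            ["positional_chisq.tsv", "phylop_profile.tsv", "positional_anova.tsv"],
            {"half_site": config.half_site}, config.seed,
            {"overlap_pairs": len(overlap),
             "positions_tested": len(chisq)},
            t0,
        )

    if stage == "permute":
        hits = pd.read_csv(_require(outdir / "hits.tsv"), sep="\t")
        gtex = enrichment.read_eqtl_tsv(_require(outdir / "gtex_eqtl.tsv"))
        sizes = intervals.read_chrom_sizes(_require(outdir / "chrom.sizes"))
        results = {}
        tests = []
        for name, lpm in lpms.items():
            sub = hits[hits["motif"] == name]
            if sub.empty:
                continue
            length = (
                len(lpm.informative_positions) if config.half_site else lpm.length
            )
            tests.append((name, sub, [(length, len(sub))]))
        m = len(tests)
        for name, sub, spec in tests:
            res = enrichment.permutation_enrichment(
                sub, gtex, sizes, spec,
                N=config.permutation_n, seed=config.seed, bonferroni_m=m,
            )
            results[name] = {
                "n_real": res.n_real, "N": int(res.draws.size),
                "p_raw": res.p_raw, "p_adj": res.p_adj, "seed": res.seed,
                "mean_null": float(res.draws.mean()),
            }
        (outdir / "permutation.json").write_text(json.dumps(results, indent=2))
        return _write_manifest(
            outdir, stage, ["hits.tsv", "gtex_eqtl.tsv", "chrom.sizes"],
            ["permutation.json"],
            {"N": config.permutation_n, "half_site": config.half_site,
             "bonferroni_m": m},
            config.seed, {k: v["n_real"] for k, v in results.items()}, t0,
        )

    if stage == "clinvar":
        hits = pd.read_csv(_require(outdir / "hits.tsv"), sep="\t")
        clinical = enrichment.read_clinvar_vcf(_require(outdir / "clinical.vcf"))
        overlap = enrichment.variant_motif_overlap(
            clinical, hits, lpms, half_site=config.half_site
        )
        table = enrichment.benign_enrichment_table(overlap, clinical, lpms)
        table.to_csv(outdir / "clinvar_positions.tsv", sep="\t", index=False)
        n_indel = int(overlap["is_indel"].sum())
        return _write_manifest(
            outdir, stage, ["hits.tsv", "clinical.vcf"],
            ["clinvar_positions.tsv"],
            {"half_site": config.half_site}, config.seed,
            {"overlap_pairs": len(overlap), "indel_overlaps": n_indel,
             "positions_tested": len(table)},
            t0,
        )

    if stage == "eqtl":
        gm = eqtl.GenotypeMatrix.from_vcf(_require(outdir / "genotypes.vcf"))
        genes = intervals.read_genes_tsv(_require(outdir / "genes.tsv"))
        pairs = eqtl.cis_pairs(genes, gm.meta.reset_index(), config.cis_window)
        outputs = []
        rows = {"pairs": len(pairs)}
        for cond, path in (("control", "expr_control.tsv"), ("tm", "expr_tm.tsv")):
            em = eqtl.ExpressionMatrix.from_tsv(
                _require(outdir / path), outdir / "genes.tsv", cond
            )
            assoc = eqtl.fdr_adjust(
                eqtl.nominal_scan(pairs, gm, em), config.fdr_alpha
            )
            out = outdir / f"assoc_{cond}.tsv"
            assoc.to_csv(out, sep="\t", index=False)
            outputs.append(out.name)
            rows[f"assoc_{cond}"] = len(assoc)
            rows[f"significant_{cond}"] = int(assoc["significant"].sum())
        return _write_manifest(
            outdir, stage,
            ["genotypes.vcf", "genes.tsv", "expr_control.tsv", "expr_tm.tsv"],
            outputs,
            {"cis_window": config.cis_window, "fdr_alpha": config.fdr_alpha},
            config.seed, rows, t0,
        )

    if stage == "classify":
        a = pd.read_csv(_require(outdir / "assoc_control.tsv"), sep="\t")
        b = pd.read_csv(_require(outdir / "assoc_tm.tsv"), sep="\t")
        classification = eqtl.classify_conditions(a, b, config.fdr_alpha)
        classification.to_csv(outdir / "classification.tsv", sep="\t", index=False)
        esz = eqtl.effect_size_table(a, b)
        esz.to_csv(outdir / "effect_size_diff.tsv", sep="\t", index=False)
        counts = classification["class"].value_counts().to_dict()
        return _write_manifest(
            outdir, stage, ["assoc_control.tsv", "assoc_tm.tsv"],
            ["classification.tsv", "effect_size_diff.tsv"],
            {"fdr_alpha": config.fdr_alpha}, config.seed,
            {str(k): int(v) for k, v in counts.items()}, t0,
        )

    if stage == "report":
        funnel = {}
        for st, key in (
            ("scan", "hits"), ("filter-proximity", "hits_out"),
            ("filter-conservation", "hits_out"),
        ):
            man = outdir / f"{st}.manifest.json"
            if man.exists():
                funnel[st] = json.loads(man.read_text())["rows"][key]
        (outdir / "report.json").write_text(json.dumps({"funnel": funnel}, indent=2))
        return _write_manifest(
            outdir, stage, [f"{s}.manifest.json" for s in funnel], ["report.json"],
            {}, config.seed, funnel, t0,
        )

    raise PipelineError(f"stage {stage!r} not implemented")  # pragma: no cover


def run_all(config: PipelineConfig) -> dict[str, dict]:
    """Run every stage in order; returns manifests keyed by stage."""
    return {stage: run_stage(stage, config) for stage in STAGES}
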