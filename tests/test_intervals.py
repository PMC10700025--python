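"""Interval arithmetic: window filtering, overlap counting, random regions,
half-site masking and motif-position projection — cross-checked against a
quadratic oracle and against bedtools."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from ermotifs.intervals import (
    GeneModel,
    half_site_mask,
    intersect_count,
    motif_position_to_genomic,
    project_to_motif_position,
    random_regions,
    read_bed,
    read_chrom_sizes,
    read_genes_tsv,
    window_filter,
    write_bed,
    write_chrom_sizes,
    write_genes_tsv,
)

from conftest import hits_frame


def intervals_frame(triples):
    return pd.DataFrame(triples, columns=["chrom", "start", "end"])


def quadratic_overlap(query, subject):
    """O(n*m) overlap oracle on half-open intervals."""
    pairs = set()
    for qi, q in query.iterrows():
        for si, s in subject.iterrows():
            if q["chrom"] == s["chrom"] and q["start"] < s["end"] and s["start"] < q["end"]:
                pairs.add((qi, si))
    return pairs


def random_intervals(rng, n, chroms=("c1", "c2"), size=1000, max_len=60):
    starts = rng.integers(0, size - max_len, n)
    lengths = rng.integers(0, max_len, n)  # zero-length intervals allowed
    return pd.DataFrame(
        {
            "chrom": rng.choice(chroms, n),
            "start": starts,
            "end": starts + lengths,
        }
    )


class TestGeneModel:
    def test_tss_strand_aware(self):
        plus = GeneModel("g", "c", 100, 200, "+")
        minus = GeneModel("g", "c", 100, 200, "-")
        assert plus.tss == 101
        assert minus.tss == 200

    def test_rejects_bad_coordinates(self):
        with pytest.raises(ValueError):
            GeneModel("g", "c", 200, 100, "+")


class TestWindowFilter:
    GENES = pd.DataFrame(
        [{"gene_id": "G1", "chrom": "c", "start": 1000, "end": 2000, "strand": "+"}]
    )

    def test_hit_in_downstream_window_retained(self):
        hits = hits_frame([("c", 2500, 2519, "+", "M")])
        retained, pairs, n_genes = window_filter(hits, self.GENES, 2000)
        assert len(retained) == 1
        assert n_genes == 1

    def test_hit_past_window_dropped(self):
        hits = hits_frame([("c", 4100, 4119, "+", "M")])
        retained, _, _ = window_filter(hits, self.GENES, 2000)
        assert retained.empty

    def test_hit_inside_gene_body_retained(self):
        hits = hits_frame([("c", 1500, 1519, "+", "M")])
        retained, _, _ = window_filter(hits, self.GENES, 2000)
        assert len(retained) == 1

    def test_zero_window_equals_gene_body_overlap(self):
        rng = np.random.default_rng(4)
        hits = random_intervals(rng, 60).assign(strand="+", motif="M",
                                                score=0.0, pvalue=1.0)
        genes = random_intervals(rng, 10)
        genes["gene_id"] = [f"G{i}" for i in range(10)]
        genes["strand"] = "+"
        retained, _, _ = window_filter(hits, genes, 0)
        expected = {qi for qi, _ in quadratic_overlap(hits, genes)}
        assert set(retained.index) == expected

    def test_empty_gene_list(self):
        hits = hits_frame([("c", 0, 10, "+", "M")])
        retained, pairs, n_genes = window_filter(hits, self.GENES.iloc[0:0], 2000)
        assert retained.empty and n_genes == 0


class TestIntersectCount:
    def test_point_variant_in_motif(self):
        q = intervals_frame([("c", 10, 11)])
        s = intervals_frame([("c", 5, 24)])
        pairs, counts = intersect_count(q, s)
        assert counts == {"n_pairs": 1, "n_distinct_query": 1}

    def test_touching_intervals_do_not_overlap(self):
        q = intervals_frame([("c", 0, 5)])
        s = intervals_frame([("c", 5, 10)])
        _, counts = intersect_count(q, s)
        assert counts["n_pairs"] == 0

    def test_distinct_vs_pair_counts(self):
        q = intervals_frame([("c", 10, 11)])
        s = intervals_frame([("c", 5, 24), ("c", 8, 30)])
        _, counts = intersect_count(q, s)
        assert counts == {"n_pairs": 2, "n_distinct_query": 1}

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_quadratic_oracle(self, seed):
        rng = np.random.default_rng(seed)
        q = random_intervals(rng, int(rng.integers(5, 50)))
        s = random_intervals(rng, int(rng.integers(5, 50)))
        pairs, _ = intersect_count(q, s)
        got = set(zip(pairs["query_index"], pairs["subject_index"]))
        assert got == quadratic_overlap(q, s)


class TestRandomRegions:
    def test_widths_and_counts_match_spec(self):
        sizes = {"c1": 5000, "c2": 3000}
        regions = random_regions(sizes, [(10, 300), (8, 200)], 0)
        assert len(regions) == 500
        widths = regions["end"] - regions["start"]
        assert (widths.iloc[:300] == 10).all()
        assert (widths.iloc[300:] == 8).all()
        for row in regions.itertuples():
            assert 0 <= row.start and row.end <= sizes[row.chrom]

    def test_forced_placement_single_slot(self):
        regions = random_regions({"c": 100}, [(100, 1)], 0)
        assert regions.iloc[0][["start", "end"]].tolist() == [0, 100]

    def test_deterministic_given_seed(self):
        sizes = {"c1": 5000, "c2": 3000}
        a = random_regions(sizes, [(10, 500)], 42)
        b = random_regions(sizes, [(10, 500)], 42)
        pd.testing.assert_frame_equal(a, b)

    def test_length_exceeding_all_chromosomes(self):
        with pytest.raises(ValueError):
            random_regions({"c": 50}, [(100, 1)], 0)

    def test_starts_proportional_to_chromosome_length(self):
        # 2-chromosome toy genome, 10,000 draws: chr share within 4 SD
        sizes = {"a": 3000, "b": 1000}
        regions = random_regions(sizes, [(10, 10_000)], 7)
        p = (3000 - 9) / (3000 - 9 + 1000 - 9)
        n_a = int((regions["chrom"] == "a").sum())
        sd = np.sqrt(10_000 * p * (1 - p))
        assert abs(n_a - 10_000 * p) < 4 * sd


class TestHalfSiteMask:
    def test_ersei_plus_strand(self, motifs):
        hit = hits_frame([("c", 100, 119, "+", "ERSEI")]).iloc[0]
        mask = half_site_mask(hit, motifs["ERSEI"])
        assert mask == [("c", 100, 105), ("c", 114, 119)]

    def test_ersei_minus_strand_symmetric(self, motifs):
        hit = hits_frame([("c", 100, 119, "-", "ERSEI")]).iloc[0]
        mask = half_site_mask(hit, motifs["ERSEI"])
        assert mask == [("c", 100, 105), ("c", 114, 119)]

    def test_erseii_single_spacer(self, motifs):
        hit = hits_frame([("c", 50, 61, "+", "ERSEII")]).iloc[0]
        mask = half_site_mask(hit, motifs["ERSEII"])
        assert mask == [("c", 50, 55), ("c", 56, 61)]

    def test_upre_identity(self, motifs):
        hit = hits_frame([("c", 10, 18, "+", "UPRE")]).iloc[0]
        assert half_site_mask(hit, motifs["UPRE"]) == [("c", 10, 18)]

    def test_motif_name_mismatch_rejected(self, motifs):
        hit = hits_frame([("c", 10, 18, "+", "UPRE")]).iloc[0]
        with pytest.raises(ValueError):
            half_site_mask(hit, motifs["ERSEI"])


class TestProjection:
    def test_plus_strand_examples(self):
        hit = hits_frame([("c", 100, 119, "+", "ERSEI")]).iloc[0]
        assert project_to_motif_position(117, hit) == 18
        assert project_to_motif_position(100, hit) == 1

    def test_minus_strand_example(self):
        hit = hits_frame([("c", 100, 119, "-", "ERSEI")]).iloc[0]
        assert project_to_motif_position(101, hit) == 18

    def test_outside_hit_rejected(self):
        hit = hits_frame([("c", 100, 119, "+", "ERSEI")]).iloc[0]
        with pytest.raises(ValueError):
            project_to_motif_position(119, hit)

    @pytest.mark.parametrize("strand", "+-")
    def test_projection_round_trip(self, strand):
        hit = hits_frame([("c", 100, 119, strand, "ERSEI")]).iloc[0]
        for p in range(1, 20):
            g = motif_position_to_genomic(p, hit)
            assert project_to_motif_position(g, hit) == p
        for g in range(100, 119):
            assert motif_position_to_genomic(project_to_motif_position(g, hit), hit) == g


class TestBedtoolsOracle:
    """Cross-checks against bedtools intersect/window on random inputs."""

    @pytest.fixture(autouse=True)
    def _bedtools(self):
        assert shutil.which("bedtools"), "bedtools expected on PATH"

    def run_bedtools(self, args, cwd):
        return subprocess.run(
            ["bedtools", *args], capture_output=True, text=True, check=True, cwd=cwd
        ).stdout

    def test_intersect_matches_bedtools(self, tmp_path):
        rng = np.random.default_rng(21)
        q = random_intervals(rng, 40).sort_values(["chrom", "start"])
        s = random_intervals(rng, 40).sort_values(["chrom", "start"])
        # bedtools treats zero-length intervals differently; keep them positive
        q["end"] = np.maximum(q["end"], q["start"] + 1)
        s["end"] = np.maximum(s["end"], s["start"] + 1)
        write_bed(tmp_path / "q.bed", q)
        write_bed(tmp_path / "s.bed", s)
        out = self.run_bedtools(
            ["intersect", "-a", "q.bed", "-b", "s.bed", "-wa", "-wb"], tmp_path
        )
        n_bedtools = len([l for l in out.splitlines() if l.strip()])
        _, counts = intersect_count(q, s)
        assert counts["n_pairs"] == n_bedtools

    def test_window_matches_bedtools(self, tmp_path):
        rng = np.random.default_rng(22)
        hits = random_intervals(rng, 50, size=20_000)
        hits = hits.assign(strand="+", motif="M", score=0.0, pvalue=1.0)
        hits["end"] = hits["start"] + 19
        genes = random_intervals(rng, 8, size=20_000)
        genes["end"] = genes["start"] + 2000
        genes["gene_id"] = [f"G{i}" for i in range(8)]
        genes["strand"] = "+"
        write_bed(tmp_path / "hits.bed", hits[["chrom", "start", "end"]])
        write_bed(tmp_path / "genes.bed", genes[["chrom", "start", "end"]])
        out = self.run_bedtools(
            ["window", "-a", "hits.bed", "-b", "genes.bed", "-w", "2000", "-u"],
            tmp_path,
        )
        n_bedtools = len([l for l in out.splitlines() if l.strip()])
        retained, _, _ = window_filter(hits, genes, 2000)
        assert len(retained) == n_bedtools


def test_text_format_round_trips(tmp_path):
    sizes = {"chr1": 1000, "chr2": 500}
    write_chrom_sizes(tmp_path / "sizes", sizes)
    assert read_chrom_sizes(tmp_path / "sizes") == sizes

    genes = pd.DataFrame(
        [
            {"gene_id": "G1", "chrom": "chr1", "start": 10, "end": 400, "strand": "+"},
            {"gene_id": "G2", "chrom": "chr2", "start": 5, "end": 300, "strand": "-"},
        ]
    )
    write_genes_tsv(tmp_path / "genes.tsv", genes)
    back = read_genes_tsv(tmp_path / "genes.tsv")
    assert back["tss"].tolist() == [11, 300]

    bed = pd.DataFrame(
        {"chrom": ["chr1"], "start": [5], "end": [25],
         "name": ["M"], "score": [1.5], "strand": ["-"]}
    )
    write_bed(tmp_path / "x.bed", bed)
    back = read_bed(tmp_path / "x.bed")
    assert back.loc[0, "strand"] == "-"
    assert back.loc[0, "start"] == 5


def test_bed_reader_reports_line_number(tmp_path):
    (tmp_path / "bad.bed").write_text("chr1\t0\t10\nchr1\t5\n")
    with pytest.raises(ValueError, match="2"):
        read_bed(tmp_path / "bad.bed")


def test_gene_tsv_rejects_missing_columns(tmp_path):
    (tmp_path / "genes.tsv").write_text("gene_id\tchrom\n")
    with pytest.raises(ValueError, match="missing columns"):
        read_genes_tsv(tmp_path / "genes.tsv")
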