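"""Genomic interval arithmetic with bedtools-compatible semantics.

All coordinates are 0-based half-open.  Overlap means >= 1 shared base, so
touching intervals ([0,5) and [5,10)) do not overlap.  The operations here
mirror the classic `bedtools window`, `intersect` and `random` commands:
gene-proximity filtering of motif hits, variant/motif overlap counting, and
matched random region generation for permutation nulls.  Also houses the
strand-aware projection between genome coordinates and 1-based motif
positions, and the ERSE half-site mask (first/last five bases of
ERSEI/ERSEII; the spacer sets spacing only).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .motifs import LetterProbabilityMatrix


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene body with its strand-aware TSS (1-based)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"{self.gene_id}: start must be < end")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")

    @property
    def tss(self) -> int:
        """1-based transcription start: start+1 on +, end on -."""
        return self.start + 1 if self.strand == "+" else self.end


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    payload: object | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("start must be <= end")


def overlap_pairs(query: pd.DataFrame, subject: pd.DataFrame) -> pd.DataFrame:
    """All (query, subject) index pairs sharing >= 1 base.

    Both frames need ``chrom, start, end`` columns; returned frame has
    ``query_index`` / ``subject_index`` referring to the input row labels.
    """
    out_q: list[np.ndarray] = []
    out_s: list[np.ndarray] = []
    for chrom, qc in query.groupby("chrom", sort=False):
        sc = subject[subject["chrom"] == chrom]
        if sc.empty or qc.empty:
            continue
        s_order = np.argsort(sc["start"].to_numpy(), kind="stable")
        s_start = sc["start"].to_numpy()[s_order]
        s_end = sc["end"].to_numpy()[s_order]
        s_idx = sc.index.to_numpy()[s_order]
        q_start = qc["start"].to_numpy()
        q_end = qc["end"].to_numpy()
        q_idx = qc.index.to_numpy()
        # subjects with start < q.end are candidates; filter on end > q.start
        hi = np.searchsorted(s_start, q_end, side="left")
        for qi, qs, h in zip(q_idx, q_start, hi):
            cand = np.where(s_end[:h] > qs)[0]
            if cand.size:
                out_q.append(np.full(cand.size, qi))
                out_s.append(s_idx[cand])
    if not out_q:
        return pd.DataFrame({"query_index": [], "subject_index": []}, dtype=np.int64)
    return pd.DataFrame(
        {
            "query_index": np.concatenate(out_q),
            "subject_index": np.concatenate(out_s),
        }
    )


def intersect_count(
    query: pd.DataFrame, subject: pd.DataFrame
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Overlap pairs plus the two summary counts.

    ``n_pairs`` counts every (query, subject) pair; ``n_distinct_query``
    counts query features overlapping >= 1 subject (a variant hitting two
    motifs counts once).  Both are reported because either reading of
    "number of overlaps" is defensible.
    """
    pairs = overlap_pairs(query, subject)
    return pairs, {
        "n_pairs": len(pairs),
        "n_distinct_query": int(pairs["query_index"].nunique()),
    }


def window_filter(
    hits: pd.DataFrame,
    genes: pd.DataFrame,
    window_bp: int = 2000,
) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Keep hits within ``window_bp`` of a gene body (or inside one).

    A hit is retained iff it overlaps ``[gene.start - window, gene.end +
    window)`` for at least one gene — i.e. up to 2 kb upstream, within the
    gene, or up to 2 kb downstream at the default.  Returns ``(retained
    hits, hit-gene pairs, number of genes with >= 1 retained hit)``.
    """
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")
    if genes.empty or hits.empty:
        empty = pd.DataFrame({"query_index": [], "gene_id": []})
        return hits.iloc[0:0], empty, 0
    windows = genes.copy()
    windows["start"] = (windows["start"] - window_bp).clip(lower=0)
    windows["end"] = windows["end"] + window_bp
    pairs = overlap_pairs(hits, windows)
    pairs = pairs.assign(gene_id=genes.loc[pairs["subject_index"], "gene_id"].to_numpy()
                         if len(pairs) else [])
    retained = hits.loc[np.unique(pairs["query_index"])] if len(pairs) else hits.iloc[0:0]
    n_genes = int(pairs["gene_id"].nunique()) if len(pairs) else 0
    return retained, pairs[["query_index", "gene_id"]], n_genes


def random_regions(
    chrom_sizes: Mapping[str, int],
    spec: Sequence[tuple[int, int]],
    rng: np.random.Generator | int,
    names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Random genomic intervals matched in length and number to a motif set.

    For each ``(length, count)`` entry, draws ``count`` intervals of exactly
    ``length`` bases placed uniformly over all valid start positions (so
    chromosomes are weighted by length), fully inside a chromosome; regions
    may overlap each other.  Deterministic given the RNG/seed.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    chroms = list(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=np.int64)
    frames = []
    for j, (length, count) in enumerate(spec):
        if count < 1:
            raise ValueError("each spec count must be >= 1")
        valid = sizes - length + 1
        if (valid <= 0).all():
            raise ValueError(f"length {length} exceeds every chromosome")
        w = np.clip(valid, 0, None)
        cum = np.cumsum(w)
        r = rng.integers(0, cum[-1], size=count)
        ci = np.searchsorted(cum, r, side="right")
        start = r - (cum[ci] - w[ci])
        frames.append(
            pd.DataFrame(
                {
                    "chrom": np.array(chroms, dtype=object)[ci],
                    "start": start,
                    "end": start + length,
                    "name": names[j] if names is not None else f"set{j}",
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def half_site_mask(hit, lpm: LetterProbabilityMatrix) -> list[tuple[str, int, int]]:
    """Genomic sub-intervals covering the non-spacer motif positions.

    ``hit`` is any object with ``chrom/start/end/strand/motif`` attributes
    (a MotifHit or a hit-table row).  Strand-aware: motif position p maps to
    genomic base start+p-1 on '+' and end-p on '-'.  Motifs without a spacer
    return the whole hit interval.
    """
    if hit.motif != lpm.name:
        raise ValueError(f"hit motif {hit.motif!r} does not match LPM {lpm.name!r}")
    if not lpm.spacer_positions:
        return [(hit.chrom, int(hit.start), int(hit.end))]
    runs: list[tuple[int, int]] = []
    for p in lpm.informative_positions:
        if runs and p == runs[-1][1] + 1:
            runs[-1] = (runs[-1][0], p)
        else:
            runs.append((p, p))
    out = []
    for a, b in runs:
        if hit.strand == "+":
            out.append((hit.chrom, int(hit.start) + a - 1, int(hit.start) + b))
        else:
            out.append((hit.chrom, int(hit.end) - b, int(hit.end) - a + 1))
    return sorted(out, key=lambda t: t[1])


def project_to_motif_position(position: int, hit) -> int:
    """Map a 0-based genomic base inside a hit to its 1-based motif position."""
    if not int(hit.start) <= position < int(hit.end):
        raise ValueError(
            f"position {position} outside hit [{hit.start}, {hit.end})"
        )
    if hit.strand == "+":
        return position - int(hit.start) + 1
    return int(hit.end) - position


def motif_position_to_genomic(motif_position: int, hit) -> int:
    """Inverse of :func:`project_to_motif_position` (0-based genomic base)."""
    L = int(hit.end) - int(hit.start)
    if not 1 <= motif_position <= L:
        raise ValueError(f"motif position {motif_position} outside 1..{L}")
    if hit.strand == "+":
        return int(hit.start) + motif_position - 1
    return int(hit.end) - motif_position


# ---------------------------------------------------------------------------
# plain-text readers/writers
# ---------------------------------------------------------------------------

def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    out: dict[str, int] = {}
    for line in Path(path).read_text().splitlines():
        if line.strip():
            name, size = line.split("\t")[:2]
            out[name] = int(size)
    return out


def write_chrom_sizes(path: str | Path, sizes: Mapping[str, int]) -> None:
    Path(path).write_text("".join(f"{c}\t{n}\n" for c, n in sizes.items()))


def read_genes_tsv(path: str | Path) -> pd.DataFrame:
    """Gene TSV: gene_id, chrom, start, end, strand (header required)."""
    genes = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"gene_id", "chrom", "start", "end", "strand"}
    missing = required - set(genes.columns)
    if missing:
        raise ValueError(f"{path}: gene TSV missing columns {sorted(missing)}")
    genes["tss"] = np.where(genes["strand"] == "+", genes["start"] + 1, genes["end"])
    return genes


def write_genes_tsv(path: str | Path, genes: pd.DataFrame) -> None:
    genes[["gene_id", "chrom", "start", "end", "strand"]].to_csv(
        path, sep="\t", index=False
    )


def read_bed(path: str | Path) -> pd.DataFrame:
    """BED3/BED6 reader (no header; track/browser lines skipped)."""
    rows = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("track", "browser", "#")):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: BED line has fewer than 3 fields")
        row = {"chrom": parts[0], "start": int(parts[1]), "end": int(parts[2])}
        if len(parts) >= 6:
            row.update(name=parts[3], score=parts[4], strand=parts[5])
        rows.append(row)
    return pd.DataFrame(rows)


def write_bed(path: str | Path, intervals: pd.DataFrame) -> None:
    """Write BED6 when name/score/strand columns exist, else BED3."""
    cols = ["chrom", "start", "end"]
    bed6 = {"name", "score", "strand"} <= set(intervals.columns)
    with open(path, "w") as fh:
        for row in intervals.itertuples(index=False):
            fields = [str(getattr(row, c)) for c in cols]
            if bed6:
                fields += [str(row.name), str(row.score), str(row.strand)]
            fh.write("\t".join(fields) + "\n")


def hits_to_bed(hits: pd.DataFrame) -> pd.DataFrame:
    """Hit table -> BED6 frame (name=motif, score=bits to 3 decimals)."""
    return pd.DataFrame(
        {
            "chrom": hits["chrom"],
            "start": hits["start"],
            "end": hits["end"],
            "name": hits["motif"],
            "score": hits["score"].round(3),
            "strand": hits["strand"],
        }
    )
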