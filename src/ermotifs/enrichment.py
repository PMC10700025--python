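"""Variant-enrichment statistics for predicted binding sites.

Three bespoke procedures:

* a permutation null that regenerates random genomic regions matched in
  length and number to the predicted motif set and recounts variant
  overlaps, with the unbiased estimate
  ``p = (#{n* >= n_real} + 1) / (N + 1)``;
* a per-position chi-squared goodness-of-fit test asking whether one motif
  position holds more variants than the others combined, assuming equal
  counts across positions (df = 1, Bonferroni over positions);
* a per-position one-sided binomial test for overrepresentation of benign
  relative to pathogenic clinical variants, with the benign probability
  estimated motif-wide.

SNV counting respects the ERSE half-site rule (only the first and last five
bases of ERSEI/ERSEII contact the factors) while insertions/deletions count
anywhere in the motif, spacer included, because they change half-site
spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import overlap_pairs, project_to_motif_position
from .motifs import LetterProbabilityMatrix

PATH_LABELS = {"pathogenic", "likely_pathogenic"}
BENIGN_LABELS = {"benign", "likely_benign"}


@dataclass(frozen=True)
class VariantRecord:
    """A point variant or indel with optional clinical/eQTL payload."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    significance: str | None = None
    payload: Mapping | None = None

    @property
    def var_class(self) -> str:
        return "SNV" if len(self.ref) == 1 and len(self.alt) == 1 else "indel"

    @property
    def group(self) -> str | None:
        """PATH / BENIGN grouping used by the binomial analysis."""
        if self.significance is None:
            return None
        sig = self.significance.lower().replace(" ", "_")
        if sig in PATH_LABELS:
            return "PATH"
        if sig in BENIGN_LABELS:
            return "BENIGN"
        return None


@dataclass
class PermutationResult:
    """Observed overlap count against N matched-random-region redraws."""

    n_real: int
    draws: np.ndarray
    seed: int
    bonferroni_m: int = 1
    p_raw: float = field(init=False)
    p_adj: float = field(init=False)

    def __post_init__(self) -> None:
        self.draws = np.asarray(self.draws)
        n_ge = int((self.draws >= self.n_real).sum())
        self.p_raw = (n_ge + 1) / (self.draws.size + 1)
        self.p_adj = min(1.0, self.p_raw * self.bonferroni_m)


# ---------------------------------------------------------------------------
# variant tables
# ---------------------------------------------------------------------------

def variants_to_frame(variants: Sequence[VariantRecord]) -> pd.DataFrame:
    """Tabulate records with half-open interval columns for overlap math.

    SNVs span one base; a deletion spans its full reference allele.
    """
    rows = []
    for v in variants:
        rows.append(
            {
                "chrom": v.chrom,
                "start": v.pos - 1,
                "end": v.pos - 1 + max(1, len(v.ref)),
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "var_class": v.var_class,
                "group": v.group,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "pos", "ref", "alt", "var_class", "group",
        ],
    )


def read_clinvar_vcf(path: str | Path) -> pd.DataFrame:
    """Read a VCF with clinical significance under the CLNSIG info key."""
    from cyvcf2 import VCF

    records = []
    for var in VCF(str(path)):
        sig = var.INFO.get("CLNSIG")
        for alt in var.ALT:
            records.append(
                VariantRecord(
                    chrom=var.CHROM,
                    pos=var.POS,
                    ref=var.REF,
                    alt=alt,
                    significance=str(sig) if sig is not None else None,
                )
            )
    return variants_to_frame(records)


def read_eqtl_tsv(path: str | Path) -> pd.DataFrame:
    """eQTL summary TSV: variant_id (chrom_pos_ref_alt), gene_id, tissue,
    pval_nominal.  Adds parsed interval columns."""
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str})
    required = {"variant_id", "gene_id", "tissue", "pval_nominal"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: eQTL TSV missing columns {sorted(missing)}")
    parts = df["variant_id"].str.rsplit("_", n=3, expand=True)
    df["chrom"] = parts[0]
    df["pos"] = parts[1].astype(np.int64)
    df["ref"] = parts[2]
    df["alt"] = parts[3]
    df["start"] = df["pos"] - 1
    df["end"] = df["start"] + df["ref"].str.len().clip(lower=1)
    df["var_class"] = np.where(
        (df["ref"].str.len() == 1) & (df["alt"].str.len() == 1), "SNV", "indel"
    )
    return df


# ---------------------------------------------------------------------------
# overlap with motif hits
# ---------------------------------------------------------------------------

def variant_motif_overlap(
    variants: pd.DataFrame,
    hits: pd.DataFrame,
    lpms: Mapping[str, LetterProbabilityMatrix],
    half_site: bool = True,
) -> pd.DataFrame:
    """All (variant, hit) pairs that count under the half-site/indel rules.

    SNVs count only at non-spacer motif positions when ``half_site`` is on
    (whole motif otherwise, or for motifs without a spacer); indels count
    when they overlap any motif base, spacer included, and carry no single
    motif position.  Returns one row per counted pair with
    ``variant_index, hit_index, motif, motif_position, is_indel, in_spacer``.
    """
    pairs = overlap_pairs(variants, hits)
    if pairs.empty:
        return pd.DataFrame(
            columns=[
                "variant_index", "hit_index", "motif",
                "motif_position", "is_indel", "in_spacer",
            ]
        )
    rows = []
    for vi, hi in zip(pairs["query_index"], pairs["subject_index"]):
        var = variants.loc[vi]
        hit = hits.loc[hi]
        lpm = lpms[hit["motif"]]
        if var["var_class"] == "indel":
            rows.append(
                {
                    "variant_index": vi,
                    "hit_index": hi,
                    "motif": hit["motif"],
                    "motif_position": np.nan,
                    "is_indel": True,
                    "in_spacer": True,  # counted regardless; flag is informational
                }
            )
            continue
        mpos = project_to_motif_position(int(var["start"]), hit)
        in_spacer = mpos in lpm.spacer_positions
        if half_site and in_spacer:
            continue
        rows.append(
            {
                "variant_index": vi,
                "hit_index": hi,
                "motif": hit["motif"],
                "motif_position": mpos,
                "is_indel": False,
                "in_spacer": in_spacer,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "variant_index", "hit_index", "motif",
            "motif_position", "is_indel", "in_spacer",
        ],
    )


def _count_covered_points(
    points: np.ndarray, starts: np.ndarray, ends: np.ndarray
) -> int:
    """Number of sorted points covered by the union of [start, end) ranges."""
    if points.size == 0 or starts.size == 0:
        return 0
    lo = np.searchsorted(points, starts, side="left")
    hi = np.searchsorted(points, ends, side="left")
    order = np.argsort(lo, kind="stable")
    lo, hi = lo[order], hi[order]
    hi_acc = np.maximum.accumulate(hi)
    prev = np.concatenate([[0], hi_acc[:-1]])
    return int(np.clip(hi - np.maximum(lo, prev), 0, None).sum())


def permutation_enrichment(
    hits: pd.DataFrame,
    variants: pd.DataFrame,
    chrom_sizes: Mapping[str, int],
    spec: Sequence[tuple[int, int]],
    N: int = 9999,
    seed: int = 0,
    bonferroni_m: int = 1,
) -> PermutationResult:
    """Permutation test of variant overlap against matched random regions.

    ``n_real`` counts distinct variants overlapping >= 1 hit.  Each of the
    ``N`` draws regenerates random regions per ``spec`` (length, count per
    motif) and recounts; ``p_raw = (#{n* >= n_real} + 1)/(N + 1)``.  Draw i
    uses a Philox stream keyed on (seed, i) so results are independent of
    execution order.  Variants are treated as points at their start base,
    matching single-base overlap counting of SNVs.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    pairs = overlap_pairs(variants, hits)
    n_real = int(pairs["query_index"].nunique()) if len(pairs) else 0

    chroms = list(chrom_sizes)
    points = {
        c: np.sort(variants.loc[variants["chrom"] == c, "start"].to_numpy(np.int64))
        for c in chroms
    }
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=np.int64)
    draws = np.empty(N, dtype=np.int64)
    for i in range(N):
        rng = np.random.Generator(np.random.Philox(key=[seed, i]))
        total = 0
        for length, count in spec:
            valid = np.clip(sizes - length + 1, 0, None)
            cum = np.cumsum(valid)
            r = rng.integers(0, cum[-1], size=count)
            ci = np.searchsorted(cum, r, side="right")
            start = r - (cum[ci] - valid[ci])
            for j, c in enumerate(chroms):
                m = ci == j
                if m.any():
                    total += _count_covered_points(
                        points[c], start[m], start[m] + length
                    )
        draws[i] = total
    return PermutationResult(n_real=n_real, draws=draws, seed=seed,
                             bonferroni_m=bonferroni_m)


# ---------------------------------------------------------------------------
# positional tests
# ---------------------------------------------------------------------------

def position_chisq(
    position_counts: Mapping[int, int] | Sequence[int],
    position: int,
) -> tuple[float, float, float]:
    """Chi-squared goodness-of-fit for one position vs the rest combined.

    Observed = (count at ``position``, count elsewhere); expected assumes
    equal counts across the k analysed positions, i.e. (total/k,
    total*(k-1)/k); df = 1, no continuity correction.  Returns
    ``(statistic, p, p_adj)`` with Bonferroni multiplier k.
    """
    if isinstance(position_counts, Mapping):
        keys = sorted(position_counts)
        counts = np.array([position_counts[k] for k in keys], dtype=float)
        idx = keys.index(position)
    else:
        counts = np.asarray(position_counts, dtype=float)
        idx = position - 1
    k = counts.size
    total = counts.sum()
    if total < 1:
        raise ValueError("total variant count must be >= 1")
    obs = np.array([counts[idx], total - counts[idx]])
    exp = np.array([total / k, total * (k - 1) / k])
    statistic = float(((obs - exp) ** 2 / exp).sum())
    p = float(stats.chi2.sf(statistic, df=1))
    return statistic, p, min(1.0, p * k)


def position_chisq_table(
    overlap: pd.DataFrame,
    lpms: Mapping[str, LetterProbabilityMatrix],
    dedup_variants: bool = True,
) -> pd.DataFrame:
    """Per-position chi-squared tests for every motif in an overlap table.

    ``overlap`` is the output of :func:`variant_motif_overlap`; indel rows
    are ignored (they carry no position).  For ERSE motifs only the
    half-site positions are analysed.  ``dedup_variants`` counts each
    variant once per motif position even when it overlaps several hits.
    """
    snvs = overlap[~overlap["is_indel"]]
    rows = []
    for motif, sub in snvs.groupby("motif", sort=False):
        lpm = lpms[motif]
        positions = list(lpm.informative_positions)
        if dedup_variants:
            sub = sub.drop_duplicates(["variant_index", "motif_position"])
        counts = {
            p: int((sub["motif_position"] == p).sum()) for p in positions
        }
        if sum(counts.values()) == 0:
            continue
        for p in positions:
            statistic, praw, padj = position_chisq(counts, p)
            rows.append(
                {
                    "motif": motif,
                    "position": p,
                    "count": counts[p],
                    "statistic": statistic,
                    "p": praw,
                    "p_adj": padj,
                }
            )
    return pd.DataFrame(
        rows, columns=["motif", "position", "count", "statistic", "p", "p_adj"]
    )


def benign_enrichment(
    benign_counts: Mapping[int, int] | Sequence[int],
    path_counts: Mapping[int, int] | Sequence[int],
) -> pd.DataFrame:
    """One-sided binomial tests for benign overrepresentation per position.

    The benign probability is estimated motif-wide as
    ``p_benign = B / (B + P)``; at a position with b benign of n variants,
    ``p = P(X >= b | Binomial(n, p_benign))``, Bonferroni-corrected over the
    positions analysed.  Positions with zero variants are skipped.
    """
    if isinstance(benign_counts, Mapping):
        keys = sorted(set(benign_counts) | set(path_counts))
        b = np.array([benign_counts.get(k, 0) for k in keys], dtype=np.int64)
        g = np.array([path_counts.get(k, 0) for k in keys], dtype=np.int64)
        positions = np.array(keys)
    else:
        b = np.asarray(benign_counts, dtype=np.int64)
        g = np.asarray(path_counts, dtype=np.int64)
        positions = np.arange(1, b.size + 1)
    total_b, total_g = int(b.sum()), int(g.sum())
    if total_b + total_g == 0:
        raise ValueError("no variants across the motif")
    p_benign = total_b / (total_b + total_g)
    n = b + g
    keep = n > 0
    k = int(keep.sum())
    pvals = stats.binom.sf(b[keep] - 1, n[keep], p_benign)
    return pd.DataFrame(
        {
            "position": positions[keep],
            "n": n[keep],
            "benign": b[keep],
            "pathogenic": g[keep],
            "p_benign": p_benign,
            "p": pvals,
            "p_adj": np.minimum(1.0, pvals * k),
            "enriched": np.minimum(1.0, pvals * k) < 0.05,
        }
    )


def benign_enrichment_table(
    overlap: pd.DataFrame,
    variants: pd.DataFrame,
    lpms: Mapping[str, LetterProbabilityMatrix],
) -> pd.DataFrame:
    """Benign-vs-pathogenic binomial tests per motif from an overlap table.

    Uses SNV rows whose variant carries a PATH/BENIGN group; each variant
    counts once per (motif, position).
    """
    snvs = overlap[~overlap["is_indel"]].drop_duplicates(
        ["variant_index", "motif", "motif_position"]
    )
    snvs = snvs.assign(group=variants.loc[snvs["variant_index"], "group"].to_numpy()
                       if len(snvs) else [])
    snvs = snvs[snvs["group"].isin(["PATH", "BENIGN"])]
    frames = []
    for motif, sub in snvs.groupby("motif", sort=False):
        positions = list(lpms[motif].informative_positions)
        bc = {
            p: int(((sub["motif_position"] == p) & (sub["group"] == "BENIGN")).sum())
            for p in positions
        }
        gc = {
            p: int(((sub["motif_position"] == p) & (sub["group"] == "PATH")).sum())
            for p in positions
        }
        if sum(bc.values()) + sum(gc.values()) == 0:
            continue
        table = benign_enrichment(bc, gc)
        table.insert(0, "motif", motif)
        frames.append(table)
    if not frames:
        return pd.DataFrame(
            columns=[
                "motif", "position", "n", "benign", "pathogenic",
                "p_benign", "p", "p_adj", "enriched",
            ]
        )
    return pd.concat(frames, ignore_index=True)
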