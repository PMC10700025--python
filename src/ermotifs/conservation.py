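"""Cross-species conservation filtering and positional profiles.

Two kinds of per-base track are supported: PhastCons-like (probability in
[0,1] that a base belongs to a conserved element) and PhyloP-like (signed
per-base rate, 0 = neutral).  Binding-site candidates are filtered on their
mean PhastCons score (fully-covered motifs only), and per-motif-position
PhyloP means are compared across positions with a one-way ANOVA followed —
when significant — by Tukey's HSD, including the one-vs-rest-combined
contrast used to ask whether variant-hotspot positions are less conserved
than the rest of the motif.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import motif_position_to_genomic


@dataclass
class ConservationTrack:
    """Per-base conservation signal held as dense per-chromosome arrays.

    Uncovered bases are NaN and always reported as missing, never as 0.
    ``kind`` is ``"phastcons"`` (values in [0,1]) or ``"phylop"`` (signed).
    """

    values: dict[str, np.ndarray]
    kind: str = "phastcons"

    def __post_init__(self) -> None:
        if self.kind not in ("phastcons", "phylop"):
            raise ValueError("kind must be 'phastcons' or 'phylop'")
        if self.kind == "phastcons":
            for chrom, arr in self.values.items():
                with np.errstate(invalid="ignore"):
                    if ((arr < 0) | (arr > 1)).any():
                        raise ValueError(
                            f"{chrom}: phastcons values must lie in [0, 1]"
                        )

    @classmethod
    def from_bedgraph(
        cls,
        path: str | Path,
        kind: str = "phastcons",
        chrom_sizes: Mapping[str, int] | None = None,
    ) -> "ConservationTrack":
        """Load a bedGraph (chrom, start, end, value; 0-based half-open)."""
        df = pd.read_csv(
            path,
            sep="\t",
            names=["chrom", "start", "end", "value"],
            comment="#",
            dtype={"chrom": str},
        )
        df = df[~df["chrom"].str.startswith(("track", "browser"))]
        values: dict[str, np.ndarray] = {}
        for chrom, sub in df.groupby("chrom", sort=False):
            size = (
                chrom_sizes[chrom]
                if chrom_sizes is not None
                else int(sub["end"].max())
            )
            arr = np.full(size, np.nan)
            start = sub["start"].to_numpy(np.int64)
            end = sub["end"].to_numpy(np.int64)
            val = sub["value"].to_numpy(float)
            lengths = end - start
            # expand run-length rows to per-base assignments
            idx = np.repeat(start, lengths) + (
                np.arange(lengths.sum()) - np.repeat(np.cumsum(lengths) - lengths, lengths)
            )
            arr[idx] = np.repeat(val, lengths)
            values[chrom] = arr
        return cls(values, kind=kind)

    def to_bedgraph(self, path: str | Path, decimals: int = 4) -> None:
        """Write covered bases as bedGraph, merging equal-value runs."""
        with open(path, "w") as fh:
            for chrom, arr in self.values.items():
                covered = np.where(~np.isnan(arr))[0]
                if covered.size == 0:
                    continue
                vals = np.round(arr[covered], decimals)
                breaks = np.where(
                    (np.diff(covered) != 1) | (np.diff(vals) != 0)
                )[0]
                starts = np.concatenate([[0], breaks + 1])
                ends = np.concatenate([breaks, [covered.size - 1]])
                for a, b in zip(starts, ends):
                    fh.write(
                        f"{chrom}\t{covered[a]}\t{covered[b] + 1}\t{vals[a]:.{decimals}f}\n"
                    )

    def get(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Values over [start, end); NaN where uncovered or off-chromosome."""
        arr = self.values.get(chrom)
        out = np.full(end - start, np.nan)
        if arr is None:
            return out
        lo, hi = max(start, 0), min(end, arr.size)
        if hi > lo:
            out[lo - start : hi - start] = arr[lo:hi]
        return out


def mean_over_interval(
    track: ConservationTrack, chrom: str, start: int, end: int
) -> tuple[float, bool]:
    """Mean over covered bases and whether every base was covered.

    Zero covered bases yields ``(nan, False)``.
    """
    vals = track.get(chrom, start, end)
    covered = ~np.isnan(vals)
    if not covered.any():
        return float("nan"), False
    return float(vals[covered].mean()), bool(covered.all())


def conservation_filter(
    hits: pd.DataFrame, track: ConservationTrack, cutoff: float = 0.5
) -> pd.DataFrame:
    """Keep hits fully covered by the track with mean score >= cutoff.

    Partially covered motifs are excluded before thresholding, mirroring the
    rule that a motif must have a PhastCons value for every base.
    """
    if track.kind != "phastcons":
        raise ValueError("conservation_filter requires a phastcons-like track")
    keep = []
    for row in hits.itertuples():
        mean, full = mean_over_interval(track, row.chrom, int(row.start), int(row.end))
        keep.append(full and mean >= cutoff)
    return hits[np.array(keep, dtype=bool)] if len(hits) else hits


def positional_values(
    hits: pd.DataFrame, track: ConservationTrack
) -> list[np.ndarray]:
    """Per-motif-position conservation values pooled over hits.

    Element p-1 holds the track values at motif position p (strand-aware
    projection to the genome) across all hits where that base is covered.
    Hits must share one motif (equal length assumed).
    """
    if hits.empty:
        return []
    L = int((hits["end"] - hits["start"]).iloc[0])
    groups: list[list[float]] = [[] for _ in range(L)]
    for row in hits.itertuples():
        vals = track.get(row.chrom, int(row.start), int(row.end))
        for p in range(1, L + 1):
            g = motif_position_to_genomic(p, row)
            v = vals[g - int(row.start)]
            if not np.isnan(v):
                groups[p - 1].append(float(v))
    return [np.asarray(g) for g in groups]


def positional_profile(
    hits: pd.DataFrame, track: ConservationTrack
) -> pd.DataFrame:
    """Mean/sd/n of PhyloP-like scores at each motif position over hits."""
    groups = positional_values(hits, track)
    motif = hits["motif"].iloc[0] if len(hits) else ""
    return pd.DataFrame(
        {
            "motif": motif,
            "position": np.arange(1, len(groups) + 1),
            "mean": [g.mean() if g.size else np.nan for g in groups],
            "sd": [g.std(ddof=1) if g.size > 1 else np.nan for g in groups],
            "n": [g.size for g in groups],
        }
    )


def anova_positions(groups: Sequence[np.ndarray]) -> tuple[float, float]:
    """One-way fixed-effects ANOVA across motif positions.

    Returns ``(F, p)``; F is NaN (flagged via warning) when within-group
    variance is zero everywhere.
    """
    groups = [np.asarray(g, dtype=float) for g in groups if len(g) >= 2]
    if len(groups) < 2:
        raise ValueError("ANOVA needs >= 2 positions with >= 2 observations")
    if all(np.ptp(g) == 0 for g in groups):
        if len({g[0] for g in groups}) == 1:
            return 0.0, 1.0
        warnings.warn("zero within-group variance: F undefined")
        return float("nan"), float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.f_oneway(*groups)
    return float(res.statistic), float(res.pvalue)


def tukey_hsd(
    groups: Sequence[np.ndarray],
    labels: Sequence[object] | None = None,
) -> pd.DataFrame:
    """All-pairs Tukey HSD adjusted p-values (studentized range).

    Groups with fewer than 2 observations are excluded with a warning.
    Returns a tidy frame (group_a, group_b, diff, p_adj).
    """
    if labels is None:
        labels = list(range(1, len(groups) + 1))
    keep = [i for i, g in enumerate(groups) if len(g) >= 2]
    if len(keep) < len(groups):
        warnings.warn("excluding groups with < 2 observations from Tukey HSD")
    arrs = [np.asarray(groups[i], dtype=float) for i in keep]
    labs = [labels[i] for i in keep]
    if len(arrs) < 2:
        raise ValueError("Tukey HSD needs >= 2 usable groups")
    res = stats.tukey_hsd(*arrs)
    rows = []
    for i in range(len(arrs)):
        for j in range(i + 1, len(arrs)):
            rows.append(
                {
                    "group_a": labs[i],
                    "group_b": labs[j],
                    "diff": float(arrs[i].mean() - arrs[j].mean()),
                    "p_adj": float(res.pvalue[i, j]),
                }
            )
    return pd.DataFrame(rows)


def tukey_one_vs_rest(
    groups: Sequence[np.ndarray], focal: Sequence[int]
) -> pd.DataFrame:
    """Tukey HSD of focal position(s) against all other positions combined.

    ``focal`` holds 1-based position indices; the remaining positions are
    pooled into a single comparison group before the standard procedure is
    applied to the two-group layout.
    """
    focal = sorted(set(focal))
    rest = [g for i, g in enumerate(groups, start=1) if i not in focal and len(g)]
    if not rest:
        raise ValueError("no non-focal observations to pool")
    pooled = np.concatenate(rest)
    rows = []
    for p in focal:
        sub = tukey_hsd([np.asarray(groups[p - 1]), pooled], labels=[p, "rest"])
        rows.append(sub.iloc[0])
    return pd.DataFrame(rows).reset_index(drop=True)
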