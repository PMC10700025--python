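"""Position-weight-matrix models for the ER stress response elements.

The unfolded protein response is driven by three transcription factors
(ATF6/NFY, XBP1, ATF4) whose binding preferences are summarised as letter
probability matrices (LPMs): per-position nucleotide probabilities in
A, C, G, T order.  This module converts LPMs to log-odds (bits), computes
the exact score distribution under an i.i.d. background by dynamic
programming, derives p-value thresholds — in particular the "one wobble"
threshold, the score of the consensus sequence with its weakest single
substitution to the second-most-probable base — and scans genomic sequence
on both strands, keeping overlapping matches.

Coordinates are 0-based half-open (BED convention); motif positions are
1-based on the motif's own strand.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

BASES = "ACGT"
UNIFORM_BACKGROUND = np.full(4, 0.25)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: hit-table columns produced by :func:`scan_genome`
HIT_COLUMNS = ["chrom", "start", "end", "strand", "motif", "score", "pvalue"]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class MotifValidationError(ValueError):
    """Raised when an LPM violates its stochastic-matrix contract."""


@dataclass(frozen=True)
class LetterProbabilityMatrix:
    """A motif as per-position nucleotide probabilities.

    Parameters
    ----------
    name
        Motif identifier (e.g. ``ERSEI``, ``ERSEII``, ``UPRE``, ``ATF4``).
    probs
        ``L x 4`` array of probabilities, columns in A, C, G, T order;
        every row must sum to 1 (tolerance 1e-6) and be non-negative.
    spacer_positions
        1-based motif positions that do not contact the factor (the ERSEI
        N9 spacer, the ERSEII single-N spacer); excluded from half-site
        analyses but load-bearing for site spacing.
    pseudocount
        Probability mass added to every cell (rows renormalised) before
        log-odds conversion, so LPM zeros do not map to -inf.
    """

    name: str
    probs: np.ndarray
    spacer_positions: frozenset[int] = frozenset()
    pseudocount: float = 1e-4

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != 4:
            raise MotifValidationError(
                f"{self.name}: probs must be L x 4, got shape {probs.shape}"
            )
        if (probs < 0).any():
            row = int(np.where((probs < 0).any(axis=1))[0][0]) + 1
            raise MotifValidationError(f"{self.name}: negative probability in row {row}")
        sums = probs.sum(axis=1)
        bad = np.where(np.abs(sums - 1.0) > 1e-6)[0]
        if bad.size:
            raise MotifValidationError(
                f"{self.name}: row {bad[0] + 1} sums to {sums[bad[0]]:.8f}, not 1"
            )
        if not all(1 <= p <= probs.shape[0] for p in self.spacer_positions):
            raise MotifValidationError(
                f"{self.name}: spacer positions must lie in 1..{probs.shape[0]}"
            )
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "spacer_positions", frozenset(self.spacer_positions))

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    @property
    def informative_positions(self) -> tuple[int, ...]:
        """1-based positions outside the spacer (the 'half sites' for ERSEs)."""
        return tuple(
            p for p in range(1, self.length + 1) if p not in self.spacer_positions
        )

    def consensus(self) -> str:
        """Most probable base at each position; spacer positions as N."""
        letters = [BASES[i] for i in self.probs.argmax(axis=1)]
        for p in self.spacer_positions:
            letters[p - 1] = "N"
        return "".join(letters)


@dataclass(frozen=True)
class MotifHit:
    """One scored motif match in genome coordinates (0-based half-open)."""

    chrom: str
    start: int
    end: int
    strand: str
    motif: str
    score: float
    pvalue: float = float("nan")


@dataclass
class ScoreDistribution:
    """Exact PWM score distribution under an i.i.d. background.

    ``support`` holds the distinct scores (ascending) after rounding each
    per-position log-odds term to a grid of step ``granularity`` bits;
    ``mass`` the probability of each.  The survival function
    ``S(s) = P(score >= s)`` is evaluated with half-grid tolerance so that
    grid-rounded and exact scores agree on which atoms they dominate.
    """

    support: np.ndarray
    mass: np.ndarray
    granularity: float
    _sf: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        order = np.argsort(self.support)
        self.support = np.asarray(self.support, dtype=float)[order]
        self.mass = np.asarray(self.mass, dtype=float)[order]
        # reverse cumulative sum; _sf[i] = P(score >= support[i])
        self._sf = np.concatenate([np.cumsum(self.mass[::-1])[::-1], [0.0]])

    def sf(self, score: float | np.ndarray) -> float | np.ndarray:
        """P(score >= s), tolerant to half-grid rounding of ``s``."""
        idx = np.searchsorted(self.support, np.asarray(score) - 0.5 * self.granularity)
        out = self._sf[idx]
        return float(out) if np.isscalar(score) else out


def log_odds(
    lpm: LetterProbabilityMatrix,
    background: np.ndarray = UNIFORM_BACKGROUND,
) -> np.ndarray:
    """Convert an LPM to a log2 (bits) odds matrix against ``background``.

    Pseudocount is added to every cell and rows renormalised first, so a
    probability of 0 in the LPM yields a large negative — but finite —
    score.
    """
    background = np.asarray(background, dtype=float)
    if background.shape != (4,) or (background <= 0).any():
        raise ValueError("background must be 4 positive frequencies")
    if abs(background.sum() - 1.0) > 1e-6:
        raise ValueError("background frequencies must sum to 1")
    p = lpm.probs + lpm.pseudocount
    p = p / p.sum(axis=1, keepdims=True)
    return np.log2(p / background)


def exact_score_distribution(
    lpm: LetterProbabilityMatrix,
    background: np.ndarray = UNIFORM_BACKGROUND,
    granularity: float = 1e-3,
) -> ScoreDistribution:
    """Exact score distribution by convolution over positions.

    Per-position log-odds scores are rounded to an integer grid of step
    ``granularity`` bits and the (score, mass) pairs convolved position by
    position — identical (up to grid rounding) to enumerating all 4^L
    sequences and summing their background probabilities per score.
    """
    if granularity <= 0:
        raise ValueError("granularity must be positive")
    if lpm.length > 30:
        raise ValueError("exact distribution limited to motifs of length <= 30")
    background = np.asarray(background, dtype=float)
    W = log_odds(lpm, background)
    keys = np.rint(W / granularity).astype(np.int64)
    dist: dict[int, float] = {0: 1.0}
    for i in range(lpm.length):
        nxt: dict[int, float] = {}
        for b in range(4):
            kb, mb = keys[i, b], background[b]
            for k, m in dist.items():
                key = k + kb
                nxt[key] = nxt.get(key, 0.0) + m * mb
        dist = nxt
    support = np.array(sorted(dist), dtype=np.int64)
    mass = np.array([dist[k] for k in support])
    return ScoreDistribution(support * granularity, mass, granularity)


def threshold_for_pvalue(
    dist: ScoreDistribution, alpha: float
) -> tuple[float, float, bool]:
    """Smallest support score whose tail probability is <= ``alpha``.

    Returns ``(threshold, realized_tail, attained)``.  ``attained`` is False
    when even the top score's mass exceeds ``alpha``; the top score is then
    returned with its (larger) realised tail.  ``alpha = 1`` returns the
    minimum support score.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    sf = dist._sf[:-1]
    ok = np.where(sf <= alpha + 1e-12)[0]
    if ok.size == 0:
        return float(dist.support[-1]), float(sf[-1]), False
    i = ok[0]
    return float(dist.support[i]), float(sf[i]), True


def wobble_score(
    lpm: LetterProbabilityMatrix,
    background: np.ndarray = UNIFORM_BACKGROUND,
) -> float:
    """Exact score of the weakest single-wobble variant of the consensus.

    For each position the consensus base is replaced by the
    second-most-probable base (a "wobble"); the wobble score is the minimum
    over positions of the resulting sequence scores.  Ties for second place
    are broken toward the lower substituted score, which admits both bases.
    """
    W = log_odds(lpm, background)
    order = np.argsort(-lpm.probs, axis=1, kind="stable")
    consensus_total = W[np.arange(lpm.length), order[:, 0]].sum()
    best = W[np.arange(lpm.length), order[:, 0]]
    worst = np.inf
    for i in range(lpm.length):
        p_sorted = -np.sort(-lpm.probs[i])
        second_p = p_sorted[1]
        tied = np.where(np.abs(lpm.probs[i] - second_p) < 1e-12)[0]
        tied = [b for b in tied if b != order[i, 0]]
        sub_scores = [consensus_total - best[i] + W[i, b] for b in tied]
        worst = min(worst, min(sub_scores))
    return float(worst)


def wobble_pvalue(
    lpm: LetterProbabilityMatrix,
    background: np.ndarray = UNIFORM_BACKGROUND,
    granularity: float = 1e-3,
) -> float:
    """Tail probability of the one-wobble score under the exact distribution.

    This realises the cutoff rule "allow one wobble base for the next most
    likely base at that position": scores at or above the weakest
    one-substitution consensus variant are accepted.
    """
    dist = exact_score_distribution(lpm, background, granularity)
    return float(dist.sf(wobble_score(lpm, background)))


def _encode(seq: str) -> np.ndarray:
    lut = np.full(256, 4, dtype=np.uint8)
    for i, b in enumerate(BASES):
        lut[ord(b)] = i
        lut[ord(b.lower())] = i
    return lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def scan_sequence(
    seq: str,
    lpm: LetterProbabilityMatrix,
    threshold: float,
    background: np.ndarray = UNIFORM_BACKGROUND,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Score all windows of one sequence on both strands.

    Returns ``(starts, strands, scores)`` for windows with score >=
    threshold (1e-9 float tolerance).  Windows containing a non-ACGT
    character are skipped on both strands.  Minus-strand windows are scored
    on the reverse complement but reported at their plus-strand interval.
    """
    L = lpm.length
    codes = _encode(seq)
    n = codes.size
    if n < L:
        return (np.empty(0, dtype=np.int64), np.empty(0, dtype="U1"), np.empty(0))
    W = log_odds(lpm, background)
    # column 4 = non-ACGT sentinel: -inf so any N window fails every threshold
    W5 = np.column_stack([W, np.full(L, -np.inf)])
    # reverse-complement scoring matrix: position i reads base complement
    W5rc = np.column_stack([W[::-1, ::-1], np.full(L, -np.inf)])
    nwin = n - L + 1
    fwd = np.zeros(nwin)
    rev = np.zeros(nwin)
    for i in range(L):
        fwd += W5[i, codes[i : i + nwin]]
        rev += W5rc[i, codes[i : i + nwin]]
    tol = 1e-9
    starts, strands, scores = [], [], []
    for vec, strand in ((fwd, "+"), (rev, "-")):
        keep = np.where(vec >= threshold - tol)[0]
        starts.append(keep)
        strands.append(np.full(keep.size, strand, dtype="U1"))
        scores.append(vec[keep])
    return (
        np.concatenate(starts),
        np.concatenate(strands),
        np.concatenate(scores),
    )


def scan_genome(
    genome: Mapping[str, str],
    lpm: LetterProbabilityMatrix,
    threshold: float,
    background: np.ndarray = UNIFORM_BACKGROUND,
    dist: ScoreDistribution | None = None,
) -> pd.DataFrame:
    """Scan every chromosome for motif matches at or above ``threshold``.

    Overlapping matches are kept.  Returns a hit table with columns
    ``chrom, start, end, strand, motif, score, pvalue`` sorted by
    coordinate; p-values come from the exact score distribution (computed
    here unless supplied).
    """
    if dist is None:
        dist = exact_score_distribution(lpm, background)
    frames = []
    for chrom in genome:
        seq = str(genome[chrom])
        starts, strands, scores = scan_sequence(seq, lpm, threshold, background)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": starts + lpm.length,
                    "strand": strands,
                    "motif": lpm.name,
                    "score": scores,
                    "pvalue": dist.sf(scores),
                }
            )
        )
    hits = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=HIT_COLUMNS
    )
    return hits.sort_values(["chrom", "start", "strand"], kind="stable").reset_index(
        drop=True
    )


# ---------------------------------------------------------------------------
# LPM file format: "># name", optional "#spacer: 6-14,16" comment, then
# L whitespace-separated rows of 4 probabilities in A C G T order.
# ---------------------------------------------------------------------------

def _parse_spacer(text: str) -> frozenset[int]:
    out: set[int] = set()
    for part in text.replace(" ", "").split(","):
        if not part:
            continue
        if "-" in part:
            a, b = part.split("-")
            out.update(range(int(a), int(b) + 1))
        else:
            out.add(int(part))
    return frozenset(out)


def read_lpm_file(path: str | Path) -> list[LetterProbabilityMatrix]:
    """Read one or more LPMs from the plain-text matrix format."""
    motifs: list[LetterProbabilityMatrix] = []
    name: str | None = None
    rows: list[list[float]] = []
    spacer: frozenset[int] = frozenset()

    def flush() -> None:
        nonlocal rows, spacer
        if name is not None:
            motifs.append(
                LetterProbabilityMatrix(name, np.array(rows), spacer_positions=spacer)
            )
        rows, spacer = [], frozenset()

    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            name = re.sub(r"^>#?\s*", "", line)
        elif line.lower().startswith("#spacer:"):
            spacer = _parse_spacer(line.split(":", 1)[1])
        elif line.startswith("#"):
            continue
        else:
            rows.append([float(x) for x in line.split()])
    flush()
    return motifs


def write_lpm_file(path: str | Path, motifs: Iterable[LetterProbabilityMatrix]) -> None:
    with open(path, "w") as fh:
        for m in motifs:
            fh.write(f"># {m.name}\n")
            if m.spacer_positions:
                fh.write(
                    "#spacer: " + ",".join(str(p) for p in sorted(m.spacer_positions)) + "\n"
                )
            for row in m.probs:
                fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")
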