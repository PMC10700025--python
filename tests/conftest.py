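import numpy as np
import pandas as pd
import pytest

from ermotifs.motifs import (
    BASES,
    LetterProbabilityMatrix,
    log_odds,
    reverse_complement,
)
from ermotifs.simulate import SimulationConfig, default_motifs, simulate_genome

UNIFORM = np.full(4, 0.25)


@pytest.fixture(scope="session")
def motifs():
    return default_motifs()


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale study conditions shrunk for unit tests."""
    return SimulationConfig(
        seed=11,
        chrom_lengths=(("chr1", 60_000), ("chr2", 40_000)),
        n_genes=12,
        motif_counts=(("ERSEI", 6), ("ERSEII", 6), ("UPRE", 6), ("ATF4", 6)),
        n_motif_snvs=600,
        n_clinical_snvs=400,
        n_background_snvs=100,
        n_spacer_indels=8,
        n_samples=60,
        n_eqtl_per_class=(("shared", 3), ("control_only", 3), ("tm_only", 3)),
        n_null_variants=20,
    )


@pytest.fixture(scope="session")
def small_genome(small_config, motifs):
    return simulate_genome(small_config, motifs)


def random_lpm(rng, length, name="RND", spacer=()):
    """Random valid LPM via Dirichlet rows."""
    probs = rng.dirichlet(np.ones(4), size=length)
    return LetterProbabilityMatrix(name, probs, spacer_positions=frozenset(spacer))


def random_sequence(rng, n, alphabet="ACGT"):
    return "".join(np.array(list(alphabet))[rng.integers(0, len(alphabet), n)])


def score_window_bruteforce(window, lpm, background=UNIFORM):
    """Independent per-window scorer: explicit per-base log-odds sum."""
    if any(b not in BASES for b in window):
        return None
    W = log_odds(lpm, background)
    return sum(W[i, BASES.index(b)] for i, b in enumerate(window))


def scan_bruteforce(seq, lpm, threshold, background=UNIFORM):
    """Exhaustive both-strand window enumeration oracle."""
    L = lpm.length
    out = []
    for start in range(len(seq) - L + 1):
        window = seq[start : start + L]
        for strand, w in (("+", window), ("-", reverse_complement(window))):
            s = score_window_bruteforce(w, lpm, background)
            if s is not None and s >= threshold - 1e-9:
                out.append((start, strand, s))
    return sorted(out, key=lambda t: (t[0], t[1]))


def enumerate_distribution(lpm, background=UNIFORM, granularity=1e-3):
    """Brute-force score distribution over all 4^L sequences on the grid."""
    import itertools

    W = log_odds(lpm, background)
    keys = np.rint(W / granularity).astype(np.int64)
    masses = {}
    for combo in itertools.product(range(4), repeat=lpm.length):
        key = sum(keys[i, b] for i, b in enumerate(combo))
        mass = np.prod([background[b] for b in combo])
        masses[key] = masses.get(key, 0.0) + mass
    support = np.array(sorted(masses)) * granularity
    mass = np.array([masses[round(s / granularity)] for s in support])
    return support, mass


def hits_frame(rows):
    """Build a hit table from (chrom, start, end, strand, motif) tuples."""
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "strand", "motif"]
    ).assign(score=0.0, pvalue=1.0)
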