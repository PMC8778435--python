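"""Shared fixtures and independent brute-force oracles.

The oracles here are deliberately naive (quadratic DP, all-positions scans)
and independent of the package's seeded/banded implementations, so they can
certify the optimised code paths on small inputs.
"""

from __future__ import annotations

import numpy as np
import pytest

from prophagekit.synthetic_data import SimulationConfig, generate_cohort

COHORT_SEED = 1


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=COHORT_SEED)


@pytest.fixture(scope="session")
def cohort(default_config):
    """The default 10-genome cohort with planted truth (shared, read-only)."""
    return generate_cohort(default_config)


@pytest.fixture(scope="session")
def cohort_genomes(cohort):
    return {g.id: g for g in cohort[0]}


@pytest.fixture(scope="session")
def cohort_truth(cohort):
    return cohort[1]


@pytest.fixture(scope="session")
def prophage_sequences(cohort_genomes, cohort_truth):
    return {p.prophage_id:
            cohort_genomes[p.genome_id].sequence[p.start:p.end]
            for p in cohort_truth.prophages}


@pytest.fixture(scope="session")
def cohort_similarity(prophage_sequences):
    """Fragmented-identity matrix over the cohort prophages (computed once)."""
    from prophagekit.clade_similarity import similarity_matrix
    return similarity_matrix(prophage_sequences)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def sw_local_score(a: str, b: str, match: float = 1.0,
                   mismatch: float = -3.0, gap_open: float = 5.0,
                   gap_extend: float = 2.0) -> float:
    """Naive Gotoh local alignment; a gap of length L costs open + L*extend.

    N scores as a mismatch against everything, itself included.
    """
    n, m = len(a), len(b)
    neg = -1e9
    s_prev = np.zeros(m + 1)
    e_prev = np.full(m + 1, neg)
    f_prev = np.full(m + 1, neg)
    best = 0.0
    for i in range(1, n + 1):
        s_cur = np.zeros(m + 1)
        e_cur = np.full(m + 1, neg)
        f_cur = np.full(m + 1, neg)
        for j in range(1, m + 1):
            sub = match if (a[i - 1] == b[j - 1] and a[i - 1] != "N") \
                else mismatch
            e_cur[j] = max(e_cur[j - 1] - gap_extend,
                           s_cur[j - 1] - gap_open - gap_extend)
            f_cur[j] = max(f_prev[j] - gap_extend,
                           s_prev[j] - gap_open - gap_extend)
            s_cur[j] = max(0.0, s_prev[j - 1] + sub, e_cur[j], f_cur[j])
            best = max(best, s_cur[j])
        s_prev, e_prev, f_prev = s_cur, e_cur, f_cur
    return best


def naive_hamming_hits(pattern: str, text: str, max_mm: int
                       ) -> list[tuple[int, int]]:
    """All-positions Hamming scan; N never matches."""
    hits = []
    m = len(pattern)
    for i in range(len(text) - m + 1):
        window = text[i:i + m]
        d = sum(1 for x, y in zip(pattern, window)
                if x != y or x == "N" or y == "N")
        if d <= max_mm:
            hits.append((i, d))
    return hits


def random_dna_str(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))
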