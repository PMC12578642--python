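"""Shared fixtures and independent oracles.

The oracles here are deliberately naive re-derivations (full-matrix Gotoh
dynamic programming, exact rank-sum null distribution by counting) kept
separate from the library code paths they check.
"""

from __future__ import annotations

import math

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from h2profile import ReferenceDB, FamilySpec, ReferenceSequence
from h2profile.synthetic_data import example_reference_db

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def gotoh_local_score(query: str, target: str, gap_open: int = 11, gap_extend: int = 1) -> float:
    """Exhaustive affine-gap local alignment score (three-state Gotoh DP).

    BLAST cost convention: a gap of length k costs gap_open + k*gap_extend.
    """
    NEG = -1e9
    n, m = len(query), len(target)
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(n + 1)]
    Iy = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    first = gap_open + gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            Ix[i][j] = max(M[i - 1][j] - first, Ix[i - 1][j] - gap_extend,
                           Iy[i - 1][j] - first)
            Iy[i][j] = max(M[i][j - 1] - first, Iy[i][j - 1] - gap_extend,
                           Ix[i][j - 1] - first)
            s = _BLOSUM62[query[i - 1], target[j - 1]]
            M[i][j] = max(0.0, max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1]) + s)
            if M[i][j] > best:
                best = M[i][j]
    return best


def rank_sum_null_counts(m: int, n: int) -> np.ndarray:
    """Exact tie-free null distribution of the rank sum of the first group:
    counts[w] = number of m-subsets of ranks 1..m+n with sum w."""
    N = m + n
    max_sum = N * (N + 1) // 2
    ways = np.zeros((m + 1, max_sum + 1))
    ways[0, 0] = 1.0
    for r in range(1, N + 1):
        for k in range(min(m, r), 0, -1):
            ways[k, r:] += ways[k - 1, :-r]
    return ways[m]


def exact_two_sided_p(w: float, m: int, n: int) -> float:
    """Two-sided exact rank-sum p from the counting distribution."""
    counts = rank_sum_null_counts(m, n)
    total = counts.sum()
    w_int = int(round(w))
    p_le = counts[: w_int + 1].sum() / total
    p_ge = counts[w_int:].sum() / total
    return min(1.0, 2.0 * min(p_le, p_ge))


@pytest.fixture(scope="session")
def db() -> ReferenceDB:
    """Synthetic reference DB: 32 families (incl. 14 markers), 2 refs each."""
    return example_reference_db(seed=17)


@pytest.fixture()
def toy_db() -> ReferenceDB:
    """Minimal hand-built database: 3 sequences, 2 families."""
    families = {
        "FeFe_B": FamilySpec("FeFe_B", "hydrogenase", 60.0),
        "AcsB": FamilySpec("AcsB", "reductase", 50.0),
    }
    sequences = {
        "b1": ReferenceSequence(
            "b1", "FeFe_B",
            ("Bacteria", "Bacillota", "Clostridia", "Eubacteriales",
             "Lachnospiraceae", "Roseburia", "Roseburia sp1"),
            "MKLVINGHEVEVPKGTTILEAARQAGIHIPTLCYLKDINEIGACRMCLVEIEGARGLQAACVTPVAEGMVVHTRSEKVL",
        ),
        "b2": ReferenceSequence(
            "b2", "FeFe_B",
            ("Bacteria", "Bacillota", "Clostridia", "Eubacteriales",
             "Lachnospiraceae", "Blautia", "Blautia sp1"),
            "MKLVINGHEVEVPKGTSILEAARQAGIHIPTLCYLKDINEIGACRMCLVEIEGARGLQAACVTPVAEGMVVHTNSEKVL",
        ),
        "a1": ReferenceSequence(
            "a1", "AcsB",
            ("Bacteria", "Bacillota", "Clostridia", "Eubacteriales",
             "Oscillospiraceae", "Blautia", "Blautia sp2"),
            "MSKVDASLMEELRAYAEAVKAQGGRLPRVAMVGCVNAYTNEPEHLLRMIRETGADVVMFEGLPVDPAELSKLPQLKVG",
        ),
    }
    return ReferenceDB(families=families, sequences=sequences)
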