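"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the package's own scanning code paths:
they are naive per-position enumerations used to cross-check the optimized
implementations.
"""

from __future__ import annotations

import random

import pytest

from cryptorf import (
    GeneticCode,
    default_code,
    make_littlee_fixture,
    make_pacc40_fixture,
    make_shilan_fixture,
)

_RC = str.maketrans("ACGTN", "TGCAN")

STARTS = frozenset({"ATG", "GTG", "TTG"})
STOPS = frozenset({"TAA", "TAG", "TGA"})


def revcomp_str(s: str) -> str:
    return s.translate(_RC)[::-1]


def brute_force_orfs(
    seq: str,
    starts: frozenset = STARTS,
    stops: frozenset = STOPS,
    min_len_aa: int = 1,
    both_strands: bool = True,
) -> set[tuple[str, int, int]]:
    """Exhaustive ORF enumeration: every position is tested for start-codon
    membership and walked codon by codon to the first in-frame stop.
    Returns {(strand, start_nt_1based, stop_nt_1based)}."""
    found: set[tuple[str, int, int]] = set()

    def one_strand(s: str, strand: str) -> None:
        for p in range(len(s) - 2):
            if s[p : p + 3] not in starts:
                continue
            q = p + 3
            while q + 3 <= len(s):
                codon = s[q : q + 3]
                if codon in stops:
                    if (q - p) // 3 >= min_len_aa:
                        found.add((strand, p + 1, q + 3))
                    break
                q += 3

    one_strand(seq, "+")
    if both_strands:
        one_strand(revcomp_str(seq), "-")
    return found


def random_dna(rng: random.Random, length: int, with_n: bool = False) -> str:
    alphabet = "ACGTN" if with_n else "ACGT"
    return "".join(rng.choice(alphabet) for _ in range(length))


@pytest.fixture(scope="session")
def code() -> GeneticCode:
    return default_code()


@pytest.fixture(scope="session")
def shilan():
    return make_shilan_fixture(seed=11)


@pytest.fixture(scope="session")
def littlee():
    return make_littlee_fixture(seed=11)


@pytest.fixture(scope="session")
def pacc40():
    return make_pacc40_fixture(seed=11)
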