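"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately naive — exact-rational summation of the
count-test formula and literal subset enumeration for the hypergeometric
tail — so they share no code path with the implementations they check.
"""

from fractions import Fraction
from itertools import combinations

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from lactamir import pipeline
from lactamir.synthetic import SimConfig


def ac_oracle_tails(x: int, y: int, n1: int, n2: int):
    """Exact-rational (lower tail, upper tail, pmf) of the two-library test.

    Terms follow the recurrence p(k|x) = p(k-1|x) * r * (x+k) / (k * (1+r))
    from p(0|x) = 1 / (1+r)^(x+1), with r = N2/N1 kept as a Fraction.
    """
    r = Fraction(n2, n1)
    p = Fraction(1) / (1 + r) ** (x + 1)
    lower = p
    for k in range(1, y + 1):
        p = p * r * (x + k) / (k * (1 + r))
        lower += p
    upper = 1 - (lower - p)
    return lower, upper, p


def ac_oracle_two_sided(x: int, y: int, n1: int, n2: int) -> Fraction:
    lower, upper, _ = ac_oracle_tails(x, y, n1, n2)
    return min(Fraction(1), 2 * min(lower, upper))


def hypergeom_oracle(N: int, n: int, M: int, m: int) -> Fraction:
    """P(X >= m) by enumerating every size-n draw from an N-element universe."""
    term = set(range(M))
    hits = total = 0
    for draw in combinations(range(N), n):
        total += 1
        if len(term.intersection(draw)) >= m:
            hits += 1
    return Fraction(hits, total)


def make_fastq_records(cleanset, adapter_3p: str):
    """Re-expand a CleanReadSet into adapter-bearing raw records."""
    records = []
    for seq, mult in cleanset.counts.items():
        full = seq + adapter_3p
        records.extend([(full, "I" * len(full))] * mult)
    return records


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(
        seed=42,
        n_mirnas=30,
        n_reads_per_library=20_000,
        planted_de=(("syn-mir-0005", 2.0), ("syn-mir-0010", -2.0)),
    )


@pytest.fixture(scope="session")
def small_run(small_config):
    """One fully analyzed small synthetic experiment, shared across tests."""
    result, truth = pipeline.run_synthetic(small_config)
    return small_config, result, truth
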