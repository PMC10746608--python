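import math
from fractions import Fraction

import pytest
from hypothesis import HealthCheck, settings

from coretf.io import GeneSet, GeneSetLibrary

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


def hypergeom_tail_oracle(k: int, K: int, n: int, N: int) -> float:
    """Independent brute-force oracle: P(X >= k) as a direct sum of the
    hypergeometric pmf over the full upper support, in exact rational
    arithmetic (integer binomial coefficients), rounded once at the end."""
    lo = max(k, max(0, K + n - N))
    hi = min(K, n)
    total = Fraction(0)
    denom = math.comb(N, n)
    for x in range(lo, hi + 1):
        total += Fraction(math.comb(K, x) * math.comb(N - K, n - x), denom)
    return float(total)


def bh_stepup_oracle(pvalues):
    """Hand-rolled BH step-up: q_(i) = p_(i) * m / i on the sorted values,
    monotone from the top rank down, capped at 1, returned in input order."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, pvalues[i] * m / rank, 1.0)
        q[i] = val
        prev = val
    return q


def make_library(sets: dict, library_id: str = "lib", background_size: int = 1000,
                 universe=None, tf_names: bool = False) -> GeneSetLibrary:
    """Compact library builder: {name: members} -> GeneSetLibrary."""
    gene_sets = tuple(
        GeneSet(
            name=name,
            description="",
            members=frozenset(members),
            tf_symbol=name.split()[0].upper() if tf_names else None,
        )
        for name, members in sets.items()
    )
    return GeneSetLibrary(
        library_id=library_id,
        sets=gene_sets,
        background_size=background_size,
        background_universe=frozenset(universe) if universe is not None else None,
    )


@pytest.fixture
def library_factory():
    return make_library
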