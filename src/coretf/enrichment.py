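"""Over-representation statistics: Fisher-exact/hypergeometric tail tests,
Benjamini–Hochberg adjustment, per-library enrichment and cross-library
combination.

The model: a query gene list of effective size ``n`` is drawn from a
background universe of ``N`` genes; a library set has ``K`` members; the
overlap ``k`` is tested against Hypergeom(N, K, n) with the one-sided
upper-tail probability P(X >= k), which equals the one-sided ("greater")
Fisher exact p-value of the 2x2 table [[k, n-k], [K-k, N-K-n+k]].
Adjustment is Benjamini–Hochberg within one library at a time; combining
libraries concatenates and re-ranks without re-adjusting, mirroring a
survey that runs each library separately and then pools the hits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io import GeneList, GeneSetLibrary

logger = logging.getLogger("coretf")

__all__ = [
    "overlap_pvalue",
    "overlap_pvalues",
    "odds_ratio",
    "bh_adjust",
    "EnrichmentRecord",
    "EnrichmentTable",
    "enrich",
    "combine_libraries",
]


def _validate_counts(k: int, K: int, n: int, N: int) -> None:
    if N <= 0:
        raise ValueError(f"background size N={N} must be positive")
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"need 0 <= K,n <= N; got K={K}, n={n}, N={N}")
    if not (max(0, K + n - N) <= k <= min(K, n)):
        raise ValueError(
            f"overlap k={k} outside the feasible range "
            f"[{max(0, K + n - N)}, {min(K, n)}] for K={K}, n={n}, N={N}"
        )


def overlap_pvalue(k: int, K: int, n: int, N: int) -> float:
    """One-sided upper-tail hypergeometric probability P(X >= k).

    X ~ Hypergeom(N, K, n): the overlap between a size-``n`` draw and a
    size-``K`` set in a universe of ``N``.  For k = 0 this is exactly 1.
    """
    _validate_counts(k, K, n, N)
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def overlap_pvalues(
    k: np.ndarray | Sequence[int],
    K: np.ndarray | Sequence[int],
    n: np.ndarray | Sequence[int] | int,
    N: np.ndarray | Sequence[int] | int,
) -> np.ndarray:
    """Vectorized :func:`overlap_pvalue` over broadcastable count arrays."""
    k_arr, K_arr, n_arr, N_arr = np.broadcast_arrays(
        np.asarray(k), np.asarray(K), np.asarray(n), np.asarray(N)
    )
    if np.any(N_arr <= 0) or np.any(K_arr > N_arr) or np.any(n_arr > N_arr):
        raise ValueError("need 0 <= K,n <= N and N > 0")
    if np.any(k_arr > np.minimum(K_arr, n_arr)) or np.any(k_arr < np.maximum(0, K_arr + n_arr - N_arr)):
        raise ValueError("overlap k outside the feasible range")
    return np.asarray(hypergeom.sf(k_arr - 1, N_arr, K_arr, n_arr), dtype=float)


def odds_ratio(k: int, K: int, n: int, N: int) -> float:
    """Sample odds ratio of the 2x2 overlap table, Haldane–Anscombe corrected.

    The table is [[k, n-k], [K-k, N-K-n+k]]; when any cell is zero, 0.5 is
    added to all four cells so the ratio stays finite.  Used for reporting
    and deterministic tie-breaking, not for inference.
    """
    _validate_counts(k, K, n, N)
    a, b, c, d = k, n - k, K - k, N - K - n + k
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in the input order.

    q_(i) = p_(i) * m / i on the ascending order statistics, made monotone
    from the largest rank down and capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class EnrichmentRecord:
    """One set's over-representation result against one query."""

    library_id: str
    set_name: str
    k: int
    K: int
    n: int
    N: int
    odds_ratio: float
    p_raw: float
    p_adj: float
    overlap_members: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.overlap_members) not in (0, self.k):
            raise ValueError(
                f"{self.set_name}: k={self.k} but {len(self.overlap_members)} overlap members"
            )
        if self.p_adj < self.p_raw - 1e-12:
            raise ValueError(f"{self.set_name}: p_adj < p_raw")


_SORT_KEY = lambda r: (r.p_adj, -r.odds_ratio, r.set_name)  # noqa: E731


@dataclass(frozen=True)
class EnrichmentTable:
    """Ordered enrichment records for one query, with the threshold used.

    Records are kept sorted by (p_adj ascending, odds ratio descending,
    set name ascending), making every ranking deterministic.
    """

    records: tuple[EnrichmentRecord, ...]
    threshold: float
    query_label: str
    presorted: bool = field(default=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not (0 < self.threshold <= 1):
            raise ValueError(f"threshold {self.threshold} outside (0, 1]")
        if not self.presorted:
            object.__setattr__(self, "records", tuple(sorted(self.records, key=_SORT_KEY)))

    def __len__(self) -> int:
        return len(self.records)

    def significant(self, threshold: Optional[float] = None) -> tuple[EnrichmentRecord, ...]:
        """Records with adjusted p strictly below the threshold."""
        cut = self.threshold if threshold is None else threshold
        return tuple(r for r in self.records if r.p_adj < cut)

    def to_frame(self) -> pd.DataFrame:
        from .io import ENRICHMENT_COLUMNS

        return pd.DataFrame(
            [
                {
                    "library_id": r.library_id, "set_name": r.set_name,
                    "k": r.k, "K": r.K, "n": r.n, "N": r.N,
                    "odds_ratio": r.odds_ratio, "p_raw": r.p_raw, "p_adj": r.p_adj,
                    "overlap_members": ";".join(r.overlap_members),
                }
                for r in self.records
            ],
            columns=list(ENRICHMENT_COLUMNS),
        )


def enrich(
    query: GeneList,
    library: GeneSetLibrary,
    threshold: float = 0.01,
    adjust: str = "bh",
    filter_significant: bool = False,
    keep_overlap_members: bool = True,
) -> EnrichmentTable:
    """Test every set of one library for over-representation of the query.

    The effective query size ``n`` is the number of query genes inside the
    library's explicit universe when one is supplied; otherwise the full
    query size is used against the declared background size (a standard
    approximation when only N is known).  Adjustment (``adjust="bh"``;
    ``"none"`` leaves raw p-values, for calibration work) spans all sets of
    the library, significant or not.  ``filter_significant`` keeps only
    records with adjusted p strictly below ``threshold``; by default the
    full table is returned with the threshold recorded.
    """
    if len(query) == 0:
        raise ValueError("empty query list")
    if len(library) == 0:
        raise ValueError(f"library {library.library_id!r} has no sets")
    if adjust not in ("bh", "none"):
        raise ValueError(f"unknown adjustment {adjust!r}")

    qset = set(query.symbol_set)
    if library.background_universe is not None:
        effective = qset & library.background_universe
        if len(effective) < len(qset):
            logger.info(
                "query %r: %d of %d genes outside universe of %r excluded",
                query.label, len(qset) - len(effective), len(qset), library.library_id,
            )
    else:
        effective = qset
        logger.debug(
            "library %r has no explicit universe; using full query size n=%d against N=%d",
            library.library_id, len(qset), library.background_size,
        )
    n = len(effective)
    N = library.background_size
    if n > N:
        raise ValueError(f"query size n={n} exceeds background N={N}")

    overlaps = [sorted(effective & s.members) for s in library.sets]
    k_arr = np.array([len(o) for o in overlaps])
    K_arr = np.array([len(s) for s in library.sets])
    p_raw = np.where(k_arr == 0, 1.0, overlap_pvalues(k_arr, K_arr, n, N))
    p_adj = bh_adjust(p_raw) if adjust == "bh" else p_raw
    # p_adj can undershoot p_raw only by float noise; clamp to keep the invariant
    p_adj = np.minimum(np.maximum(p_adj, p_raw), 1.0)

    records = []
    for s, ov, k, p, q in zip(library.sets, overlaps, k_arr, p_raw, p_adj):
        records.append(
            EnrichmentRecord(
                library_id=library.library_id,
                set_name=s.name,
                k=int(k), K=len(s), n=n, N=N,
                odds_ratio=odds_ratio(int(k), len(s), n, N),
                p_raw=float(p), p_adj=float(q),
                overlap_members=tuple(ov) if keep_overlap_members else (),
            )
        )
    table = EnrichmentTable(records=tuple(records), threshold=threshold, query_label=query.label)
    if filter_significant:
        table = EnrichmentTable(
            records=table.significant(), threshold=threshold,
            query_label=query.label, presorted=True,
        )
    return table


def combine_libraries(tables: Iterable[EnrichmentTable]) -> EnrichmentTable:
    """Pool per-library tables for one query into a single ranking.

    Records are concatenated with their library provenance and re-sorted by
    (p_adj, odds ratio desc, set name); adjusted p-values are NOT recomputed
    across libraries, and identical set names from different libraries stay
    distinct records.
    """
    tables = list(tables)
    if not tables:
        raise ValueError("no tables to combine")
    labels = {t.query_label for t in tables}
    if len(labels) > 1:
        raise ValueError(f"tables derive from different queries: {sorted(labels)}")
    records = tuple(r for t in tables for r in t.records)
    return EnrichmentTable(
        records=records,
        threshold=tables[0].threshold,
        query_label=tables[0].query_label,
    )
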