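"""Over-representation statistics for catalog-set x query-set comparisons.

The central quantity is *representativity*: the fraction of a query set's
genes (restricted to the universe) that belong to a given catalog set.  Its
significance against the universe background rate K/N is assessed with a
one-sample proportion z-test — the test used throughout the source analyses —
with an exact hypergeometric tail probability computed alongside as oracle.
A pooled two-proportion variant lives in :mod:`generep.differential`.

Percentages are rendered through one shared formatter (nearest integer at
>= 10%, one decimal below) so every table and figure caption in the pipeline
prints percentages the same way.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .geneset import Catalog, GeneSet, Universe, restrict

__all__ = [
    "OverlapResult",
    "RepresentativityMatrix",
    "UndefinedRatioError",
    "DegenerateBackgroundError",
    "format_percent",
    "representativity",
    "annotation_coverage",
    "enrichment_ztest",
    "hypergeometric_test",
    "overlap_result",
    "cross_tabulate",
]

TAILS = ("over", "under", "two_sided")


class UndefinedRatioError(ZeroDivisionError):
    """Raised when a representativity denominator is empty after restriction."""


class DegenerateBackgroundError(ValueError):
    """Raised when the background proportion K/N is 0 or 1."""


def format_percent(fraction: float) -> str:
    """Render a fraction as a percentage string.

    Values >= 10% go to the nearest integer ("56%"), values below 10% to one
    decimal ("5.4%", "0.6%").  This mirrors the house style of the printed
    tables the pipeline reproduces.
    """
    pct = 100.0 * fraction
    if pct >= 10:
        return f"{round(pct):d}%"
    return f"{pct:.1f}%"


# ---------------------------------------------------------------------------
# core statistics
# ---------------------------------------------------------------------------


def enrichment_ztest(
    k: int,
    n_query: int,
    K: int,
    N: int,
    tail: str = "over",
    continuity: bool = False,
) -> tuple[float, float]:
    """One-sample proportion z-test of k/n_query against the background K/N.

    z = (p_hat - p0) / sqrt(p0 (1 - p0) / n_query) with p_hat = k/n_query and
    p0 = K/N; the p-value comes from the standard normal for the requested
    tail.  ``continuity`` applies a Yates-style 0.5/n correction toward p0.

    Returns (z, p).
    """
    _check_counts(k, n_query, K, N)
    if tail not in TAILS:
        raise ValueError(f"tail must be one of {TAILS}")
    p0 = K / N
    if p0 <= 0.0 or p0 >= 1.0:
        raise DegenerateBackgroundError(f"background rate K/N = {p0} is degenerate")
    p_hat = k / n_query
    diff = p_hat - p0
    if continuity:
        corr = 0.5 / n_query
        diff = math.copysign(max(abs(diff) - corr, 0.0), diff)
    z = diff / math.sqrt(p0 * (1.0 - p0) / n_query)
    if tail == "over":
        p = stats.norm.sf(z)
    elif tail == "under":
        p = stats.norm.cdf(z)
    else:
        p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(min(p, 1.0))


def hypergeometric_test(k: int, n_query: int, K: int, N: int, tail: str = "over") -> float:
    """Exact tail probability of the overlap count under random draws.

    Over tail: P(X >= k); under: P(X <= k); two-sided: min(1, 2*min(over, under)),
    where X ~ Hypergeom(N, K, n_query).
    """
    _check_counts(k, n_query, K, N)
    if tail not in TAILS:
        raise ValueError(f"tail must be one of {TAILS}")
    if K <= 0 or K >= N:
        raise DegenerateBackgroundError(f"catalog size K={K} degenerate for N={N}")
    dist = stats.hypergeom(N, K, n_query)
    over = float(dist.sf(k - 1))
    under = float(dist.cdf(k))
    if tail == "over":
        return min(over, 1.0)
    if tail == "under":
        return min(under, 1.0)
    return min(1.0, 2.0 * min(over, under))


def _check_counts(k: int, n_query: int, K: int, N: int) -> None:
    if not (0 < n_query < N):
        raise ValueError(f"need 0 < n_query < N, got n_query={n_query}, N={N}")
    if not (0 <= K <= N):
        raise ValueError(f"need 0 <= K <= N, got K={K}, N={N}")
    if not (0 <= k <= min(n_query, K)):
        raise ValueError(f"need 0 <= k <= min(n_query, K), got k={k}")


# ---------------------------------------------------------------------------
# set-level operations
# ---------------------------------------------------------------------------


def representativity(catalog_set: GeneSet, query_set: GeneSet, universe: Universe) -> float:
    """Fraction of the (universe-restricted) query set inside the catalog set.

    Genes outside the universe never count on either side, so the reported
    percentages match analyses done against detected-gene backgrounds.
    """
    q = restrict(query_set, universe)
    if len(q) == 0:
        raise UndefinedRatioError(
            f"query set {query_set.name!r} is empty after restriction to {universe.name!r}"
        )
    t = restrict(catalog_set, universe)
    return len(t.genes & q.genes) / len(q)


def annotation_coverage(catalog: Catalog, query_set: GeneSet, universe: Universe) -> float:
    """Fraction of the restricted query set covered by the union of catalog sets."""
    if len(catalog) == 0:
        raise ValueError("catalog is empty")
    q = restrict(query_set, universe)
    if len(q) == 0:
        raise UndefinedRatioError(
            f"query set {query_set.name!r} is empty after restriction to {universe.name!r}"
        )
    covered = q.genes & catalog.union_genes() & universe.genes
    return len(covered) / len(q)


@dataclass
class OverlapResult:
    """One catalog-set x query-set comparison.

    ``representativity`` is k/n_query; ``background_rate`` is K/N; ``z`` and
    ``p_z`` come from the proportion z-test and ``p_exact`` from the
    hypergeometric oracle.  ``significant`` is judged on the configured test's
    p-value at alpha = 1 - confidence.  ``flag`` records degenerate cells
    (kept, never dropped) and z/exact disagreement beyond tolerance.
    """

    catalog_set_name: str
    query_set_name: str
    k: int
    n_query: int
    K: int
    N: int
    representativity: float
    background_rate: float
    z: float
    p_z: float
    p_exact: float
    significant: bool
    tail: str
    flag: str | None = None

    @property
    def percent(self) -> str:
        return format_percent(self.representativity)


def overlap_result(
    catalog_set: GeneSet,
    query_set: GeneSet,
    universe: Universe,
    confidence: float = 0.95,
    tail: str = "over",
    test: str = "z",
    continuity: bool = False,
    oracle_tolerance: float = 0.01,
) -> OverlapResult:
    """Build the full overlap statistic for one catalog-set/query-set pair."""
    q = restrict(query_set, universe)
    if len(q) == 0:
        raise UndefinedRatioError(
            f"query set {query_set.name!r} empty after restriction to {universe.name!r}"
        )
    t = restrict(catalog_set, universe)
    k = len(t.genes & q.genes)
    n_query, K, N = len(q), len(t), len(universe)
    alpha = 1.0 - confidence

    flag = None
    if K == 0 or K == N:
        z, p_z, p_exact = float("nan"), 1.0, 1.0
        flag = "degenerate_background"
    else:
        z, p_z = enrichment_ztest(k, n_query, K, N, tail=tail, continuity=continuity)
        p_exact = hypergeometric_test(k, n_query, K, N, tail=tail)
        p0 = K / N
        expected = min(n_query * p0, n_query * (1.0 - p0))
        if expected >= 5 and abs(p_z - p_exact) > oracle_tolerance:
            flag = "oracle_disagreement"
        elif expected < 5:
            flag = "low_expected_count"

    p_used = p_exact if test == "exact" else p_z
    return OverlapResult(
        catalog_set_name=catalog_set.name,
        query_set_name=query_set.name,
        k=k,
        n_query=n_query,
        K=K,
        N=N,
        representativity=k / n_query,
        background_rate=K / N,
        z=z,
        p_z=p_z,
        p_exact=p_exact,
        significant=bool(p_used < alpha),
        tail=tail,
        flag=flag,
    )


@dataclass
class RepresentativityMatrix:
    """All pairwise overlap results for one catalog against several queries.

    Rows are catalog set names, columns query set names, in input order; every
    (row, col) pair has exactly one cell and all cells share one universe.
    """

    rows: list[str]
    cols: list[str]
    cells: dict[tuple[str, str], OverlapResult]
    universe: str
    confidence: float
    row_role: str = "annotation"
    col_role: str = "condition"
    metadata: dict = field(default_factory=dict)

    def cell(self, row: str, col: str) -> OverlapResult:
        return self.cells[(row, col)]

    def significant_cells(self) -> list[OverlapResult]:
        return [self.cells[(r, c)] for r in self.rows for c in self.cols if self.cells[(r, c)].significant]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table, one row per cell, in deterministic row-major order."""
        records = []
        for r in self.rows:
            for c in self.cols:
                cell = self.cells[(r, c)]
                records.append(
                    {
                        "catalog_set": cell.catalog_set_name,
                        "query_set": cell.query_set_name,
                        "k": cell.k,
                        "n_query": cell.n_query,
                        "K": cell.K,
                        "N": cell.N,
                        "representativity": cell.representativity,
                        "z": cell.z,
                        "p_z": cell.p_z,
                        "p_exact": cell.p_exact,
                        "significant": cell.significant,
                        "flag": cell.flag or "",
                    }
                )
        return pd.DataFrame.from_records(records)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, lineterminator="\n")


def cross_tabulate(
    catalog: Catalog,
    queries: Sequence[GeneSet] | Iterable[GeneSet],
    universe: Universe,
    confidence: float = 0.95,
    tail: str = "over",
    test: str = "z",
    continuity: bool = False,
    adjust: str | None = None,
) -> RepresentativityMatrix:
    """Fill an OverlapResult for every catalog set x query set pair.

    Per-cell degeneracies are flagged in place, never fatal.  With
    ``adjust='bh'`` significance is re-called on Benjamini-Hochberg adjusted
    p-values (off by default: the pipeline's reference analyses report
    unadjusted z-test significance).
    """
    queries = list(queries)
    rows = list(catalog.sets)
    cols = [q.name for q in queries]
    if len(set(cols)) != len(cols):
        raise ValueError("query set names must be unique")
    cells: dict[tuple[str, str], OverlapResult] = {}
    for rname in rows:
        for q in queries:
            cells[(rname, q.name)] = overlap_result(
                catalog.sets[rname],
                q,
                universe,
                confidence=confidence,
                tail=tail,
                test=test,
                continuity=continuity,
            )
    if adjust == "bh":
        keys = [(r, c) for r in rows for c in cols]
        pvals = np.array(
            [cells[key].p_exact if test == "exact" else cells[key].p_z for key in keys]
        )
        adjusted = stats.false_discovery_control(pvals, method="bh")
        alpha = 1.0 - confidence
        for key, p_adj in zip(keys, adjusted):
            cells[key].significant = bool(p_adj < alpha)
    elif adjust is not None:
        raise ValueError(f"unknown adjustment {adjust!r}; use 'bh' or None")
    return RepresentativityMatrix(
        rows=rows,
        cols=cols,
        cells=cells,
        universe=universe.name,
        confidence=confidence,
        row_role=catalog.role,
        col_role="condition",
    )
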