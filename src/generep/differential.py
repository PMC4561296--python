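"""Differential representativity of one catalog set across two query contexts.

Answers questions of the form "is the fraction of glucose-regulated genes that
are targets of this transcription factor higher in HepG2-like cells than in
generic human cells?".  Each context keeps its own query set and universe; the
comparison is a pooled two-proportion z-test on the two conditional rates,
and each catalog entry is classified increased / reduced / unchanged at the
configured confidence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy import stats

from .enrichment import DegenerateBackgroundError, TAILS
from .geneset import Catalog, GeneSet, Universe, restrict

__all__ = [
    "DifferentialResult",
    "two_proportion_ztest",
    "differential_profile",
    "write_differential_tsv",
]


def two_proportion_ztest(
    k1: int, n1: int, k2: int, n2: int, tail: str = "two_sided"
) -> tuple[float, float]:
    """Pooled two-proportion z-test of k2/n2 against k1/n1.

    z = (p2 - p1) / sqrt(p_pool (1 - p_pool) (1/n1 + 1/n2)) with
    p_pool = (k1 + k2)/(n1 + n2).  Positive z means the rate is higher in
    context 2.  Returns (z, p) with p from the standard normal per tail
    ('over' = context-2 rate larger).
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("both sample sizes must be positive")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("counts must satisfy 0 <= k_i <= n_i")
    if tail not in TAILS:
        raise ValueError(f"tail must be one of {TAILS}")
    pooled = (k1 + k2) / (n1 + n2)
    if pooled <= 0.0 or pooled >= 1.0:
        raise DegenerateBackgroundError(f"pooled proportion {pooled} is degenerate")
    z = (k2 / n2 - k1 / n1) / math.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    if tail == "over":
        p = stats.norm.sf(z)
    elif tail == "under":
        p = stats.norm.cdf(z)
    else:
        p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(min(p, 1.0))


@dataclass
class DifferentialResult:
    """One catalog set's representativity compared across two contexts.

    r1 = k1/n1 and r2 = k2/n2 are the conditional rates in contexts 1 and 2;
    classification is 'unchanged' when p_diff >= alpha, else 'increased' or
    'reduced' by the sign of r2 - r1.
    """

    catalog_set_name: str
    k1: int
    n1: int
    k2: int
    n2: int
    r1: float
    r2: float
    z_diff: float
    p_diff: float
    classification: str
    confidence: float
    flag: str | None = None


def _classify(p: float, r1: float, r2: float, alpha: float) -> str:
    if p >= alpha or r1 == r2:
        return "unchanged"
    return "increased" if r2 > r1 else "reduced"


def differential_profile(
    catalog: Catalog,
    query1: GeneSet,
    query2: GeneSet,
    universe1: Universe,
    universe2: Universe,
    confidence: float = 0.95,
    tail: str = "two_sided",
) -> list[DifferentialResult]:
    """Classify every catalog set as increased / reduced / unchanged between contexts.

    Each context's counts are computed against its own universe (the query
    sets may derive from different experiments with different detected-gene
    backgrounds).  Degenerate cells — a set absent from both contexts, or
    saturating both — are flagged 'degenerate' and classified unchanged, never
    fatal.  Results are ordered by |z_diff| descending, ties broken by name.
    """
    q1 = restrict(query1, universe1)
    q2 = restrict(query2, universe2)
    if len(q1) == 0 or len(q2) == 0:
        raise ValueError("both query sets must be nonempty after restriction")
    alpha = 1.0 - confidence
    out: list[DifferentialResult] = []
    for name in catalog.sets:
        t1 = restrict(catalog.sets[name], universe1)
        t2 = restrict(catalog.sets[name], universe2)
        k1, n1 = len(t1.genes & q1.genes), len(q1)
        k2, n2 = len(t2.genes & q2.genes), len(q2)
        r1, r2 = k1 / n1, k2 / n2
        try:
            z, p = two_proportion_ztest(k1, n1, k2, n2, tail=tail)
            flag = None
        except DegenerateBackgroundError:
            z, p, flag = 0.0, 1.0, "degenerate"
        out.append(
            DifferentialResult(
                catalog_set_name=name,
                k1=k1,
                n1=n1,
                k2=k2,
                n2=n2,
                r1=r1,
                r2=r2,
                z_diff=z,
                p_diff=p,
                classification=_classify(p, r1, r2, alpha),
                confidence=confidence,
                flag=flag,
            )
        )
    out.sort(key=lambda r: (-abs(r.z_diff), r.catalog_set_name))
    return out


def write_differential_tsv(results: list[DifferentialResult], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "catalog_set": r.catalog_set_name,
                "k1": r.k1,
                "n1": r.n1,
                "k2": r.k2,
                "n2": r.n2,
                "r1": r.r1,
                "r2": r.r2,
                "z_diff": r.z_diff,
                "p_diff": r.p_diff,
                "classification": r.classification,
                "flag": r.flag or "",
            }
            for r in results
        ]
    ).to_csv(path, sep="\t", index=False, lineterminator="\n")
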