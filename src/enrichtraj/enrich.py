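"""Two-sided hypergeometric enrichment/depletion of ontology terms.

Each condition's DE list is tested against every ontology term whose level
lies in a configured band (default 3-9) and whose universe annotation count
meets a minimum; p-values are Bonferroni-corrected over the terms actually
tested for that list. Tail probabilities are computed with exact integer
binomial-coefficient sums, so they agree with full enumeration to floating
precision at any universe size.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable

from .containers import AnnotationSet, OntologyGraph


@lru_cache(maxsize=200_000)
def _comb(n: int, k: int) -> int:
    return math.comb(n, k)


def _support(n: int, K: int, N: int) -> range:
    return range(max(0, n + K - N), min(n, K) + 1)


def hypergeom_tails_exact(k: int, n: int, K: int, N: int) -> tuple[float, float]:
    """(P(X >= k), P(X <= k)) for X ~ Hypergeometric(N, K, n), exact.

    Numerators are exact integers over the common denominator C(N, n); the
    only rounding is the final big-int division.
    """
    den = _comb(N, n)
    upper = sum(_comb(K, j) * _comb(N - K, n - j) for j in _support(n, K, N) if j >= k)
    lower = sum(_comb(K, j) * _comb(N - K, n - j) for j in _support(n, K, N) if j <= k)
    return upper / den, lower / den


def hypergeom_minlike_p(k: int, n: int, K: int, N: int) -> float:
    """Two-sided p by the minimum-likelihood rule: sum of P(X = j) over all j
    whose point probability is <= P(X = k), compared exactly on integers."""
    den = _comb(N, n)
    obs = _comb(K, k) * _comb(N - K, n - k)
    num = sum(
        c
        for j in _support(n, K, N)
        if (c := _comb(K, j) * _comb(N - K, n - j)) <= obs
    )
    return num / den


def hypergeom_test(
    k: int, n: int, K: int, N: int, two_sided: str = "double"
) -> tuple[float, float, float]:
    """Enrichment, depletion, and two-sided p for a k-gene overlap.

    ``n`` genes drawn (the list), ``K`` annotated in the universe of ``N``.
    The default two-sided rule doubles the smaller tail and caps at 1;
    ``two_sided="minlike"`` uses the minimum-likelihood rule instead.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"require 0 <= K <= N and 0 <= n <= N, got k={k} n={n} K={K} N={N}")
    if not (max(0, n + K - N) <= k <= min(n, K)):
        raise ValueError(f"k={k} outside hypergeometric support for n={n} K={K} N={N}")
    p_enrich, p_deplete = hypergeom_tails_exact(k, n, K, N)
    if two_sided == "double":
        p_two = min(1.0, 2.0 * min(p_enrich, p_deplete))
    elif two_sided == "minlike":
        p_two = hypergeom_minlike_p(k, n, K, N)
    else:
        raise ValueError(f"unknown two-sided rule {two_sided!r}")
    return p_enrich, p_deplete, p_two


@dataclass
class EnrichmentRecord:
    term_id: str
    condition: str
    k_hits: int
    n_list: int
    K_term: int
    N_universe: int
    p_enrich: float
    p_deplete: float
    p_two_sided: float
    p_bonferroni: float
    direction: str               # "enriched" | "depleted"
    hit_genes: frozenset[str]
    level: int | None = None
    term_name: str = ""


def enrich_condition(
    list_genes: Iterable[str],
    annotations: AnnotationSet,
    ontology: OntologyGraph,
    condition: str = "",
    min_level: int = 3,
    max_level: int = 9,
    min_term_genes: int = 3,
    universe: Iterable[str] | None = None,
    two_sided: str = "double",
) -> list[EnrichmentRecord]:
    """Two-sided term tests for one condition's DE list.

    Terms tested: ontology level within [min_level, max_level] and at least
    ``min_term_genes`` universe genes annotated. The Bonferroni factor is
    the number of terms actually tested for this list. List genes outside
    the universe are dropped (warned). Records come back sorted by the
    two-sided p.
    """
    uni = frozenset(universe) if universe is not None else annotations.universe
    genes = frozenset(list_genes)
    dropped = genes - uni
    if dropped:
        warnings.warn(
            f"{len(dropped)} list genes outside the universe were dropped",
            stacklevel=2,
        )
    genes &= uni
    if not genes:
        warnings.warn("empty gene list after universe intersection", stacklevel=2)
        return []

    tested: list[tuple[str, frozenset[str]]] = []
    for t in ontology.terms_in_level_range(min_level, max_level):
        tg = annotations.genes_for(t) & uni
        if len(tg) >= min_term_genes:
            tested.append((t, tg))
    m = len(tested)
    N, n = len(uni), len(genes)
    records = []
    for t, tg in tested:
        hits = genes & tg
        p_e, p_d, p_2 = hypergeom_test(len(hits), n, len(tg), N, two_sided=two_sided)
        records.append(
            EnrichmentRecord(
                term_id=t,
                condition=condition,
                k_hits=len(hits),
                n_list=n,
                K_term=len(tg),
                N_universe=N,
                p_enrich=p_e,
                p_deplete=p_d,
                p_two_sided=p_2,
                p_bonferroni=min(1.0, p_2 * m),
                direction="enriched" if p_e <= p_d else "depleted",
                hit_genes=hits,
                level=ontology.level[t],
                term_name=ontology.terms[t],
            )
        )
    records.sort(key=lambda r: (r.p_two_sided, r.term_id))
    return records


def expression_universe(expr, annotations: AnnotationSet) -> frozenset[str]:
    """Default test universe: genes on the expression table that carry at
    least one annotation."""
    annotated = frozenset().union(*annotations.term_to_genes.values(), frozenset())
    return frozenset(expr.gene_ids) & annotated
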