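"""Condition dominance of ontology terms across an ordered stress time course.

For a term and a treatment condition, dominance measures how exclusively
that condition's DE genes account for the term:

    Dominance(group, term) = (n_group / n_unique)
                             x (1 - log(n_total / n_unique) / log(n_total))
                             x 100

where n_group counts the condition's DE genes annotated to the term,
n_unique the distinct such genes across all conditions, and n_total the
sum over conditions (a gene counted once per condition whose list carries
it). The ratio-of-logs correction is base-invariant; natural log is used.
A term carried by a single condition scores exactly 100 there; sharing
across conditions pulls every condition's score down. Each (condition,
term) cell also gets a two-sided Fisher exact p from the 2x2 table of
term membership vs list membership over the pooled DE universe.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import AnnotationSet
from .enrich import _comb, _support


@dataclass(frozen=True)
class DominanceInputs:
    n_group_term: int      # condition's DE genes annotated to the term
    n_unique_term: int     # distinct annotated DE genes across all conditions
    n_total_term: int      # summed per-condition counts (with multiplicity)

    def __post_init__(self) -> None:
        if not 0 <= self.n_group_term <= self.n_unique_term <= self.n_total_term:
            raise ValueError(
                "require 0 <= n_group <= n_unique <= n_total, got "
                f"{self.n_group_term}, {self.n_unique_term}, {self.n_total_term}"
            )


def dominance_score(inp: DominanceInputs) -> float:
    """Evaluate the dominance percentage for one (condition, term) cell.

    Degenerate case: n_total = 1 (a sole gene seen in a sole condition)
    is defined as 100, where the log denominator would vanish.
    """
    g, u, t = inp.n_group_term, inp.n_unique_term, inp.n_total_term
    if t == 0:
        raise ValueError("term has no DE genes in any condition; do not score it")
    if t == 1:
        return 100.0
    return (g / u) * (1.0 - math.log(t / u) / math.log(t)) * 100.0


def fisher_two_sided_exact(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p for a 2x2 table, point-probability method.

    Sums hypergeometric probabilities of all fixed-margin tables whose
    point probability is at most the observed one, with the tie comparison
    done on exact integer numerators (common denominator C(N, n)), so the
    result agrees with exhaustive enumeration to floating precision.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    N = a + b + c + d
    if N == 0:
        raise ValueError("empty universe")
    K = a + b   # first-row margin (e.g. genes in the term)
    n = a + c   # first-column margin (e.g. genes in the condition list)
    obs = _comb(K, a) * _comb(N - K, n - a)
    num = sum(
        w
        for j in _support(n, K, N)
        if (w := _comb(K, j) * _comb(N - K, n - j)) <= obs
    )
    return num / _comb(N, n)


def fisher_condition_term(
    list_genes: Iterable[str],
    term_genes: Iterable[str],
    universe: Iterable[str],
) -> tuple[float, tuple[tuple[int, int], tuple[int, int]]]:
    """Two-sided Fisher exact test of term membership vs list membership.

    The 2x2 table over the universe is
    [[in term & in list,  in term & not in list],
     [not in term & in list, in neither]].
    """
    uni = frozenset(universe)
    if not uni:
        raise ValueError("empty universe")
    lst = frozenset(list_genes) & uni
    term = frozenset(term_genes) & uni
    a = len(term & lst)
    b = len(term - lst)
    c = len(lst - term)
    d = len(uni) - a - b - c
    table = ((a, b), (c, d))
    return fisher_two_sided_exact(table), table


@dataclass
class TrajectoryTable:
    """Term x condition table of (dominance_pct, fisher_p) cells."""

    conditions: list[str]
    table: pd.DataFrame          # MultiIndex columns (condition, field)
    significance_floor: float = 0.05

    def cell(self, term_id: str, condition: str) -> tuple[float, float]:
        row = self.table.loc[term_id]
        return (
            float(row[(condition, "dominance_pct")]),
            float(row[(condition, "fisher_p")]),
        )

    def argmax_condition(self, term_id: str) -> str:
        row = self.table.loc[term_id]
        vals = {c: float(row[(c, "dominance_pct")]) for c in self.conditions}
        return max(vals, key=vals.get)

    def to_long(self) -> pd.DataFrame:
        """Long-format bubble-chart data: one row per (term, condition)."""
        rows = []
        for term in self.table.index:
            for c in self.conditions:
                dom, p = self.cell(term, c)
                rows.append(
                    {
                        "term_id": term,
                        "condition": c,
                        "dominance_pct": dom,
                        "fisher_p": p,
                        "significant": p < self.significance_floor,
                    }
                )
        return pd.DataFrame(rows)


def term_condition_counts(
    term_genes: frozenset[str], condition_lists: Mapping[str, frozenset[str]]
) -> dict[str, DominanceInputs]:
    """Dominance count triples for one term across all conditions."""
    per_cond = {c: term_genes & lst for c, lst in condition_lists.items()}
    unique = frozenset().union(*per_cond.values(), frozenset())
    total = sum(len(g) for g in per_cond.values())
    return {
        c: DominanceInputs(len(per_cond[c]), len(unique), total)
        for c in condition_lists
    }


def build_trajectory(
    condition_lists: Mapping[str, frozenset[str]],
    annotations: AnnotationSet,
    terms_of_interest: Iterable[str],
    conditions: Sequence[str] | None = None,
    significance_floor: float = 0.05,
    fisher_universe: Iterable[str] | None = None,
) -> TrajectoryTable:
    """Dominance + Fisher p per (term, condition), in time order.

    ``conditions`` fixes the column order (defaults to the mapping order of
    ``condition_lists``). The Fisher universe defaults to the union of the
    condition DE lists. Terms with no DE gene in any condition are dropped
    with a warning.
    """
    conds = list(conditions) if conditions is not None else list(condition_lists)
    universe = (
        frozenset(fisher_universe)
        if fisher_universe is not None
        else frozenset().union(*condition_lists.values(), frozenset())
    )
    rows: dict[str, dict] = {}
    for term in terms_of_interest:
        tg = annotations.genes_for(term) & universe
        counts = term_condition_counts(tg, {c: condition_lists[c] for c in conds})
        if counts[conds[0]].n_total_term == 0:
            warnings.warn(
                f"term {term} has no DE genes in any condition; row dropped",
                stacklevel=2,
            )
            continue
        row: dict = {}
        for c in conds:
            p, _ = fisher_condition_term(condition_lists[c], tg, universe)
            row[(c, "dominance_pct")] = dominance_score(counts[c])
            row[(c, "fisher_p")] = p
        rows[term] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    if not table.empty:
        table.columns = pd.MultiIndex.from_tuples(table.columns)
        table = table[[(c, f) for c in conds for f in ("dominance_pct", "fisher_p")]]
    return TrajectoryTable(
        conditions=conds, table=table, significance_floor=significance_floor
    )
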