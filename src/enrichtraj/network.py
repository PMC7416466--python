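"""Kappa-similarity network over enriched terms and its communities.

Term-term similarity is Cohen's kappa between the two terms' binary
gene-membership vectors over the union of all conditions' DE genes. Edges
at kappa >= 0.5 (default) define the network; communities are its
connected components, each labeled by its most significant member term.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import networkx as nx

from .containers import AnnotationSet
from .enrich import EnrichmentRecord


def kappa_score(genes_a: Iterable[str], genes_b: Iterable[str], universe: Iterable[str]) -> float:
    """Cohen's kappa of two gene sets viewed as binary vectors over a universe.

    kappa = (po - pe) / (1 - pe) with po the observed agreement and pe the
    chance agreement of the 2x2 membership table; identical sets give 1
    (including the degenerate po = pe = 1 case).
    """
    uni = frozenset(universe)
    if not uni:
        raise ValueError("empty universe")
    a = frozenset(genes_a)
    b = frozenset(genes_b)
    if not a <= uni or not b <= uni:
        raise ValueError("gene sets must be subsets of the universe")
    n = len(uni)
    n11 = len(a & b)
    n10 = len(a - b)
    n01 = len(b - a)
    n00 = n - n11 - n10 - n01
    po = (n11 + n00) / n
    if po == 1.0:
        return 1.0
    pe = ((n11 + n10) * (n11 + n01) + (n01 + n00) * (n10 + n00)) / (n * n)
    return (po - pe) / (1.0 - pe)


@dataclass(frozen=True)
class KappaEdge:
    term_a: str
    term_b: str
    kappa: float


@dataclass
class TermCommunity:
    community_id: str
    term_ids: frozenset[str]
    leading_term: str
    leading_p: float
    per_condition_gene_share: dict[str, float]
    dominant_condition: str | None = None    # condition with share >= 0.5, if any
    n_genes: int = 0


def build_network(
    records: Sequence[EnrichmentRecord],
    annotations: AnnotationSet,
    condition_lists: dict[str, frozenset[str]],
    kappa_min: float = 0.5,
    p_max: float | None = 0.05,
) -> tuple[list[KappaEdge], list[TermCommunity]]:
    """Kappa network plus connected-component communities over enriched terms.

    ``records`` pool every condition's enrichment results. A term enters the
    network when its best Bonferroni p across conditions is below ``p_max``
    (None disables the filter). Term gene sets are restricted to the union
    of the condition DE lists — the genes actually uploaded — which is also
    the kappa universe. Ties for the leading term (equal best p) break
    toward the larger restricted gene set, then lexicographic id.
    """
    if not 0.0 < kappa_min <= 1.0:
        raise ValueError("kappa_min must be in (0, 1]")
    universe = frozenset().union(*condition_lists.values(), frozenset())
    best_p: dict[str, float] = {}
    for r in records:
        best_p[r.term_id] = min(best_p.get(r.term_id, 1.0), r.p_bonferroni)
    terms = sorted(
        t for t, p in best_p.items() if p_max is None or p < p_max
    )
    if not terms:
        warnings.warn("no enriched terms; network is empty", stacklevel=2)
        return [], []
    term_genes = {t: annotations.genes_for(t) & universe for t in terms}

    g = nx.Graph()
    g.add_nodes_from(terms)
    edges: list[KappaEdge] = []
    for ta, tb in combinations(terms, 2):
        k = kappa_score(term_genes[ta], term_genes[tb], universe)
        if k >= kappa_min:
            g.add_edge(ta, tb)
            edges.append(KappaEdge(ta, tb, k))

    communities: list[TermCommunity] = []
    comps = sorted(nx.connected_components(g), key=lambda c: sorted(c)[0])
    for i, comp in enumerate(comps, start=1):
        members = frozenset(comp)
        leading = min(
            members, key=lambda t: (best_p[t], -len(term_genes[t]), t)
        )
        comm_genes = frozenset().union(*(term_genes[t] for t in members), frozenset())
        shares = {
            c: (len(comm_genes & lst) / len(comm_genes) if comm_genes else 0.0)
            for c, lst in condition_lists.items()
        }
        dominant = max(shares, key=shares.get) if shares else None
        if dominant is not None and shares[dominant] < 0.5:
            dominant = None
        communities.append(
            TermCommunity(
                community_id=f"C{i}",
                term_ids=members,
                leading_term=leading,
                leading_p=best_p[leading],
                per_condition_gene_share=shares,
                dominant_condition=dominant,
                n_genes=len(comm_genes),
            )
        )
    return edges, communities


def write_network(
    edges: Sequence[KappaEdge],
    communities: Sequence[TermCommunity],
    edge_path,
    community_path,
    graphml_path=None,
) -> None:
    """Edge-list TSV, community table TSV, and optional GraphML dump."""
    import pandas as pd

    pd.DataFrame(
        [(e.term_a, e.term_b, e.kappa) for e in edges],
        columns=["term_a", "term_b", "kappa"],
    ).to_csv(edge_path, sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "community": c.community_id,
                "terms": "|".join(sorted(c.term_ids)),
                "leading_term": c.leading_term,
                "leading_p": c.leading_p,
                "n_genes": c.n_genes,
                "dominant_condition": c.dominant_condition or "none",
                **{f"share_{k}": v for k, v in c.per_condition_gene_share.items()},
            }
            for c in communities
        ]
    ).to_csv(community_path, sep="\t", index=False)
    if graphml_path is not None:
        g = nx.Graph()
        for c in communities:
            for t in c.term_ids:
                g.add_node(t, community=c.community_id, leading=t == c.leading_term)
        for e in edges:
            g.add_edge(e.term_a, e.term_b, kappa=e.kappa)
        nx.write_graphml(g, graphml_path)
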