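"""Core in-memory containers shared across the pipeline.

The pipeline operates on a gene-level log2 expression matrix with a
condition design (one control plus ordered treatment conditions), a rooted
ontology DAG with per-term levels, and term->gene annotation maps.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class ExpressionTable:
    """Log2 gene x sample expression matrix plus its condition design.

    Parameters
    ----------
    values : pandas.DataFrame
        Genes on rows (index = gene ids), samples on columns, log2 scale.
    design : mapping sample_id -> condition label. Insertion order of the
        *conditions* (first appearance) defines the experimental time order.
    control_condition : the condition treated as baseline (e.g. home cage).
    """

    values: pd.DataFrame
    design: dict[str, str]
    control_condition: str

    def __post_init__(self) -> None:
        self.values = pd.DataFrame(self.values)
        missing = [s for s in self.values.columns if s not in self.design]
        if missing:
            raise ValueError(f"samples missing from design: {missing}")
        if self.control_condition not in set(self.design.values()):
            raise ValueError(
                f"control condition {self.control_condition!r} not in design"
            )
        if self.values.isna().any().any():
            bad = np.argwhere(self.values.isna().to_numpy())
            g, s = bad[0]
            raise ValueError(
                "missing values are not allowed; first NaN at "
                f"gene {self.values.index[g]!r}, sample {self.values.columns[s]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def conditions(self) -> list[str]:
        """Conditions in design insertion order (control included)."""
        seen: dict[str, None] = {}
        for s in self.design:
            seen.setdefault(self.design[s], None)
        return list(seen)

    @property
    def treatment_conditions(self) -> list[str]:
        return [c for c in self.conditions if c != self.control_condition]

    def condition_samples(self, condition: str) -> list[str]:
        cols = [s for s in self.sample_ids if self.design[s] == condition]
        if not cols:
            raise KeyError(f"no samples for condition {condition!r}")
        return cols

    def condition_matrix(self, condition: str) -> np.ndarray:
        return self.values[self.condition_samples(condition)].to_numpy()

    def equals(self, other: "ExpressionTable") -> bool:
        return (
            self.values.equals(other.values)
            and self.design == other.design
            and self.control_condition == other.control_condition
        )


@dataclass
class OntologyGraph:
    """Rooted ontology DAG with shortest-path term levels.

    ``parents`` maps each term to its ``is_a`` parents. The level of a term
    is its breadth-first (shortest-path) distance from the root; the root
    has level 0.
    """

    terms: dict[str, str]            # term_id -> name
    parents: dict[str, tuple[str, ...]]
    root_id: str
    level: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = {
            p for ps in self.parents.values() for p in ps if p not in self.terms
        }
        if unknown:
            raise ValueError(f"is_a references unknown terms: {sorted(unknown)}")
        g = self.to_networkx()
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValueError(f"ontology contains a cycle: {cycle}")
        if not self.level:
            self.level = self._compute_levels(g)
        if self.level.get(self.root_id) != 0:
            raise ValueError("root must be at level 0")

    def to_networkx(self) -> nx.DiGraph:
        """Directed graph with child -> parent edges."""
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for child, ps in self.parents.items():
            for p in ps:
                g.add_edge(child, p)
        return g

    def _compute_levels(self, g: nx.DiGraph) -> dict[str, int]:
        # BFS from the root over parent -> child direction
        dist = nx.single_source_shortest_path_length(g.reverse(copy=False), self.root_id)
        unreachable = set(self.terms) - set(dist)
        if unreachable:
            raise ValueError(
                f"terms not reachable from root {self.root_id!r}: {sorted(unreachable)}"
            )
        return dict(dist)

    def terms_in_level_range(self, min_level: int, max_level: int) -> list[str]:
        return [t for t in self.terms if min_level <= self.level[t] <= max_level]

    def ancestors(self, term_id: str) -> set[str]:
        out: set[str] = set()
        stack = list(self.parents.get(term_id, ()))
        while stack:
            t = stack.pop()
            if t not in out:
                out.add(t)
                stack.extend(self.parents.get(t, ()))
        return out


@dataclass
class AnnotationSet:
    """Term -> gene annotations over a declared gene universe."""

    term_to_genes: dict[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        self.term_to_genes = {
            t: frozenset(g) for t, g in self.term_to_genes.items()
        }
        self.universe = frozenset(self.universe)
        stray = set().union(*self.term_to_genes.values(), set()) - self.universe
        if stray:
            raise ValueError(
                f"{len(stray)} annotated genes outside universe, e.g. "
                f"{sorted(stray)[:5]}"
            )

    def restricted_to(self, universe: Iterable[str]) -> "AnnotationSet":
        """Intersect every term's gene set with a new universe.

        Terms left empty after restriction are dropped.
        """
        uni = frozenset(universe)
        mapped = {
            t: g & uni for t, g in self.term_to_genes.items()
        }
        return AnnotationSet(
            {t: g for t, g in mapped.items() if g}, uni
        )

    def propagated(self, ontology: OntologyGraph) -> "AnnotationSet":
        """True-path propagation: each gene annotated to a term is also
        annotated to every ancestor of that term."""
        out: dict[str, set[str]] = {t: set(g) for t, g in self.term_to_genes.items()}
        for t, genes in self.term_to_genes.items():
            for anc in ontology.ancestors(t):
                out.setdefault(anc, set()).update(genes)
        return AnnotationSet({t: frozenset(g) for t, g in out.items()}, self.universe)

    def genes_for(self, term_id: str) -> frozenset[str]:
        return self.term_to_genes.get(term_id, frozenset())


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style) for GSEA."""

    sets: dict[str, tuple[str, frozenset[str]]]

    def __post_init__(self) -> None:
        for sid, (_, genes) in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {sid!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def genes(self, set_id: str) -> frozenset[str]:
        return self.sets[set_id][1]

    def description(self, set_id: str) -> str:
        return self.sets[set_id][0]
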