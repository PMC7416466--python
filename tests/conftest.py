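import numpy as np
import pandas as pd
import pytest

from enrichtraj.containers import AnnotationSet, ExpressionTable, OntologyGraph
from enrichtraj.synthetic import SyntheticConfig, generate_bundle


@pytest.fixture(scope="session")
def bundle():
    """A moderately sized planted-truth bundle shared by read-only tests."""
    return generate_bundle(SyntheticConfig(n_genes=2000, rng_seed=11))


@pytest.fixture
def tiny_expr():
    """3 genes x 4 samples over two conditions."""
    values = pd.DataFrame(
        [[5.0, 5.2, 7.1, 7.0], [6.0, 6.1, 6.0, 5.9], [4.0, 4.1, 4.2, 4.0]],
        index=["g1", "g2", "g3"],
        columns=["a1", "a2", "b1", "b2"],
    )
    design = {"a1": "HC", "a2": "HC", "b1": "CSD", "b2": "CSD"}
    return ExpressionTable(values=values, design=design, control_condition="HC")


@pytest.fixture
def diamond_ontology():
    """root -> A, root -> B, A -> C, B -> C (shortest-path level of C is 2)."""
    terms = {"root": "root", "A": "a", "B": "b", "C": "c"}
    parents = {"root": (), "A": ("root",), "B": ("root",), "C": ("A", "B")}
    return OntologyGraph(terms=terms, parents=parents, root_id="root")


def bfs_levels(parents: dict[str, tuple[str, ...]], root: str) -> dict[str, int]:
    """Independent breadth-first level oracle over child->parent edges."""
    children: dict[str, list[str]] = {t: [] for t in parents}
    for child, ps in parents.items():
        for p in ps:
            children[p].append(child)
    level = {root: 0}
    frontier = [root]
    while frontier:
        nxt = []
        for t in frontier:
            for c in children[t]:
                if c not in level:
                    level[c] = level[t] + 1
                    nxt.append(c)
        frontier = nxt
    return level
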