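"""Readers and writers for the pipeline's external formats.

Expression matrices travel as TSV (genes x samples) with a sidecar design
file (sample, condition); gene sets as GMT; annotations as two-column
TSV (term_id, gene_id); ontologies as an OBO subset with id/name/is_a.
Readers validate and reject malformed input rather than coercing it; every
writer's output round-trips through its paired reader.
"""
from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Iterable

import numpy as np
import obonet
import pandas as pd

from .containers import AnnotationSet, ExpressionTable, GeneSetCollection, OntologyGraph

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# expression matrix + design

def read_expression(
    matrix_path: str | Path,
    design_path: str | Path,
    control: str,
    duplicate_rule: str = "max_mean",
) -> ExpressionTable:
    """Load a log2 expression TSV plus its sample->condition design.

    Duplicate gene ids are collapsed by ``duplicate_rule`` (currently only
    ``"max_mean"``: keep the row with the largest mean intensity); the number
    of collapsed rows is logged.
    """
    df = pd.read_csv(matrix_path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for j, col in enumerate(df.columns):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            gene = df.index[int(np.argmax(bad.to_numpy()))]
            raise ValueError(
                f"non-numeric expression value at gene {gene!r}, sample {col!r}"
            )
        df[col] = coerced

    design_df = pd.read_csv(design_path, sep="\t", dtype=str)
    if list(design_df.columns[:2]) != ["sample", "condition"]:
        raise ValueError(
            "design file must have columns 'sample' and 'condition', got "
            f"{list(design_df.columns)}"
        )
    design = dict(zip(design_df["sample"], design_df["condition"]))
    missing = [s for s in df.columns if s not in design]
    if missing:
        raise ValueError(f"samples missing from design: {missing}")

    if df.index.duplicated().any():
        n_dup = int(df.index.duplicated().sum())
        if duplicate_rule != "max_mean":
            raise ValueError(f"unknown duplicate rule {duplicate_rule!r}")
        df = (
            df.assign(_mean=df.mean(axis=1))
            .sort_values("_mean", ascending=False)
            .groupby(level=0, sort=False)
            .head(1)
            .drop(columns="_mean")
        )
        df = df.loc[sorted(df.index)]
        logger.info("collapsed %d duplicate gene rows (rule=%s)", n_dup, duplicate_rule)

    return ExpressionTable(values=df, design=design, control_condition=control)


def write_expression(
    table: ExpressionTable, matrix_path: str | Path, design_path: str | Path
) -> None:
    table.values.to_csv(matrix_path, sep="\t", index_label="gene")
    pd.DataFrame(
        {"sample": list(table.design), "condition": list(table.design.values())}
    ).to_csv(design_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GMT gene sets

def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: set_id <TAB> description <TAB> gene1 <TAB> gene2 ..."""
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not any(ln.strip() for ln in lines):
        warnings.warn(f"GMT file {path} is empty", stacklevel=2)
        return GeneSetCollection({})
    for i, ln in enumerate(lines, start=1):
        if not ln.strip():
            continue
        fields = ln.split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{i}: GMT line has fewer than 3 fields")
        set_id, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g]
        if len(set(genes)) < len(genes):
            warnings.warn(
                f"{path}:{i}: duplicate genes in set {set_id!r} de-duplicated",
                stacklevel=2,
            )
        sets[set_id] = (desc, frozenset(genes))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, (desc, genes) in collection.sets.items():
            fh.write("\t".join([sid, desc, *sorted(genes)]) + "\n")


# ---------------------------------------------------------------------------
# OBO subset ontology

def read_obo_subset(path: str | Path) -> OntologyGraph:
    """Parse an OBO subset (id, name, is_a stanzas) into an OntologyGraph.

    Obsolete terms are skipped (count logged). The root is the unique term
    with no parents. Cycles and dangling is_a references raise.
    """
    graph = obonet.read_obo(path, ignore_obsolete=False)
    obsolete = [n for n, d in graph.nodes(data=True) if d.get("is_obsolete") == "true"]
    if obsolete:
        logger.info("skipping %d obsolete terms", len(obsolete))
        graph.remove_nodes_from(obsolete)
    terms = {n: graph.nodes[n].get("name", n) for n in graph.nodes}
    parents: dict[str, tuple[str, ...]] = {}
    dangling = set()
    for n in graph.nodes:
        ps = []
        for ref in graph.nodes[n].get("is_a", []):
            if ref not in terms:
                dangling.add(ref)
            ps.append(ref)
        # obonet also records is_a as edges; prefer explicit stanza data but
        # fall back to edges for nodes parsed without attribute lists
        if not ps:
            ps = [v for _, v, k in graph.out_edges(n, keys=True) if k == "is_a"]
        parents[n] = tuple(ps)
    if dangling:
        raise ValueError(f"is_a references unknown terms: {sorted(dangling)}")
    roots = [t for t in terms if not parents.get(t)]
    if len(roots) != 1:
        raise ValueError(f"expected exactly one root term, found {sorted(roots)}")
    return OntologyGraph(terms=terms, parents=parents, root_id=roots[0])


def write_obo_subset(ontology: OntologyGraph, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n\n")
        for t in ontology.terms:
            fh.write("[Term]\n")
            fh.write(f"id: {t}\n")
            fh.write(f"name: {ontology.terms[t]}\n")
            for p in ontology.parents.get(t, ()):
                fh.write(f"is_a: {p} ! {ontology.terms[p]}\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# two-column annotations (GAF-like subset: term_id <TAB> gene_id)

def read_annotations(path: str | Path, universe: Iterable[str] | None = None) -> AnnotationSet:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="!")
    if list(df.columns[:2]) != ["term_id", "gene_id"]:
        raise ValueError(
            f"annotation file must have columns 'term_id' and 'gene_id', got "
            f"{list(df.columns)}"
        )
    term_to_genes: dict[str, set[str]] = {}
    for t, g in zip(df["term_id"], df["gene_id"]):
        term_to_genes.setdefault(t, set()).add(g)
    uni = (
        frozenset(universe)
        if universe is not None
        else frozenset().union(*term_to_genes.values(), frozenset())
    )
    annot = AnnotationSet({t: frozenset(g) for t, g in term_to_genes.items()}, uni)
    if universe is not None:
        annot = annot.restricted_to(uni)
    return annot


def write_annotations(annotations: AnnotationSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("term_id\tgene_id\n")
        for t in sorted(annotations.term_to_genes):
            for g in sorted(annotations.term_to_genes[t]):
                fh.write(f"{t}\t{g}\n")


# ---------------------------------------------------------------------------
# ranked gene list TSV (gene <TAB> t)

def read_ranked_list(path: str | Path):
    from .gsea import RankedGeneList

    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if list(df.columns[:2]) != ["gene", "t"]:
        raise ValueError(
            f"ranked list must have columns 'gene' and 't', got {list(df.columns)}"
        )
    return RankedGeneList.from_metric(dict(zip(df["gene"], df["t"].astype(float))))


def write_ranked_list(ranked, path: str | Path) -> None:
    pd.DataFrame(
        {"gene": ranked.gene_ids, "t": [ranked.metric[g] for g in ranked.gene_ids]}
    ).to_csv(path, sep="\t", index=False)
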