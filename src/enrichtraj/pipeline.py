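"""End-to-end orchestration: simulate -> DE -> enrichment -> network ->
dominance trajectory (-> GSEA), with TSV outputs at every stage.

The stage functions here are thin wrappers that the CLI and the examples
share; all science lives in the per-stage modules.
"""
from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import de, dominance, enrich, gsea, io, network, synthetic
from .containers import GeneSetCollection

logger = logging.getLogger(__name__)


def write_bundle(bundle: synthetic.SyntheticBundle, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    io.write_expression(bundle.expression, out / "expression.tsv", out / "design.tsv")
    io.write_obo_subset(bundle.ontology, out / "ontology.obo")
    io.write_annotations(bundle.annotations, out / "annotations.tsv")
    io.write_gmt(
        GeneSetCollection(
            {
                p.program_id: (f"planted program {p.program_id}", frozenset(p.gene_ids))
                for p in bundle.programs
            }
        ),
        out / "programs.gmt",
    )
    with open(out / "truth_manifest.json", "w") as fh:
        json.dump(bundle.truth_manifest, fh, indent=2, sort_keys=True)
    pd.DataFrame(
        [
            {
                "animal_id": b.animal_id,
                "condition": b.condition,
                "time_mouse_cylinder": b.time_mouse_cylinder,
                "time_empty_cylinder": b.time_empty_cylinder,
                "si_quotient": b.si_quotient,
                "ld_crosses": b.ld_crosses,
            }
            for b in bundle.behavior
        ]
    ).to_csv(out / "behavior.tsv", sep="\t", index=False)


def run_de(
    expr, out_dir: str | Path, threshold_fold: float = 1.3, q_max: float = 0.05
):
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stats = de.anova_fdr(expr)
    stats.to_csv(out / "de_stats.tsv", sep="\t", index_label="gene")
    lists = de.build_lists(stats, threshold_fold=threshold_fold, q_max=q_max)
    for c, genes in lists.lists.items():
        (out / f"de_list_{c}.txt").write_text("\n".join(sorted(genes)) + "\n")
    return stats, lists


def run_enrichment(
    lists, annotations, ontology, expr=None, out_dir: str | Path | None = None,
    min_level: int = 3, max_level: int = 9, min_term_genes: int = 3,
):
    universe = (
        enrich.expression_universe(expr, annotations)
        if expr is not None
        else annotations.universe
    )
    all_records = []
    for c, genes in lists.lists.items():
        recs = enrich.enrich_condition(
            genes, annotations, ontology, condition=c,
            min_level=min_level, max_level=max_level,
            min_term_genes=min_term_genes, universe=universe,
        )
        all_records.extend(recs)
        if out_dir is not None:
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            pd.DataFrame(
                [
                    {
                        "term": r.term_id,
                        "name": r.term_name,
                        "level": r.level,
                        "k": r.k_hits,
                        "n": r.n_list,
                        "K": r.K_term,
                        "N": r.N_universe,
                        "p_enrich": r.p_enrich,
                        "p_deplete": r.p_deplete,
                        "p_two_sided": r.p_two_sided,
                        "p_bonferroni": r.p_bonferroni,
                        "direction": r.direction,
                        "hit_genes": "|".join(sorted(r.hit_genes)),
                    }
                    for r in recs
                ]
            ).to_csv(out / f"enrichment_{c}.tsv", sep="\t", index=False)
    return all_records


def run_network(records, annotations, lists, out_dir: str | Path | None = None,
                kappa_min: float = 0.5):
    edges, communities = network.build_network(
        records, annotations, dict(lists.lists), kappa_min=kappa_min
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        network.write_network(
            edges, communities,
            out / "kappa_edges.tsv", out / "communities.tsv",
            out / "term_network.graphml",
        )
    return edges, communities


def run_trajectory(lists, annotations, communities, conditions,
                   out_dir: str | Path | None = None, terms=None):
    if terms is None:
        terms = [c.leading_term for c in communities if len(c.term_ids) > 1]
    traj = dominance.build_trajectory(
        dict(lists.lists), annotations, terms, conditions=conditions
    )
    if out_dir is not None and not traj.table.empty:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        traj.to_long().to_csv(out / "trajectory.tsv", sep="\t", index=False)
    return traj


def run_all(config: synthetic.SyntheticConfig, out_dir: str | Path,
            threshold_fold: float = 1.3, kappa_min: float = 0.5,
            with_gsea: bool = True) -> dict:
    """Simulate a bundle and chain every transcriptomic stage over it.

    Returns a summary dict of the headline quantities each stage computed.
    """
    out = Path(out_dir)
    bundle = synthetic.generate_bundle(config)
    write_bundle(bundle, out / "bundle")
    stats, lists = run_de(bundle.expression, out, threshold_fold=threshold_fold)
    records = run_enrichment(
        lists, bundle.annotations, bundle.ontology, expr=bundle.expression,
        out_dir=out,
    )
    edges, communities = run_network(
        records, bundle.annotations, lists, out_dir=out, kappa_min=kappa_min
    )
    treatment = [c for c in bundle.expression.conditions
                 if c != bundle.expression.control_condition]
    traj = run_trajectory(lists, bundle.annotations, communities, treatment, out_dir=out)
    summary = {
        "n_genes": len(bundle.expression.gene_ids),
        "n_de_q05": int((stats["q"] < 0.05).sum()),
        "n_union_de": len(lists.union),
        "per_condition_list_sizes": {c: len(g) for c, g in lists.lists.items()},
        "n_significant_terms": len({r.term_id for r in records if r.p_bonferroni < 0.05}),
        "n_kappa_edges": len(edges),
        "n_communities": len(communities),
        "n_multi_term_communities": sum(1 for c in communities if len(c.term_ids) > 1),
        "n_trajectory_terms": 0 if traj.table.empty else len(traj.table),
    }
    if with_gsea:
        condition = treatment[-1]
        ranked = gsea.rank_genes(bundle.expression, condition)
        sets = GeneSetCollection(
            {
                p.program_id: (f"planted program {p.program_id}", frozenset(p.gene_ids))
                for p in bundle.programs
            }
        )
        gsea_records = gsea.permutation_stats(
            ranked, sets, n_perm=1000, rng_seed=config.rng_seed
        )
        gsea.records_to_frame(gsea_records).to_csv(
            out / f"gsea_{condition}.tsv", sep="\t", index=False
        )
        summary["gsea_condition"] = condition
        summary["gsea_min_p"] = min(r.p_perm for r in gsea_records)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
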