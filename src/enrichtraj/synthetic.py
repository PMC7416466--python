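"""Synthetic study generator with planted ground truth.

Emulates the study design the pipeline targets: brain endothelial
transcriptomes sampled under a home-cage control (HC) and an ordered series
of social-defeat exposures (CSD1, CSD7, CSD14) plus a recovery point
(CSDrec), with condition-specific upregulated gene programs tied to
ontology terms, a toy rooted ontology DAG, per-animal behavior scores, and
two-channel fluorescence images with known area fractions. Every generator
is deterministic given the bundle seed; each stage draws from its own
seed stream so adding a stage never perturbs earlier ones.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import AnnotationSet, ExpressionTable, OntologyGraph
from .histology import BehaviorRecord, TwoChannelImage

__all__ = [
    "PlantedProgram",
    "SyntheticConfig",
    "SyntheticBundle",
    "BehaviorParams",
    "generate_expression",
    "generate_ontology",
    "generate_images",
    "generate_behavior",
    "generate_bundle",
]

# study design: per-condition array counts of the emulated experiment
DEFAULT_CONDITIONS = ("HC", "CSD1", "CSD7", "CSD14", "CSDrec")
DEFAULT_SAMPLES = {"HC": 9, "CSD1": 5, "CSD7": 5, "CSD14": 8, "CSDrec": 9}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent generator per (seed, stage name).

    The stage name is hashed into the seed sequence so the draw order of one
    stage never depends on which other stages ran.
    """
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, zlib.crc32(stage.encode())])


@dataclass(frozen=True)
class PlantedProgram:
    """A block of genes upregulated together at specific conditions and
    annotated to a small clique of ontology terms."""

    program_id: str
    term_ids: tuple[str, ...]
    gene_ids: tuple[str, ...]
    active_conditions: tuple[str, ...]
    effect_log2: float
    direction: int = 1  # +1 up, -1 down

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValueError(f"program {self.program_id}: gene_ids empty")
        if not self.active_conditions:
            raise ValueError(f"program {self.program_id}: active_conditions empty")
        if self.effect_log2 <= 0:
            raise ValueError(f"program {self.program_id}: effect_log2 must be > 0")
        if self.direction not in (1, -1):
            raise ValueError("direction must be +1 or -1")


@dataclass(frozen=True)
class SyntheticConfig:
    n_genes: int = 10_000
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    control_condition: str = "HC"
    samples_per_condition: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SAMPLES)
    )
    baseline_mean_log2: float = 6.0
    baseline_sd_log2: float = 1.5
    noise_sd_log2: float = 0.3
    n_programs: int = 5
    genes_per_program: int = 20
    terms_per_program: int = 3
    effect_log2: float = 1.0
    frac_downregulated: float = 0.02
    down_effect_log2: float = 0.6
    ontology_n_terms: int = 150
    ontology_max_depth: int = 6
    program_level_range: tuple[int, int] = (3, 9)
    term_gene_frac: float = 0.9  # fraction of a program's genes each term carries
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.control_condition not in self.conditions:
            raise ValueError("control condition missing from conditions")
        for c in self.conditions:
            if self.samples_per_condition.get(c, 0) < 2:
                raise ValueError(
                    f"condition {c!r} needs >= 2 samples for within-group variance"
                )
        if not 0.0 <= self.frac_downregulated <= 1.0:
            raise ValueError("frac_downregulated must be in [0, 1]")

    @property
    def treatment_conditions(self) -> tuple[str, ...]:
        return tuple(c for c in self.conditions if c != self.control_condition)


@dataclass
class SyntheticBundle:
    expression: ExpressionTable
    ontology: OntologyGraph
    annotations: AnnotationSet
    programs: list[PlantedProgram]
    behavior: list[BehaviorRecord]
    truth_manifest: dict[str, dict]
    down_gene_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        genes = set(self.expression.gene_ids)
        for p in self.programs:
            missing = set(p.gene_ids) - genes
            if missing:
                raise ValueError(f"planted genes absent from expression: {missing}")
            for t in p.term_ids:
                if t not in self.ontology.terms:
                    raise ValueError(f"planted term {t} absent from ontology")
                if not self.annotations.genes_for(t):
                    raise ValueError(f"planted term {t} has no annotations")


# ---------------------------------------------------------------------------
# expression

def _gene_ids(n: int) -> list[str]:
    return [f"g{i:05d}" for i in range(n)]


def generate_expression(
    config: SyntheticConfig,
    programs: Sequence[PlantedProgram],
    down_gene_ids: Sequence[str] = (),
) -> ExpressionTable:
    """Baseline log2 intensities plus planted condition-specific shifts.

    Each gene's baseline is drawn once from Normal(baseline_mean, baseline_sd);
    every sample adds Normal(0, noise_sd) noise. Genes of a program are
    shifted by ``direction * effect_log2`` in that program's active
    conditions; ``down_gene_ids`` are shifted by ``-down_effect_log2`` in all
    treatment conditions. A gene planted with conflicting directions raises.
    """
    rng = stage_rng(config.rng_seed, "expression")
    gene_ids = _gene_ids(config.n_genes)
    index = {g: i for i, g in enumerate(gene_ids)}

    direction_of: dict[str, int] = {}
    for p in programs:
        for g in p.gene_ids:
            if g not in index:
                raise ValueError(f"program gene {g} not indexable within n_genes")
            prev = direction_of.get(g)
            if prev is not None and prev != p.direction:
                raise ValueError(
                    f"gene {g} planted with conflicting directions across programs"
                )
            direction_of[g] = p.direction
    for g in down_gene_ids:
        if direction_of.get(g, -1) != -1:
            raise ValueError(
                f"gene {g} planted both in an upregulated program and the "
                "downregulated set"
            )

    samples: list[str] = []
    design: dict[str, str] = {}
    for c in config.conditions:
        for j in range(config.samples_per_condition[c]):
            sid = f"{c}_s{j + 1}"
            samples.append(sid)
            design[sid] = c

    baseline = rng.normal(config.baseline_mean_log2, config.baseline_sd_log2, config.n_genes)
    noise = rng.normal(0.0, config.noise_sd_log2, (config.n_genes, len(samples)))
    values = baseline[:, None] + noise

    col_of_condition = {
        c: [j for j, s in enumerate(samples) if design[s] == c] for c in config.conditions
    }
    for p in programs:
        rows = [index[g] for g in p.gene_ids]
        for c in p.active_conditions:
            if c not in col_of_condition:
                raise ValueError(f"program {p.program_id}: unknown condition {c!r}")
            cols = col_of_condition[c]
            values[np.ix_(rows, cols)] += p.direction * p.effect_log2
    if down_gene_ids:
        rows = [index[g] for g in down_gene_ids]
        for c in config.treatment_conditions:
            values[np.ix_(rows, col_of_condition[c])] -= config.down_effect_log2

    df = pd.DataFrame(values, index=gene_ids, columns=samples)
    return ExpressionTable(values=df, design=design, control_condition=config.control_condition)


# ---------------------------------------------------------------------------
# ontology

def generate_ontology(
    n_terms: int, max_depth: int, rng_seed: int = 0
) -> OntologyGraph:
    """Random rooted DAG whose term level is the BFS distance from the root.

    The first ``min(n_terms, max_depth + 1)`` terms form a root-anchored
    chain so the level range [0, max_depth] is realized whenever the term
    count permits; remaining terms attach to one or two parents drawn so
    their shortest-path level is uniform over [1, max_depth].
    """
    if n_terms < 1 or max_depth < 1:
        raise ValueError("n_terms and max_depth must be >= 1")
    rng = stage_rng(rng_seed, "ontology")
    ids = [f"GO:SYN{i:05d}" for i in range(n_terms)]
    terms = {t: f"synthetic process {i}" for i, t in enumerate(ids)}
    parents: dict[str, tuple[str, ...]] = {ids[0]: ()}
    level = {ids[0]: 0}
    by_level: dict[int, list[str]] = {0: [ids[0]]}

    chain_len = min(n_terms, max_depth + 1)
    for i in range(1, chain_len):
        parents[ids[i]] = (ids[i - 1],)
        level[ids[i]] = i
        by_level.setdefault(i, []).append(ids[i])

    for i in range(chain_len, n_terms):
        lv = int(rng.integers(1, max_depth + 1))
        primary = str(rng.choice(by_level[lv - 1]))
        ps = [primary]
        # optional second parent at level >= lv - 1 keeps the BFS level at lv
        if rng.random() < 0.3:
            candidates = [
                t for l2 in range(lv - 1, max_depth) for t in by_level.get(l2, [])
            ]
            extra = str(rng.choice(candidates))
            if extra not in ps:
                ps.append(extra)
        parents[ids[i]] = tuple(ps)
        level[ids[i]] = lv
        by_level.setdefault(lv, []).append(ids[i])

    return OntologyGraph(terms=terms, parents=parents, root_id=ids[0], level=level)


# ---------------------------------------------------------------------------
# programs + annotations

def generate_programs(
    config: SyntheticConfig, ontology: OntologyGraph
) -> list[PlantedProgram]:
    """Assign disjoint gene blocks and eligible-level terms to programs,
    round-robin over the treatment conditions."""
    rng = stage_rng(config.rng_seed, "programs")
    lo, hi = config.program_level_range
    eligible = sorted(ontology.terms_in_level_range(lo, hi))
    needed = config.n_programs * config.terms_per_program
    if len(eligible) < needed:
        raise ValueError(
            f"ontology has {len(eligible)} terms in level range {lo}-{hi}, "
            f"need {needed}"
        )
    if config.n_programs * config.genes_per_program > config.n_genes:
        raise ValueError("not enough genes for the requested programs")
    term_pool = list(rng.permutation(eligible))
    gene_ids = _gene_ids(config.n_genes)
    gene_pool = list(rng.permutation(gene_ids))
    treatments = config.treatment_conditions
    programs = []
    for i in range(config.n_programs):
        terms = tuple(term_pool[i * config.terms_per_program:(i + 1) * config.terms_per_program])
        genes = tuple(
            sorted(gene_pool[i * config.genes_per_program:(i + 1) * config.genes_per_program])
        )
        programs.append(
            PlantedProgram(
                program_id=f"prog{i + 1}",
                term_ids=terms,
                gene_ids=genes,
                active_conditions=(treatments[i % len(treatments)],),
                effect_log2=config.effect_log2,
            )
        )
    return programs


def generate_annotations(
    config: SyntheticConfig,
    ontology: OntologyGraph,
    programs: Sequence[PlantedProgram],
) -> AnnotationSet:
    """Annotate program terms to (most of) their program's genes and the
    remaining terms to random background genes.

    Every planted gene is annotated to at least one of its program's terms:
    gene j is always carried by term ``j mod terms_per_program`` and joins
    the others independently with probability ``term_gene_frac``.
    """
    rng = stage_rng(config.rng_seed, "annotations")
    gene_ids = _gene_ids(config.n_genes)
    universe = frozenset(gene_ids)
    term_to_genes: dict[str, set[str]] = {}
    program_terms: set[str] = set()
    for p in programs:
        for j, t in enumerate(p.term_ids):
            program_terms.add(t)
            carried = {
                g
                for i, g in enumerate(p.gene_ids)
                if i % len(p.term_ids) == j or rng.random() < config.term_gene_frac
            }
            term_to_genes.setdefault(t, set()).update(carried)
    for t in ontology.terms:
        if t == ontology.root_id or t in program_terms:
            continue
        size = int(rng.integers(5, 51))
        picks = rng.choice(config.n_genes, size=min(size, config.n_genes), replace=False)
        term_to_genes[t] = {gene_ids[i] for i in picks}
    return AnnotationSet({t: frozenset(g) for t, g in term_to_genes.items()}, universe)


# ---------------------------------------------------------------------------
# behavior

@dataclass(frozen=True)
class BehaviorParams:
    """Normal means/sds for investigation times (s) and light:dark crossings.

    Defaults put control SI quotients near 2 (sociable) and stressed near
    0.5, with stressed mice crossing less in the light:dark box — the
    direction the defeat paradigm produces.
    """

    control_time_mouse: tuple[float, float] = (120.0, 20.0)
    control_time_empty: tuple[float, float] = (60.0, 10.0)
    stressed_time_mouse: tuple[float, float] = (40.0, 15.0)
    stressed_time_empty: tuple[float, float] = (80.0, 15.0)
    control_ld: tuple[float, float] = (30.0, 5.0)
    stressed_ld: tuple[float, float] = (12.0, 4.0)


def generate_behavior(
    n_control: int,
    n_stressed: int,
    params: BehaviorParams = BehaviorParams(),
    rng_seed: int = 0,
    control_label: str = "HC",
    stressed_label: str = "CSD",
) -> list[BehaviorRecord]:
    """Per-animal SI investigation times and light:dark crossing counts.

    Times are clipped at zero; crossing counts are rounded clipped normals.
    Negative requested means are rejected.
    """
    if n_control < 1 or n_stressed < 1:
        raise ValueError("need at least one animal per group")
    for mean, _ in (
        params.control_time_mouse,
        params.control_time_empty,
        params.stressed_time_mouse,
        params.stressed_time_empty,
    ):
        if mean < 0:
            raise ValueError("negative investigation times requested")
    rng = stage_rng(rng_seed, "behavior")
    records = []
    for group, n, label in (
        ("control", n_control, control_label),
        ("stressed", n_stressed, stressed_label),
    ):
        tm_mu, tm_sd = getattr(params, f"{group}_time_mouse")
        te_mu, te_sd = getattr(params, f"{group}_time_empty")
        ld_mu, ld_sd = getattr(params, f"{group}_ld")
        for i in range(n):
            tm = max(0.0, float(rng.normal(tm_mu, tm_sd)))
            te = max(0.0, float(rng.normal(te_mu, te_sd)))
            ld = max(0, int(round(rng.normal(ld_mu, ld_sd))))
            records.append(
                BehaviorRecord(
                    animal_id=f"{label}_{i + 1}",
                    condition=label,
                    time_mouse_cylinder=tm,
                    time_empty_cylinder=te,
                    ld_crosses=ld,
                )
            )
    return records


# ---------------------------------------------------------------------------
# images

def generate_images(
    vessel_area_frac: float,
    stain_area_frac: float,
    shape: tuple[int, int] = (512, 512),
    rng_seed: int = 0,
    overlap_frac: float = 1.0,
    background_mean: float = 10.0,
    background_sd: float = 1.0,
    foreground_level: float = 100.0,
) -> tuple[TwoChannelImage, np.ndarray, np.ndarray]:
    """Two-channel image painted from known masks, returned with its truth.

    Target pixel counts are ``round(frac * n_pixels)`` (banker's rounding via
    numpy). A fraction of the stain mask given by ``overlap_frac`` is placed
    inside the vessel mask, the rest outside. Foreground pixels sit at
    ``foreground_level`` with unit-SD jitter, far above the Normal
    background, so the median + 2 SD threshold recovers each mask exactly
    for foreground fractions well below one half.
    """
    for name, frac in (("vessel", vessel_area_frac), ("stain", stain_area_frac)):
        if not 0.0 <= frac < 1.0:
            raise ValueError(f"{name}_area_frac must be in [0, 1)")
    if not 0.0 <= overlap_frac <= 1.0:
        raise ValueError("overlap_frac must be in [0, 1]")
    rng = stage_rng(rng_seed, "images")
    n_px = int(np.prod(shape))
    k_vessel = int(np.rint(vessel_area_frac * n_px))
    k_stain = int(np.rint(stain_area_frac * n_px))
    k_inside = int(np.rint(overlap_frac * k_stain))
    k_outside = k_stain - k_inside
    if k_inside > k_vessel:
        raise ValueError(
            f"cannot place {k_inside} stain pixels inside a {k_vessel}-pixel vessel mask"
        )
    if k_outside > n_px - k_vessel:
        raise ValueError("stain mask does not fit outside the vessel mask")

    order = rng.permutation(n_px)
    vessel_idx = order[:k_vessel]
    inside = rng.choice(vessel_idx, size=k_inside, replace=False) if k_inside else np.empty(0, int)
    outside_pool = order[k_vessel:]
    outside = outside_pool[:k_outside]
    stain_idx = np.concatenate([inside, outside]).astype(int)

    vessel_mask = np.zeros(n_px, dtype=bool)
    vessel_mask[vessel_idx] = True
    stain_mask = np.zeros(n_px, dtype=bool)
    stain_mask[stain_idx] = True

    def paint(mask: np.ndarray) -> np.ndarray:
        img = rng.normal(background_mean, background_sd, n_px)
        img[mask] = foreground_level + rng.normal(0.0, 1.0, int(mask.sum()))
        return np.clip(img, 0.0, None).reshape(shape)

    image = TwoChannelImage(paint(vessel_mask), paint(stain_mask))
    return image, vessel_mask.reshape(shape), stain_mask.reshape(shape)


# ---------------------------------------------------------------------------
# bundle

def generate_bundle(config: SyntheticConfig) -> SyntheticBundle:
    """Full synthetic study: ontology, programs, annotations, expression,
    behavior, and the truth manifest tying them together."""
    ontology = generate_ontology(
        config.ontology_n_terms, config.ontology_max_depth, config.rng_seed
    )
    programs = generate_programs(config, ontology)
    annotations = generate_annotations(config, ontology, programs)

    rng = stage_rng(config.rng_seed, "downregulated")
    planted = {g for p in programs for g in p.gene_ids}
    free = [g for g in _gene_ids(config.n_genes) if g not in planted]
    n_down = int(config.frac_downregulated * config.n_genes)
    down = tuple(sorted(rng.choice(free, size=min(n_down, len(free)), replace=False)))

    expression = generate_expression(config, programs, down_gene_ids=down)
    n_stressed = sum(
        config.samples_per_condition[c] for c in config.treatment_conditions
    )
    behavior = generate_behavior(
        n_control=config.samples_per_condition[config.control_condition],
        n_stressed=n_stressed,
        rng_seed=config.rng_seed,
    )
    manifest = {
        p.program_id: {
            "active_conditions": list(p.active_conditions),
            "gene_ids": list(p.gene_ids),
            "term_ids": list(p.term_ids),
        }
        for p in programs
    }
    return SyntheticBundle(
        expression=expression,
        ontology=ontology,
        annotations=annotations,
        programs=programs,
        behavior=behavior,
        truth_manifest=manifest,
        down_gene_ids=down,
    )
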