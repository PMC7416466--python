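"""Per-gene statistics across conditions and per-condition DE gene lists.

The screening model is a one-way ANOVA per gene across all conditions with
Benjamini-Hochberg FDR over genes (q < 0.05 gate), followed by
per-condition contrasts against the control: log2 fold change as the
difference of group means on the log2 scale, and a t statistic (Welch by
default). Per-condition DE lists take genes passing both the q gate and a
linear-scale fold threshold (e.g. 1.3x or 1.5x vs control).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests


def anova_fdr(expr, welch_t: bool = True) -> pd.DataFrame:
    """One-way ANOVA per gene plus per-condition contrasts vs control.

    Returns a DataFrame indexed by gene with columns ``F``, ``p``, ``q``,
    ``zero_within_var`` (flag: all groups constant yet means differ, p
    reported as 0), and per treatment condition ``log2fc_<cond>`` and
    ``t_<cond>``. Genes constant across every sample get F=0, p=q=1.
    """
    conditions = expr.conditions
    if len(conditions) < 2:
        raise ValueError("need >= 2 conditions")
    groups = {c: expr.condition_matrix(c) for c in conditions}
    for c, g in groups.items():
        if g.shape[1] < 2:
            raise ValueError(f"condition {c!r} has < 2 samples")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sps.f_oneway(*(groups[c] for c in conditions), axis=1)
    f_stat = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)

    values = expr.values.to_numpy()
    all_equal = np.all(values == values[:, [0]], axis=1)
    within_var = np.stack([g.var(axis=1) for g in groups.values()])
    means = np.stack([g.mean(axis=1) for g in groups.values()])
    zero_within = (within_var.max(axis=0) == 0) & ~all_equal

    f_stat[all_equal] = 0.0
    p[all_equal] = 1.0
    f_stat[zero_within] = np.inf
    p[zero_within] = 0.0
    bad = np.isnan(p)
    f_stat[bad] = 0.0
    p[bad] = 1.0

    q = multipletests(p, method="fdr_bh")[1]

    out = pd.DataFrame(
        {"F": f_stat, "p": p, "q": q, "zero_within_var": zero_within},
        index=expr.values.index,
    )
    control = expr.control_condition
    ctrl = groups[control]
    for c in conditions:
        if c == control:
            continue
        out[f"log2fc_{c}"] = groups[c].mean(axis=1) - ctrl.mean(axis=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            t = sps.ttest_ind(groups[c], ctrl, axis=1, equal_var=not welch_t).statistic
        t = np.asarray(t, dtype=float)
        diff = groups[c].mean(axis=1) - ctrl.mean(axis=1)
        nan_t = np.isnan(t)
        t[nan_t & (diff == 0)] = 0.0
        t[nan_t & (diff > 0)] = np.inf
        t[nan_t & (diff < 0)] = -np.inf
        out[f"t_{c}"] = t
    out.attrs["conditions"] = list(conditions)
    out.attrs["control_condition"] = control
    return out


@dataclass
class ConditionGeneLists:
    """Per-condition DE gene sets plus their unique/shared partition."""

    threshold_fold: float
    direction: str                       # "up" or "down"
    q_max: float
    lists: dict[str, frozenset[str]]
    unique_by_condition: dict[str, frozenset[str]] = field(default_factory=dict)
    shared_all: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        union_others = {
            c: frozenset().union(
                *(g for c2, g in self.lists.items() if c2 != c), frozenset()
            )
            for c in self.lists
        }
        self.unique_by_condition = {
            c: frozenset(self.lists[c]) - union_others[c] for c in self.lists
        }
        if self.lists:
            self.shared_all = frozenset.intersection(
                *(frozenset(g) for g in self.lists.values())
            )
        else:
            self.shared_all = frozenset()

    @property
    def union(self) -> frozenset[str]:
        return frozenset().union(*self.lists.values(), frozenset())

    @property
    def conditions(self) -> list[str]:
        return list(self.lists)


def build_lists(
    stats: pd.DataFrame,
    threshold_fold: float,
    direction: str = "up",
    q_max: float = 0.05,
    require_fdr: bool = True,
) -> ConditionGeneLists:
    """Per-condition DE lists from the ANOVA table.

    A gene enters condition c's list when its linear-scale ratio vs control
    (2**log2fc) is >= threshold_fold (direction "up") or <= 1/threshold_fold
    ("down"), and — unless ``require_fdr`` is off — its ANOVA q is < q_max.
    """
    if threshold_fold <= 1:
        raise ValueError("threshold_fold must be > 1")
    if not 0 < q_max <= 1:
        raise ValueError("q_max must be in (0, 1]")
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    conds = [c.removeprefix("log2fc_") for c in stats.columns if c.startswith("log2fc_")]
    log2_thr = np.log2(threshold_fold)
    lists: dict[str, frozenset[str]] = {}
    for c in conds:
        fc = stats[f"log2fc_{c}"]
        hit = fc >= log2_thr if direction == "up" else fc <= -log2_thr
        if require_fdr:
            hit &= stats["q"] < q_max
        lists[c] = frozenset(stats.index[hit])
    return ConditionGeneLists(
        threshold_fold=threshold_fold, direction=direction, q_max=q_max, lists=lists
    )


@dataclass
class ClusterOrder:
    genes: list[str]
    samples: list[str]
    zero_variance_genes: list[str]


def cluster_order(expr, gene_subset) -> ClusterOrder:
    """Leaf orders for heatmap rendering via average-linkage clustering.

    Rows are z-scored per gene (mean 0, SD 1; zero-variance genes become
    all-zero rows and are flagged), then genes and samples are clustered
    with Euclidean distance and average linkage.
    """
    genes = [g for g in expr.gene_ids if g in set(gene_subset)]
    if not genes:
        raise ValueError("gene subset is empty")
    mat = expr.values.loc[genes].to_numpy(dtype=float)
    mu = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, keepdims=True)
    flat = sd[:, 0] == 0
    sd[flat] = 1.0
    z = (mat - mu) / sd
    z[flat] = 0.0

    def leaves(data: np.ndarray) -> list[int]:
        if data.shape[0] < 2:
            return list(range(data.shape[0]))
        link = hierarchy.linkage(data, method="average", metric="euclidean")
        return list(hierarchy.leaves_list(link))

    gene_order = [genes[i] for i in leaves(z)]
    sample_order = [expr.sample_ids[i] for i in leaves(z.T)]
    return ClusterOrder(
        genes=gene_order,
        samples=sample_order,
        zero_variance_genes=[g for g, f in zip(genes, flat) if f],
    )
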