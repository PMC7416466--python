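"""Compact gene set enrichment analysis (GSEA).

Genes are ranked by a Student t statistic between two conditions; each
gene set gets a running-sum enrichment score (the weighted
Kolmogorov-Smirnov-style statistic), a normalized score (NES) against a
gene-set permutation null, a permutation p-value with the add-one rule,
and an FDR q from the sign-split pooled-null scheme.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .containers import GeneSetCollection


@dataclass
class RankedGeneList:
    """Genes in descending metric order with a stable, documented tie rule:
    equal metrics order by ascending gene id."""

    gene_ids: list[str]
    metric: dict[str, float]

    @classmethod
    def from_metric(cls, metric: Mapping[str, float]) -> "RankedGeneList":
        order = sorted(metric, key=lambda g: (-metric[g], g))
        return cls(gene_ids=order, metric=dict(metric))

    def __post_init__(self) -> None:
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate genes in ranked list")

    def __len__(self) -> int:
        return len(self.gene_ids)


def rank_genes(expr, condition: str, pooled_t: bool = True) -> RankedGeneList:
    """Rank all genes by the t statistic of a condition vs the control.

    ``pooled_t`` selects the classic Student (pooled-variance) statistic;
    set False for Welch.
    """
    cond = expr.condition_matrix(condition)
    ctrl = expr.condition_matrix(expr.control_condition)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        t = sps.ttest_ind(cond, ctrl, axis=1, equal_var=pooled_t).statistic
    t = np.nan_to_num(np.asarray(t, dtype=float), nan=0.0)
    return RankedGeneList.from_metric(dict(zip(expr.gene_ids, t)))


@dataclass
class GseaRecord:
    set_id: str
    size: int
    es: float
    nes: float
    p_perm: float
    fdr_q: float
    n_perm: int = 1000
    weight_exponent: float = 1.0


def enrichment_score(
    ranked: RankedGeneList,
    gene_set: Iterable[str],
    weight_exponent: float = 1.0,
) -> tuple[float, np.ndarray]:
    """Running-sum enrichment score and its full profile.

    Walking the ranked list, a hit increments by |metric|^weight_exponent
    normalized over the set's hits (equal steps when all weights vanish),
    a miss decrements by 1/(N - m). The score is the running-sum value of
    maximal absolute deviation, sign retained; among equal absolute
    deviations the earliest position wins.
    """
    members = frozenset(gene_set) & set(ranked.gene_ids)
    if not members:
        raise ValueError("gene set has no overlap with the ranked list")
    n = len(ranked)
    m = len(members)
    if m == n:
        raise ValueError("gene set covers the entire ranked list; miss penalty undefined")
    hit = np.fromiter((g in members for g in ranked.gene_ids), dtype=bool, count=n)
    w = np.abs(np.fromiter((ranked.metric[g] for g in ranked.gene_ids), float, count=n)) ** weight_exponent
    w_hit = np.where(hit, w, 0.0)
    total = w_hit.sum()
    inc = w_hit / total if total > 0 else hit / m
    steps = np.where(hit, inc, -1.0 / (n - m))
    profile = np.cumsum(steps)
    i = int(np.argmax(np.abs(profile)))
    return float(profile[i]), profile


def _null_es(
    absw: np.ndarray, n_perm: int, m: int, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized null enrichment scores for random m-gene sets.

    For each permutation the profile's extremes occur at hit entry/exit
    points, so only those candidates are evaluated. ``absw`` is
    |metric|^weight in ranked order.
    """
    n = absw.size
    keys = rng.random((n_perm, n))
    pos = np.sort(np.argpartition(keys, m - 1, axis=1)[:, :m], axis=1)
    w = absw[pos]
    tot = w.sum(axis=1, keepdims=True)
    zero = tot[:, 0] == 0
    cum = np.where(zero[:, None], np.arange(1, m + 1) / m, np.cumsum(w, axis=1) / np.where(tot == 0, 1, tot))
    dec = 1.0 / (n - m)
    idx = np.arange(m)
    tops = cum - (pos - idx) * dec
    prev = np.concatenate([np.zeros((n_perm, 1)), cum[:, :-1]], axis=1)
    bottoms = prev - (pos - idx) * dec
    top = tops.max(axis=1)
    bottom = bottoms.min(axis=1)
    return np.where(top >= -bottom, top, bottom)


def permutation_stats(
    ranked: RankedGeneList,
    sets: GeneSetCollection,
    n_perm: int = 1000,
    weight_exponent: float = 1.0,
    rng_seed: int = 0,
) -> list[GseaRecord]:
    """Gene-set permutation test for every set in the collection.

    Null sets are random same-size draws from the ranked universe. The NES
    is es divided by the mean |null es| of matching sign; p is the add-one
    permutation fraction of nulls as or more extreme in absolute ES (so the
    smallest attainable p is 1/(n_perm + 1)). FDR q uses
    the sign-split pooled-null scheme: for a positive-NES set, the fraction
    of all positive null NES at least as large, over the fraction of
    observed positive NES at least as large (clipped to [0, 1], monotone
    from the most extreme score down); symmetrically for negative NES.
    Genes of a set absent from the ranked list are dropped (counted in the
    returned size); sets with no overlap raise, matching enrichment_score.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    n = len(ranked)
    absw = np.abs(
        np.fromiter((ranked.metric[g] for g in ranked.gene_ids), float, count=n)
    ) ** weight_exponent
    rng = np.random.default_rng(rng_seed)

    set_ids = list(sets)
    es_obs: dict[str, float] = {}
    sizes: dict[str, int] = {}
    nes_obs: dict[str, float] = {}
    null_nes_pos: list[np.ndarray] = []
    null_nes_neg: list[np.ndarray] = []
    p_perm: dict[str, float] = {}
    null_cache: dict[int, np.ndarray] = {}

    for sid in set_ids:
        members = sets.genes(sid) & frozenset(ranked.gene_ids)
        m = len(members)
        if m > n:
            raise ValueError(f"set {sid!r} larger than the ranked universe")
        es, _ = enrichment_score(ranked, members, weight_exponent)
        if m not in null_cache:
            null_cache[m] = _null_es(absw, n_perm, m, rng)
        null = null_cache[m]
        pos_mean = np.abs(null[null > 0]).mean() if (null > 0).any() else np.nan
        neg_mean = np.abs(null[null < 0]).mean() if (null < 0).any() else np.nan
        denom = pos_mean if es >= 0 else neg_mean
        if not np.isfinite(denom) or denom == 0:
            denom = np.abs(null).mean() or 1.0
        nes = es / denom
        with np.errstate(invalid="ignore"):
            null_nes = np.where(
                null >= 0,
                null / (pos_mean if np.isfinite(pos_mean) and pos_mean > 0 else denom),
                null / (neg_mean if np.isfinite(neg_mean) and neg_mean > 0 else denom),
            )
        null_nes_pos.append(null_nes[null_nes > 0])
        null_nes_neg.append(null_nes[null_nes < 0])
        # two-sided permutation p: nulls as or more extreme in |ES|
        p = (1 + int((np.abs(null) >= abs(es)).sum())) / (1 + n_perm)
        es_obs[sid], nes_obs[sid], p_perm[sid], sizes[sid] = es, nes, p, m

    pos_null = np.concatenate(null_nes_pos) if null_nes_pos else np.empty(0)
    neg_null = np.concatenate(null_nes_neg) if null_nes_neg else np.empty(0)
    obs_pos = np.array([v for v in nes_obs.values() if v >= 0])
    obs_neg = np.array([v for v in nes_obs.values() if v < 0])

    raw_q: dict[str, float] = {}
    for sid in set_ids:
        nes = nes_obs[sid]
        if nes >= 0:
            null_frac = (pos_null >= nes).mean() if pos_null.size else 0.0
            obs_frac = (obs_pos >= nes).mean() if obs_pos.size else 1.0
        else:
            null_frac = (neg_null <= nes).mean() if neg_null.size else 0.0
            obs_frac = (obs_neg <= nes).mean() if obs_neg.size else 1.0
        raw_q[sid] = min(1.0, null_frac / obs_frac) if obs_frac > 0 else 1.0

    # q-value: the smallest estimated FDR over NES thresholds that still
    # include the set, i.e. a cumulative minimum walking toward more
    # extreme scores; keeps q monotone non-increasing in |NES| per sign
    fdr_q = dict(raw_q)
    for sign_ids in (
        [s for s in set_ids if nes_obs[s] >= 0],
        [s for s in set_ids if nes_obs[s] < 0],
    ):
        best = np.inf
        for sid in sorted(sign_ids, key=lambda s: abs(nes_obs[s])):
            best = min(best, raw_q[sid])
            fdr_q[sid] = best

    return [
        GseaRecord(
            set_id=sid,
            size=sizes[sid],
            es=es_obs[sid],
            nes=nes_obs[sid],
            p_perm=p_perm[sid],
            fdr_q=fdr_q[sid],
            n_perm=n_perm,
            weight_exponent=weight_exponent,
        )
        for sid in set_ids
    ]


def records_to_frame(records: Sequence[GseaRecord]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "set": r.set_id,
                "size": r.size,
                "es": r.es,
                "nes": r.nes,
                "p": r.p_perm,
                "q": r.fdr_q,
            }
            for r in records
        ]
    )
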