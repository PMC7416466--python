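"""ANOVA screening, BH q-values, DE list construction, clustering orders."""
import numpy as np
import pandas as pd
import pytest

from enrichtraj.containers import ExpressionTable
from enrichtraj.de import anova_fdr, build_lists, cluster_order
from enrichtraj.synthetic import PlantedProgram, SyntheticConfig, generate_expression


def make_expr(values, design, control="HC"):
    genes = [f"g{i}" for i in range(len(values))]
    samples = list(design)
    return ExpressionTable(
        pd.DataFrame(values, index=genes, columns=samples), design, control
    )


def bh_oracle(pvals):
    """Independent Benjamini-Hochberg step-up implementation."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q


class TestAnova:
    def test_constant_gene_gets_f0_p1_q1(self):
        design = {"a1": "HC", "a2": "HC", "b1": "CSD", "b2": "CSD"}
        expr = make_expr([[3.0, 3.0, 3.0, 3.0], [1.0, 2.0, 5.0, 6.0]], design)
        stats = anova_fdr(expr)
        assert stats.loc["g0", "F"] == 0.0
        assert stats.loc["g0", "p"] == 1.0

    def test_zero_within_variance_unequal_means_flagged(self):
        design = {"a1": "HC", "a2": "HC", "b1": "CSD", "b2": "CSD"}
        expr = make_expr([[1.0, 1.0, 2.0, 2.0]], design)
        stats = anova_fdr(expr)
        assert stats.loc["g0", "p"] == 0.0
        assert bool(stats.loc["g0", "zero_within_var"])

    def test_q_values_match_independent_bh_step_up(self, bundle):
        stats = anova_fdr(bundle.expression)
        np.testing.assert_allclose(
            stats["q"].to_numpy(), bh_oracle(stats["p"].to_numpy()), atol=1e-12
        )

    def test_bh_hand_example_via_step_up(self):
        # 0.01/0.02/0.03/0.04 with m=4: q all equal 0.04 under step-up
        np.testing.assert_allclose(bh_oracle([0.01, 0.02, 0.03, 0.04]), 0.04)

    def test_planted_gene_recovered_with_accurate_fold_change(self):
        cfg = SyntheticConfig(
            n_genes=400,
            samples_per_condition={c: 5 for c in ("HC", "CSD1", "CSD7", "CSD14", "CSDrec")},
            noise_sd_log2=0.05,
            rng_seed=3,
        )
        prog = PlantedProgram(
            "p", ("GO:SYN00001",), tuple(f"g{i:05d}" for i in range(8)),
            ("CSD7",), 1.0,
        )
        expr = generate_expression(cfg, [prog])
        stats = anova_fdr(expr)
        # oracle: group means straight off the matrix
        hc = expr.condition_matrix("HC").mean(axis=1)
        c7 = expr.condition_matrix("CSD7").mean(axis=1)
        for g in prog.gene_ids:
            i = expr.gene_ids.index(g)
            assert stats.loc[g, "q"] < 0.05
            assert stats.loc[g, "log2fc_CSD7"] == pytest.approx(c7[i] - hc[i])
            assert abs(stats.loc[g, "log2fc_CSD7"] - 1.0) < 3 * 0.05

    def test_control_fold_change_is_zero_by_definition(self, bundle):
        stats = anova_fdr(bundle.expression)
        assert "log2fc_HC" not in stats.columns  # control carries no contrast


class TestBuildLists:
    def fake_stats(self, rows):
        """rows: gene -> (q, log2fc_A, log2fc_B)"""
        return pd.DataFrame(
            {
                "q": {g: v[0] for g, v in rows.items()},
                "log2fc_A": {g: v[1] for g, v in rows.items()},
                "log2fc_B": {g: v[2] for g, v in rows.items()},
            }
        )

    def test_unique_and_shared_partition(self):
        big = 2.0
        stats = self.fake_stats(
            {
                "g1": (0.01, big, 0.0),
                "g2": (0.01, big, big),
                "g3": (0.01, big, big),
                "g4": (0.01, 0.0, big),
            }
        )
        lists = build_lists(stats, threshold_fold=1.3)
        assert lists.lists["A"] == {"g1", "g2", "g3"}
        assert lists.unique_by_condition["A"] == {"g1"}
        assert lists.unique_by_condition["B"] == {"g4"}
        assert lists.shared_all == {"g2", "g3"}

    def test_linear_scale_threshold(self):
        # 2**0.40 = 1.3195 >= 1.3, so log2fc 0.40 passes a 1.3x filter
        stats = self.fake_stats({"g1": (0.01, 0.40, 0.0), "g2": (0.01, 0.37, 0.0)})
        lists = build_lists(stats, threshold_fold=1.3)
        assert lists.lists["A"] == {"g1"}

    def test_down_direction(self):
        stats = self.fake_stats({"g1": (0.01, -0.5, 0.1), "g2": (0.01, 0.5, 0.1)})
        lists = build_lists(stats, threshold_fold=1.3, direction="down")
        assert lists.lists["A"] == {"g1"}
        assert lists.lists["B"] == frozenset()

    def test_empty_stats_yield_empty_lists(self):
        lists = build_lists(
            pd.DataFrame(columns=["q", "log2fc_A"]), threshold_fold=1.3
        )
        assert lists.lists == {"A": frozenset()}

    def test_q_max_validated(self):
        stats = self.fake_stats({"g1": (0.01, 1.0, 1.0)})
        with pytest.raises(ValueError):
            build_lists(stats, threshold_fold=1.3, q_max=1.5)

    def test_order_independent(self):
        stats = self.fake_stats(
            {"g1": (0.01, 1.0, 0.0), "g2": (0.01, 0.0, 1.0), "g3": (0.2, 1.0, 1.0)}
        )
        shuffled = stats.iloc[::-1]
        a = build_lists(stats, 1.3)
        b = build_lists(shuffled, 1.3)
        assert a.lists == b.lists and a.shared_all == b.shared_all

    def test_fdr_gate_conjunction(self):
        stats = self.fake_stats({"g1": (0.2, 1.0, 1.0)})
        assert build_lists(stats, 1.3).lists["A"] == frozenset()
        assert build_lists(stats, 1.3, require_fdr=False).lists["A"] == {"g1"}


class TestClusterOrder:
    def test_identical_genes_adjacent(self):
        design = {f"s{i}": ("HC" if i < 2 else "CSD") for i in range(4)}
        vals = [
            [1.0, 2.0, 5.0, 6.0],
            [9.0, 1.0, 4.0, 2.0],
            [1.0, 2.0, 5.0, 6.0],
        ]
        expr = make_expr(vals, design)
        order = cluster_order(expr, ["g0", "g1", "g2"]).genes
        assert abs(order.index("g0") - order.index("g2")) == 1

    def test_sample_groups_contiguous(self):
        rng = np.random.default_rng(0)
        design = {f"s{i}": ("HC" if i < 4 else "CSD") for i in range(8)}
        base = rng.normal(0, 0.1, (10, 8))
        base[:, 4:] += 5.0  # strong two-group sample structure
        expr = make_expr(base, design)
        order = cluster_order(expr, expr.gene_ids).samples
        first_half = {f"s{i}" for i in range(4)}
        assert set(order[:4]) in ({f"s{i}" for i in range(4)}, set(order) - first_half)

    def test_zscore_rows_standardized(self):
        rng = np.random.default_rng(1)
        design = {f"s{i}": ("HC" if i < 3 else "CSD") for i in range(6)}
        expr = make_expr(rng.normal(6, 1, (5, 6)), design)
        mat = expr.values.to_numpy()
        z = (mat - mat.mean(1, keepdims=True)) / mat.std(1, keepdims=True)
        assert np.allclose(z.mean(1), 0, atol=1e-9)
        assert np.allclose(z.std(1), 1, atol=1e-9)
        cluster_order(expr, expr.gene_ids)  # runs without error on the same data

    def test_zero_variance_gene_flagged(self):
        design = {f"s{i}": ("HC" if i < 2 else "CSD") for i in range(4)}
        expr = make_expr([[2.0, 2.0, 2.0, 2.0], [1.0, 2.0, 3.0, 4.0]], design)
        res = cluster_order(expr, ["g0", "g1"])
        assert res.zero_variance_genes == ["g0"]

    def test_empty_subset_errors(self, tiny_expr):
        with pytest.raises(ValueError):
            cluster_order(tiny_expr, [])


class TestPowerProperty:
    def test_planted_recovery_rate(self):
        """Effect 1.0 log2, sd 0.2, n=5: nearly all planted genes reach the
        active condition's 1.3x list."""
        recovered = total = 0
        for seed in range(3):
            cfg = SyntheticConfig(
                n_genes=1000,
                samples_per_condition={
                    c: 5 for c in ("HC", "CSD1", "CSD7", "CSD14", "CSDrec")
                },
                noise_sd_log2=0.2,
                n_programs=4,
                genes_per_program=15,
                ontology_n_terms=100,
                program_level_range=(3, 6),
                rng_seed=seed,
            )
            from enrichtraj.synthetic import generate_bundle

            b = generate_bundle(cfg)
            stats = anova_fdr(b.expression)
            lists = build_lists(stats, 1.3)
            for p in b.programs:
                cond = p.active_conditions[0]
                total += len(p.gene_ids)
                recovered += len(set(p.gene_ids) & lists.lists[cond])
        assert recovered / total >= 0.99
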