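"""Tests for the three inference methods and their building blocks."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import cyclegrn as cg
from cyclegrn.containers import TWO_PI, CellClock, ExpressionMatrix
from cyclegrn.grn import (
    DDMatrix,
    default_mi_bins,
    genie3_total_variance_reduction,
    mutual_information_from_counts,
)


def _lognorm(df: pd.DataFrame) -> ExpressionMatrix:
    return ExpressionMatrix(df, layer="lognorm")


def _brute_force_mi(table: np.ndarray) -> float:
    """Independent double-sum over all cells of the joint table."""
    p = np.asarray(table, dtype=float) / np.asarray(table).sum()
    mi = 0.0
    for i in range(p.shape[0]):
        for j in range(p.shape[1]):
            if p[i, j] > 0:
                mi += p[i, j] * np.log(p[i, j] / (p[i].sum() * p[:, j].sum()))
    return mi


def _brute_force_ks(a: np.ndarray, b: np.ndarray) -> float:
    """Sup-norm ECDF distance by enumeration over all breakpoints."""
    pts = np.concatenate([a, b])
    return max(
        abs((a <= x).mean() - (b <= x).mean()) for x in pts
    )


class TestMutualInformation:
    def test_self_information_equals_log_bins(self):
        x = np.arange(400, dtype=float)
        assert cg.mutual_information(x, x, n_mi_bins=4) == pytest.approx(np.log(4), abs=1e-12)

    def test_independent_samples_near_zero(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=10_000), rng.normal(size=10_000)
        assert cg.mutual_information(x, y) <= 0.02

    def test_matches_brute_force_on_fixed_table(self):
        table = np.array([[4, 1, 0], [1, 4, 1], [0, 1, 4]])
        assert mutual_information_from_counts(table) == pytest.approx(
            _brute_force_mi(table), abs=1e-12
        )

    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            table = rng.integers(0, 20, size=(3, 3))
            if table.sum() == 0:
                continue
            assert mutual_information_from_counts(table) == pytest.approx(
                _brute_force_mi(table), abs=1e-12
            )

    def test_symmetry_exact(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=200), rng.lognormal(size=200)
        assert cg.mutual_information(x, y, 5) == cg.mutual_information(y, x, 5)

    def test_length_mismatch_is_error(self):
        with pytest.raises(ValueError, match="equal length"):
            cg.mutual_information(np.arange(10.0), np.arange(12.0), 4)

    def test_default_bin_rule(self):
        assert default_mi_bins(500) == 10
        assert default_mi_bins(20) == 4      # clipped low
        assert default_mi_bins(10_000) == 16  # clipped high


class TestAracne:
    def _chain(self, seed=0, n=5000):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        y = x + rng.normal(size=n)
        z = y + rng.normal(size=n)
        return _lognorm(pd.DataFrame([x, y, z], index=["X", "Y", "Z"]))

    def test_chain_removes_indirect_edge(self):
        expr = self._chain()
        # the DPI premise holds on the sample itself
        X = expr.values.to_numpy()
        mxz = cg.mutual_information(X[0], X[2])
        assert mxz < min(cg.mutual_information(X[0], X[1]), cg.mutual_information(X[1], X[2]))
        net = cg.aracne_infer(expr, dpi_tolerance=0.0)
        pairs = set(zip(net.edges["source"], net.edges["target"]))
        assert pairs == {("X", "Y"), ("Y", "Z")}

    def test_two_genes_no_triplets(self):
        rng = np.random.default_rng(3)
        expr = _lognorm(pd.DataFrame(rng.normal(size=(2, 200)), index=["a", "b"]))
        net = cg.aracne_infer(expr)
        assert net.n_edges == 1

    def test_tolerance_one_disables_pruning(self):
        expr = self._chain(n=1000)
        net = cg.aracne_infer(expr, dpi_tolerance=1.0)
        assert net.n_edges == 3

    def test_dpi_monotone_in_tolerance(self):
        expr = self._chain(seed=5, n=1000)
        kept = [
            set(map(tuple, cg.aracne_infer(expr, dpi_tolerance=tol).edges[["source", "target"]].to_numpy()))
            for tol in (0.0, 0.1, 0.3, 1.0)
        ]
        for lo, hi in zip(kept, kept[1:]):
            assert lo <= hi

    def test_undirected_output(self):
        net = cg.aracne_infer(self._chain(n=500))
        assert not net.directed
        assert (net.edges["source"] < net.edges["target"]).all()


@pytest.fixture(scope="module")
def copy_target_sim():
    rng = np.random.default_rng(0)
    n = 500
    noise = rng.normal(size=(20, n))
    reg = noise[7]
    target = reg.copy()
    pure_noise = rng.normal(size=n)
    rows = np.vstack([noise, target, pure_noise])
    names = [f"N{i:02d}" for i in range(20)] + ["COPY", "PURE"]
    return _lognorm(pd.DataFrame(rows, index=names))


class TestGenie3:
    def test_copied_regulator_has_largest_importance(self, copy_target_sim):
        net = cg.genie3_infer(copy_target_sim, seed=0)
        into_copy = net.edges[net.edges["target"] == "COPY"]
        assert into_copy.iloc[0]["source"] == "N07"

    def test_noise_target_importance_much_smaller(self, copy_target_sim):
        net = cg.genie3_infer(copy_target_sim, seed=0)
        copy_max = net.edges[net.edges["target"] == "COPY"]["weight"].max()
        noise_max = net.edges[net.edges["target"] == "PURE"]["weight"].max()
        assert copy_max >= 5 * noise_max

    def test_cell_permutation_invariance(self, copy_target_sim):
        net1 = cg.genie3_infer(copy_target_sim, seed=0)
        perm = np.random.default_rng(9).permutation(copy_target_sim.n_cells)
        shuffled = ExpressionMatrix(copy_target_sim.values.iloc[:, perm], layer="lognorm")
        net2 = cg.genie3_infer(shuffled, seed=0)
        pd.testing.assert_frame_equal(net1.edges, net2.edges)

    def test_importances_sum_to_variance_reduction(self):
        # per-target accounting: summed importances equal the mean
        # root-minus-leaf impurity reduction of the same ensemble
        from sklearn.ensemble import ExtraTreesRegressor

        rng = np.random.default_rng(2)
        X = rng.normal(size=(200, 6))
        y = X[:, 0] + 0.5 * X[:, 3] + 0.1 * rng.normal(size=200)
        est = ExtraTreesRegressor(n_estimators=50, max_features="sqrt", random_state=0)
        est.fit(X, y)
        imp = np.mean(
            [t.tree_.compute_feature_importances(normalize=False) for t in est.estimators_],
            axis=0,
        )
        assert np.all(imp >= 0)
        assert imp.sum() == pytest.approx(genie3_total_variance_reduction(est), abs=1e-9)

    def test_zero_variance_target_skipped(self):
        rng = np.random.default_rng(4)
        rows = np.vstack([rng.normal(size=(3, 50)), np.ones(50)])
        expr = _lognorm(pd.DataFrame(rows, index=list("abcd")))
        net = cg.genie3_infer(expr, seed=0)
        assert "d" not in set(net.edges["target"])


class TestKSStatistic:
    def test_identical_samples_zero(self):
        a = np.array([1.0, 2.0, 5.0])
        assert cg.ks_statistic(a, a.copy()) == 0.0

    def test_disjoint_supports_one(self):
        assert cg.ks_statistic(np.array([1.0, 2.0]), np.array([5.0, 6.0])) == 1.0

    def test_shifted_triplet(self):
        assert cg.ks_statistic(np.array([1.0, 2.0, 3.0]), np.array([2.0, 3.0, 4.0])) == pytest.approx(1 / 3)

    def test_empty_input_is_error(self):
        with pytest.raises(ValueError, match="non-empty"):
            cg.ks_statistic(np.array([]), np.array([1.0]))

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            a = rng.normal(size=rng.integers(1, 12))
            b = rng.choice([0.0, 0.5, 1.0], size=rng.integers(1, 12)) + rng.normal(scale=0.3)
            assert cg.ks_statistic(a, b) == pytest.approx(_brute_force_ks(a, b), abs=1e-12)

    @given(
        st.lists(st.floats(-5, 5, allow_nan=False), min_size=1, max_size=20),
        st.lists(st.floats(-5, 5, allow_nan=False), min_size=1, max_size=20),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_brute_force_property(self, a, b):
        a, b = np.asarray(a), np.asarray(b)
        assert cg.ks_statistic(a, b) == pytest.approx(_brute_force_ks(a, b), abs=1e-12)


def _binned_clock(bin_index, ordering_mode="tricycle"):
    n = len(bin_index)
    return CellClock(
        cell_ids=np.array([f"c{i}" for i in range(n)], dtype=object),
        real_time=np.full(n, 11.0),
        bin_index=np.asarray(bin_index, dtype=int),
        ordering_mode=ordering_mode,
    )


class TestDDMatrix:
    def test_constant_gene_gives_zero_column(self):
        rng = np.random.default_rng(0)
        vals = np.vstack([np.ones(60), rng.normal(size=60)])
        expr = _lognorm(pd.DataFrame(vals, index=["const", "var"]))
        clock = _binned_clock(np.repeat(np.arange(3), 20))
        dd = cg.distributional_distance_matrix(expr, clock)
        assert np.all(dd.values[:, 0] == 0)

    def test_row_count_is_bins_minus_one(self):
        rng = np.random.default_rng(1)
        expr = _lognorm(pd.DataFrame(rng.normal(size=(4, 100)), index=list("abcd")))
        clock = _binned_clock(np.repeat(np.arange(5), 20))
        dd = cg.distributional_distance_matrix(expr, clock)
        assert dd.values.shape == (4, 4)

    def test_alternating_disjoint_ranges_give_ones(self):
        bins = np.repeat(np.arange(4), 10)
        g = np.where(bins % 2 == 0, 0.0, 10.0) + np.tile(np.linspace(0, 0.1, 10), 4)
        expr = _lognorm(pd.DataFrame([g], index=["flip"]))
        dd = cg.distributional_distance_matrix(expr, _binned_clock(bins))
        assert np.all(dd.values[:, 0] == 1.0)

    def test_empty_bin_is_error(self):
        rng = np.random.default_rng(2)
        expr = _lognorm(pd.DataFrame(rng.normal(size=(2, 30)), index=["a", "b"]))
        bins = np.repeat([0, 1, 3], 10)  # bin 2 missing
        with pytest.raises(ValueError, match=r"empty temporal bin.*\[2\]"):
            cg.distributional_distance_matrix(expr, _binned_clock(bins))

    def test_real_mode_uses_hour_gaps(self):
        rng = np.random.default_rng(3)
        n = 80
        times = np.repeat([11.0, 12.0, 14.0, 16.0], 20)
        clock = CellClock(
            cell_ids=np.array([f"c{i}" for i in range(n)], dtype=object),
            real_time=times,
            bin_index=np.repeat(np.arange(4), 20),
            ordering_mode="real",
        )
        expr = _lognorm(pd.DataFrame(rng.normal(size=(2, n)), index=["a", "b"]))
        dd = cg.distributional_distance_matrix(expr, clock)
        assert dd.deltas.tolist() == [1.0, 2.0, 2.0]


class TestSincerities:
    def test_planted_one_bin_shift_is_top_incoming_edge(self):
        # the regulator's per-bin location shifts at bin b; the target's
        # distribution shifts one bin later: classic lag-1 Granger signal
        rng = np.random.default_rng(0)
        B, per = 8, 60
        bins = np.repeat(np.arange(B), per)
        reg_level = np.array([0, 0, 3, 3, 0, 0, 3, 3], dtype=float)
        tgt_level = np.roll(reg_level, 1)
        reg = reg_level[bins] + 0.3 * rng.normal(size=B * per)
        tgt = tgt_level[bins] + 0.3 * rng.normal(size=B * per)
        others = 0.3 * rng.normal(size=(3, B * per))
        expr = _lognorm(
            pd.DataFrame(np.vstack([reg, tgt, others]), index=["REG", "TGT", "n1", "n2", "n3"])
        )
        net = cg.sincerities_infer(expr, _binned_clock(bins))
        into_tgt = net.edges[net.edges["target"] == "TGT"]
        assert into_tgt.iloc[0]["source"] == "REG"

    def test_all_constant_genes_give_empty_network(self):
        vals = np.tile(np.array([[1.0], [2.0]]), (1, 50))
        expr = _lognorm(pd.DataFrame(vals, index=["a", "b"]))
        net = cg.sincerities_infer(expr, _binned_clock(np.repeat(np.arange(5), 10)))
        assert net.n_edges == 0

    def test_too_few_bins_is_error(self):
        rng = np.random.default_rng(1)
        expr = _lognorm(pd.DataFrame(rng.normal(size=(3, 40)), index=list("abc")))
        with pytest.raises(ValueError, match="insufficient temporal bins"):
            cg.sincerities_infer(expr, _binned_clock(np.repeat(np.arange(4), 10)))

    def test_bin_relabel_invariance(self):
        # only the order of bins matters, not their labels' spacing
        rng = np.random.default_rng(2)
        expr = _lognorm(pd.DataFrame(rng.normal(size=(4, 120)), index=list("abcd")))
        bins = np.repeat(np.arange(6), 20)
        net1 = cg.sincerities_infer(expr, _binned_clock(bins))
        # relabel bins 0..5 -> 0,1,2,3,4,5 shuffled cells, same partition order
        perm = rng.permutation(120)
        expr2 = ExpressionMatrix(expr.values.iloc[:, perm], layer="lognorm")
        net2 = cg.sincerities_infer(expr2, _binned_clock(bins[perm]))
        pd.testing.assert_frame_equal(net1.edges, net2.edges)

    def test_activating_edge_recovers_positive_sign(self):
        # an activating edge where the target's level is a monotone
        # increasing function of the regulator's realized expression:
        # the partial-correlation sign stage should call it positive
        ok = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 800
            theta = rng.uniform(0, TWO_PI, n)
            mu_reg = np.exp(1.5 + 2.0 * np.cos(theta))
            reg = rng.negative_binomial(20, 20 / (20 + mu_reg)).astype(float)
            x_reg = np.log1p(reg)
            mu_tgt = np.exp(0.5 + 0.8 * x_reg)  # activation, monotone in reg
            tgt = rng.negative_binomial(20, 20 / (20 + mu_tgt)).astype(float)
            noise = rng.negative_binomial(20, 20 / (20 + np.exp(1.5)), size=(3, n)).astype(float)
            rows = np.vstack([x_reg, np.log1p(tgt), np.log1p(noise)])
            expr = _lognorm(pd.DataFrame(rows, index=["REG", "TGT", "n1", "n2", "n3"]))
            bins = cg.quantile_bin(theta, 8)
            net = cg.sincerities_infer(expr, _binned_clock(bins))
            row = net.edges[(net.edges["source"] == "REG") & (net.edges["target"] == "TGT")]
            if len(row) and row.iloc[0]["sign"] == 1:
                ok += 1
        assert ok >= 8
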