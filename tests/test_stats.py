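import itertools
import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps
from hypothesis import given, settings, strategies as st

from neurolipidomics.stats import (
    bh_fdr,
    compare_regions,
    ddct_expression,
    mannwhitney_exact,
    select_for_annotation,
    stage_comparison,
    stage_trend,
)


class TestMannWhitney:
    def test_identical_multisets_p_one(self):
        res = compare_regions([1.0, 2, 3, 4], [1.0, 2, 3, 4])
        assert res.p == pytest.approx(1.0)

    def test_complete_separation_4v6_equals_enumeration(self):
        res = compare_regions([1.0, 2, 3, 4], [10.0, 11, 12, 13, 14, 15])
        assert res.statistic == 0.0
        assert res.p == pytest.approx(2 / math.comb(10, 4))

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_exact_path_matches_scipy_on_tie_free_data(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=4)
        y = rng.normal(size=5)
        _, p = mannwhitney_exact(x, y)
        assert p == pytest.approx(
            sps.mannwhitneyu(x, y, method="exact").pvalue, rel=1e-12
        )

    def test_ties_match_independent_midrank_enumeration(self):
        # independent oracle written here, structured differently: iterate
        # over value assignments rather than rank index combinations.
        x = np.array([1.0, 2.0, 2.0])
        y = np.array([2.0, 3.0, 4.0])
        pooled = np.concatenate([x, y])
        ranks = sps.rankdata(pooled)
        n1 = len(x)
        mu = n1 * len(y) / 2
        u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
        count = total = 0
        for idx in itertools.combinations(range(len(pooled)), n1):
            u = sum(ranks[i] for i in idx) - n1 * (n1 + 1) / 2
            total += 1
            if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
                count += 1
        _, p = mannwhitney_exact(x, y)
        assert p == pytest.approx(count / total)

    def test_asymptotic_used_above_switch_point(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=10), rng.normal(size=10)
        res = compare_regions(x, y)
        assert "approximation" in res.test_name

    def test_too_small_groups_error(self):
        with pytest.raises(ValueError):
            compare_regions([1.0], [2.0, 3.0])


class TestAnnotationScreen:
    def test_strict_boundary(self):
        from neurolipidomics.stats import TestResult

        res = [
            TestResult("a", 0, 0.009, "t", (2, 2)),
            TestResult("b", 0, 0.01, "t", (2, 2)),
            TestResult("c", 0, 0.011, "t", (2, 2)),
        ]
        assert select_for_annotation(res, 0.01) == ["a"]

    def test_empty_input(self):
        assert select_for_annotation([], 0.01) == []

    def test_counting_oracle_on_simulated_p_vector(self, rng):
        from neurolipidomics.stats import TestResult

        ps = rng.random(500)
        res = [TestResult(str(i), 0, p, "t", (2, 2)) for i, p in enumerate(ps)]
        assert len(select_for_annotation(res, 0.05)) == int((ps < 0.05).sum())


class TestKruskalWallisDunn:
    def test_identical_groups_h_near_zero(self):
        g = {"a": [1, 2, 3.0], "b": [1, 2, 3.0], "c": [1, 2, 3.0]}
        res, _ = stage_comparison(g)
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p > 0.9

    def test_hand_rank_formula_oracle(self):
        # groups {1,2},{3,4},{5,6}: H = 12/(N(N+1)) ΣR²/n − 3(N+1)
        res, _ = stage_comparison({"a": [1, 2.0], "b": [3, 4.0], "c": [5, 6.0]})
        n = 6
        r_sums = [3.0, 7.0, 11.0]
        h_oracle = 12.0 / (n * (n + 1)) * sum(r * r / 2 for r in r_sums) - 3 * (n + 1)
        assert res.statistic == pytest.approx(h_oracle, rel=1e-12)

    def test_two_groups_h_equals_z_squared(self, rng):
        x = rng.normal(size=8)
        y = rng.normal(size=9)
        res, _ = stage_comparison({"a": x, "b": y})
        z = sps.norm.isf(
            sps.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic", use_continuity=False
            ).pvalue
            / 2
        )
        assert res.statistic == pytest.approx(z**2, rel=1e-6)

    def test_dunn_z_for_known_configuration(self):
        _, posthoc = stage_comparison({"a": [1, 2.0], "b": [3, 4.0], "c": [5, 6.0]})
        by_pair = {p.pair: p for p in posthoc}
        # mean ranks 1.5, 3.5, 5.5; var term N(N+1)/12 = 3.5 (no ties)
        se = math.sqrt(3.5 * (0.5 + 0.5))
        assert by_pair[("a", "c")].z == pytest.approx((1.5 - 5.5) / se)
        assert by_pair[("a", "b")].p == pytest.approx(
            2 * sps.norm.sf(abs((1.5 - 3.5) / se))
        )

    def test_posthoc_bonferroni_flag(self):
        _, raw = stage_comparison({"a": [1, 2.0], "b": [3, 4.0], "c": [5, 6.0]})
        _, adj = stage_comparison(
            {"a": [1, 2.0], "b": [3, 4.0], "c": [5, 6.0]}, adjust_posthoc=True
        )
        for r, a in zip(raw, adj):
            assert a.p == pytest.approx(min(1.0, r.p * 3))

    def test_fewer_than_two_groups_error(self):
        with pytest.raises(ValueError):
            stage_comparison({"a": [1, 2.0]})


class TestStageTrend:
    def test_strictly_increasing_untied_ranks(self):
        res = stage_trend([1, 2, 3, 4, 5, 6.0], [0, 1, 2, 3, 4, 5])
        assert res.rho == pytest.approx(1.0)
        assert res.p == pytest.approx(0.0, abs=1e-12)

    def test_matches_pearson_on_midranks_oracle(self, rng):
        v = rng.normal(size=12)
        s = np.repeat([0, 1, 2, 3], 3)
        res = stage_trend(v, s)
        rho_oracle = np.corrcoef(sps.rankdata(v), sps.rankdata(s))[0, 1]
        assert res.rho == pytest.approx(rho_oracle, rel=1e-12)

    def test_monotone_coding_invariance(self, rng):
        v = rng.normal(size=16)
        s = np.repeat([0, 1, 2, 3], 4)
        res1 = stage_trend(v, s)
        res2 = stage_trend(v, np.array([10, 20, 35, 99])[s])
        assert res1.rho == pytest.approx(res2.rho)
        assert res1.p == pytest.approx(res2.p)

    def test_permutation_p_agrees_with_enumeration(self):
        v = np.array([3.0, 1.0, 4.0, 1.5, 5.0, 9.0])
        s = np.array([0, 0, 1, 1, 2, 2])
        res = stage_trend(v, s, method="permutation")
        rx, rs = sps.rankdata(v), sps.rankdata(s)
        rho_obs = np.corrcoef(rx, rs)[0, 1]
        count = total = 0
        for perm in itertools.permutations(rx):
            total += 1
            if abs(np.corrcoef(perm, rs)[0, 1]) >= abs(rho_obs) - 1e-12:
                count += 1
        assert res.p == pytest.approx(count / total)

    def test_constant_values_undefined(self):
        res = stage_trend([2.0] * 8, [0, 0, 1, 1, 2, 2, 3, 3])
        assert math.isnan(res.rho) and math.isnan(res.p)

    def test_null_simulation_rho_centred_and_p_uniform(self):
        rng = np.random.default_rng(42)
        s = np.repeat([0, 1, 2, 3], 6)
        rhos, ps = [], []
        for _ in range(1000):
            res = stage_trend(rng.normal(size=24), s)
            rhos.append(res.rho)
            ps.append(res.p)
        assert abs(np.mean(rhos)) < 0.05
        assert sps.kstest(ps, "uniform").pvalue > 0.01


class TestBhFdr:
    def test_single_p(self):
        assert bh_fdr([0.01])[0] == pytest.approx(0.01)

    def test_subset_against_larger_family(self):
        q = bh_fdr([0.011] * 17, m=51)
        assert np.allclose(q, 0.011 * 51 / 17)

    def test_matches_step_up_oracle(self, rng):
        p = rng.random(200)
        m = 300
        q = bh_fdr(p, m=m)
        # explicit step-up: sort, scale, cumulative minimum from the top
        order = np.argsort(p)
        scaled = p[order] * m / np.arange(1, len(p) + 1)
        oracle_sorted = [min(np.min(scaled[i:]), 1.0) for i in range(len(p))]
        oracle = np.empty_like(q)
        oracle[order] = oracle_sorted
        np.testing.assert_allclose(q, oracle, rtol=1e-12)

    def test_monotone_and_order_invariant(self, rng):
        p = rng.random(50)
        q = bh_fdr(p)
        assert np.all((q >= p - 1e-15) & (q <= 1.0))
        idx = np.argsort(p)
        assert np.all(np.diff(q[idx]) >= -1e-15)
        perm = rng.permutation(50)
        np.testing.assert_allclose(bh_fdr(p[perm]), q[perm])

    def test_family_smaller_than_list_error(self):
        with pytest.raises(ValueError):
            bh_fdr([0.1, 0.2], m=1)


class TestDdct:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["sample_id", "gene", "CT", "group"])

    def test_target_equals_reference_gives_fold_one(self):
        rows = []
        for i, grp in enumerate(["MA", "MA", "AD", "AD"]):
            rows += [(f"s{i}", "GUSB", 25.0, grp), (f"s{i}", "ACOX1", 25.0, grp)]
        out = ddct_expression(self._table(rows), "GUSB", "MA")
        assert all(r.fold_change == pytest.approx(1.0) for r in out)

    def test_minus_one_ddct_doubles_expression(self):
        rows = [
            ("c1", "GUSB", 25.0, "MA"),
            ("c1", "ACOX1", 27.0, "MA"),
            ("t1", "GUSB", 25.0, "AD"),
            ("t1", "ACOX1", 26.0, "AD"),
        ]
        out = {r.sample_id: r for r in ddct_expression(self._table(rows), "GUSB", "MA")}
        assert out["t1"].delta_delta_ct == pytest.approx(-1.0)
        assert out["t1"].fold_change == pytest.approx(2.0)

    def test_random_table_matches_spreadsheet_oracle(self, rng):
        samples = [f"s{i}" for i in range(8)]
        groups = ["MA"] * 4 + ["AD"] * 4
        ct_ref = rng.uniform(20, 30, 8)
        ct_tgt = rng.uniform(20, 30, 8)
        rows = []
        for s, g, cr, ctg in zip(samples, groups, ct_ref, ct_tgt):
            rows += [(s, "GUSB", cr, g), (s, "TGT", ctg, g)]
        out = {r.sample_id: r for r in ddct_expression(self._table(rows), "GUSB", "MA")}
        dct = ct_tgt - ct_ref
        calib = dct[:4].mean()
        for i, s in enumerate(samples):
            assert out[s].delta_ct == pytest.approx(dct[i])
            assert out[s].fold_change == pytest.approx(2.0 ** -(dct[i] - calib))

    def test_calibrator_mean_ddct_zero(self, rng):
        rows = []
        for i in range(6):
            g = "MA" if i < 3 else "AD"
            rows += [
                (f"s{i}", "GUSB", float(rng.uniform(20, 30)), g),
                (f"s{i}", "TGT", float(rng.uniform(20, 30)), g),
            ]
        out = ddct_expression(self._table(rows), "GUSB", "MA")
        calib = [r.delta_delta_ct for r in out if r.group == "MA"]
        assert np.mean(calib) == pytest.approx(0.0, abs=1e-12)

    def test_missing_reference_drops_sample(self):
        rows = [
            ("c1", "GUSB", 25.0, "MA"),
            ("c1", "TGT", 26.0, "MA"),
            ("t1", "TGT", 24.0, "AD"),
        ]
        out = ddct_expression(self._table(rows), "GUSB", "MA")
        assert {r.sample_id for r in out} == {"c1"}


@given(seed=st.integers(0, 500))
@settings(max_examples=20, deadline=None)
def test_exact_mw_property_small_n(seed):
    """Exact path equals scipy's exact distribution for random tie-free data."""
    rng = np.random.default_rng(seed)
    n1, n2 = int(rng.integers(2, 5)), int(rng.integers(2, 6))
    x, y = rng.normal(size=n1), rng.normal(size=n2)
    _, p = mannwhitney_exact(x, y)
    assert p == pytest.approx(sps.mannwhitneyu(x, y, method="exact").pvalue, rel=1e-9)
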