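import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lncscape.diffexp import (
    call_degs,
    ddct_rq,
    deg_tally,
    estimate_dispersion,
    nb_exact_test,
    size_factors,
    venn_partition,
)
from lncscape.expression_qc import ExpressionMatrix
from lncscape.synthetic_data import simulate_counts


def counts_matrix(values, groups):
    values = np.asarray(values)
    samples = [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(
        pd.DataFrame(values, index=[f"g{i}" for i in range(values.shape[0])],
                     columns=samples),
        pd.Series(groups, index=samples),
        mode="counts",
    )


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        m = counts_matrix([[10, 10], [40, 40]], ["a", "b"])
        assert np.allclose(size_factors(m).factors, 1.0)

    def test_hand_toy_example(self):
        """[[10,20],[30,60]] yields (1/sqrt(2), sqrt(2))."""
        m = counts_matrix([[10, 20], [30, 60]], ["a", "b"])
        s = size_factors(m).factors
        assert s["s0"] == pytest.approx(1 / np.sqrt(2))
        assert s["s1"] == pytest.approx(np.sqrt(2))

    def test_scale_equivariance(self, rng):
        vals = rng.integers(5, 500, size=(50, 4))
        m = counts_matrix(vals, ["a", "a", "b", "b"])
        s0 = size_factors(m).factors
        scaled = vals.copy()
        scaled[:, 2] *= 3
        s1 = size_factors(counts_matrix(scaled, ["a", "a", "b", "b"])).factors
        # scaling one sample's counts by c scales its factor by c; the other
        # factors shift only through the shared geometric-mean reference
        assert s1["s2"] / s0["s2"] == pytest.approx(3 * (s1["s0"] / s0["s0"]))

    def test_no_reference_gene_is_advisory_error(self):
        m = counts_matrix([[0, 5], [3, 0]], ["a", "b"])
        with pytest.raises(ValueError, match="pseudo_reference"):
            size_factors(m)
        s = size_factors(m, pseudo_reference=True).factors
        assert (s > 0).all()


class TestDispersion:
    def test_poisson_counts_concentrate_near_zero(self):
        counts, _, _ = simulate_counts(
            n_genes=2000, n_lnc=0, de_fraction=0, dispersion=0.0,
            mean_log2_expr=np.log2(100), log2_expr_sd=0.0, seed=4,
        )
        disp = estimate_dispersion(counts, size_factors(counts))
        assert disp.final.median() < 0.05

    def test_nb_dispersion_recovered(self):
        counts, _, _ = simulate_counts(
            n_genes=2000, n_lnc=0, de_fraction=0, dispersion=0.2,
            mean_log2_expr=np.log2(100), log2_expr_sd=0.0, seed=5,
        )
        disp = estimate_dispersion(counts, size_factors(counts))
        assert 0.1 <= disp.final.median() <= 0.4

    def test_constant_gene_falls_back_to_trend(self, rng):
        vals = rng.poisson(100, size=(200, 6))
        vals[0] = 50  # zero within-group variance
        m = counts_matrix(vals, ["a"] * 3 + ["b"] * 3)
        disp = estimate_dispersion(m, size_factors(m))
        assert disp.raw.iloc[0] <= 0
        assert disp.final.iloc[0] == pytest.approx(disp.fitted.iloc[0])


def brute_force_exact_p(ka, kb, sa, sb, alpha):
    """Joint-pmf enumeration over all partitions of the conditioned total."""
    ks = int(ka.sum() + kb.sum())
    q0 = ks / (sa.sum() + sb.sum())
    mu_a, mu_b = q0 * sa.sum(), q0 * sb.sum()
    var_a = mu_a + alpha * q0**2 * (sa**2).sum()
    var_b = mu_b + alpha * q0**2 * (sb**2).sum()

    def pmf(x, mu, var):
        if var <= mu * (1 + 1e-8):
            return stats.poisson.pmf(x, mu)
        size = mu**2 / (var - mu)
        return stats.nbinom.pmf(x, size, size / (size + mu))

    probs = [pmf(a, mu_a, var_a) * pmf(ks - a, mu_b, var_b) for a in range(ks + 1)]
    obs = pmf(ka.sum(), mu_a, var_a) * pmf(kb.sum(), mu_b, var_b)
    total = sum(probs)
    tail = sum(p for p in probs if p <= obs * (1 + 1e-7))
    return min(1.0, tail / total)


class TestExactTest:
    def test_balanced_counts_give_p_one(self):
        p = nb_exact_test(
            np.array([10, 10, 10]), np.array([10, 10, 10]),
            np.ones(3), np.ones(3), 0.1,
        )
        assert p == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(25):
            ka = rng.integers(0, 9, size=3)
            kb = rng.integers(0, 9, size=3)
            if ka.sum() + kb.sum() == 0:
                continue
            sa = rng.uniform(0.7, 1.3, 3)
            sb = rng.uniform(0.7, 1.3, 3)
            alpha = rng.uniform(0.0, 0.4)
            p = nb_exact_test(ka, kb, sa, sb, alpha)
            assert p == pytest.approx(brute_force_exact_p(ka, kb, sa, sb, alpha), rel=1e-9)

    def test_symmetric_under_condition_swap(self, rng):
        for _ in range(10):
            ka = rng.integers(0, 50, size=3)
            kb = rng.integers(0, 50, size=3)
            sa = rng.uniform(0.7, 1.3, 3)
            sb = rng.uniform(0.7, 1.3, 3)
            p1 = nb_exact_test(ka, kb, sa, sb, 0.15)
            p2 = nb_exact_test(kb, ka, sb, sa, 0.15)
            assert p1 == pytest.approx(p2, rel=1e-9)

    def test_zero_total_gives_p_one(self):
        assert nb_exact_test(np.zeros(3), np.zeros(3), np.ones(3), np.ones(3), 0.1) == 1.0


class TestCallDegs:
    def test_planted_truth_recovery(self):
        counts, fpkm, truth = simulate_counts(
            n_genes=500, n_lnc=50, de_fraction=0.1, fc=4.0, dispersion=0.1,
            mean_log2_expr=np.log2(100), log2_expr_sd=0.0,
            temporal_profiles=False, seed=0,
        )
        table = call_degs(counts, fpkm, ("1M", "control"))
        called = set(table.loc[table["deg"], "gene_id"])
        tt = truth.de_genes.set_index("gene_id")
        true_de = set(tt.index[tt["de_1M"]])
        recall = len(called & true_de) / len(true_de)
        obs_fdr = len(called - true_de) / max(len(called), 1)
        assert recall >= 0.6
        assert obs_fdr <= 0.05

    def test_null_simulation_yields_no_calls(self):
        counts, fpkm, _ = simulate_counts(
            n_genes=500, n_lnc=0, de_fraction=0.0, dispersion=0.1,
            mean_log2_expr=np.log2(100), log2_expr_sd=0.0, seed=1,
        )
        table = call_degs(counts, fpkm, ("3M", "control"))
        assert int(table["deg"].sum()) <= 1

    def test_fpkm_criterion_excludes_low_expression(self):
        counts, fpkm, _ = simulate_counts(
            n_genes=200, n_lnc=0, de_fraction=0.2, fc=6.0, dispersion=0.05,
            mean_log2_expr=np.log2(200), log2_expr_sd=0.0,
            temporal_profiles=False, seed=2,
        )
        # force every gene below the expressed threshold
        fpkm_low = ExpressionMatrix(
            fpkm.values * 0 + 0.5, fpkm.groups, fpkm.batches, "fpkm"
        )
        table = call_degs(counts, fpkm_low, ("1M", "control"))
        assert int(table["deg"].sum()) == 0

    def test_direction_and_tally(self):
        counts, fpkm, truth = simulate_counts(
            n_genes=400, n_lnc=40, de_fraction=0.15, fc=5.0, dispersion=0.05,
            mean_log2_expr=np.log2(150), log2_expr_sd=0.0,
            temporal_profiles=False, seed=3,
        )
        biotypes = truth.de_genes.set_index("gene_id")["biotype"]
        table = call_degs(counts, fpkm, ("1M", "control"), biotypes=biotypes)
        sub = table[table["deg"]]
        assert ((sub["fc"] > 1) == (sub["direction"] == "up")).all()
        tally = deg_tally(table)
        assert tally["total"].sum() == len(sub)
        assert (tally["up"] + tally["down"] == tally["total"]).all()

    def test_bh_q_at_least_p(self):
        counts, fpkm, _ = simulate_counts(
            n_genes=300, n_lnc=0, de_fraction=0.1, dispersion=0.1,
            mean_log2_expr=np.log2(100), log2_expr_sd=0.0, seed=6,
        )
        table = call_degs(counts, fpkm, ("6M", "control")).dropna(subset=["p"])
        assert (table["q"] >= table["p"] - 1e-12).all()
        assert table["q"].between(0, 1).all()


class TestVenn:
    def test_disjoint_sets(self):
        res = venn_partition({"x": {"a"}, "y": {"b"}, "z": {"c"}})
        assert res[frozenset({"x"})] == 1
        assert res[frozenset({"x", "y", "z"})] == 0

    def test_identical_sets_only_triple_region(self):
        s = {"a", "b"}
        res = venn_partition({"x": set(s), "y": set(s), "z": set(s)})
        assert res[frozenset({"x", "y", "z"})] == 2
        assert res[frozenset({"x"})] == 0

    def test_matches_membership_tabulation(self, rng):
        universe = [f"g{i}" for i in range(60)]
        sets = {
            n: set(rng.choice(universe, size=rng.integers(5, 40), replace=False))
            for n in ("p", "q", "r")
        }
        res = venn_partition(sets)
        for combo_size in (1, 2, 3):
            for combo in itertools.combinations(sorted(sets), combo_size):
                expected = sum(
                    1
                    for g in universe
                    if all(g in sets[n] for n in combo)
                    and not any(g in sets[n] for n in sets if n not in combo)
                )
                assert res[frozenset(combo)] == expected
        assert sum(res.values()) == len(set().union(*sets.values()))


class TestDdct:
    @staticmethod
    def table(ddcts):
        rows = []
        for i in range(3):
            rows.append({"sample": f"c{i}", "group": "control",
                         "ct_target": 25.0, "ct_reference": 20.0})
        for g, d in ddcts.items():
            for i in range(3):
                rows.append({"sample": f"{g}{i}", "group": g,
                             "ct_target": 25.0 + d, "ct_reference": 20.0})
        return pd.DataFrame(rows)

    def test_zero_ddct_gives_rq_one(self):
        res = ddct_rq(self.table({"1M": 0.0}), "control")
        assert res.loc[res["group"] == "1M", "rq_mean"].iloc[0] == pytest.approx(1.0)

    def test_minus_one_ddct_doubles(self):
        res = ddct_rq(self.table({"1M": -1.0}), "control")
        assert res.loc[res["group"] == "1M", "rq_mean"].iloc[0] == pytest.approx(2.0)

    def test_tenfold_down(self):
        res = ddct_rq(self.table({"1M": 3.3219}), "control")
        assert res.loc[res["group"] == "1M", "rq_mean"].iloc[0] == pytest.approx(0.1, rel=1e-3)

    def test_missing_reference_dropped(self, caplog):
        t = self.table({"1M": 1.0})
        t.loc[3, "ct_reference"] = np.nan
        res = ddct_rq(t, "control")
        assert len(res) == 2
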