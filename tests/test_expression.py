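import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from hybrase import (
    CountMatrix,
    DispersionModel,
    SimulationConfig,
    adjust_bh,
    breadth_profile,
    call_degs,
    compute_fpkm,
    detected_gene_sets,
    nb_exact_test,
    overlap_containment,
    pairwise_deg_summary,
    shannon_entropy,
    simulate_expression_matrix,
    simulate_truth,
    size_factors,
)
from hybrase.expression import ExpressionError


def nb_mat(rng, mu, phi, shape):
    mu = np.broadcast_to(mu, shape)
    if phi <= 0:
        return rng.poisson(mu)
    return rng.poisson(rng.gamma(1.0 / phi, mu * phi))


class TestCountMatrix:
    def test_rejects_negative(self):
        with pytest.raises(ExpressionError):
            CountMatrix(pd.DataFrame({"a": [-1]}))

    def test_rejects_fractional(self):
        with pytest.raises(ExpressionError):
            CountMatrix(pd.DataFrame({"a": [1.5]}))

    def test_rejects_bad_lengths(self):
        with pytest.raises(ExpressionError):
            CountMatrix(
                pd.DataFrame({"a": [1]}, index=["g1"]),
                lengths=pd.Series({"g1": 0}),
            )


class TestSizeFactors:
    def test_identical_samples(self):
        df = pd.DataFrame({"a": [10, 20, 5], "b": [10, 20, 5]})
        sf = size_factors(df)
        assert sf["a"] == pytest.approx(sf["b"])

    def test_exact_doubling(self):
        rng = np.random.default_rng(0)
        a = rng.integers(1, 500, size=200)
        df = pd.DataFrame({"a": a, "b": 2 * a})
        sf = size_factors(df)
        assert sf["b"] / sf["a"] == pytest.approx(2.0, rel=1e-12)

    def test_matches_bruteforce_median_of_ratios(self, rng):
        df = pd.DataFrame(
            nb_mat(rng, 200.0, 0.2, (300, 4)), columns=list("abcd")
        )
        sf = size_factors(df)
        # independent brute-force: per-gene geometric mean, then median ratio
        arr = df.to_numpy(float)
        expected = []
        for j in range(4):
            ratios = []
            for i in range(arr.shape[0]):
                if (arr[i] > 0).all():
                    gm = np.exp(np.mean(np.log(arr[i])))
                    ratios.append(arr[i, j] / gm)
            expected.append(np.median(ratios))
        np.testing.assert_allclose(sf.to_numpy(), expected, rtol=1e-10)

    def test_no_common_gene_errors(self):
        df = pd.DataFrame({"a": [5, 0], "b": [0, 5]})
        with pytest.raises(ExpressionError):
            size_factors(df)


class TestDispersionModel:
    def test_poisson_limit(self, rng):
        mu = np.exp(rng.normal(np.log(300), 1.0, 2000))
        df = pd.DataFrame(nb_mat(rng, mu[:, None], 0.0, (2000, 6)))
        sf = size_factors(df)
        m = DispersionModel.fit(df, sf)
        for q in (100.0, 300.0, 800.0):
            assert m.raw_variance(q) / q**2 < 0.02

    def test_nb_dispersion_recovered(self, rng):
        phi = 0.2
        mu = np.exp(rng.normal(np.log(300), 1.0, 3000))
        df = pd.DataFrame(nb_mat(rng, mu[:, None], phi, (3000, 8)))
        sf = size_factors(df)
        m = DispersionModel.fit(df, sf)
        for q in (150.0, 300.0, 600.0):
            assert m.raw_variance(q) / q**2 == pytest.approx(phi, rel=0.5)

    def test_monotone_fit_on_monotone_input(self):
        q = np.linspace(10, 1000, 500)
        w = q + 0.1 * q**2
        df = pd.DataFrame({"a": np.round(q).astype(int), "b": np.round(q).astype(int)})
        model = DispersionModel(np.log(q), w, xim=1.0)
        grid = np.linspace(20, 900, 50)
        vals = model.raw_variance(grid)
        assert (np.diff(vals) > 0).all()

    def test_needs_two_samples(self):
        df = pd.DataFrame({"a": [1, 2, 3]})
        with pytest.raises(ExpressionError):
            DispersionModel.fit(df, pd.Series({"a": 1.0}))

    def test_within_condition_variance_ignores_planted_shift(self, rng):
        # replicated conditions: a planted fold change must not inflate the fit
        phi = 0.05
        mu = np.full(1000, 400.0)
        a = nb_mat(rng, mu[:, None], phi, (1000, 3))
        b = nb_mat(rng, 4 * mu[:, None], phi, (1000, 3))
        df = pd.DataFrame(
            np.hstack([a, b]), columns=["a1", "a2", "a3", "b1", "b2", "b3"]
        )
        sf = size_factors(df)
        cond = {s: s[0] for s in df.columns}
        m = DispersionModel.fit(df, sf, conditions=cond)
        q = df.to_numpy().mean() / sf.mean()
        assert m.raw_variance(q) / q**2 < 3 * phi


class FixedModel:
    """Explicit scv model for oracle comparisons."""

    def __init__(self, scv):
        self.scv = scv

    def model(self):
        return DispersionModel.from_function(lambda q: self.scv * q * q)


def oracle_nb_exact(kA, kB, sA, sB, scv):
    """Exhaustive linear-space enumeration of the conditioned exact test."""
    ks = kA + kB
    q0 = ks / (sA + sB)

    def pmf(x, mean, var):
        if var <= mean:
            return stats.poisson.pmf(x, mean)
        r = mean * mean / (var - mean)
        p = r / (r + mean)
        return stats.nbinom.pmf(x, r, p)
    muA, muB = sA * q0, sB * q0
    varA = sA * q0 + sA**2 * scv * q0**2
    varB = sB * q0 + sB**2 * scv * q0**2
    a = np.arange(ks + 1)
    joint = pmf(a, muA, varA) * pmf(ks - a, muB, varB)
    obs = joint[kA]
    return joint[joint <= obs * (1 + 1e-9)].sum() / joint.sum()


class TestNbExactTest:
    def test_balanced_split_is_one(self):
        m = FixedModel(0.1).model()
        assert nb_exact_test(10, 10, [1.0], [1.0], m) == 1.0

    def test_zero_total(self):
        m = FixedModel(0.1).model()
        assert nb_exact_test(0, 0, [1.0], [1.0], m) == 1.0

    @pytest.mark.parametrize("sfs", [(1.0, 1.0), (1.0, 1.3)])
    @pytest.mark.parametrize("scv", [0.01, 0.2])
    def test_matches_enumeration_oracle(self, sfs, scv):
        m = FixedModel(scv).model()
        sA, sB = sfs
        for ks in range(1, 21):
            for kA in range(ks + 1):
                got = nb_exact_test(kA, ks - kA, [sA], [sB], m)
                want = oracle_nb_exact(kA, ks - kA, sA, sB, scv)
                assert abs(np.log(got) - np.log(want)) < 1e-10

    def test_null_p_stable_under_depth_doubling(self):
        m = FixedModel(0.05).model()
        p1 = nb_exact_test(480, 520, [1.0], [1.0], m)
        p2 = nb_exact_test(960, 1040, [2.0], [2.0], m)
        assert abs(np.log(p1) - np.log(p2)) < 0.5

    def test_negative_counts_rejected(self):
        with pytest.raises(ExpressionError):
            nb_exact_test(-1, 5, [1.0], [1.0], FixedModel(0.1).model())


class TestAdjustBH:
    def test_hand_computed(self):
        np.testing.assert_allclose(
            adjust_bh([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_all_ones(self):
        np.testing.assert_allclose(adjust_bh([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_never_below_input(self, rng):
        p = rng.uniform(1e-6, 1.0, 200)
        assert (adjust_bh(p) >= p).all()

    def test_permutation_invariant(self, rng):
        p = rng.uniform(1e-6, 1.0, 100)
        perm = rng.permutation(100)
        np.testing.assert_allclose(adjust_bh(p)[perm], adjust_bh(p[perm]))

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests
        p = rng.uniform(1e-6, 1.0, 500)
        _, expected, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(adjust_bh(p), expected, rtol=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ExpressionError):
            adjust_bh([0.0, 0.5])

    @given(
        st.lists(
            st.floats(min_value=1e-9, max_value=1.0, exclude_min=False),
            min_size=1, max_size=50,
        )
    )
    def test_properties_hold_for_arbitrary_inputs(self, p):
        adj = adjust_bh(p)
        assert ((adj >= np.asarray(p) - 1e-15) & (adj <= 1.0)).all()
        # idempotent on already-adjusted values up to monotonicity
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestCallDegs:
    def test_joint_rule_requires_fold_change(self, rng):
        # strong p-values but ~1.5-fold: must not be DE under min_fold=2
        n = 500
        mu = np.full(n, 2000.0)
        shift = np.ones(n)
        shift[:150] = 1.5  # only a minority shifted, so normalization holds
        a = nb_mat(rng, mu[:, None], 0.002, (n, 3))
        b = nb_mat(rng, (mu * shift)[:, None], 0.002, (n, 3))
        df = pd.DataFrame(np.hstack([a, b]),
                          columns=["a1", "a2", "a3", "b1", "b2", "b3"])
        res = call_degs(df, ["a1", "a2", "a3"], ["b1", "b2", "b3"])
        strong = res.iloc[:150][res.iloc[:150]["adjusted_p"] < 0.01]
        assert len(strong) > 100
        assert (strong["log2fc"].abs() < 1).all()
        assert not strong["is_de"].any()

    def test_null_no_calls(self, rng):
        mu = np.exp(rng.normal(np.log(400), 1.0, 800))
        df = pd.DataFrame(
            dict(a=nb_mat(rng, mu, 0.05, 800), b=nb_mat(rng, mu, 0.05, 800))
        )
        res = call_degs(df, ["a"], ["b"])
        assert res["is_de"].mean() <= 0.05

    def test_unknown_sample(self):
        df = pd.DataFrame({"a": [1], "b": [2]})
        with pytest.raises(ExpressionError, match="unknown"):
            call_degs(df, ["a"], ["zzz"])

    def test_simulated_null_design(self):
        # frac_de=0: no planted effects, DEG calls stay at false-positive level
        cfg = SimulationConfig(n_genes=600, frac_de=0.0, expr_sigma=1.0, seed=19)
        truth = simulate_truth(cfg)
        geno, _ = simulate_expression_matrix(cfg, truth)
        res = call_degs(geno, ["parent1"], ["parent2"])
        assert res["is_de"].mean() <= 0.05


class TestDegSummaries:
    def test_disjoint_and_identical(self):
        out = pairwise_deg_summary({"x": {"a", "b"}, "y": {"c"}, "z": {"a", "b"}})
        row_xy = out[(out.set_a == "x") & (out.set_b == "y")].iloc[0]
        assert row_xy["n_intersection"] == 0
        row_xz = out[(out.set_a == "x") & (out.set_b == "z")].iloc[0]
        assert row_xz["pct_a_in_b"] == 100.0

    def test_hand_enumerated_overlap(self):
        res = overlap_containment({"A", "B", "C"}, {"B", "C", "D"}, {"B", "C"})
        assert res["n_intersection"] == 2
        assert res["pct_in_reference"] == 100.0

    def test_empty_intersection(self):
        res = overlap_containment({"A"}, {"B"}, {"C"})
        assert res["n_intersection"] == 0
        assert res["pct_in_reference"] == 0.0


class TestFpkm:
    def test_unit_case(self):
        df = pd.DataFrame({"s": [100]}, index=["g"])
        lengths = pd.Series({"g": 1000})
        totals = pd.Series({"s": 1_000_000})
        assert compute_fpkm(df, lengths, totals).iloc[0, 0] == pytest.approx(100.0)

    def test_zero_count(self):
        df = pd.DataFrame({"s": [0]}, index=["g"])
        out = compute_fpkm(df, pd.Series({"g": 500}), pd.Series({"s": 10}))
        assert out.iloc[0, 0] == 0.0

    def test_doubling_total_halves_fpkm(self, rng):
        df = pd.DataFrame({"s": rng.integers(0, 100, 50)})
        lengths = pd.Series(rng.integers(200, 3000, 50), index=df.index)
        f1 = compute_fpkm(df, lengths, pd.Series({"s": 1e6}))
        f2 = compute_fpkm(df, lengths, pd.Series({"s": 2e6}))
        np.testing.assert_allclose(f1.to_numpy(), 2 * f2.to_numpy())

    def test_zero_total_errors(self):
        df = pd.DataFrame({"s": [1]}, index=["g"])
        with pytest.raises(ExpressionError):
            compute_fpkm(df, pd.Series({"g": 100}), pd.Series({"s": 0}))


class TestEntropy:
    def test_uniform_maximum(self):
        df = pd.DataFrame([np.ones(11)])
        assert shannon_entropy(df).iloc[0] == pytest.approx(np.log2(11), abs=1e-12)

    def test_single_tissue_zero(self):
        row = np.zeros(11)
        row[3] = 50.0
        assert shannon_entropy(pd.DataFrame([row])).iloc[0] == 0.0

    def test_closed_form_75_25(self):
        h = shannon_entropy(pd.DataFrame([[0.75, 0.25]])).iloc[0]
        assert h == pytest.approx(0.8113, abs=5e-5)

    def test_scale_invariance_and_bounds(self, rng):
        x = rng.uniform(0, 10, (100, 11))
        h1 = shannon_entropy(pd.DataFrame(x))
        h2 = shannon_entropy(pd.DataFrame(3.7 * x))
        np.testing.assert_allclose(h1, h2)
        assert ((h1 >= 0) & (h1 <= np.log2(11) + 1e-12)).all()

    def test_all_zero_gene_flagged_nan(self):
        df = pd.DataFrame([[0.0, 0.0], [1.0, 1.0]])
        h = shannon_entropy(df)
        assert np.isnan(h.iloc[0]) and not np.isnan(h.iloc[1])

    def test_breadth_profile_floor(self):
        df = pd.DataFrame([[0.5, 0.4], [5.0, 4.0]], index=["low", "high"])
        h = breadth_profile(df, min_fpkm=1.0)
        assert list(h.index) == ["high"]

    def test_planted_classes_separate(self):
        # tissue-specific genes must show lower breadth than broad genes
        cfg = SimulationConfig(n_genes=500, frac_tissue_specific=0.4, seed=23)
        truth = simulate_truth(cfg)
        _, tissues = simulate_expression_matrix(cfg, truth)
        h = shannon_entropy(compute_fpkm(tissues))
        spec = truth.set_index("gene_id")["breadth_class"] == "tissue_specific"
        a, b = h[spec.reindex(h.index)], h[~spec.reindex(h.index)]
        assert len(a) >= 150 and len(b) >= 150
        t = stats.ttest_ind(a.dropna(), b.dropna(), equal_var=False)
        assert a.mean() < b.mean()
        assert t.pvalue < 0.05


class TestDetectedSets:
    def test_all_zero(self):
        df = pd.DataFrame(np.zeros((5, 3), dtype=int), columns=list("abc"))
        sets, regions, union = detected_gene_sets(df)
        assert all(len(s) == 0 for s in sets.values())
        assert union == 0 and regions == {}

    def test_hybrid_union_construction(self):
        # hybrids expressing the union of parental genes detect at least as
        # many genes as either parent
        df = pd.DataFrame(
            dict(p1=[5, 0, 2, 0], p2=[0, 4, 1, 0], hyb=[3, 2, 2, 0]),
            index=list("wxyz"),
        )
        sets, _, _ = detected_gene_sets(df)
        assert sets["hyb"] == sets["p1"] | sets["p2"]
        assert len(sets["hyb"]) >= max(len(sets["p1"]), len(sets["p2"]))

    def test_regions_partition_union(self, rng):
        df = pd.DataFrame(
            rng.integers(0, 3, size=(200, 4)), columns=list("abcd")
        )
        _, regions, union = detected_gene_sets(df)
        assert sum(regions.values()) == union
        assert len(regions) <= 15
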