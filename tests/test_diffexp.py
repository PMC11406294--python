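import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cfrna.diffexp import bh_adjust, gene_auc, intersect_dag_sets, nb_wald_test, run_de
from cfrna.normalize import fit_normalization


def _null_counts(rng, G=1000, n_per=20, phi=0.1):
    mu = rng.lognormal(4, 1, size=G)
    lam = rng.gamma(1 / phi, mu[:, None] * phi, size=(G, 2 * n_per))
    return pd.DataFrame(rng.poisson(lam))


class TestNBWald:
    def test_type_i_error_on_null(self, rng):
        counts = _null_counts(rng, G=1500)
        labels = np.array(["A"] * 20 + ["B"] * 20)
        model = fit_normalization(counts)
        res = nb_wald_test(counts, model.size_factors,
                           model.moderated_dispersions(), labels, "A", "B")
        frac = (res["pvalue"] < 0.05).mean()
        assert 0.03 <= frac <= 0.07

    def test_planted_log2fc_recovered(self, rng, nb_sim):
        G = 1500
        mu = rng.lognormal(4, 1, size=G)
        fc = np.ones(G)
        fc[:75] = 2.0  # true log2fc = 1 on 5% of genes
        A = nb_sim(rng, mu, np.full(G, 0.1), 50)
        B = nb_sim(rng, mu * fc, np.full(G, 0.1), 50)
        counts = pd.DataFrame(np.hstack([A, B]))
        labels = np.array(["A"] * 50 + ["B"] * 50)
        model = fit_normalization(counts)
        res = nb_wald_test(counts, model.size_factors,
                           model.moderated_dispersions(), labels, "A", "B")
        assert abs(res["log2fc"].iloc[:75].median() - 1.0) < 0.1

    def test_matches_statsmodels_glm(self, rng, nb_sim):
        """Independent per-gene NB GLM fits agree on beta and SE."""
        import statsmodels.api as sm

        G, n = 25, 30
        mu = rng.lognormal(4, 0.5, size=G)
        K = nb_sim(rng, mu, np.full(G, 0.15), n)
        counts = pd.DataFrame(K)
        labels = np.array(["A"] * 15 + ["B"] * 15)
        s = np.ones(n)
        phi = np.full(G, 0.15)
        res = nb_wald_test(counts, s, phi, labels, "A", "B")
        X = sm.add_constant((labels == "B").astype(float))
        for i in range(G):
            fit = sm.GLM(K[i], X,
                         family=sm.families.NegativeBinomial(alpha=0.15)).fit()
            assert np.isclose(res["log2fc"].iloc[i],
                              fit.params[1] / np.log(2), atol=1e-5)
            assert np.isclose(res["stat"].iloc[i],
                              fit.params[1] / fit.bse[1], rtol=1e-4)

    def test_all_zero_gene_gets_na_and_leaves_family(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.poisson(50, size=(50, 10)))
        counts.iloc[7] = 0
        labels = np.array(["A"] * 5 + ["B"] * 5)
        res = nb_wald_test(counts, np.ones(10), np.full(50, 0.1), labels,
                           "A", "B")
        assert np.isnan(res["pvalue"].iloc[7])
        assert np.isnan(res["qvalue"].iloc[7])
        # family size excludes the NA gene: q = p * m / rank with m = 49
        finite = res.dropna().sort_values("pvalue")
        k = np.arange(1, len(finite) + 1)
        expected = np.minimum.accumulate(
            (finite["pvalue"].to_numpy() * len(finite) / k)[::-1])[::-1]
        assert np.allclose(finite["qvalue"].to_numpy(),
                           np.minimum(expected, 1), atol=1e-12)

    def test_empty_group_raises(self):
        counts = pd.DataFrame(np.ones((5, 4), dtype=int))
        with pytest.raises(ValueError, match="non-empty"):
            nb_wald_test(counts, np.ones(4), np.ones(5),
                         np.array(["A"] * 4), "A", "B")

    def test_label_swap_antisymmetry(self, rng, nb_sim):
        G = 200
        mu = rng.lognormal(4, 0.8, size=G)
        K = nb_sim(rng, mu, np.full(G, 0.1), 30)
        counts = pd.DataFrame(K)
        labels = np.array(["A"] * 15 + ["B"] * 15)
        fwd = run_de(counts, labels, "A", "B")
        rev = run_de(counts, labels, "B", "A")
        ok = fwd["log2fc"].notna() & rev["log2fc"].notna()
        assert np.allclose(fwd.loc[ok, "log2fc"], -rev.loc[ok, "log2fc"],
                           atol=1e-6)
        assert np.allclose(fwd["auc"], 1 - rev["auc"], atol=1e-12)


class TestBH:
    def test_hand_example(self):
        q = bh_adjust(np.array([0.01, 0.02, 0.03]))
        assert np.allclose(q, [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust(np.array([0.2]))[0] == pytest.approx(0.2)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.5]))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=30))
    def test_step_up_properties(self, ps):
        p = np.asarray(ps)
        q = bh_adjust(p)
        assert ((q >= p - 1e-12) & (q <= 1 + 1e-12)).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()


class TestGeneAUC:
    def test_canonical_values(self):
        vals = pd.DataFrame(
            {"a1": [0, 1, 1], "a2": [1, 1, 3], "b1": [10, 1, 2], "b2": [11, 1, 4]},
            index=["sep", "tied", "mixed"],
        )
        labels = np.array(["A", "A", "B", "B"])
        auc = gene_auc(vals, labels, "A", "B")
        assert auc["sep"] == 1.0
        assert auc["tied"] == 0.5
        assert auc["mixed"] == 0.75  # A={1,3}, B={2,4}: 3 of 4 pairs favorable

    def test_matches_bruteforce_all_pairs(self, rng):
        for _ in range(100):
            n_a = int(rng.integers(2, 8))
            n_b = int(rng.integers(2, 8))
            vals = np.round(rng.normal(size=(3, n_a + n_b)), 1)  # force ties
            labels = np.array(["A"] * n_a + ["B"] * n_b)
            auc = gene_auc(pd.DataFrame(vals), labels, "A", "B")
            for g in range(3):
                a, b = vals[g, :n_a], vals[g, n_a:]
                brute = np.mean([(bb > aa) + 0.5 * (bb == aa)
                                 for aa in a for bb in b])
                assert abs(auc.iloc[g] - brute) < 1e-12

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            gene_auc(pd.DataFrame([[1.0, 2.0]]), np.array(["A", "A"]), "A", "B")


class TestIntersectDagSets:
    def test_exclusive_patterns(self):
        out = intersect_dag_sets({"A": ["g1", "g2"], "B": ["g2", "g3"]})
        lookup = {tuple(r.sets): r.count for r in out.itertuples()}
        assert lookup == {("A",): 1, ("B",): 1, ("A", "B"): 1}
        assert out["count"].sum() == 3  # |union|

    def test_identical_sets(self):
        out = intersect_dag_sets({"A": ["x", "y"], "B": ["x", "y"]})
        assert len(out) == 1
        assert tuple(out["sets"].iloc[0]) == ("A", "B")

    def test_disjoint_sets(self):
        out = intersect_dag_sets({"A": ["x"], "B": ["y"], "C": ["z"]})
        assert set(map(tuple, out["sets"])) == {("A",), ("B",), ("C",)}

    def test_fewer_than_two_sets_rejected(self):
        with pytest.raises(ValueError):
            intersect_dag_sets({"A": ["x"]})


def test_shared_inflammation_signature_recovered_by_intersection():
    """The all-groups exclusive intersection finds the shared signature."""
    from cfrna.synthetic import default_config, make_reference, simulate_cohort

    ref = make_reference(8, 2000, seed=13)
    cfg = default_config(
        group_sizes={"KD": 30, "MIS-C": 30, "viral": 30, "bacterial": 30,
                     "healthy": 30},
        n_genes=2000, signature_log2fc=2.0, signature_size=40,
        shared_signature_size=50, seed=13,
    )
    co = simulate_cohort(cfg, ref)
    labels = co.metadata["group"].to_numpy()
    dag_sets = {}
    for g in ["KD", "MIS-C", "viral", "bacterial"]:
        de = run_de(co.counts, labels, "healthy", g)
        dag_sets[g] = de.index[de["qvalue"] < 0.05].tolist()
    shared = set.intersection(*[set(v) for v in dag_sets.values()])
    truth = set(co.truth.shared_genes)
    assert len(shared & truth) >= 0.9 * len(truth)
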