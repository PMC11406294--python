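import warnings

import numpy as np
import pandas as pd
import pytest

from cfrna.classify import (
    OvOStackClassifier,
    PenalizedLogisticClassifier,
    SplitSpec,
    _enet_logistic_path,
    model_bakeoff,
    roc_auc,
    stratified_partition,
    youden_threshold,
)


def _meta(n, groups, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "group": rng.choice(groups, size=n),
        "hospital": rng.choice(["H1", "H2"], size=n),
        "subgroup": "-",
    }, index=[f"s{i}" for i in range(n)])


class TestStratifiedPartition:
    def test_exact_division(self):
        meta = pd.DataFrame({"group": ["g"] * 100, "hospital": "H",
                             "subgroup": "-"})
        split = stratified_partition(meta, SplitSpec((60, 20, 20), ("group",), 1))
        assert split.value_counts().to_dict() == {
            "train": 60, "validation": 20, "test": 20}

    def test_largest_remainder_rounding(self):
        meta = pd.DataFrame({"group": ["g"] * 10, "hospital": "H",
                             "subgroup": "-"})
        split = stratified_partition(meta, SplitSpec((70, 30), ("group",), 1))
        assert split.value_counts().to_dict() == {"train": 7, "test": 3}

    def test_seeded_determinism(self):
        meta = _meta(80, ["a", "b"], seed=2)
        s1 = stratified_partition(meta, SplitSpec((70, 30), ("group", "hospital"), 5))
        s2 = stratified_partition(meta, SplitSpec((70, 30), ("group", "hospital"), 5))
        pd.testing.assert_series_equal(s1, s2)

    def test_within_stratum_balance(self):
        meta = _meta(300, ["a", "b", "c"], seed=3)
        split = stratified_partition(
            meta, SplitSpec((60, 20, 20), ("group", "hospital"), 7))
        for _, cell in meta.groupby(["group", "hospital"]):
            counts = split.loc[cell.index].value_counts()
            m = len(cell)
            for name, pct in zip(("train", "validation", "test"), (60, 20, 20)):
                assert abs(counts.get(name, 0) - m * pct / 100) <= 1

    def test_small_cells_collapse_to_group(self, caplog):
        meta = _meta(9, ["a", "b"], seed=4)
        meta.loc[:, "hospital"] = [f"H{i}" for i in range(9)]  # singleton cells
        with caplog.at_level("WARNING"):
            split = stratified_partition(
                meta, SplitSpec((70, 30), ("group", "hospital"), 0))
        assert split.notna().all()
        assert "collapsed" in caplog.text

    def test_missing_stratum_key_raises(self):
        meta = pd.DataFrame({"group": ["a", "b"]})
        with pytest.raises(ValueError, match="hospital"):
            stratified_partition(meta, SplitSpec((70, 30), ("group", "hospital"), 0))

    def test_bad_ratios_rejected(self):
        with pytest.raises(ValueError):
            SplitSpec((50, 20, 20))


class TestYouden:
    def test_perfect_separation_returns_midpoint(self):
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        labels = np.array(["neg", "neg", "pos", "pos"])
        t = youden_threshold(scores, labels, positive_label="pos")
        assert t == pytest.approx(0.5)

    def test_identical_scores_warn_and_return_common_value(self):
        with pytest.warns(UserWarning, match="identical"):
            t = youden_threshold(np.full(6, 0.4),
                                 np.array(["a", "b"] * 3))
        assert t == pytest.approx(0.4)

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 15))
            scores = np.round(rng.uniform(size=n), 2)
            labels = rng.choice(["n", "p"], size=n)
            if len(np.unique(labels)) < 2:
                labels[0], labels[1] = "n", "p"
            got = youden_threshold(scores, labels, positive_label="p")
            uniq = np.unique(scores)
            cands = np.concatenate(([-np.inf], (uniq[:-1] + uniq[1:]) / 2,
                                    [np.inf])) if uniq.size > 1 else uniq
            pos, neg = scores[labels == "p"], scores[labels != "p"]
            best_j, best_t = -np.inf, None
            for t in cands:
                j = (pos >= t).mean() + (neg < t).mean() - 1
                if j > best_j + 1e-15:
                    best_j, best_t = j, t
            assert got == best_t

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            youden_threshold([0.1, 0.9], ["a", "a"])


class TestRocAuc:
    def test_perfect_and_reversed(self):
        y = ["n", "n", "p", "p"]
        assert roc_auc([0.1, 0.2, 0.8, 0.9], y, "p") == 1.0
        assert roc_auc([0.9, 0.8, 0.2, 0.1], y, "p") == 0.0

    def test_matches_all_pairs_enumeration(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 12))
            scores = np.round(rng.uniform(size=n), 1)
            labels = rng.choice(["n", "p"], size=n)
            if len(np.unique(labels)) < 2:
                labels[0], labels[1] = "n", "p"
            pos, neg = scores[labels == "p"], scores[labels == "n"]
            brute = np.mean([(p > q) + 0.5 * (p == q) for q in neg for p in pos])
            assert abs(roc_auc(scores, labels, "p") - brute) < 1e-12

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.normal(size=40)
        labels = rng.choice(["n", "p"], size=40)
        labels[:2] = ["n", "p"]
        a = roc_auc(scores, labels, "p")
        b = roc_auc(np.exp(3 * scores) + 7, labels, "p")
        assert a == pytest.approx(b, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], ["a", "a"])


class TestPenalizedLogistic:
    def test_full_shrinkage_gives_log_odds_intercept(self, rng):
        X = pd.DataFrame(rng.standard_normal((60, 10)))
        y = np.array(["B"] * 20 + ["A"] * 40)
        est = PenalizedLogisticClassifier(alpha=1.0, n_lambdas=3,
                                          random_state=0)
        est._lambda_max = lambda *a: 1e6
        est.lambda_min_ratio = 1e-2
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(X, y)
        assert np.abs(est.coef_).max() == 0.0
        assert est.intercept_[0] == pytest.approx(np.log(20 / 40), abs=1e-6)

    def test_informative_feature_has_largest_coefficient(self, rng):
        n = 200
        X = rng.standard_normal((n, 50))
        y01 = rng.integers(0, 2, size=n)
        X[:, 17] += 2.0 * y01  # planted 2-sd shift
        y = np.where(y01 == 1, "case", "control")
        est = PenalizedLogisticClassifier(alpha=1.0, n_lambdas=40,
                                          random_state=1).fit(pd.DataFrame(X), y)
        coefs = np.abs(est.coef_[0])
        assert coefs[17] > 0
        assert coefs.argmax() == 17
        assert "17" in map(str, est.selected_features_) or 17 in est.selected_features_

    def test_probability_is_sigmoid_of_linear_score(self, rng):
        X = pd.DataFrame(rng.standard_normal((80, 5)))
        y = np.where(X.iloc[:, 0] + 0.3 * rng.standard_normal(80) > 0, "b", "a")
        est = PenalizedLogisticClassifier(alpha=1.0, n_lambdas=20,
                                          random_state=0).fit(X, y)
        z = ((X - est.feature_means_) / est.feature_scales_) @ est.coef_[0] \
            + est.intercept_[0]
        manual = 1 / (1 + np.exp(-z))
        assert np.allclose(est.predict_proba(X)[:, 1], manual, atol=1e-12)

    def test_solver_matches_sklearn_saga(self, rng):
        from sklearn.linear_model import LogisticRegression

        n, p = 60, 20
        X = rng.standard_normal((n, p))
        y = (X[:, 0] + rng.standard_normal(n) > 0).astype(float)
        Xs = (X - X.mean(0)) / X.std(0)
        lam = 0.05
        (coef, b0), = _enet_logistic_path(Xs, y, np.array([lam]), 1.0,
                                          tol=1e-10, max_iter=50_000)
        sk = LogisticRegression(solver="saga", l1_ratio=1.0, C=1 / (n * lam),
                                max_iter=200_000, tol=1e-10).fit(Xs, y)
        assert np.abs(coef - sk.coef_[0]).max() < 1e-6
        assert abs(b0 - sk.intercept_[0]) < 1e-6

    def test_sparsity_weakly_decreases_with_penalty(self, rng):
        n, p = 120, 60
        X = rng.standard_normal((n, p))
        beta = np.zeros(p)
        beta[:8] = 1.0
        y = (X @ beta + rng.standard_normal(n) > 0).astype(float)
        Xs = (X - X.mean(0)) / X.std(0)
        lam_max = np.abs(Xs.T @ (y - y.mean())).max() / n
        lambdas = np.geomspace(lam_max * 1.01, lam_max * 1e-3, 12)
        sols = _enet_logistic_path(Xs, y, lambdas, 1.0, tol=1e-9,
                                   max_iter=20_000)
        nnz = [int((np.abs(c) > 1e-10).sum()) for c, _ in sols]
        assert nnz[0] == 0
        assert all(a <= b for a, b in zip(nnz, nnz[1:]))
        assert nnz[-1] <= p

    def test_single_class_and_empty_panel_rejected(self, rng):
        X = pd.DataFrame(rng.standard_normal((10, 3)))
        with pytest.raises(ValueError, match="single class"):
            PenalizedLogisticClassifier().fit(X, np.array(["a"] * 10))
        with pytest.raises(ValueError, match="empty"):
            PenalizedLogisticClassifier().fit(X.iloc[:, :0],
                                              np.array(["a", "b"] * 5))


@pytest.fixture(scope="module")
def binary_data():
    rng = np.random.default_rng(8)
    n = 120
    X = rng.standard_normal((n, 30))
    y01 = rng.integers(0, 2, size=n)
    X[:, :3] += 1.5 * y01[:, None]
    y = np.where(y01 == 1, "case", "control")
    return (pd.DataFrame(X[:80]), y[:80], pd.DataFrame(X[80:]), y[80:])


class TestBakeoff:
    def test_singleton_set_is_chosen(self, binary_data):
        table, chosen, model = model_bakeoff(*binary_data,
                                             algorithms=["lasso_logistic"],
                                             seed=0)
        assert chosen == "lasso_logistic"
        assert list(table.index) == ["lasso_logistic"]

    def test_chosen_has_max_validation_auc(self, binary_data):
        table, chosen, _ = model_bakeoff(
            *binary_data,
            algorithms=["lasso_logistic", "random_forest", "knn",
                        "naive_bayes"],
            seed=0)
        assert table.loc[chosen, "val_auc"] == table["val_auc"].max()

    def test_deterministic_given_seed(self, binary_data):
        t1, c1, _ = model_bakeoff(*binary_data,
                                  algorithms=["lasso_logistic", "naive_bayes"],
                                  seed=3)
        t2, c2, _ = model_bakeoff(*binary_data,
                                  algorithms=["lasso_logistic", "naive_bayes"],
                                  seed=3)
        pd.testing.assert_frame_equal(t1, t2)
        assert c1 == c2

    def test_single_class_validation_rejected(self, binary_data):
        Xtr, ytr, Xva, _ = binary_data
        with pytest.raises(ValueError, match="single class"):
            model_bakeoff(Xtr, ytr, Xva, np.array(["case"] * len(Xva)),
                          algorithms=["naive_bayes"], seed=0)


def _four_class_vst(rng, n_per=25, p=40):
    classes = ["KD", "MIS-C", "bacterial", "viral"]
    rows, labels = [], []
    for k, cls in enumerate(classes):
        centers = np.zeros(p)
        centers[5 * k : 5 * k + 5] = 2.5
        rows.append(rng.standard_normal((n_per, p)) + centers)
        labels += [cls] * n_per
    X = pd.DataFrame(np.vstack(rows),
                     columns=[f"g{j}" for j in range(p)])
    return X, np.array(labels)


class TestOvOStack:
    @pytest.fixture(scope="class", name="fitted")
    @staticmethod
    def fitted_fixture():
        rng = np.random.default_rng(17)
        X, y = _four_class_vst(rng)
        panels = {}
        from itertools import combinations
        for a, b in combinations(sorted(set(y)), 2):
            panels[(a, b)] = list(X.columns)
        model = OvOStackClassifier(panels=panels, n_lambdas=20,
                                   random_state=17).fit(X, y)
        return model, X, y

    def test_six_pairwise_models_and_score_columns(self, fitted):
        model, X, _ = fitted
        assert len(model.pair_models_) == 6
        assert model.score_matrix(X).shape == (len(X), 6)

    def test_positive_class_is_lexicographically_larger(self, fitted):
        model, _, _ = fitted
        for pair, est in model.pair_models_.items():
            assert est.classes_[1] == max(pair)

    def test_probabilities_sum_to_one(self, fitted):
        model, X, _ = fitted
        assert np.allclose(model.predict_proba(X).sum(axis=1), 1.0, atol=1e-9)

    def test_training_sample_prediction_deterministic(self, fitted):
        model, X, _ = fitted
        p1 = model.predict_proba(X.iloc[[3]])
        p2 = model.predict_proba(X.iloc[[3]])
        assert np.array_equal(p1, p2)

    def test_separable_classes_high_training_accuracy(self, fitted):
        model, X, y = fitted
        assert (model.predict(X) == y).mean() >= 0.99

    def test_missing_panel_raises(self):
        rng = np.random.default_rng(1)
        X, y = _four_class_vst(rng, n_per=8)
        with pytest.raises(ValueError, match="missing gene panel"):
            OvOStackClassifier(panels={}).fit(X, y)

    def test_missing_genes_listed(self, fitted):
        model, X, _ = fitted
        with pytest.raises(ValueError, match="g0"):
            model.predict_proba(X.drop(columns=["g0"]))


class TestLeakageGuard:
    def test_held_out_labels_never_influence_training(self):
        """Poisoning test-set labels leaves the fitted models unchanged."""
        from cfrna.pipeline import run_multiclass_path
        from cfrna.synthetic import default_config, make_reference, simulate_cohort

        ref = make_reference(8, 1200, seed=23)
        cfg = default_config(
            group_sizes={"KD": 16, "MIS-C": 16, "viral": 16, "bacterial": 16},
            n_genes=1200, signature_log2fc=2.0, signature_size=30,
            shared_signature_size=0, seed=23)
        co = simulate_cohort(cfg, ref)
        res1 = run_multiclass_path(co.counts, co.metadata, seed=23,
                                   n_lambdas=20)
        poisoned = co.metadata.copy()
        test_ids = res1.split.index[res1.split == "test"]
        rng = np.random.default_rng(0)
        poisoned.loc[test_ids, "group"] = rng.permutation(
            poisoned.loc[test_ids, "group"].to_numpy())
        res2 = run_multiclass_path(co.counts, poisoned, seed=23, n_lambdas=20,
                                   split=res1.split)
        for pair in res1.stack.pairs_:
            assert np.array_equal(res1.stack.pair_models_[pair].coef_,
                                  res2.stack.pair_models_[pair].coef_)
        pd.testing.assert_frame_equal(res1.test_predictions,
                                      res2.test_predictions)
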