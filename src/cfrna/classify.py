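"""Partitioning, penalized-logistic classification and one-vs-one stacking.

The binary path mirrors regularized GLM practice: features (VST values
restricted to a gene panel) are standardized on the training set, an
elastic-net-penalized logistic model

    min  -(1/n) sum_i loglik_i
         + lambda * [ (1-alpha)/2 * ||b||_2^2 + alpha * ||b||_1 ]

(intercept unpenalized) is fit along a 100-point log-spaced lambda path
from lambda_max (first all-zero solution) down to lambda_max * 1e-4,
lambda is chosen by 5-fold cross-validated ROC-AUC, and the decision
threshold is set by Youden's J on the training scores.

The multiclass framework trains one such LASSO model per unordered class
pair on only that pair's training samples, scores *all* samples with all
C(k,2) models, and feeds the resulting score matrix to a random-forest
meta-classifier; the class with the highest meta probability is the
prediction (no Youden thresholding in the multiclass path).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)

__all__ = [
    "SplitSpec",
    "stratified_partition",
    "youden_threshold",
    "roc_auc",
    "PenalizedLogisticClassifier",
    "train_regularized_logistic",
    "model_bakeoff",
    "OvOStackClassifier",
    "train_ovo_stack",
    "predict_multiclass",
    "BAKEOFF_ALGORITHMS",
]


# ---------------------------------------------------------------------------
# partitioning


@dataclass(frozen=True)
class SplitSpec:
    """Stratified split specification (ratios are percentages)."""

    ratios: tuple[int, ...] = (60, 20, 20)
    strata: tuple[str, ...] = ("group", "hospital", "subgroup")
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.ratios) != 100:
            raise ValueError("split ratios must sum to 100")
        if not 2 <= len(self.ratios) <= 3:
            raise ValueError("supported splits have 2 or 3 sets")

    @property
    def set_names(self) -> tuple[str, ...]:
        return ("train", "test") if len(self.ratios) == 2 else (
            "train", "validation", "test")


def _allocate(m: int, ratios: Sequence[int]) -> list[int]:
    """Largest-remainder apportionment of m samples to the ratio targets."""
    exact = [m * r / 100.0 for r in ratios]
    base = [int(np.floor(e)) for e in exact]
    short = m - sum(base)
    remainders = sorted(
        range(len(ratios)), key=lambda i: (-(exact[i] - base[i]), i)
    )
    for i in remainders[:short]:
        base[i] += 1
    return base


def stratified_partition(metadata: pd.DataFrame, spec: SplitSpec) -> pd.Series:
    """Assign every sample to a split set, stratified on the spec's keys.

    Within each stratum cell (cross-product of the strata columns),
    samples are shuffled with the spec's seed and allocated by largest-
    remainder rounding.  Cells with fewer samples than split sets are
    collapsed to group-only strata (a warning is logged).
    """
    for key in spec.strata:
        if key not in metadata.columns:
            raise ValueError(f"stratification key {key!r} not in metadata")
    n_sets = len(spec.ratios)
    rng = np.random.default_rng(spec.seed)
    assignment = pd.Series(index=metadata.index, dtype=object, name="split")

    cells = list(metadata.groupby(list(spec.strata), sort=True).groups.items())
    small_idx: list = []
    kept_cells = []
    for key, idx in cells:
        if len(idx) < n_sets and spec.strata != ("group",):
            small_idx.extend(idx)
        else:
            kept_cells.append((key, idx))
    if small_idx:
        logger.warning(
            "%d samples in stratum cells smaller than %d sets; collapsed to "
            "group-only strata", len(small_idx), n_sets,
        )
        coarse = metadata.loc[small_idx].groupby("group", sort=True).groups.items()
        kept_cells.extend(coarse)

    for _, idx in kept_cells:
        idx = list(idx)
        order = rng.permutation(len(idx))
        sizes = _allocate(len(idx), spec.ratios)
        pos = 0
        for set_name, size in zip(spec.set_names, sizes):
            for k in order[pos : pos + size]:
                assignment.loc[idx[k]] = set_name
            pos += size
    return assignment


# ---------------------------------------------------------------------------
# scores, thresholds


def roc_auc(scores, labels, positive_label=None) -> float:
    """Trapezoidal / midrank ROC-AUC of scores against binary labels."""
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("roc_auc requires exactly two classes present")
    if positive_label is None:
        positive_label = classes[1]
    return float(roc_auc_score(labels == positive_label, np.asarray(scores, float)))


def youden_threshold(scores, labels, positive_label=None) -> float:
    """Score threshold maximizing Youden's J = sensitivity + specificity - 1.

    Candidates are the midpoints between consecutive sorted unique
    scores plus the two infinities; a sample is called positive when its
    score is >= the threshold.  Ties in J are broken toward the lowest
    threshold.  If all scores are identical J = 0 everywhere and the
    common score is returned with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("youden_threshold requires both classes present")
    if positive_label is None:
        positive_label = classes[1]
    pos = scores[labels == positive_label]
    neg = scores[labels != positive_label]
    uniq = np.unique(scores)
    if uniq.size == 1:
        warnings.warn("all scores identical; Youden's J is 0 everywhere")
        return float(uniq[0])
    candidates = np.concatenate(
        ([-np.inf], (uniq[:-1] + uniq[1:]) / 2.0, [np.inf])
    )
    best_t, best_j = candidates[0], -np.inf
    for t in candidates:
        j = (pos >= t).mean() + (neg < t).mean() - 1.0
        if j > best_j + 1e-15:
            best_j, best_t = j, t
    return float(best_t)


# ---------------------------------------------------------------------------
# penalized logistic along a lambda path


def _enet_logistic_path(
    X: np.ndarray,
    y: np.ndarray,
    lambdas: np.ndarray,
    alpha: float,
    tol: float = 1e-8,
    max_iter: int = 2000,
) -> list[tuple[np.ndarray, float]]:
    """Elastic-net logistic solutions along a decreasing penalty path.

    Minimizes, for each lambda,

        (1/n) sum_i log(1 + exp(-t_i (x_i'b + b0)))
        + lambda [ (1-alpha)/2 ||b||_2^2 + alpha ||b||_1 ]

    with the intercept b0 unpenalized, by accelerated proximal gradient
    (FISTA) with warm starts from the previous path point.  For
    ``lambda >= lambda_max`` the solution is b = 0 with b0 the empirical
    log-odds.  Returns one ``(coef, intercept)`` per lambda.
    """
    n, p = X.shape
    Xt = np.ascontiguousarray(X.T)
    # Lipschitz bound for the logistic part over [1, X]
    aug = np.column_stack([np.ones(n), X])
    L0 = float(np.linalg.norm(aug, 2)) ** 2 / (4.0 * n)
    ybar = y.mean()
    beta = np.zeros(p)
    b0 = float(np.log(ybar / (1.0 - ybar)))
    out: list[tuple[np.ndarray, float]] = []
    for i, lam in enumerate(lambdas):
        l1 = lam * alpha
        l2 = lam * (1.0 - alpha)
        step = 1.0 / (L0 + l2)
        # warm-started path points only need moderate precision; the
        # last point (the returned model) is solved tightly
        last = i == len(lambdas) - 1
        lam_tol = tol if last else max(tol, 3e-5)
        lam_iter = max_iter if last else min(max_iter, 250)
        zb, z0, t_acc = beta.copy(), b0, 1.0
        for _ in range(lam_iter):
            eta = np.clip(X @ zb + z0, -35.0, 35.0)
            mu = 1.0 / (1.0 + np.exp(-eta))
            grad_b = Xt @ (mu - y) / n + l2 * zb
            grad_0 = float((mu - y).mean())
            cand = zb - step * grad_b
            new_beta = np.sign(cand) * np.maximum(np.abs(cand) - step * l1, 0.0)
            new_b0 = z0 - step * grad_0
            t_new = (1.0 + np.sqrt(1.0 + 4.0 * t_acc * t_acc)) / 2.0
            mom = (t_acc - 1.0) / t_new
            zb = new_beta + mom * (new_beta - beta)
            z0 = new_b0 + mom * (new_b0 - b0)
            delta = max(np.max(np.abs(new_beta - beta), initial=0.0),
                        abs(new_b0 - b0))
            beta, b0, t_acc = new_beta, new_b0, t_new
            if delta < lam_tol:
                break
        out.append((beta.copy(), float(b0)))
    return out


class PenalizedLogisticClassifier(BaseEstimator, ClassifierMixin):
    """Elastic-net logistic regression with CV-AUC lambda selection.

    Parameters
    ----------
    alpha : float in [0, 1]
        Elastic-net mixing; 1 = LASSO, 0 = ridge.
    n_lambdas, lambda_min_ratio
        Log-spaced penalty path from lambda_max (smallest penalty giving
        an all-zero coefficient vector) down to
        ``lambda_max * lambda_min_ratio``.
    cv : int
        Stratified CV folds used to pick lambda by mean ROC-AUC.
    random_state : int or None
        Seeds the CV shuffling (the solver itself is deterministic).

    Fitted attributes include ``coef_``, ``intercept_``, ``lambda_``,
    ``selected_features_`` (non-zero coefficients), the standardization
    ``feature_means_`` / ``feature_scales_``, the path diagnostics
    ``lambda_path_`` / ``cv_auc_path_`` and the training-set
    ``youden_threshold_``.
    """

    def __init__(self, alpha: float = 1.0, n_lambdas: int = 100,
                 lambda_min_ratio: float = 1e-4, cv: int = 5,
                 max_iter: int = 2000, random_state: int | None = None):
        self.alpha = alpha
        self.n_lambdas = n_lambdas
        self.lambda_min_ratio = lambda_min_ratio
        self.cv = cv
        self.max_iter = max_iter
        self.random_state = random_state

    # lambda_max as in coordinate-descent GLM practice: the smallest
    # penalty at which every coefficient is zero
    @staticmethod
    def _lambda_max(Xs: np.ndarray, y01: np.ndarray, alpha: float) -> float:
        n = len(y01)
        resid = y01 - y01.mean()
        return float(np.max(np.abs(Xs.T @ resid)) / (n * max(alpha, 1e-3)))

    def _path_fit(self, Xs: np.ndarray, y01: np.ndarray, lambdas: np.ndarray):
        """Warm-started fits along the path; yields (lam, coef, intercept)."""
        sols = _enet_logistic_path(Xs, y01, lambdas, self.alpha,
                                   max_iter=self.max_iter)
        return [(lam, coef, b0) for lam, (coef, b0) in zip(lambdas, sols)]

    def fit(self, X, y):
        Xdf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(X)
        if Xdf.shape[1] == 0:
            raise ValueError("empty feature panel")
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("y contains a single class")
        if len(self.classes_) > 2:
            raise ValueError("binary classifier; use OvOStackClassifier")
        y01 = (y == self.classes_[1]).astype(float)

        Xarr = Xdf.to_numpy(dtype=float)
        self.feature_names_in_ = np.asarray(Xdf.columns, dtype=object)
        self.n_features_in_ = Xarr.shape[1]
        self.feature_means_ = Xarr.mean(axis=0)
        sd = Xarr.std(axis=0, ddof=0)
        self.feature_scales_ = np.where(sd > 0, sd, 1.0)
        Xs = (Xarr - self.feature_means_) / self.feature_scales_

        lam_max = self._lambda_max(Xs, y01, self.alpha)
        lambdas = np.geomspace(lam_max, lam_max * self.lambda_min_ratio,
                               self.n_lambdas)
        self.lambda_path_ = lambdas

        skf = StratifiedKFold(n_splits=self.cv, shuffle=True,
                              random_state=self.random_state)
        fold_aucs = np.zeros((self.cv, len(lambdas)))
        for f, (tr, va) in enumerate(skf.split(Xs, y01)):
            mu = Xs[tr].mean(axis=0)
            s = Xs[tr].std(axis=0, ddof=0)
            s = np.where(s > 0, s, 1.0)
            Xtr, Xva = (Xs[tr] - mu) / s, (Xs[va] - mu) / s
            if len(np.unique(y01[va])) < 2 or len(np.unique(y01[tr])) < 2:
                fold_aucs[f] = np.nan
                continue
            for k, (lam, coef, b0) in enumerate(
                self._path_fit(Xtr, y01[tr], lambdas)
            ):
                sc = Xva @ coef + b0
                if np.ptp(sc) == 0:
                    fold_aucs[f, k] = 0.5
                else:
                    fold_aucs[f, k] = roc_auc_score(y01[va], sc)
        mean_auc = np.nanmean(fold_aucs, axis=0)
        self.cv_auc_path_ = mean_auc
        # argmax with ties toward the larger (sparser) lambda, i.e. the
        # first index on the decreasing path
        best = int(np.argmax(np.round(mean_auc, 12)))
        path = self._path_fit(Xs, y01, lambdas[: best + 1])
        _, coef, b0 = path[-1]
        # a fully shrunk refit is dominated by any equally-scoring smaller
        # lambda whose refit keeps features; walk down within the CV tie
        while (np.abs(coef).max() == 0 and best + 1 < len(lambdas)
               and mean_auc[best + 1] >= mean_auc[best] - 1e-12
               and mean_auc[best] > 0.5):
            best += 1
            path = self._path_fit(Xs, y01, lambdas[: best + 1])
            _, coef, b0 = path[-1]
        self.lambda_ = float(lambdas[best])
        self.coef_ = coef[None, :]
        self.intercept_ = np.array([b0])
        self.selected_features_ = tuple(
            self.feature_names_in_[np.abs(coef) > 0]
        )
        train_scores = self.predict_proba(Xdf)[:, 1]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.youden_threshold_ = youden_threshold(
                train_scores, y, positive_label=self.classes_[1]
            )
        return self

    def _standardize(self, X) -> np.ndarray:
        Xdf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(
            X, columns=self.feature_names_in_
        )
        missing = [c for c in self.feature_names_in_ if c not in Xdf.columns]
        if missing:
            raise ValueError(f"missing panel genes in input: {missing[:10]}")
        Xarr = Xdf.loc[:, list(self.feature_names_in_)].to_numpy(dtype=float)
        return (Xarr - self.feature_means_) / self.feature_scales_

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "coef_")
        return self._standardize(X) @ self.coef_[0] + self.intercept_[0]

    def predict_proba(self, X) -> np.ndarray:
        z = self.decision_function(X)
        p = 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))
        return np.column_stack([1.0 - p, p])

    def predict(self, X) -> np.ndarray:
        """Youden-thresholded class calls (positive when score >= J*)."""
        p = self.predict_proba(X)[:, 1]
        return np.where(p >= self.youden_threshold_, self.classes_[1],
                        self.classes_[0])


def train_regularized_logistic(
    X, y, alpha: float = 1.0, n_folds: int = 5,
    lambda_grid: Sequence[float] | None = None, random_state: int | None = 0,
) -> PenalizedLogisticClassifier:
    """Functional wrapper over :class:`PenalizedLogisticClassifier`."""
    est = PenalizedLogisticClassifier(alpha=alpha, cv=n_folds,
                                      random_state=random_state)
    if lambda_grid is not None:
        lambda_grid = np.sort(np.asarray(lambda_grid, float))[::-1]
        est.n_lambdas = len(lambda_grid)

        est._lambda_max = lambda Xs, y01, a, _g=lambda_grid: float(_g[0])  # type: ignore
        est.lambda_min_ratio = float(lambda_grid[-1] / lambda_grid[0])
    return est.fit(X, y)


# ---------------------------------------------------------------------------
# bake-off harness


def _bakeoff_registry(seed: int | None) -> dict[str, tuple]:
    scaler = lambda est: Pipeline([("scale", StandardScaler()), ("model", est)])
    return {
        "lasso_logistic": (
            PenalizedLogisticClassifier(alpha=1.0, random_state=seed), None),
        "ridge_logistic": (
            PenalizedLogisticClassifier(alpha=0.0, random_state=seed), None),
        "random_forest": (
            RandomForestClassifier(random_state=seed),
            {"n_estimators": [500], "max_features": ["sqrt", 0.25]}),
        "linear_svm": (
            scaler(SVC(kernel="linear", random_state=seed)),
            {"model__C": [0.01, 0.1, 1.0, 10.0]}),
        "knn": (
            scaler(KNeighborsClassifier()),
            {"model__n_neighbors": [3, 5, 7, 11]}),
        "naive_bayes": (
            GaussianNB(), {"var_smoothing": [1e-9, 1e-6]}),
    }


BAKEOFF_ALGORITHMS = tuple(_bakeoff_registry(None))


def _score_samples(est, X, positive_class) -> np.ndarray:
    if hasattr(est, "predict_proba"):
        proba = est.predict_proba(X)
        classes = est.classes_ if hasattr(est, "classes_") else est[-1].classes_
        return proba[:, list(classes).index(positive_class)]
    return est.decision_function(X)


def _n_features_used(est, n_total: int) -> int:
    inner = est
    if isinstance(est, GridSearchCV):
        inner = est.best_estimator_
    if isinstance(inner, PenalizedLogisticClassifier):
        return len(inner.selected_features_)
    return n_total


def model_bakeoff(
    X_train, y_train, X_val, y_val,
    algorithms: Sequence[str] | None = None,
    seed: int | None = 0, cv: int = 5,
) -> tuple[pd.DataFrame, str, object]:
    """Train a set of algorithms and pick the best by validation AUC.

    Every algorithm is tuned on the training set only (5-fold stratified
    CV grid search, ROC-AUC scoring); the validation set is used solely
    to rank the tuned models.  Ties in validation AUC go to the model
    using fewer features, then to algorithm-name order.  The test set is
    never seen here.

    Returns ``(table, chosen_name, chosen_model)`` where ``table`` has
    one row per algorithm with ``val_auc`` and ``n_features``.
    """
    registry = _bakeoff_registry(seed)
    names = list(algorithms) if algorithms is not None else list(registry)
    if not names:
        raise ValueError("algorithm set is empty")
    y_val = np.asarray(y_val)
    if len(np.unique(y_val)) < 2:
        raise ValueError("validation set contains a single class")
    positive = np.unique(np.asarray(y_train))[1]

    rows, fitted = [], {}
    for name in names:
        est, grid = registry[name]
        if grid is None:
            model = clone(est).fit(X_train, y_train)
        else:
            model = GridSearchCV(
                clone(est), grid, scoring="roc_auc",
                cv=StratifiedKFold(cv, shuffle=True, random_state=seed),
                n_jobs=None,
            ).fit(np.asarray(X_train, float), np.asarray(y_train))
        val_scores = _score_samples(
            model, np.asarray(X_val, float) if grid is not None else X_val,
            positive)
        rows.append({
            "algorithm": name,
            "val_auc": roc_auc(val_scores, y_val, positive_label=positive),
            "n_features": _n_features_used(model, np.asarray(X_train).shape[1]),
        })
        fitted[name] = model
    table = pd.DataFrame(rows).set_index("algorithm")
    ranked = table.sort_values(
        by=["val_auc", "n_features"], ascending=[False, True], kind="stable"
    )
    # stable sort keeps name order among exact ties
    chosen = str(ranked.index[0])
    return table, chosen, fitted[chosen]


# ---------------------------------------------------------------------------
# one-vs-one stacking


class OvOStackClassifier(BaseEstimator, ClassifierMixin):
    """One-vs-one LASSO models stacked by a random-forest meta-classifier.

    For k classes, C(k,2) pairwise LASSO-logistic models are each
    trained on only that pair's training samples (restricted to the
    pair's gene panel); all training samples — including those outside
    the pair — are then scored by every pairwise model, and the
    resulting n x C(k,2) score matrix trains a 500-tree random forest
    against the k-class labels.  Per pair the "classification score" is
    the predicted probability of the lexicographically larger class.
    """

    def __init__(self, panels: Mapping | None = None, alpha: float = 1.0,
                 n_lambdas: int = 100, cv: int = 5, n_estimators: int = 500,
                 random_state: int | None = None):
        self.panels = panels
        self.alpha = alpha
        self.n_lambdas = n_lambdas
        self.cv = cv
        self.n_estimators = n_estimators
        self.random_state = random_state

    @staticmethod
    def _pair_key(a: str, b: str) -> tuple[str, str]:
        return tuple(sorted((str(a), str(b))))

    def _panel_genes(self, pair) -> list[str]:
        panels = self.panels or {}
        lookup = {self._pair_key(*k): v for k, v in panels.items()}
        if pair not in lookup:
            raise ValueError(f"missing gene panel for class pair {pair}")
        panel = lookup[pair]
        return list(panel.gene_ids) if hasattr(panel, "gene_ids") else list(panel)

    def fit(self, X, y):
        Xdf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(X)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes")
        from itertools import combinations

        self.pairs_ = [self._pair_key(a, b)
                       for a, b in combinations(self.classes_, 2)]
        base_seed = 0 if self.random_state is None else int(self.random_state)
        self.pair_models_ = {}
        for i, pair in enumerate(self.pairs_):
            genes = self._panel_genes(pair)
            missing = [g for g in genes if g not in Xdf.columns]
            if missing:
                raise ValueError(
                    f"panel genes absent from input for pair {pair}: "
                    f"{missing[:10]}")
            mask = np.isin(y, pair)
            est = PenalizedLogisticClassifier(
                alpha=self.alpha, n_lambdas=self.n_lambdas, cv=self.cv,
                random_state=base_seed + i,
            )
            est.fit(Xdf.loc[mask, genes], y[mask])
            self.pair_models_[pair] = est
        scores = self.score_matrix(Xdf)
        self.meta_ = RandomForestClassifier(
            n_estimators=self.n_estimators, max_features="sqrt",
            random_state=base_seed,
        ).fit(scores.to_numpy(), y)
        return self

    def score_matrix(self, X) -> pd.DataFrame:
        """n x C(k,2) matrix of pairwise positive-class probabilities."""
        check_is_fitted(self, "pair_models_")
        Xdf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(X)
        cols = {}
        for pair in self.pairs_:
            est = self.pair_models_[pair]
            genes = list(est.feature_names_in_)
            missing = [g for g in genes if g not in Xdf.columns]
            if missing:
                raise ValueError(
                    f"panel genes absent from input for pair {pair}: "
                    f"{missing[:10]}")
            # probability of the lexicographically larger class
            cols["|".join(pair)] = est.predict_proba(Xdf[genes])[:, 1]
        return pd.DataFrame(cols, index=Xdf.index)

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "meta_")
        return self.meta_.predict_proba(self.score_matrix(X).to_numpy())

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        # argmax takes the first (lexicographically smallest) class on ties
        return self.classes_[np.argmax(proba, axis=1)]


def train_ovo_stack(vst_train, labels, per_pair_panels, seed: int | None = 0,
                    **kwargs) -> OvOStackClassifier:
    """Functional wrapper over :class:`OvOStackClassifier`."""
    return OvOStackClassifier(panels=per_pair_panels, random_state=seed,
                              **kwargs).fit(vst_train, labels)


def predict_multiclass(model: OvOStackClassifier, vst_new) -> pd.DataFrame:
    """Class probabilities, ranked diagnoses and the argmax prediction.

    Returns a DataFrame indexed like the input with one probability
    column per class, a ``predicted`` column and a ``ranked`` column
    (classes ordered by descending probability).
    """
    Xdf = vst_new if isinstance(vst_new, pd.DataFrame) else pd.DataFrame(vst_new)
    proba = model.predict_proba(Xdf)
    out = pd.DataFrame(proba, columns=list(model.classes_), index=Xdf.index)
    order = np.argsort(-proba, axis=1, kind="stable")
    out["predicted"] = model.classes_[order[:, 0]]
    out["ranked"] = [tuple(model.classes_[row]) for row in order]
    return out
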