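"""End-to-end orchestration: QC -> split -> normalize -> DE -> panels ->
classifiers -> deconvolution -> per-patient reports.

Three entry points, each consuming a count matrix plus sample metadata
(e.g. a :class:`~cfrna.synthetic.SyntheticCohort`):

``run_binary_path``
    The two-group path (e.g. KD vs MIS-C): 60:20:20 stratified split,
    differential abundance on the training set, filter-cascade panel,
    model bake-off ranked on the validation set, Youden threshold from
    training scores, final evaluation on the untouched test set.

``run_multiclass_path``
    The one-vs-one stacked path over four disease classes: 70:30 split,
    per-pair DE + top-N panels on the training set, six pairwise LASSO
    models stacked by a random forest, argmax prediction on test.

``run_report_pipeline``
    The multiclass path plus cell-type deconvolution, healthy-donor
    organ statistics and a report per passing test sample.

Held-out labels are only read at the final evaluation step; models are
fit exclusively on training data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import (
    OvOStackClassifier,
    SplitSpec,
    model_bakeoff,
    predict_multiclass,
    roc_auc,
    stratified_partition,
)
from .deconv import deconvolve
from .diffexp import run_de
from .features import FilterCriteria, GenePanel, select_panel
from .normalize import NormalizationModel, fit_normalization, project_new_samples, vst
from .qc import QCThresholds, apply_qc
from .report import (
    DEFAULT_ORGAN_MAP,
    HealthyStats,
    PatientReport,
    build_report,
    healthy_stats,
    organ_zscores,
)

__all__ = [
    "BinaryPathResult",
    "MulticlassPathResult",
    "ReportPipelineResult",
    "run_binary_path",
    "run_multiclass_path",
    "run_report_pipeline",
]

DEFAULT_CLASSES = ("KD", "MIS-C", "bacterial", "viral")
_STRATA = ("group", "hospital", "subgroup")


def _qc_pass(counts: pd.DataFrame, metadata: pd.DataFrame,
             thresholds: QCThresholds | None):
    qc_table = apply_qc(metadata, thresholds)
    passing = qc_table.index[qc_table["passed"]]
    return qc_table, counts.loc[:, passing], metadata.loc[passing]


@dataclass
class BinaryPathResult:
    split: pd.Series
    de_result: pd.DataFrame
    panel: GenePanel
    normalization: NormalizationModel
    bakeoff_table: pd.DataFrame
    chosen_algorithm: str
    model: object
    youden_threshold: float
    auc: dict[str, float]
    accuracy: dict[str, float]
    scores: dict[str, pd.Series]
    qc_table: pd.DataFrame


def run_binary_path(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    group_a: str = "KD",
    group_b: str = "MIS-C",
    seed: int = 0,
    criteria: FilterCriteria | str = "misc_kd",
    algorithms: Sequence[str] = ("lasso_logistic",),
    ratios: tuple[int, ...] = (60, 20, 20),
    qc_thresholds: QCThresholds | None = None,
    split: pd.Series | None = None,
) -> BinaryPathResult:
    """Binary classification path between two disease groups."""
    qc_table, counts, metadata = _qc_pass(counts, metadata, qc_thresholds)
    mask = metadata["group"].isin([group_a, group_b])
    meta2 = metadata.loc[mask]
    counts2 = counts.loc[:, meta2.index]
    if split is None:
        split = stratified_partition(meta2, SplitSpec(ratios, _STRATA, seed))
    else:
        split = split.reindex(meta2.index)
    names = split.dropna().unique()
    train_ids = split.index[split == "train"]
    val_name = "validation" if "validation" in names else "test"

    train_counts = counts2.loc[:, train_ids]
    norm = fit_normalization(train_counts)
    de = run_de(train_counts, meta2.loc[train_ids, "group"].to_numpy(),
                group_a, group_b)
    panel = select_panel(de, criteria, name=f"{group_a}_vs_{group_b}")
    genes = list(panel.gene_ids)

    X = {"train": vst(train_counts, norm).T[genes]}
    y = {"train": meta2.loc[train_ids, "group"]}
    for set_name in names:
        if set_name == "train":
            continue
        ids = split.index[split == set_name]
        X[set_name] = project_new_samples(norm, counts2.loc[:, ids]).T[genes]
        y[set_name] = meta2.loc[ids, "group"]

    table, chosen, model = model_bakeoff(
        X["train"], y["train"].to_numpy(),
        X[val_name], y[val_name].to_numpy(),
        algorithms=algorithms, seed=seed,
    )
    positive = max(group_a, group_b)
    scores = {
        name: pd.Series(_model_scores(model, X[name], positive), index=X[name].index)
        for name in X
    }
    threshold = getattr(model, "youden_threshold_", None)
    if threshold is None:
        from .classify import youden_threshold as _yt
        threshold = _yt(scores["train"].to_numpy(), y["train"].to_numpy(),
                        positive_label=positive)
    auc = {name: roc_auc(scores[name].to_numpy(), y[name].to_numpy(),
                         positive_label=positive)
           for name in X if len(np.unique(y[name])) == 2}
    accuracy = {}
    for name in X:
        calls = np.where(scores[name].to_numpy() >= threshold, positive,
                         min(group_a, group_b))
        accuracy[name] = float((calls == y[name].to_numpy()).mean())
    return BinaryPathResult(
        split=split, de_result=de, panel=panel, normalization=norm,
        bakeoff_table=table, chosen_algorithm=chosen, model=model,
        youden_threshold=float(threshold), auc=auc, accuracy=accuracy,
        scores=scores, qc_table=qc_table,
    )


def _model_scores(model, X, positive_class) -> np.ndarray:
    if hasattr(model, "predict_proba"):
        proba = model.predict_proba(X)
        classes = getattr(model, "classes_", None)
        if classes is None:  # pipeline / grid search
            classes = model.best_estimator_.classes_
        return proba[:, list(classes).index(positive_class)]
    return model.decision_function(np.asarray(X, float))


@dataclass
class MulticlassPathResult:
    split: pd.Series
    normalization: NormalizationModel
    de_results: dict[tuple[str, str], pd.DataFrame]
    panels: dict[tuple[str, str], GenePanel]
    stack: OvOStackClassifier
    train_predictions: pd.DataFrame
    test_predictions: pd.DataFrame
    train_accuracy: float
    test_accuracy: float
    qc_table: pd.DataFrame
    metadata: pd.DataFrame = field(repr=False, default=None)
    counts: pd.DataFrame = field(repr=False, default=None)


def run_multiclass_path(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    classes: Sequence[str] = DEFAULT_CLASSES,
    seed: int = 0,
    criteria: FilterCriteria | str = "multiclass_pairwise",
    ratios: tuple[int, ...] = (70, 30),
    qc_thresholds: QCThresholds | None = None,
    n_lambdas: int = 100,
    split: pd.Series | None = None,
) -> MulticlassPathResult:
    """One-vs-one stacked multiclass path over the given disease classes.

    ``split`` can supply a precomputed train/test assignment (indexed by
    sample id); otherwise a stratified partition is drawn from ``seed``.
    """
    qc_table, counts, metadata = _qc_pass(counts, metadata, qc_thresholds)
    mask = metadata["group"].isin(list(classes))
    meta2 = metadata.loc[mask]
    counts2 = counts.loc[:, meta2.index]
    if split is None:
        split = stratified_partition(meta2, SplitSpec(ratios, _STRATA, seed))
    else:
        split = split.reindex(meta2.index)
    train_ids = split.index[split == "train"]
    test_ids = split.index[split == "test"]

    train_counts = counts2.loc[:, train_ids]
    labels_train = meta2.loc[train_ids, "group"]
    norm = fit_normalization(train_counts)
    vst_train = vst(train_counts, norm).T

    de_results, panels = {}, {}
    for a, b in combinations(sorted(classes), 2):
        pair_mask = labels_train.isin([a, b]).to_numpy()
        de = run_de(train_counts.loc[:, pair_mask],
                    labels_train[pair_mask].to_numpy(), a, b)
        de_results[(a, b)] = de
        panels[(a, b)] = select_panel(de, criteria, name=f"{a}_vs_{b}")

    stack = OvOStackClassifier(panels=panels, random_state=seed,
                               n_lambdas=n_lambdas)
    stack.fit(vst_train, labels_train.to_numpy())

    vst_test = project_new_samples(norm, counts2.loc[:, test_ids]).T
    train_pred = predict_multiclass(stack, vst_train)
    test_pred = predict_multiclass(stack, vst_test)
    train_acc = float(
        (train_pred["predicted"].to_numpy() == labels_train.to_numpy()).mean())
    test_acc = float(
        (test_pred["predicted"].to_numpy()
         == meta2.loc[test_ids, "group"].to_numpy()).mean())
    return MulticlassPathResult(
        split=split, normalization=norm, de_results=de_results, panels=panels,
        stack=stack, train_predictions=train_pred, test_predictions=test_pred,
        train_accuracy=train_acc, test_accuracy=test_acc, qc_table=qc_table,
        metadata=metadata, counts=counts,
    )


@dataclass
class ReportPipelineResult:
    multiclass: MulticlassPathResult
    fractions: pd.DataFrame
    healthy: HealthyStats
    zscores: pd.DataFrame
    reports: dict[str, PatientReport]


def run_report_pipeline(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    reference,
    classes: Sequence[str] = DEFAULT_CLASSES,
    seed: int = 0,
    criteria: FilterCriteria | str = "multiclass_pairwise",
    qc_thresholds: QCThresholds | None = None,
    organ_map: Mapping | None = None,
    borderline_margin: float = 0.10,
    n_lambdas: int = 100,
) -> ReportPipelineResult:
    """Full pipeline ending in a report per passing multiclass test sample."""
    mc = run_multiclass_path(counts, metadata, classes=classes, seed=seed,
                             criteria=criteria, qc_thresholds=qc_thresholds,
                             n_lambdas=n_lambdas)
    organ_map = dict(organ_map or DEFAULT_ORGAN_MAP)
    # deconvolve every passing sample (healthy included, for the z reference)
    fractions = deconvolve(mc.counts, reference)
    healthy_ids = mc.metadata.index[mc.metadata["group"] == "healthy"]
    stats = healthy_stats(fractions, healthy_ids, organ_map)
    z = organ_zscores(fractions, stats, organ_map)

    reports: dict[str, PatientReport] = {}
    class_cols = list(mc.stack.classes_)
    for sample_id, row in mc.test_predictions.iterrows():
        probs = {c: float(row[c]) for c in class_cols}
        reports[sample_id] = build_report(
            sample_id,
            probs,
            z.loc[sample_id].to_dict(),
            qc_status="pass",
            borderline_margin=borderline_margin,
            low_confidence_organs=stats.floored_organs,
        )
    return ReportPipelineResult(
        multiclass=mc, fractions=fractions, healthy=stats, zscores=z,
        reports=reports,
    )
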