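"""Gene-panel selection from differential-abundance results.

A filter cascade keeps genes that are simultaneously significant
(BH-adjusted p), abundant (base mean), discriminative (per-gene ROC-AUC,
counted symmetrically so markers of either group survive) and strongly
changed (absolute log2 fold change); optionally the survivors are ranked
by symmetric AUC and truncated to a fixed panel size.

Shipped presets:

``misc_kd``
    q < 0.01, base mean > 100, AUC > 0.65, |log2FC| > 0.25 — the binary
    KD-vs-MIS-C cascade.
``multiclass_pairwise``
    q < 0.05, base mean > 50, |log2FC| > 1, top 150 by AUC — the panel
    used per pairwise model inside the one-vs-one multiclass stack.
``covid_vs_other_viral``
    q < 0.01, base mean > 100, AUC > 0.65, |log2FC| > 0.25, top 150 by
    AUC — the intra-viral COVID-19 contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["FilterCriteria", "GenePanel", "select_panel", "PRESETS"]


@dataclass(frozen=True)
class FilterCriteria:
    q_max: float
    base_mean_min: float
    abs_lfc_min: float
    auc_min: Optional[float] = None
    top_n: Optional[int] = None
    rank_by: str = "gene_auc"

    def __post_init__(self) -> None:
        if min(self.q_max, self.base_mean_min) <= 0 or self.abs_lfc_min < 0:
            raise ValueError("filter thresholds must be positive")
        if self.auc_min is not None and self.auc_min <= 0:
            raise ValueError("auc_min must be positive")
        if self.top_n is not None and self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        if self.rank_by != "gene_auc":
            raise ValueError("only rank_by='gene_auc' is supported")


PRESETS: dict[str, FilterCriteria] = {
    "misc_kd": FilterCriteria(q_max=0.01, base_mean_min=100, auc_min=0.65,
                              abs_lfc_min=0.25),
    "multiclass_pairwise": FilterCriteria(q_max=0.05, base_mean_min=50,
                                          abs_lfc_min=1.0, top_n=150),
    "covid_vs_other_viral": FilterCriteria(q_max=0.01, base_mean_min=100,
                                           auc_min=0.65, abs_lfc_min=0.25,
                                           top_n=150),
}


@dataclass(frozen=True)
class GenePanel:
    name: str
    gene_ids: tuple[str, ...]
    provenance: dict

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValueError("a gene panel cannot be empty")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate genes in panel")

    def __len__(self) -> int:
        return len(self.gene_ids)


def select_panel(
    de_result: pd.DataFrame,
    criteria: FilterCriteria | str,
    name: str = "panel",
    de_run_id: str = "",
) -> GenePanel:
    """Apply the filter cascade to a DE result table.

    ``de_result`` must carry ``qvalue``, ``base_mean``, ``log2fc`` and —
    when the criteria include an AUC floor or a top-N ranking — ``auc``.
    The AUC rule is two-sided: a gene passes when ``max(auc, 1 - auc)``
    exceeds the floor, so down-markers are retained.  With ``top_n``,
    survivors are ordered by symmetric AUC descending (ties broken by
    ascending q then gene id) and truncated.

    Raises ``ValueError`` naming the first filter that emptied the set.
    """
    if isinstance(criteria, str):
        criteria = PRESETS[criteria]
    df = de_result
    needed = {"qvalue", "base_mean", "log2fc"}
    if criteria.auc_min is not None or criteria.top_n is not None:
        needed.add("auc")
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"DE result is missing columns: {sorted(missing)}")

    stages = [
        ("qvalue", df["qvalue"] < criteria.q_max),
        ("base_mean", df["base_mean"] > criteria.base_mean_min),
        ("abs_log2fc", df["log2fc"].abs() > criteria.abs_lfc_min),
    ]
    if criteria.auc_min is not None:
        sym = np.maximum(df["auc"], 1.0 - df["auc"])
        stages.append(("auc", sym > criteria.auc_min))

    mask = pd.Series(True, index=df.index)
    for stage_name, stage_mask in stages:
        mask &= stage_mask.fillna(False)
        if not mask.any():
            raise ValueError(
                f"filter {stage_name!r} left no genes in panel {name!r}"
            )
    kept = df.loc[mask].copy()
    kept["_sym_auc"] = np.maximum(kept["auc"], 1.0 - kept["auc"]) if "auc" in kept else 0.0
    kept["_gene"] = kept.index.astype(str)
    kept = kept.sort_values(
        by=["_sym_auc", "qvalue", "_gene"], ascending=[False, True, True],
        kind="stable",
    )
    if criteria.top_n is not None:
        kept = kept.head(criteria.top_n)
    return GenePanel(
        name=name,
        gene_ids=tuple(kept.index.astype(str)),
        provenance={"criteria": asdict(criteria), "de_run_id": de_run_id,
                    "n_input_genes": int(len(df))},
    )
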