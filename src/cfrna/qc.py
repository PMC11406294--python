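"""Sample-level quality control for cfRNA sequencing libraries.

Three rules, applied to per-sample QC metrics computed upstream of the
count matrix:

* DNA contamination: intron-to-exon read ratio greater than 3 fails;
* sequencing depth: fewer than 75,000 total feature counts fails;
* RNA degradation: 5'-3' read-coverage bias greater than 2 fails.

All comparisons are strict, so a sample sitting exactly on a boundary
passes.  rRNA contamination is recorded when present but carries no
filter threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["QCThresholds", "apply_qc", "QC_METRIC_COLUMNS"]

QC_METRIC_COLUMNS = ("intron_exon_ratio", "total_counts", "bias_5to3")


@dataclass(frozen=True)
class QCThresholds:
    max_intron_exon: float = 3.0
    min_total_counts: int = 75_000
    max_bias: float = 2.0

    def __post_init__(self) -> None:
        if min(self.max_intron_exon, self.min_total_counts, self.max_bias) <= 0:
            raise ValueError("QC thresholds must be positive")


def apply_qc(
    metrics: pd.DataFrame, thresholds: QCThresholds | None = None
) -> pd.DataFrame:
    """Evaluate the three QC rules for every sample.

    Parameters
    ----------
    metrics
        Table indexed by (or containing) ``sample_id`` with the columns
        ``intron_exon_ratio``, ``total_counts`` and ``bias_5to3``.
    thresholds
        Rule boundaries; defaults to the standard thresholds (3 / 75,000
        / 2).

    Returns
    -------
    DataFrame indexed by sample id with ``passed`` (bool) and ``reasons``
    (semicolon-joined names of every violated rule; empty when passing).
    A sample fails iff ratio > max, counts < min, or bias > max — strict
    inequalities, so boundary values pass.
    """
    thresholds = thresholds or QCThresholds()
    table = metrics.set_index("sample_id") if "sample_id" in metrics.columns else metrics
    for col in QC_METRIC_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"QC metrics table is missing column {col!r}")
        vals = pd.to_numeric(table[col], errors="coerce")
        bad = table.index[~np.isfinite(vals.to_numpy(dtype=float))]
        if len(bad):
            raise ValueError(
                f"sample {bad[0]!r} has missing or non-finite QC metric {col!r}"
            )

    ratio = table["intron_exon_ratio"].to_numpy(dtype=float)
    counts = table["total_counts"].to_numpy(dtype=float)
    bias = table["bias_5to3"].to_numpy(dtype=float)

    checks = {
        "intron_exon": ratio > thresholds.max_intron_exon,
        "total_counts": counts < thresholds.min_total_counts,
        "bias_5to3": bias > thresholds.max_bias,
    }
    fail_any = np.zeros(len(table), dtype=bool)
    reasons = [[] for _ in range(len(table))]
    for name, mask in checks.items():
        fail_any |= mask
        for i in np.flatnonzero(mask):
            reasons[i].append(name)

    return pd.DataFrame(
        {"passed": ~fail_any, "reasons": [";".join(r) for r in reasons]},
        index=table.index,
    )
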