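"""Per-patient clinical decision-support reports.

Each report combines the multiclass classifier's probability vector
(ranked diagnoses, with a "borderline" flag when the top two
probabilities are close) with organ-injury z-scores: per organ, the
mapped cell-type fractions are summed and standardized against the
healthy-donor distribution (mean/sd over healthy samples).  Z-scores use
the raw (unscaled) fractions — the cohort min-max scaling is a plotting
convention, while z-scoring already standardizes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_ORGAN_MAP",
    "HealthyStats",
    "PatientReport",
    "healthy_stats",
    "organ_zscores",
    "build_report",
]

#: organ -> contributing cell types in the deconvolution output
DEFAULT_ORGAN_MAP: dict[str, tuple[str, ...]] = {
    "endothelium": ("endothelial cell",),
    "heart": ("cardiac muscle cell",),
    "liver": ("hepatocyte",),
    "lung": ("club cell", "type I pneumocyte"),
    "neuronal": ("Schwann cell",),
}

_SD_FLOOR = 1e-8


def _organ_fractions(fractions: pd.DataFrame, organ_map) -> pd.DataFrame:
    cols = {}
    for organ, cell_types in organ_map.items():
        missing = [ct for ct in cell_types if ct not in fractions.columns]
        if missing:
            raise ValueError(
                f"organ {organ!r} maps to cell types absent from fractions: "
                f"{missing}")
        cols[organ] = fractions[list(cell_types)].sum(axis=1)
    return pd.DataFrame(cols, index=fractions.index)


@dataclass(frozen=True)
class HealthyStats:
    """Mean/sd of each organ's summed fraction over healthy donors."""

    means: pd.Series
    sds: pd.Series
    n_healthy: int
    floored_organs: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_healthy < 2:
            raise ValueError("need at least 2 healthy samples")
        if (self.sds < 0).any():
            raise ValueError("sd must be nonnegative")


def healthy_stats(fractions: pd.DataFrame, healthy_sample_ids,
                  organ_map=None) -> HealthyStats:
    """Healthy-donor distribution of organ fractions (n-1 sd denominator).

    Organs whose healthy sd is 0 get the 1e-8 floor and are flagged; the
    z-scores computed against them carry a low-confidence flag.
    """
    organ_map = organ_map or DEFAULT_ORGAN_MAP
    ids = [s for s in healthy_sample_ids if s in fractions.index]
    if len(ids) < 2:
        raise ValueError("need at least 2 healthy samples with fractions")
    organ = _organ_fractions(fractions.loc[ids], organ_map)
    means = organ.mean(axis=0)
    sds = organ.std(axis=0, ddof=1)
    floored = tuple(sds.index[sds < _SD_FLOOR])
    sds = sds.clip(lower=_SD_FLOOR)
    return HealthyStats(means=means, sds=sds, n_healthy=len(ids),
                        floored_organs=floored)


def organ_zscores(fractions: pd.DataFrame, stats: HealthyStats,
                  organ_map=None) -> pd.DataFrame:
    """Per-sample, per-organ z = (organ fraction - healthy mean)/healthy sd."""
    organ_map = organ_map or DEFAULT_ORGAN_MAP
    organ = _organ_fractions(fractions, organ_map)
    if set(organ.columns) != set(stats.means.index):
        raise ValueError("organ map does not match the healthy stats organs")
    return (organ - stats.means) / stats.sds


@dataclass
class PatientReport:
    """Diagnostic probabilities plus organ-injury z-scores for one sample."""

    sample_id: str
    class_probabilities: dict[str, float]
    ranked_diagnoses: tuple[str, ...]
    organ_zscores: dict[str, float]
    qc_status: str
    borderline: bool
    borderline_margin: float
    low_confidence_organs: tuple[str, ...] = ()
    binary_score: float | None = None
    binary_call: str | None = None
    model_version: str = "cfrna-report-1"

    def to_dict(self) -> dict:
        d = {
            "schema": self.model_version,
            "sample_id": self.sample_id,
            "class_probabilities": self.class_probabilities,
            "ranked_diagnoses": list(self.ranked_diagnoses),
            "organ_zscores": self.organ_zscores,
            "qc_status": self.qc_status,
            "borderline": self.borderline,
            "borderline_margin": self.borderline_margin,
            "low_confidence_organs": list(self.low_confidence_organs),
        }
        if self.binary_score is not None:
            d["binary_score"] = self.binary_score
            d["binary_call"] = self.binary_call
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PatientReport":
        d = json.loads(text)
        return cls(
            sample_id=d["sample_id"],
            class_probabilities=d["class_probabilities"],
            ranked_diagnoses=tuple(d["ranked_diagnoses"]),
            organ_zscores=d["organ_zscores"],
            qc_status=d["qc_status"],
            borderline=d["borderline"],
            borderline_margin=d["borderline_margin"],
            low_confidence_organs=tuple(d.get("low_confidence_organs", ())),
            binary_score=d.get("binary_score"),
            binary_call=d.get("binary_call"),
            model_version=d.get("schema", "cfrna-report-1"),
        )

    def to_markdown(self) -> str:
        lines = [
            f"# cfRNA report — {self.sample_id}",
            "",
            f"QC: {self.qc_status}",
            "",
            "## Diagnostic predictions",
            "",
            "| rank | condition | probability |",
            "| --- | --- | --- |",
        ]
        for i, cls_name in enumerate(self.ranked_diagnoses, start=1):
            lines.append(
                f"| {i} | {cls_name} | {self.class_probabilities[cls_name]!r} |")
        if self.borderline:
            lines.append("")
            lines.append(
                f"**Borderline call**: top two probabilities differ by less "
                f"than {self.borderline_margin!r}.")
        if self.binary_score is not None:
            lines.append("")
            lines.append(
                f"KD-vs-MIS-C score: {self.binary_score!r} "
                f"(call: {self.binary_call})")
        lines += ["", "## Organ involvement (z vs healthy donors)", "",
                  "| organ | z-score |", "| --- | --- |"]
        for organ, z in self.organ_zscores.items():
            flag = " (low confidence)" if organ in self.low_confidence_organs else ""
            lines.append(f"| {organ} | {z!r}{flag} |")
        return "\n".join(lines) + "\n"


def build_report(
    sample_id: str,
    class_probabilities: dict[str, float],
    zscores: dict[str, float],
    qc_status: str = "pass",
    borderline_margin: float = 0.10,
    low_confidence_organs=(),
    binary_score: float | None = None,
    binary_call: str | None = None,
) -> PatientReport:
    """Assemble a :class:`PatientReport` from model outputs.

    Diagnoses are ranked by probability descending (ties alphabetical);
    the borderline flag is set when the top two probabilities differ by
    less than ``borderline_margin``.  The probability vector must sum to
    1 within 1e-6.
    """
    total = float(sum(class_probabilities.values()))
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"class probabilities sum to {total}, not 1")
    ranked = tuple(sorted(class_probabilities,
                          key=lambda c: (-class_probabilities[c], c)))
    probs = [class_probabilities[c] for c in ranked]
    borderline = len(probs) >= 2 and (probs[0] - probs[1]) < borderline_margin
    return PatientReport(
        sample_id=str(sample_id),
        class_probabilities={k: float(v) for k, v in class_probabilities.items()},
        ranked_diagnoses=ranked,
        organ_zscores={k: float(v) for k, v in zscores.items()},
        qc_status=qc_status,
        borderline=bool(borderline),
        borderline_margin=float(borderline_margin),
        low_confidence_organs=tuple(low_confidence_organs),
        binary_score=None if binary_score is None else float(binary_score),
        binary_call=binary_call,
    )
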