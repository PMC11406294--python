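"""Cell-type-of-origin deconvolution and group comparison of fractions.

Each sample's relative gene abundance vector is modeled as a convex
mixture of cell-type reference profiles.  Fractions are recovered per
sample by non-negative least squares against the row-normalized
reference,

    theta = argmin_{theta >= 0} || x - R^T theta ||_2 ,

then renormalized to sum to 1 — a deterministic estimator with the same
input/output contract as Bayesian deconvolution tools (reference
profiles in, per-sample fractions out).  Fractions can be min-max
scaled per cell type across the cohort for plotting, and two-group
contrasts (e.g. high-vs-normal ALT) are tested per cell type with the
Wilcoxon rank-sum test and BH adjustment.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.stats import mannwhitneyu

from .diffexp import bh_adjust

__all__ = [
    "deconvolve",
    "scale_fractions",
    "ScaledFractions",
    "compare_groups",
    "alt_strata",
    "cardiac_strata",
    "severity_strata",
]


def _reference_frame(reference) -> pd.DataFrame:
    if hasattr(reference, "to_frame"):
        return reference.to_frame()
    return reference if isinstance(reference, pd.DataFrame) else pd.DataFrame(reference)


def deconvolve(counts, reference) -> pd.DataFrame:
    """Estimate cell-type fractions for every sample (samples x cell types).

    ``counts`` is genes x samples; ``reference`` is cell types x genes
    (rows are renormalized over the shared gene space).  The estimate is
    invariant to per-sample count rescaling since each sample is first
    normalized to relative abundance.
    """
    cdf = counts if isinstance(counts, pd.DataFrame) else pd.DataFrame(counts)
    ref = _reference_frame(reference)
    shared = cdf.index.intersection(ref.columns)
    if len(shared) < ref.shape[0]:
        raise ValueError(
            f"only {len(shared)} genes shared between counts and reference; "
            f"need at least {ref.shape[0]}")
    R = ref.loc[:, shared].to_numpy(dtype=float)
    R = R / R.sum(axis=1, keepdims=True)
    if np.linalg.matrix_rank(R) < R.shape[0]:
        raise ValueError("reference is rank-deficient on the shared genes; "
                         "fractions are not identifiable")
    A = R.T  # genes x cell types
    out = np.empty((cdf.shape[1], R.shape[0]))
    X = cdf.loc[shared].to_numpy(dtype=float)
    for j in range(cdf.shape[1]):
        x = X[:, j]
        total = x.sum()
        if total <= 0:
            raise ValueError(f"sample {cdf.columns[j]!r} has zero counts on "
                             "the shared genes")
        theta, _ = nnls(A, x / total)
        s = theta.sum()
        out[j] = theta / s if s > 0 else np.full(R.shape[0], 1.0 / R.shape[0])
    return pd.DataFrame(out, index=cdf.columns, columns=ref.index)


class ScaledFractions(NamedTuple):
    values: pd.DataFrame  # samples x cell types, min-max scaled per column
    constant_cell_types: tuple[str, ...]  # columns flagged as degenerate


def scale_fractions(fractions: pd.DataFrame) -> ScaledFractions:
    """Min-max scale each cell-type column to [0, 1] across the cohort.

    Constant columns cannot be scaled; they are set to 0 and flagged.
    Idempotent on non-degenerate columns.
    """
    if fractions.empty:
        raise ValueError("empty fractions table")
    arr = fractions.to_numpy(dtype=float)
    lo = arr.min(axis=0)
    hi = arr.max(axis=0)
    span = hi - lo
    constant = span == 0
    span_safe = np.where(constant, 1.0, span)
    scaled = (arr - lo) / span_safe
    scaled[:, constant] = 0.0
    return ScaledFractions(
        values=pd.DataFrame(scaled, index=fractions.index,
                            columns=fractions.columns),
        constant_cell_types=tuple(fractions.columns[constant]),
    )


def _wilcoxon(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided rank-sum p; exact enumeration for small groups."""
    method = "exact" if (len(a) <= 10 and len(b) <= 10
                         and len(np.unique(np.concatenate([a, b])))
                         == len(a) + len(b)) else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def compare_groups(
    fractions: pd.DataFrame, strata: pd.Series,
    group_a: str | None = None, group_b: str | None = None,
) -> pd.DataFrame:
    """Per-cell-type two-group Wilcoxon rank-sum comparison.

    ``strata`` assigns each sample to one of two groups (NaN/other
    values are dropped).  Returns a table per cell type with group
    sizes, group medians of the (min-max scaled) fractions, U statistic,
    raw p and BH q across cell types (one family per contrast).
    """
    strata = strata.reindex(fractions.index)
    levels = [lv for lv in pd.unique(strata.dropna())]
    if group_a is None or group_b is None:
        if len(levels) != 2:
            raise ValueError(f"expected exactly two groups, got {levels}")
        group_a, group_b = sorted(map(str, levels))
    mask_a = (strata.astype(str) == group_a).to_numpy()
    mask_b = (strata.astype(str) == group_b).to_numpy()
    if mask_a.sum() == 0 or mask_b.sum() == 0:
        raise ValueError(
            f"a group is empty after stratification ({group_a}: "
            f"{int(mask_a.sum())}, {group_b}: {int(mask_b.sum())})")
    scaled = scale_fractions(fractions.loc[mask_a | mask_b]).values
    in_a = mask_a[mask_a | mask_b]
    rows = []
    for ct in fractions.columns:
        a = fractions.loc[mask_a, ct].to_numpy(dtype=float)
        b = fractions.loc[mask_b, ct].to_numpy(dtype=float)
        stat, p = _wilcoxon(a, b)
        rows.append({
            "cell_type": ct,
            "n_a": len(a), "n_b": len(b),
            "median_a": float(np.median(scaled.loc[in_a, ct])),
            "median_b": float(np.median(scaled.loc[~in_a, ct])),
            "statistic": stat, "pvalue": p,
        })
    out = pd.DataFrame(rows).set_index("cell_type")
    out["qvalue"] = bh_adjust(out["pvalue"].to_numpy())
    out.attrs["groups"] = (group_a, group_b)
    return out


def alt_strata(metadata: pd.DataFrame, alt_column: str = "alt") -> pd.Series:
    """High- vs normal-ALT stratification for the liver contrast.

    normal: ALT < 40 IU/L; high: ALT > 100 IU/L; samples with ALT in
    [40, 100] (or missing) are excluded (NaN).
    """
    alt = pd.to_numeric(metadata[alt_column], errors="coerce")
    out = pd.Series(np.nan, index=metadata.index, dtype=object, name="alt_group")
    out[alt < 40] = "normal"
    out[alt > 100] = "high"
    return out


def cardiac_strata(metadata: pd.DataFrame,
                   column: str = "cardiac_function") -> pd.Series:
    """Normal vs abnormal cardiac function stratification."""
    vals = metadata[column].astype(str)
    out = pd.Series(np.nan, index=metadata.index, dtype=object,
                    name="cardiac_group")
    out[vals == "normal"] = "normal"
    out[vals == "abnormal"] = "abnormal"
    return out


def severity_strata(metadata: pd.DataFrame,
                    column: str = "covid_severity") -> pd.Series:
    """Moderate vs severe COVID-19 stratification (non-COVID excluded)."""
    vals = metadata[column].astype(str)
    out = pd.Series(np.nan, index=metadata.index, dtype=object,
                    name="severity_group")
    out[vals == "moderate"] = "moderate"
    out[vals == "severe"] = "severe"
    return out
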