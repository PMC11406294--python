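"""Negative-binomial differential abundance between two sample groups.

Per gene, counts are modeled as NB with a log link,

    E[K_ij] = s_j * exp(b0 + b1 * x_j),   Var = mu + phi * mu^2,

with ``x_j`` the group indicator and the dispersion ``phi_i`` held fixed
(gene-wise estimates floored at the fitted trend).  The two-parameter
GLM is fit by iteratively reweighted least squares, vectorized across
genes; ``log2fc = b1/ln 2`` and the Wald statistic ``b1/se(b1)`` gives a
two-sided normal p-value.  Benjamini–Hochberg adjustment is applied per
comparison, and a per-gene ROC-AUC is computed on VST values as a
threshold-free effect size.
"""

from __future__ import annotations

from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from statsmodels.stats.multitest import multipletests

from .normalize import fit_normalization, vst

__all__ = [
    "nb_wald_test",
    "bh_adjust",
    "gene_auc",
    "intersect_dag_sets",
    "run_de",
]

_MAX_ITER = 100
_TOL = 1e-8
_ETA_BOUND = 30.0


def nb_wald_test(
    counts,
    size_factors,
    dispersions,
    condition,
    group_a: str,
    group_b: str,
) -> pd.DataFrame:
    """Per-gene NB Wald test of group B vs group A.

    Parameters
    ----------
    counts : genes x samples nonnegative integer matrix (DataFrame).
    size_factors : per-sample size factor aligned with columns.
    dispersions : per-gene NB dispersion (fixed during fitting).
    condition : per-sample group label aligned with columns.
    group_a, group_b : the two labels to contrast (log2fc is B over A).

    Returns a DataFrame per gene with ``base_mean``, ``log2fc``, ``se``,
    ``stat``, ``pvalue``, ``qvalue``.  All-zero genes and non-converged
    fits get NA statistics and are excluded from the BH family.
    """
    df = counts if isinstance(counts, pd.DataFrame) else pd.DataFrame(counts)
    cond = np.asarray(condition)
    in_a = cond == group_a
    in_b = cond == group_b
    if in_a.sum() == 0 or in_b.sum() == 0:
        raise ValueError(f"both groups must be non-empty ({group_a}: {in_a.sum()}, "
                         f"{group_b}: {in_b.sum()})")
    keep = in_a | in_b
    K = df.to_numpy(dtype=float)[:, keep]
    s = np.asarray(size_factors, dtype=float)[keep]
    x = in_b[keep].astype(float)
    phi = np.asarray(dispersions, dtype=float)
    G, n = K.shape

    base_mean = (K / s[None, :]).mean(axis=1)
    nonzero = K.sum(axis=1) > 0

    # vectorized IRLS for the 2-parameter log-link NB GLM with offsets
    off = np.log(s)[None, :]
    b0 = np.log(np.clip(base_mean, 1e-8, None))[:, None]
    b1 = np.zeros((G, 1))
    converged = np.zeros(G, dtype=bool)
    active = nonzero.copy()
    se = np.full(G, np.nan)
    for _ in range(_MAX_ITER):
        if not active.any():
            break
        eta = np.clip(off + b0 + b1 * x[None, :], -_ETA_BOUND, _ETA_BOUND)
        mu = np.exp(eta)
        w = mu / (1.0 + phi[:, None] * mu)  # NB working weights, log link
        z = (b0 + b1 * x[None, :]) + (K - mu) / mu  # working response minus offset
        S0 = w.sum(axis=1)
        S1 = (w * x[None, :]).sum(axis=1)
        T0 = (w * z).sum(axis=1)
        T1 = (w * x[None, :] * z).sum(axis=1)
        det = S0 * S1 - S1 * S1  # x binary: sum(w x^2) = S1
        ok = active & (det > 1e-12)
        nb0 = np.where(ok, (S1 * T0 - S1 * T1) / np.where(det > 0, det, 1.0), b0[:, 0])
        nb1 = np.where(ok, (S0 * T1 - S1 * T0) / np.where(det > 0, det, 1.0), b1[:, 0])
        nb0 = np.clip(nb0, -50.0, 50.0)
        nb1 = np.clip(nb1, -50.0, 50.0)
        delta = np.maximum(np.abs(nb0 - b0[:, 0]), np.abs(nb1 - b1[:, 0]))
        b0 = nb0[:, None]
        b1 = nb1[:, None]
        newly = ok & (delta < _TOL)
        converged |= newly
        active &= ~newly

    # standard errors from the Fisher information at the final fit
    eta = np.clip(off + b0 + b1 * x[None, :], -_ETA_BOUND, _ETA_BOUND)
    mu = np.exp(eta)
    w = mu / (1.0 + phi[:, None] * mu)
    S0 = w.sum(axis=1)
    S1 = (w * x[None, :]).sum(axis=1)
    det = S0 * S1 - S1 * S1
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(np.where(det > 0, S0 / det, np.nan))

    valid = nonzero & converged & np.isfinite(se)
    log2fc = np.where(valid, b1[:, 0] / np.log(2.0), np.nan)
    stat = np.where(valid, b1[:, 0] / se, np.nan)
    pvalue = np.where(valid, 2.0 * norm.sf(np.abs(stat)), np.nan)
    out = pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": log2fc,
            "se": np.where(valid, se / np.log(2.0), np.nan),
            "stat": stat,
            "pvalue": pvalue,
        },
        index=df.index,
    )
    out["qvalue"] = bh_adjust(out["pvalue"])
    return out


def bh_adjust(p_values) -> pd.Series | np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values.

    NAs are excluded from the family size m and returned as NA.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    finite = np.isfinite(p)
    if finite.any():
        vals = p[finite]
        if (vals < 0).any() or (vals > 1).any():
            raise ValueError("p-values must lie in [0, 1]")
        out[finite] = multipletests(vals, method="fdr_bh")[1]
    if isinstance(p_values, pd.Series):
        return pd.Series(out, index=p_values.index, name="qvalue")
    return out


def gene_auc(values, labels, group_a: str, group_b: str) -> pd.Series:
    """Per-gene ROC-AUC of group B vs group A on transformed abundances.

    Computed as the Mann-Whitney U statistic with midrank tie handling,
    ``AUC_i = P(value_B > value_A) + 0.5 P(tie)``; identical to the
    trapezoidal ROC area.
    """
    df = values if isinstance(values, pd.DataFrame) else pd.DataFrame(values)
    lab = np.asarray(labels)
    in_a = lab == group_a
    in_b = lab == group_b
    n_a, n_b = int(in_a.sum()), int(in_b.sum())
    if n_a == 0 or n_b == 0:
        raise ValueError("both groups must be non-empty for gene AUC")
    sub = df.to_numpy(dtype=float)[:, in_a | in_b]
    is_b = in_b[in_a | in_b]
    ranks = rankdata(sub, axis=1)
    rank_sum_b = ranks[:, is_b].sum(axis=1)
    u = rank_sum_b - n_b * (n_b + 1) / 2.0
    return pd.Series(u / (n_a * n_b), index=df.index, name="auc")


def intersect_dag_sets(named_gene_sets: Mapping[str, Sequence[str]]) -> pd.DataFrame:
    """Exclusive intersection counts over all non-empty membership patterns.

    UpSet semantics: each gene in the union is attributed to exactly the
    pattern of sets that contain it, so pattern counts sum to the union
    size.  Returns a table with one row per non-empty pattern, columns
    ``sets`` (tuple of member set names) and ``count``, sorted by count
    descending then pattern.
    """
    names = list(named_gene_sets)
    if len(names) != len(set(names)):
        raise ValueError("duplicate set names")
    if len(names) < 2:
        raise ValueError("need at least 2 named sets")
    sets = {name: set(named_gene_sets[name]) for name in names}
    union = set().union(*sets.values())
    membership: dict[tuple[str, ...], int] = {}
    for gene in union:
        pattern = tuple(name for name in names if gene in sets[name])
        membership[pattern] = membership.get(pattern, 0) + 1
    rows = []
    for r in range(1, len(names) + 1):
        for pattern in combinations(names, r):
            if pattern in membership:
                rows.append({"sets": pattern, "count": membership[pattern]})
    out = pd.DataFrame(rows, columns=["sets", "count"])
    return out.sort_values(
        by=["count", "sets"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)


def run_de(counts, condition, group_a: str, group_b: str) -> pd.DataFrame:
    """Full two-group differential-abundance run on raw counts.

    Fits normalization (size factors, dispersions, trend) on the given
    samples, moderates gene dispersions by flooring at the trend, runs
    the NB Wald test, BH adjustment, and appends the per-gene ROC-AUC on
    VST values.
    """
    df = counts if isinstance(counts, pd.DataFrame) else pd.DataFrame(counts)
    cond = np.asarray(condition)
    keep = (cond == group_a) | (cond == group_b)
    sub = df.loc[:, keep]
    model = fit_normalization(sub)
    res = nb_wald_test(
        sub,
        model.size_factors.loc[sub.columns],
        model.moderated_dispersions(),
        cond[keep],
        group_a,
        group_b,
    )
    res["auc"] = gene_auc(vst(sub, model), cond[keep], group_a, group_b)
    return res
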