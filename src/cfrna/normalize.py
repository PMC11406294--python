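"""Size factors, dispersion trend and the variance-stabilizing transform.

Counts are made comparable across sequencing depths with median-of-ratios
size factors.  Gene-wise negative-binomial dispersions (variance =
mu + phi*mu^2) are estimated by method of moments on normalized counts
and summarized by the parametric trend phi(mu) = a0 + a1/mu, fit
robustly.  The trend defines a closed-form variance-stabilizing
transform (VST) which is applied on the log2-like scale.

Train/apply separation is strict: a fitted :class:`NormalizationModel`
stores the training pseudo-reference and trend, and new samples are
projected one at a time against that frozen state — their size factors
come from the training pseudo-reference and the dispersion trend is
never refit.  This keeps held-out data from influencing the transform.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "NormalizationModel",
    "estimate_size_factors",
    "fit_dispersion",
    "fit_normalization",
    "vst",
    "nb_vst",
    "project_new_samples",
    "VSTNormalizer",
]


def _as_count_frame(counts) -> pd.DataFrame:
    df = counts if isinstance(counts, pd.DataFrame) else pd.DataFrame(counts)
    arr = df.to_numpy()
    if (np.asarray(arr) < 0).any():
        raise ValueError("counts must be nonnegative")
    return df


def estimate_size_factors(counts) -> pd.Series:
    """Median-of-ratios size factors.

    For each sample j, ``s_j = median_i(K_ij / g_i)`` where ``g_i`` is
    the geometric mean of gene i across samples and the median runs over
    "usable" genes — those with no zero count in any sample.
    """
    df = _as_count_frame(counts)
    arr = df.to_numpy(dtype=float)
    usable = (arr > 0).all(axis=1)
    if not usable.any():
        raise ValueError(
            "no gene has all-positive counts across samples; size factors "
            "are undefined (a pseudo-reference fallback is not applied silently)"
        )
    log_g = np.log(arr[usable]).mean(axis=1)
    ratios = arr[usable] / np.exp(log_g)[:, None]
    s = np.median(ratios, axis=0)
    return pd.Series(s, index=df.columns, name="size_factor")


def _pseudo_reference(counts: pd.DataFrame) -> pd.Series:
    """Per-gene geometric mean of counts; NaN where any count is zero."""
    arr = counts.to_numpy(dtype=float)
    usable = (arr > 0).all(axis=1)
    ref = np.full(arr.shape[0], np.nan)
    ref[usable] = np.exp(np.log(arr[usable]).mean(axis=1))
    return pd.Series(ref, index=counts.index, name="pseudo_reference")


def _fit_trend(phi: np.ndarray, mu: np.ndarray, n_iter: int = 10) -> tuple[float, float]:
    """Robust nonnegative fit of phi ~ a0 + a1/mu.

    Iteratively reweighted least squares with Tukey bisquare weights on
    MAD-scaled residuals; coefficients constrained >= 0 via NNLS.
    """
    A = np.column_stack([np.ones_like(mu), 1.0 / mu])
    w = np.ones_like(phi)
    a = np.array([0.0, 0.0])
    for _ in range(n_iter):
        sw = np.sqrt(w)
        a, _ = nnls(A * sw[:, None], phi * sw)
        resid = phi - A @ a
        scale = np.median(np.abs(resid - np.median(resid))) * 1.4826
        if scale <= 0:
            break
        u = resid / (4.685 * scale)
        w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
        if w.sum() < 2:  # degenerate reweighting; keep previous fit
            break
    return float(max(a[0], 0.0)), float(max(a[1], 0.0))


def fit_dispersion(counts, size_factors) -> tuple[pd.Series, float, float]:
    """Gene-wise method-of-moments dispersions and the parametric trend.

    ``phi_i = max(0, (v_i - m_i) / m_i^2)`` on normalized counts
    ``q_ij = K_ij / s_j`` (sample variance ``v_i``, mean ``m_i``); the
    trend ``phi(mu) = a0 + a1/mu`` is fit over genes with positive
    dispersion estimates.
    """
    df = _as_count_frame(counts)
    if df.shape[1] < 2:
        raise ValueError("need at least 2 samples to estimate dispersion")
    s = np.asarray(size_factors, dtype=float)
    q = df.to_numpy(dtype=float) / s[None, :]
    mu = q.mean(axis=1)
    v = q.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.where(mu > 0, (v - mu) / mu**2, 0.0)
    phi = np.clip(phi, 0.0, None)
    pos = phi > 0
    if pos.sum() < 10:
        raise ValueError(
            "fewer than 10 genes with positive dispersion; trend unidentifiable"
        )
    a0, a1 = _fit_trend(phi[pos], mu[pos])
    return pd.Series(phi, index=df.index, name="dispersion"), a0, a1


@dataclass
class NormalizationModel:
    """Frozen training-state needed to transform and to project new samples."""

    size_factors: pd.Series  # per training sample
    pseudo_reference: pd.Series  # per gene; NaN where unusable
    dispersions: pd.Series  # gene-wise method-of-moments phi
    a0: float  # trend asymptotic dispersion
    a1: float  # trend extra-Poisson coefficient
    gene_means: pd.Series  # mean normalized counts (training)
    version: str = "cfrna-normalization-1"

    @property
    def gene_ids(self) -> pd.Index:
        return self.pseudo_reference.index

    def trend(self, mu) -> np.ndarray:
        """Trend dispersion at mean(s) mu."""
        mu = np.asarray(mu, dtype=float)
        with np.errstate(divide="ignore"):
            return self.a0 + self.a1 / mu

    def moderated_dispersions(self) -> pd.Series:
        """Gene-wise phi floored at the trend value (used for testing)."""
        tr = self.trend(np.clip(self.gene_means.to_numpy(), 1e-8, None))
        return pd.Series(
            np.maximum(self.dispersions.to_numpy(), tr),
            index=self.dispersions.index,
            name="moderated_dispersion",
        )

    def to_json(self) -> str:
        payload = {
            "version": self.version,
            "a0": self.a0,
            "a1": self.a1,
            "sample_ids": list(map(str, self.size_factors.index)),
            "size_factors": self.size_factors.to_numpy().tolist(),
            "gene_ids": list(map(str, self.pseudo_reference.index)),
            "pseudo_reference": [
                None if not np.isfinite(v) else v
                for v in self.pseudo_reference.to_numpy()
            ],
            "dispersions": self.dispersions.to_numpy().tolist(),
            "gene_means": self.gene_means.to_numpy().tolist(),
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "NormalizationModel":
        d = json.loads(text)
        genes = pd.Index(d["gene_ids"])
        ref = pd.Series(
            [np.nan if v is None else v for v in d["pseudo_reference"]],
            index=genes, name="pseudo_reference",
        )
        return cls(
            size_factors=pd.Series(d["size_factors"],
                                   index=pd.Index(d["sample_ids"]),
                                   name="size_factor"),
            pseudo_reference=ref,
            dispersions=pd.Series(d["dispersions"], index=genes,
                                  name="dispersion"),
            a0=float(d["a0"]),
            a1=float(d["a1"]),
            gene_means=pd.Series(d["gene_means"], index=genes,
                                 name="gene_mean"),
            version=d.get("version", "cfrna-normalization-1"),
        )


def fit_normalization(counts) -> NormalizationModel:
    """Fit size factors, dispersions and trend on a training count matrix."""
    df = _as_count_frame(counts)
    s = estimate_size_factors(df)
    phi, a0, a1 = fit_dispersion(df, s)
    q = df.to_numpy(dtype=float) / s.to_numpy()[None, :]
    return NormalizationModel(
        size_factors=s,
        pseudo_reference=_pseudo_reference(df),
        dispersions=phi,
        a0=a0,
        a1=a1,
        gene_means=pd.Series(q.mean(axis=1), index=df.index, name="gene_mean"),
    )


def nb_vst(q, a0: float, a1: float):
    """Closed-form variance stabilizer for variance mu(1+a1) + a0*mu^2.

    ``h(q) = log2((1 + a1 + 2 a0 q + 2 sqrt(a0 q (1 + a1 + a0 q))) / (4 a0))``,
    strictly increasing in q with ``h(q) - log2(q) -> const`` as q grows.
    For a0 = 0 (no asymptotic dispersion) the transform degenerates to the
    square-root stabilizer ``2 sqrt(q / (1 + a1))``.
    """
    q = np.asarray(q, dtype=float)
    if (q < 0).any():
        raise ValueError("normalized counts must be nonnegative")
    if a0 <= 0:
        return 2.0 * np.sqrt(q / (1.0 + a1))
    t = a0 * q
    return np.log2((1.0 + a1 + 2.0 * t + 2.0 * np.sqrt(t * (1.0 + a1 + t))) / (4.0 * a0))


def vst(counts, model: NormalizationModel):
    """Transform counts of training samples with their stored size factors."""
    df = _as_count_frame(counts)
    if not df.index.equals(model.gene_ids):
        raise ValueError("gene ids do not match the fitted model")
    missing = df.columns.difference(model.size_factors.index)
    if len(missing):
        raise ValueError(
            f"samples not in the training set: {list(missing[:5])}; "
            "use project_new_samples for unseen samples"
        )
    s = model.size_factors.loc[df.columns].to_numpy()
    q = df.to_numpy(dtype=float) / s[None, :]
    return pd.DataFrame(nb_vst(q, model.a0, model.a1), index=df.index, columns=df.columns)


def project_new_samples(
    model: NormalizationModel, counts_new, min_usable: int = 50
):
    """Transform unseen samples against the frozen training model.

    Each new sample's size factor is the median of ``K_i / ref_i`` over
    training-usable genes; the training trend (a0, a1) is then applied.
    The result for a sample never depends on which other samples are in
    the batch.
    """
    df = _as_count_frame(counts_new)
    # per-sample purity: usable-gene set must not depend on batch
    # composition, so restrict to genes positive in *this* sample only
    out = {}
    aligned = df.reindex(model.gene_ids)
    if aligned.isna().any().any():
        raise ValueError("new samples are missing genes present in the model")
    ref_all = model.pseudo_reference
    for sample in df.columns:
        col = aligned[sample].to_numpy(dtype=float)
        ok = ref_all.notna().to_numpy() & (col > 0)
        if ok.sum() < min_usable:
            raise ValueError(
                f"sample {sample!r} shares only {int(ok.sum())} usable genes "
                f"with the training pseudo-reference (<{min_usable})"
            )
        s = float(np.median(col[ok] / ref_all.to_numpy()[ok]))
        out[sample] = nb_vst(col / s, model.a0, model.a1)
    return pd.DataFrame(out, index=model.gene_ids)


def new_sample_size_factors(model: NormalizationModel, counts_new) -> pd.Series:
    """Size factors of unseen samples vs the training pseudo-reference."""
    df = _as_count_frame(counts_new).reindex(model.gene_ids)
    ref = model.pseudo_reference.to_numpy()
    vals = {}
    for sample in df.columns:
        col = df[sample].to_numpy(dtype=float)
        ok = np.isfinite(ref) & (col > 0)
        vals[sample] = float(np.median(col[ok] / ref[ok]))
    return pd.Series(vals, name="size_factor")


class VSTNormalizer(BaseEstimator, TransformerMixin):
    """Variance-stabilizing normalizer with train/apply separation.

    scikit-learn transformer over ``X`` of shape (n_samples, n_genes)
    (note: transposed relative to the genes-by-samples convention of the
    functional API).  ``fit`` estimates size factors, gene dispersions
    and the dispersion trend on the training samples; ``transform``
    projects any samples — training or unseen — against the frozen
    training pseudo-reference and trend.

    Attributes
    ----------
    model_ : NormalizationModel
    size_factors_ : ndarray of training size factors
    dispersions_ : ndarray of gene-wise dispersions
    trend_coef_ : (a0, a1)
    """

    def __init__(self, min_usable: int = 50):
        self.min_usable = min_usable

    def fit(self, X, y=None):
        X = X if isinstance(X, pd.DataFrame) else pd.DataFrame(X)
        self.model_ = fit_normalization(X.T)
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        self.size_factors_ = self.model_.size_factors.to_numpy()
        self.dispersions_ = self.model_.dispersions.to_numpy()
        self.trend_coef_ = (self.model_.a0, self.model_.a1)
        return self

    def transform(self, X):
        check_is_fitted(self, "model_")
        X = X if isinstance(X, pd.DataFrame) else pd.DataFrame(
            X, columns=self.feature_names_in_
        )
        out = project_new_samples(self.model_, X.T, min_usable=self.min_usable)
        return out.T.loc[X.index]

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "model_")
        return self.feature_names_in_
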