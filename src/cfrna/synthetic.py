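"""Synthetic plasma cfRNA cohort generator.

Plasma cell-free RNA is a mixture of transcripts released by dying cells
from many tissues, sequenced to a library size that varies by orders of
magnitude between samples.  The generator emulates exactly the structure
the downstream pipeline assumes:

* each sample's expected expression is a convex mixture of cell-type
  reference profiles (mixture weights drawn from a per-group Dirichlet),
* disease groups carry planted, disjoint gene signatures (fold changes on
  top of the mixture), plus an optional shared "inflammation" signature
  common to every disease group,
* counts are negative-binomial (variance = mu + phi*mu^2) around the
  library-size-scaled mixture,
* QC metrics are drawn from passing ranges except for a planted fraction
  of samples that each fail exactly one QC rule,
* clinical covariates are tied to the true cell-type fractions (ALT to
  hepatocyte, cardiac-function flag to cardiac muscle, COVID severity to
  the lung fractions).

Ground truth (mixture fractions, planted genes, realized fold changes,
dispersions) is returned alongside the data for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CellTypeReference",
    "CovariateParams",
    "SimulationConfig",
    "CohortTruth",
    "SyntheticCohort",
    "make_reference",
    "simulate_cohort",
    "simulate_clinical_covariates",
    "default_config",
]

#: canonical cell types; the first six are the ones the organ map and the
#: clinical covariates refer to.
DEFAULT_CELL_TYPES = (
    "hepatocyte",
    "cardiac muscle cell",
    "endothelial cell",
    "club cell",
    "type I pneumocyte",
    "Schwann cell",
    "monocyte",
    "neutrophil",
)

GROUPS = ("KD", "MIS-C", "viral", "bacterial", "healthy", "other")
DISEASE_GROUPS = ("KD", "MIS-C", "viral", "bacterial", "other")
HOSPITALS = ("UCSD", "Emory", "CNH", "UCSF")


@dataclass(frozen=True)
class CellTypeReference:
    """Relative expression profiles of the cell types cfRNA can derive from.

    ``profiles`` is (cell types x genes); every row is a probability
    vector (sums to 1).  Each cell type has a disjoint block of marker
    genes with strongly elevated relative expression, which makes the
    mixture identifiable for deconvolution.
    """

    cell_type_ids: tuple[str, ...]
    gene_ids: tuple[str, ...]
    profiles: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.profiles, dtype=float)
        if p.shape != (len(self.cell_type_ids), len(self.gene_ids)):
            raise ValueError("profiles shape does not match id lists")
        if len(set(self.cell_type_ids)) != len(self.cell_type_ids):
            raise ValueError("duplicate cell type ids")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if (p < 0).any():
            raise ValueError("reference profiles must be nonnegative")
        if not np.allclose(p.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("reference rows must sum to 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.profiles, index=list(self.cell_type_ids), columns=list(self.gene_ids)
        )


@dataclass(frozen=True)
class CovariateParams:
    """Links between true cell-type fractions and clinical covariates.

    ALT (IU/L) is affine in the hepatocyte fraction; the cardiac-function
    flag thresholds the cardiac-muscle fraction at a cohort quantile with
    an optional mislabel rate; the severity ordinal (0/1/2) follows the
    summed lung fractions (club cell + type I pneumocyte) with additive
    noise before binning at the cohort terciles.
    """

    alt_intercept: float = 10.0
    alt_slope: float = 500.0
    alt_noise_sd: float = 8.0
    cardiac_quantile: float = 0.75
    cardiac_mislabel_rate: float = 0.05
    severity_noise_sd: float = 0.02


@dataclass
class SimulationConfig:
    """All knobs of the cohort generator, with cohort-scale defaults.

    Defaults mirror the study cohort: ~370 samples over six groups with
    KD and MIS-C the two largest, heavily overdispersed counts and
    library sizes well above the 75,000-count QC floor except for the
    planted QC failures.
    """

    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: {
            "KD": 101,
            "MIS-C": 97,
            "viral": 80,
            "bacterial": 30,
            "healthy": 40,
            "other": 22,
        }
    )
    n_genes: int = 5000
    n_cell_types: int = 8
    dirichlet_alpha: Mapping[str, Sequence[float]] | None = None
    signature_size: int = 60
    signature_log2fc: float = 1.5
    shared_signature_size: int = 100
    dispersion_mean: float = 0.3
    library_size_range: tuple[float, float] = (100_000.0, 600_000.0)
    qc_fail_fraction: float = 0.05
    covariate_params: CovariateParams = field(default_factory=CovariateParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be nonnegative")
        if self.signature_size > self.n_genes:
            raise ValueError("signature_size cannot exceed n_genes")
        if self.library_size_range[0] <= 0:
            raise ValueError("library_size_range minimum must be positive")
        if not 0.0 <= self.qc_fail_fraction <= 1.0:
            raise ValueError("qc_fail_fraction must lie in [0, 1]")
        unknown = set(self.group_sizes) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown groups: {sorted(unknown)}")


#: per-group Dirichlet concentrations over DEFAULT_CELL_TYPES, chosen so
#: that MIS-C/KD show liver, cardiac and endothelial involvement, viral
#: shows lung involvement, bacterial is neutrophil-dominated, and blood
#: cell types dominate every profile (as in plasma cfRNA).
DEFAULT_DIRICHLET_ALPHA: dict[str, tuple[float, ...]] = {
    "healthy": (1.0, 0.6, 1.2, 0.5, 0.5, 0.4, 6.0, 8.0),
    "KD": (1.5, 2.0, 3.0, 0.7, 0.7, 0.5, 5.0, 7.0),
    "MIS-C": (3.0, 2.5, 2.5, 0.8, 0.8, 0.5, 5.0, 7.0),
    "viral": (1.0, 0.8, 1.0, 2.0, 2.0, 0.4, 6.0, 6.0),
    "bacterial": (0.8, 0.6, 1.0, 0.5, 0.5, 0.3, 4.0, 12.0),
    "other": (1.0, 1.0, 1.5, 0.8, 0.8, 0.5, 5.0, 7.0),
}


@dataclass
class CohortTruth:
    """Ground truth recorded for recovery tests."""

    fractions: pd.DataFrame  # samples x cell types, rows sum to 1
    planted_genes: dict[str, list[str]]  # group -> planted gene ids
    realized_log2fc: dict[str, pd.Series]  # group -> per-gene delta
    shared_genes: list[str]
    dispersions: pd.Series  # per-gene true NB dispersion
    library_sizes: pd.Series  # per-sample target library size


@dataclass
class SyntheticCohort:
    counts: pd.DataFrame  # genes x samples, nonnegative integers
    metadata: pd.DataFrame  # indexed by sample_id, 1:1 with count columns
    truth: CohortTruth


def make_reference(
    n_cell_types: int,
    n_genes: int,
    seed: int = 0,
    cell_type_names: Sequence[str] | None = None,
    marker_fold: float = 20.0,
) -> CellTypeReference:
    """Build a synthetic cell-type reference with disjoint marker blocks.

    Every cell type shares a common log-normal baseline, perturbed per
    cell type, and receives a disjoint block of marker genes whose
    relative expression is multiplied by ``marker_fold``; rows are then
    normalized to sum to 1.  The disjoint markers make the profile matrix
    full rank, so mixtures are identifiable.
    """
    if n_cell_types < 2:
        raise ValueError("need at least 2 cell types")
    if n_genes < n_cell_types:
        raise ValueError("need at least as many genes as cell types")
    if cell_type_names is None:
        cell_type_names = [
            DEFAULT_CELL_TYPES[i] if i < len(DEFAULT_CELL_TYPES) else f"cell_type_{i + 1}"
            for i in range(n_cell_types)
        ]
    elif len(cell_type_names) != n_cell_types:
        raise ValueError("cell_type_names length must equal n_cell_types")

    rng = np.random.default_rng(seed)
    gene_ids = tuple(f"gene_{i + 1:05d}" for i in range(n_genes))
    baseline = rng.lognormal(mean=0.0, sigma=1.2, size=n_genes)
    profiles = baseline * rng.lognormal(mean=0.0, sigma=0.4, size=(n_cell_types, n_genes))

    n_markers = max(1, min(50, n_genes // (2 * n_cell_types)))
    marker_genes = rng.choice(n_genes, size=n_markers * n_cell_types, replace=False)
    for c in range(n_cell_types):
        block = marker_genes[c * n_markers : (c + 1) * n_markers]
        profiles[c, block] *= marker_fold
    profiles /= profiles.sum(axis=1, keepdims=True)
    return CellTypeReference(tuple(cell_type_names), gene_ids, profiles)


def default_config(**overrides) -> SimulationConfig:
    """A `SimulationConfig` at the cohort-scale defaults, with overrides."""
    return SimulationConfig(**overrides)


def _plant_signatures(
    config: SimulationConfig,
    reference: CellTypeReference,
    rng: np.random.Generator,
) -> tuple[dict[str, np.ndarray], list[int]]:
    """Choose disjoint planted gene sets (per disease group + shared)."""
    mean_expr = reference.profiles.mean(axis=0)
    # plant only on reasonably expressed genes so effects are detectable
    eligible = np.flatnonzero(mean_expr > np.median(mean_expr))
    groups = [g for g in config.group_sizes if g in DISEASE_GROUPS]
    need = config.signature_size * len(groups) + config.shared_signature_size
    if need > eligible.size:
        raise ValueError("not enough expressed genes to plant disjoint signatures")
    chosen = rng.choice(eligible, size=need, replace=False)
    shared = list(chosen[: config.shared_signature_size])
    per_group: dict[str, np.ndarray] = {}
    off = config.shared_signature_size
    for g in groups:
        per_group[g] = chosen[off : off + config.signature_size]
        off += config.signature_size
    return per_group, shared


def simulate_cohort(
    config: SimulationConfig, reference: CellTypeReference
) -> SyntheticCohort:
    """Draw a full synthetic cohort (counts, metadata, truth) from ``config``.

    Deterministic given ``config.seed``.  Hospital labels are assigned
    independently of the counts (no batch effect).  The healthy group
    carries no planted signature; disease groups additionally share the
    common inflammation signature when ``shared_signature_size > 0``.
    """
    if len(reference.gene_ids) != config.n_genes:
        raise ValueError("reference gene count must equal config.n_genes")
    if len(reference.cell_type_ids) != config.n_cell_types:
        raise ValueError("reference cell type count must equal config.n_cell_types")

    if config.dirichlet_alpha is not None:
        alphas = dict(config.dirichlet_alpha)
    else:
        # adapt the default 8-type vectors to the requested width
        alphas = {
            g: tuple(v[i] if i < len(v) else 1.0 for i in range(config.n_cell_types))
            for g, v in DEFAULT_DIRICHLET_ALPHA.items()
        }
    for g in config.group_sizes:
        if g not in alphas:
            raise ValueError(f"no Dirichlet alpha for group {g!r}")
        if len(alphas[g]) != config.n_cell_types:
            raise ValueError(
                f"Dirichlet alpha for group {g!r} has length {len(alphas[g])}, "
                f"expected {config.n_cell_types}"
            )

    rng = np.random.default_rng(config.seed)
    G = config.n_genes
    R = reference.profiles  # (C, G)

    per_group, shared_idx = _plant_signatures(config, reference, rng)

    sample_ids: list[str] = []
    groups_col: list[str] = []
    theta_rows: list[np.ndarray] = []
    k = 0
    for g, n in config.group_sizes.items():
        theta = rng.dirichlet(np.asarray(alphas[g], dtype=float), size=n)
        for j in range(n):
            sample_ids.append(f"S{k + 1:04d}")
            groups_col.append(g)
            theta_rows.append(theta[j])
            k += 1
    n_samples = k
    theta_mat = np.vstack(theta_rows) if n_samples else np.empty((0, config.n_cell_types))

    # realized per-group log2 effects (jitter proportional to the effect,
    # so a zero configured effect is exactly null)
    realized: dict[str, pd.Series] = {}
    delta = {}
    jitter_sd = 0.1 * abs(config.signature_log2fc)
    for g, idx in per_group.items():
        d = np.zeros(G)
        d[idx] = config.signature_log2fc + jitter_sd * rng.standard_normal(idx.size)
        if shared_idx:
            d[shared_idx] = config.signature_log2fc + jitter_sd * rng.standard_normal(
                len(shared_idx)
            )
        delta[g] = d
        realized[g] = pd.Series(
            d[np.concatenate([idx, np.asarray(shared_idx, dtype=int)]) if shared_idx else idx],
            index=[reference.gene_ids[i] for i in
                   (np.concatenate([idx, np.asarray(shared_idx, dtype=int)]) if shared_idx else idx)],
            name=g,
        )

    dispersions = (
        rng.lognormal(mean=np.log(config.dispersion_mean), sigma=0.3, size=G)
        if config.dispersion_mean > 0
        else np.zeros(G)
    )

    lo, hi = config.library_size_range
    library = rng.uniform(lo, hi, size=n_samples)

    # planted QC failures: each fails exactly one rule, cycling the rules
    n_fail = int(round(config.qc_fail_fraction * n_samples))
    fail_ids = rng.choice(n_samples, size=n_fail, replace=False) if n_fail else np.array([], int)
    fail_rule = {int(s): ("intron_exon", "total_counts", "bias_5to3")[i % 3]
                 for i, s in enumerate(fail_ids)}
    for s, rule in fail_rule.items():
        if rule == "total_counts":
            library[s] = rng.uniform(20_000.0, 60_000.0)

    counts = np.empty((G, n_samples), dtype=np.int64)
    for j in range(n_samples):
        g = groups_col[j]
        x = theta_mat[j] @ R
        if g in delta:
            x = x * np.exp2(delta[g])
        x = x / x.sum()
        mu = library[j] * x
        if config.dispersion_mean > 0:
            lam = rng.gamma(shape=1.0 / dispersions, scale=mu * dispersions)
            counts[:, j] = rng.poisson(lam)
        else:
            counts[:, j] = rng.poisson(mu)

    counts_df = pd.DataFrame(counts, index=list(reference.gene_ids), columns=sample_ids)
    fractions = pd.DataFrame(
        theta_mat, index=sample_ids, columns=list(reference.cell_type_ids)
    )

    # QC metrics: passing ranges, except the planted single-rule failures
    intron_exon = rng.uniform(0.8, 2.5, size=n_samples)
    bias = rng.uniform(0.8, 1.8, size=n_samples)
    for s, rule in fail_rule.items():
        if rule == "intron_exon":
            intron_exon[s] = rng.uniform(3.2, 5.0)
        elif rule == "bias_5to3":
            bias[s] = rng.uniform(2.2, 3.5)

    hospitals = rng.choice(HOSPITALS, size=n_samples)
    covariates = simulate_clinical_covariates(
        fractions, config.covariate_params, seed=int(rng.integers(2**31 - 1))
    )

    subgroup = np.full(n_samples, "-", dtype=object)
    covid_severity = np.full(n_samples, "", dtype=object)
    viral_mask = np.asarray(groups_col) == "viral"
    viral_pos = np.flatnonzero(viral_mask)
    is_covid = np.zeros(n_samples, dtype=bool)
    if viral_pos.size:
        covid_pos = viral_pos[rng.permutation(viral_pos.size)[: viral_pos.size // 2]]
        is_covid[covid_pos] = True
        subgroup[viral_pos] = "other-viral"
        subgroup[covid_pos] = "COVID-19"
        sev = covariates["severity"].to_numpy()
        covid_severity[covid_pos] = np.where(sev[covid_pos] >= 2, "severe", "moderate")

    metadata = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "group": groups_col,
            "hospital": hospitals,
            "subgroup": subgroup,
            "covid_severity": covid_severity,
            "intron_exon_ratio": intron_exon,
            "total_counts": counts_df.sum(axis=0).to_numpy(),
            "bias_5to3": bias,
            "rrna_frac": rng.uniform(0.0, 0.3, size=n_samples),
            "alt": covariates["alt"].to_numpy(),
            "cardiac_function": covariates["cardiac_function"].to_numpy(),
            "severity": covariates["severity"].to_numpy(),
            "qc_planted_fail": [fail_rule.get(j, "") for j in range(n_samples)],
        }
    ).set_index("sample_id", drop=False)

    truth = CohortTruth(
        fractions=fractions,
        planted_genes={
            g: [reference.gene_ids[i] for i in idx] for g, idx in per_group.items()
        },
        realized_log2fc=realized,
        shared_genes=[reference.gene_ids[i] for i in shared_idx],
        dispersions=pd.Series(dispersions, index=list(reference.gene_ids)),
        library_sizes=pd.Series(library, index=sample_ids),
    )
    return SyntheticCohort(counts=counts_df, metadata=metadata, truth=truth)


def simulate_clinical_covariates(
    fractions: pd.DataFrame,
    params: CovariateParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Clinical covariates driven by true cell-type fractions.

    Returns a table with ``alt`` (IU/L), ``cardiac_function``
    ('normal'/'abnormal') and ``severity`` (ordinal 0/1/2), indexed like
    ``fractions``.  Deterministic per seed.
    """
    params = params or CovariateParams()
    required = {"hepatocyte", "cardiac muscle cell", "club cell", "type I pneumocyte"}
    missing = required - set(fractions.columns)
    if missing:
        raise ValueError(f"fractions missing required cell types: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    n = len(fractions)

    alt = (
        params.alt_intercept
        + params.alt_slope * fractions["hepatocyte"].to_numpy()
        + params.alt_noise_sd * rng.standard_normal(n)
    )
    alt = np.clip(alt, 1.0, None)

    cardiac = fractions["cardiac muscle cell"].to_numpy()
    thresh = np.quantile(cardiac, params.cardiac_quantile)
    abnormal = cardiac > thresh
    if params.cardiac_mislabel_rate > 0:
        flip = rng.random(n) < params.cardiac_mislabel_rate
        abnormal = abnormal ^ flip

    lung = (fractions["club cell"] + fractions["type I pneumocyte"]).to_numpy()
    noisy = lung + params.severity_noise_sd * rng.standard_normal(n)
    terciles = np.quantile(noisy, [1 / 3, 2 / 3])
    severity = np.digitize(noisy, terciles)

    return pd.DataFrame(
        {
            "alt": alt,
            "cardiac_function": np.where(abnormal, "abnormal", "normal"),
            "severity": severity,
        },
        index=fractions.index,
    )


def config_to_yaml_dict(config: SimulationConfig) -> dict:
    """Plain-dict form of a config for YAML serialization."""
    d = asdict(config)
    d["library_size_range"] = list(config.library_size_range)
    d["group_sizes"] = dict(config.group_sizes)
    if config.dirichlet_alpha is not None:
        d["dirichlet_alpha"] = {g: list(v) for g, v in config.dirichlet_alpha.items()}
    return d


def config_from_yaml_dict(d: Mapping) -> SimulationConfig:
    d = dict(d)
    if "library_size_range" in d:
        d["library_size_range"] = tuple(d["library_size_range"])
    if "covariate_params" in d and isinstance(d["covariate_params"], Mapping):
        d["covariate_params"] = CovariateParams(**d["covariate_params"])
    return SimulationConfig(**d)
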