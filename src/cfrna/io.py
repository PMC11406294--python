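"""Reading and writing the pipeline's on-disk formats.

Counts travel as TSV (genes x samples, first column the gene id) or as
MatrixMarket MTX with sidecar gene/sample id files; metadata, fractions
and DE tables as CSV; simulation configs as YAML; normalization models
as JSON; fitted classifiers via joblib.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import io as spio
from scipy.sparse import csr_matrix

from .normalize import NormalizationModel
from .synthetic import SimulationConfig, config_from_yaml_dict, config_to_yaml_dict

__all__ = [
    "read_counts_tsv", "write_counts_tsv",
    "read_counts_mtx", "write_counts_mtx",
    "read_metadata", "write_metadata",
    "read_config", "write_config",
    "read_normalization_model", "write_normalization_model",
]


def read_counts_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.to_numpy() < 0).any():
        raise ValueError(f"negative counts in {path}")
    return df


def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_counts_mtx(path) -> pd.DataFrame:
    """Read an MTX matrix with `<stem>.genes.txt` / `<stem>.samples.txt`."""
    path = Path(path)
    stem = path.with_suffix("")
    genes = stem.with_suffix(".genes.txt").read_text().split()
    samples = stem.with_suffix(".samples.txt").read_text().split()
    mat = spio.mmread(path).toarray()
    return pd.DataFrame(np.asarray(mat), index=genes, columns=samples)


def write_counts_mtx(counts: pd.DataFrame, path) -> None:
    path = Path(path)
    stem = path.with_suffix("")
    spio.mmwrite(str(path), csr_matrix(counts.to_numpy()))
    stem.with_suffix(".genes.txt").write_text("\n".join(map(str, counts.index)) + "\n")
    stem.with_suffix(".samples.txt").write_text("\n".join(map(str, counts.columns)) + "\n")


def read_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "sample_id" in df.columns:
        df = df.set_index("sample_id", drop=False)
    return df


def write_metadata(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path, index=False)


def read_config(path) -> SimulationConfig:
    with open(path) as fh:
        return config_from_yaml_dict(yaml.safe_load(fh) or {})


def write_config(config: SimulationConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_yaml_dict(config), fh, sort_keys=False)


def read_normalization_model(path) -> NormalizationModel:
    return NormalizationModel.from_json(Path(path).read_text())


def write_normalization_model(model: NormalizationModel, path) -> None:
    Path(path).write_text(model.to_json())
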