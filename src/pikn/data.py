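"""Omics dataset container and delimited-text I/O.

A dataset is a plain sample x feature matrix of molecular measures
(expression values, copy-number calls, ...) with named features, optional
binary labels and a modality tag.  Matrices are stored dense in float64;
the cohorts this package targets are at most a few thousand samples by a
few thousand features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["OmicsDataset", "Standardizer", "read_matrix_tsv", "read_labels_tsv"]


@dataclass
class OmicsDataset:
    """Sample x feature matrix with named features and optional binary labels.

    Parameters
    ----------
    X : ndarray of shape (n_samples, n_features)
    feature_names : list of str, unique
    sample_ids : list of str
    labels : ndarray of shape (n_samples,) with values in {0, 1}, or None
    modality : free-form tag, e.g. ``"expression"`` or ``"cna"``
    """

    X: np.ndarray
    feature_names: list[str]
    sample_ids: list[str]
    labels: np.ndarray | None = None
    modality: str = "expression"

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        if self.X.ndim != 2:
            raise ValueError(f"X must be 2-D, got shape {self.X.shape}")
        self.feature_names = [str(f).strip() for f in self.feature_names]
        if len(self.feature_names) != self.X.shape[1]:
            raise ValueError(
                f"{len(self.feature_names)} feature names for {self.X.shape[1]} columns"
            )
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.sample_ids) != self.X.shape[0]:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for {self.X.shape[0]} rows"
            )
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != (self.X.shape[0],):
                raise ValueError("labels must be one per sample")
            bad = set(np.unique(self.labels)) - {0, 1}
            if bad:
                raise ValueError(f"labels must be binary 0/1, found {sorted(bad)}")
            self.labels = self.labels.astype(np.int64)

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def subset(self, idx) -> "OmicsDataset":
        """Row subset (copy) keeping feature space and modality."""
        idx = np.asarray(idx)
        return OmicsDataset(
            X=self.X[idx],
            feature_names=list(self.feature_names),
            sample_ids=[self.sample_ids[i] for i in np.atleast_1d(idx)],
            labels=None if self.labels is None else self.labels[idx],
            modality=self.modality,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, index=self.sample_ids, columns=self.feature_names)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="sample_id")


@dataclass
class Standardizer:
    """Per-feature z-scoring fitted on training data.

    Constant features get unit scale so they map to zero rather than NaN.
    """

    mean: np.ndarray = field(default_factory=lambda: np.zeros(0))
    scale: np.ndarray = field(default_factory=lambda: np.ones(0))

    def fit(self, X: np.ndarray) -> "Standardizer":
        X = np.asarray(X, dtype=np.float64)
        self.mean = X.mean(axis=0)
        sd = X.std(axis=0)
        self.scale = np.where(sd > 1e-12, sd, 1.0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=np.float64) - self.mean) / self.scale


def read_matrix_tsv(path, modality: str = "expression") -> OmicsDataset:
    """Read a sample x feature TSV (header = feature names, first column = sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return OmicsDataset(
        X=df.to_numpy(dtype=np.float64),
        feature_names=[str(c) for c in df.columns],
        sample_ids=[str(i) for i in df.index],
        modality=modality,
    )


def read_labels_tsv(path) -> pd.Series:
    """Read a two-column TSV (sample_id, label) into a Series indexed by sample id."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] != 1:
        raise ValueError(f"label file must have exactly one label column, got {df.shape[1]}")
    return df.iloc[:, 0].astype(int)


def attach_labels(ds: OmicsDataset, labels: pd.Series) -> OmicsDataset:
    """Align a label Series to the dataset's sample ids and attach it."""
    try:
        y = labels.loc[ds.sample_ids].to_numpy()
    except KeyError as e:
        raise ValueError(f"label file is missing sample ids present in the data: {e}") from e
    return OmicsDataset(ds.X, ds.feature_names, ds.sample_ids, y, ds.modality)
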