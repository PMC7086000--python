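"""Regional atrophy from cross-sectional volumes, z-scored against controls.

A patient's measured degeneration is the per-region z-score of gray-matter
volume against the healthy-control distribution, z = (X - mu) / sigma.
Volume loss gives negative z; all downstream correlations use the
loss-oriented "measured atrophy" y = -z so that a positive correlation means
the diffusion model predicts the loss pattern. Sample (n-1) standard
deviation throughout — the control cohorts in scope are small (~19).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from ._io import read_delimited
from .parcellation import Parcellation


@dataclass(frozen=True)
class VolumeTable:
    """Subjects x regions table of regional gray-matter volumes (> 0)."""

    subjects: tuple
    volumes: np.ndarray
    parcellation: Parcellation

    def __post_init__(self):
        V = np.asarray(self.volumes, dtype=float)
        subs = tuple(str(s) for s in self.subjects)
        if V.shape != (len(subs), self.parcellation.n_regions):
            raise ValueError("volume table shape does not match subjects x regions")
        if not np.all(np.isfinite(V)):
            raise ValueError("missing or non-finite volumes")
        if np.any(V <= 0):
            raise ValueError("volumes must be strictly positive")
        object.__setattr__(self, "volumes", V)
        object.__setattr__(self, "subjects", subs)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @classmethod
    def read(cls, path, parcellation: Parcellation) -> "VolumeTable":
        """Delimited text: first column subject id, remaining columns regions."""
        df = read_delimited(path, index_col=0)
        cols = [str(c) for c in df.columns]
        if cols != list(parcellation.region_names):
            raise ValueError(f"{path}: region columns do not match parcellation order")
        return cls(tuple(str(s) for s in df.index), df.to_numpy(dtype=float), parcellation)

    def write(self, path) -> None:
        pd.DataFrame(self.volumes, index=list(self.subjects),
                     columns=self.parcellation.region_names) \
            .to_csv(Path(path), index_label="subject")


@dataclass(frozen=True)
class ControlStats:
    """Per-region control mean and sample SD used for z-scoring."""

    mu: np.ndarray
    sigma: np.ndarray
    n_controls: int

    def __post_init__(self):
        mu = np.asarray(self.mu, dtype=float)
        sigma = np.asarray(self.sigma, dtype=float)
        if mu.shape != sigma.shape:
            raise ValueError("mu and sigma length mismatch")
        if self.n_controls < 2:
            raise ValueError("need at least 2 control subjects")
        if np.any(sigma <= 0):
            raise ValueError("zero-variance region in controls; cannot z-score")
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "sigma", sigma)


@dataclass(frozen=True)
class AtrophyMap:
    """z: volume z-scores; y = -z: loss-oriented measured atrophy."""

    z: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        z = np.asarray(self.z, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if not (np.all(np.isfinite(z)) and np.all(np.isfinite(y))):
            raise ValueError("non-finite atrophy values")
        if not np.array_equal(y, -z):
            raise ValueError("y must equal -z exactly")
        object.__setattr__(self, "z", z)
        object.__setattr__(self, "y", y)


def compute_control_stats(controls: VolumeTable) -> ControlStats:
    """Per-region sample mean and sample (n-1) SD over the control cohort."""
    if controls.n_subjects < 2:
        raise ValueError("need at least 2 control subjects")
    mu = controls.volumes.mean(axis=0)
    sigma = controls.volumes.std(axis=0, ddof=1)
    if np.any(sigma <= 0):
        bad = [controls.parcellation.region_names[i] for i in np.where(sigma <= 0)[0]]
        raise ValueError(f"zero variance across controls in regions: {bad}")
    return ControlStats(mu, sigma, controls.n_subjects)


def zscore_atrophy(patient_volumes, stats: ControlStats) -> AtrophyMap:
    """z_i = (X_i - mu_i) / sigma_i; measured atrophy y = -z."""
    X = np.asarray(patient_volumes, dtype=float)
    if X.shape != stats.mu.shape:
        raise ValueError("patient volume vector length mismatch")
    z = (X - stats.mu) / stats.sigma
    return AtrophyMap(z, -z)


class ControlReferenceScaler(BaseEstimator, TransformerMixin):
    """Transformer: fit on control volumes, transform volumes to atrophy y.

    ``fit(X)`` learns per-region control mean ``mu_`` and sample SD ``sigma_``;
    ``transform(X)`` returns loss-oriented atrophy -(X - mu_)/sigma_ row-wise.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("X must be a 2-D controls-by-regions array with >= 2 rows")
        self.mu_ = X.mean(axis=0)
        self.sigma_ = X.std(axis=0, ddof=1)
        if np.any(self.sigma_ <= 0):
            raise ValueError("zero variance region in controls")
        self.n_controls_ = X.shape[0]
        return self

    def transform(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return -(X - self.mu_) / self.sigma_

    def control_stats(self) -> ControlStats:
        return ControlStats(self.mu_, self.sigma_, self.n_controls_)
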