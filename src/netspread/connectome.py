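"""Structural connectomes and the graph Laplacian diffusion operator.

The connectome is a symmetric nonnegative weighted adjacency matrix over a
parcellation (edge weight = streamline count or any nonnegative strength).
Diffusion runs on the graph Laplacian H = D - W. Streamline counts can be in
the thousands, which with a fixed diffusion rate would drive the heat kernel
to steady state within one time step; the default therefore rescales W by its
largest entry before building H (``max-weight-scaled``), preserving the
operator's form while keeping an integer time grid informative. The raw
``combinatorial`` operator remains selectable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components

from ._io import read_delimited
from .parcellation import Parcellation

ASYMMETRY_RTOL = 1e-6
NORMALIZATIONS = ("combinatorial", "max-weight-scaled")


@dataclass(frozen=True)
class Connectome:
    """Validated symmetric nonnegative weighted adjacency matrix."""

    weights: np.ndarray
    parcellation: Parcellation

    def __post_init__(self):
        W = np.asarray(self.weights, dtype=float)
        n = self.parcellation.n_regions
        if W.shape != (n, n):
            raise ValueError(
                f"weight matrix shape {W.shape} does not match parcellation of {n} regions")
        if not np.all(np.isfinite(W)):
            raise ValueError("non-finite entries in weight matrix")
        if np.any(W < 0):
            raise ValueError("negative entries in weight matrix")
        if np.any(np.abs(np.diag(W)) > 1e-9):
            raise ValueError("diagonal of connectome must be zero (no self-loops)")
        if np.max(np.abs(W - W.T)) > 1e-9 * max(1.0, np.max(np.abs(W))):
            raise ValueError("weight matrix is not symmetric")
        object.__setattr__(self, "weights", W)

    @property
    def n_regions(self) -> int:
        return self.parcellation.n_regions

    def n_connected_components(self) -> int:
        ncomp, _ = connected_components(self.weights > 0, directed=False)
        return int(ncomp)


@dataclass(frozen=True)
class LaplacianOperator:
    """Graph Laplacian H = D - W (degree matrix minus adjacency).

    ``normalization`` records whether W was first divided by its largest
    entry. H is symmetric positive semidefinite with zero row sums; its null
    space (one uniform vector per connected component) is what makes graph
    diffusion mass-conserving.
    """

    H: np.ndarray
    normalization: str
    parcellation: Parcellation

    def __post_init__(self):
        H = np.asarray(self.H, dtype=float)
        if np.max(np.abs(H - H.T)) > 1e-9 * max(1.0, np.max(np.abs(H))):
            raise ValueError("Laplacian must be symmetric")
        if np.max(np.abs(H.sum(axis=1))) > 1e-8 * max(1.0, np.max(np.abs(H))):
            raise ValueError("Laplacian rows must sum to zero")
        object.__setattr__(self, "H", H)

    @property
    def n_regions(self) -> int:
        return self.H.shape[0]


def _symmetrize(W: np.ndarray, source: str) -> np.ndarray:
    scale = max(np.max(np.abs(W)), 1e-300)
    asym = np.max(np.abs(W - W.T)) / scale
    if asym > ASYMMETRY_RTOL:
        raise ValueError(
            f"{source}: matrix asymmetry {asym:.2e} exceeds tolerance {ASYMMETRY_RTOL:.0e}; "
            "refusing to symmetrize silently")
    return (W + W.T) / 2.0


def read_connectome(path, parcellation: Parcellation) -> Connectome:
    """Read a delimited NxN matrix, optionally labelled with region names.

    Comma or tab delimited (auto-detected). If the first cell is non-numeric
    the first row and column are treated as region names and checked against
    the parcellation order. Near-symmetric input (relative asymmetry <= 1e-6,
    typical of tractography output) is symmetrized by averaging; anything
    worse is an error.
    """
    path = Path(path)
    raw = read_delimited(path, header=None)
    first = raw.iat[0, 0]
    if pd.isna(first):                 # empty corner cell of a labelled matrix
        has_labels = True
    else:
        try:
            float(str(first))
            has_labels = False
        except ValueError:
            has_labels = True
    if has_labels:
        names = [str(x) for x in raw.iloc[0, 1:]]
        row_names = [str(x) for x in raw.iloc[1:, 0]]
        if names != list(parcellation.region_names) or row_names != list(parcellation.region_names):
            raise ValueError(f"{path}: region labels do not match parcellation order")
        body = raw.iloc[1:, 1:]
    else:
        body = raw
    try:
        W = body.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric cell in matrix body") from exc
    n = parcellation.n_regions
    if W.shape != (n, n):
        raise ValueError(f"{path}: matrix is {W.shape[0]}x{W.shape[1]}, parcellation has {n} regions")
    if np.any(W < 0):
        raise ValueError(f"{path}: negative entries")
    W = _symmetrize(W, str(path))
    np.fill_diagonal(W, 0.0)
    return Connectome(W, parcellation)


def write_connectome(conn: Connectome, path) -> None:
    """Write with region-name header row and column (CSV)."""
    df = pd.DataFrame(conn.weights,
                      index=conn.parcellation.region_names,
                      columns=conn.parcellation.region_names)
    df.to_csv(Path(path))


def average_connectomes(connectomes) -> Connectome:
    """Element-wise mean of weight matrices (e.g. the control-group template).

    All inputs must share one parcellation; the mean of symmetric nonnegative
    matrices keeps every connectome invariant.
    """
    connectomes = list(connectomes)
    if not connectomes:
        raise ValueError("need at least one connectome to average")
    parc = connectomes[0].parcellation
    for c in connectomes[1:]:
        if c.parcellation.region_names != parc.region_names:
            raise ValueError("connectomes use different parcellations")
    W = np.mean([c.weights for c in connectomes], axis=0)
    return Connectome(W, parc)


def graph_laplacian(connectome: Connectome,
                    normalization: str = "max-weight-scaled") -> LaplacianOperator:
    """Build H = D - W, optionally on W rescaled by its largest entry."""
    if normalization not in NORMALIZATIONS:
        raise ValueError(f"normalization must be one of {NORMALIZATIONS}")
    W = connectome.weights
    wmax = np.max(W)
    if wmax <= 0:
        raise ValueError("all-zero connectome has no Laplacian")
    if normalization == "max-weight-scaled":
        W = W / wmax
    if connectome.n_connected_components() > 1:
        warnings.warn("connectome is disconnected; diffusion proceeds per component",
                      UserWarning, stacklevel=2)
    H = np.diag(W.sum(axis=1)) - W
    return LaplacianOperator(H, normalization, connectome.parcellation)
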