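"""Network diffusion model: linear spread of pathology on the connectome.

The model is the first-order diffusion f(t) = exp(-alpha * H * t) f(0), with
H the graph Laplacian, alpha a dimensionless diffusion rate (default 0.25)
and t a unitless time index (default grid 0..19). Because H is symmetric
positive semidefinite and small (N ~ 82), the matrix exponential is computed
once per graph by symmetric eigendecomposition; one decomposition serves all
seeds and all time points. Mass is conserved (columns of the kernel sum to 1)
and on a connected graph every trajectory relaxes to the uniform vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import eigh

from .connectome import LaplacianOperator

DEFAULT_ALPHA = 0.25
DEFAULT_TIMEPOINTS = tuple(range(20))

# eigendecomposition round-off: kernel entries this far below zero are noise
_NEG_CLAMP = 1e-10


@dataclass(frozen=True)
class DiffusionProfile:
    """Predicted pathology per region (rows) per time point (columns)."""

    values: np.ndarray          # N x T, nonnegative
    alpha: float
    timepoints: tuple
    f0: np.ndarray              # length-N initial condition

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(self, "f0", np.asarray(self.f0, dtype=float))
        object.__setattr__(self, "timepoints", tuple(float(t) for t in self.timepoints))

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]

    def to_frame(self, region_names=None) -> pd.DataFrame:
        idx = list(region_names) if region_names is not None else list(range(self.n_regions))
        return pd.DataFrame(self.values, index=idx,
                            columns=[f"t{t:g}" for t in self.timepoints])


class DiffusionKernel:
    """Cached eigendecomposition of alpha*H for repeated kernel evaluation."""

    def __init__(self, laplacian: LaplacianOperator, alpha: float = DEFAULT_ALPHA):
        if alpha < 0:
            raise ValueError("alpha must be >= 0")
        H = laplacian.H
        if np.max(np.abs(H - H.T)) > 1e-8 * max(1.0, np.max(np.abs(H))):
            raise ValueError("Laplacian must be symmetric")
        self.alpha = float(alpha)
        self.laplacian = laplacian
        evals, evecs = eigh(H)
        # PSD up to round-off; clamp so exp(-a*l*t) never blows up
        self._evals = np.clip(evals, 0.0, None)
        self._evecs = evecs
        self._exp_cache = {}

    def _exp_table(self, timepoints) -> np.ndarray:
        """exp(-alpha * lambda_k * t) table, shape (N, T); cached per grid."""
        key = tuple(float(t) for t in timepoints)
        E = self._exp_cache.get(key)
        if E is None:
            E = np.exp(-self.alpha * np.outer(self._evals, np.array(key)))
            self._exp_cache[key] = E
        return E

    def kernel(self, t: float) -> np.ndarray:
        """The heat kernel exp(-alpha*H*t); doubly stochastic and symmetric."""
        if t < 0:
            raise ValueError("time must be >= 0")
        if t == 0:                     # exact identity, not QQ^T round-off
            return np.eye(len(self._evals))
        Q = self._evecs
        K = (Q * np.exp(-self.alpha * self._evals * t)) @ Q.T
        K[K < 0] = np.where(K[K < 0] > -_NEG_CLAMP, 0.0, K[K < 0])
        return K

    def kernels(self, timepoints) -> np.ndarray:
        """Stacked kernels, shape (T, N, N)."""
        return np.stack([self.kernel(t) for t in timepoints])

    def propagate(self, f0: np.ndarray, timepoints) -> np.ndarray:
        """Trajectory columns f(t) = K(t) f0, shape (N, T)."""
        f0 = np.asarray(f0, dtype=float)
        Q = self._evecs
        coef = Q.T @ f0
        out = Q @ (self._exp_table(timepoints) * coef[:, None])
        out[(out < 0) & (out > -_NEG_CLAMP)] = 0.0
        for j, t in enumerate(timepoints):
            if t == 0:                 # exact initial condition at t = 0
                out[:, j] = f0
        return out


def heat_kernel(laplacian: LaplacianOperator, alpha: float, t: float) -> np.ndarray:
    """exp(-alpha*H*t) via symmetric eigendecomposition."""
    return DiffusionKernel(laplacian, alpha).kernel(t)


def simulate_diffusion(laplacian: LaplacianOperator,
                       f0,
                       alpha: float = DEFAULT_ALPHA,
                       timepoints=DEFAULT_TIMEPOINTS) -> DiffusionProfile:
    """Run the diffusion model from initial pathology distribution f0.

    Parameters
    ----------
    f0 : array-like, length N
        Nonnegative initial pathology, typically an indicator of seed regions
        with value 1 per seeded region.
    alpha : float
        Diffusion rate (default 0.25).
    timepoints : sequence of float
        Evaluation times (default the integer grid 0..19).
    """
    f0 = np.asarray(f0, dtype=float)
    timepoints = tuple(timepoints)
    if not timepoints:
        raise ValueError("timepoints must be non-empty")
    if f0.shape != (laplacian.n_regions,):
        raise ValueError("f0 length does not match Laplacian size")
    if np.any(f0 < 0):
        raise ValueError("f0 must be nonnegative")
    if not np.any(f0 > 0):
        raise ValueError("f0 must not be all zero")
    values = DiffusionKernel(laplacian, alpha).propagate(f0, timepoints)
    return DiffusionProfile(values, alpha, timepoints, f0)


def all_seed_profiles(laplacian: LaplacianOperator,
                      alpha: float = DEFAULT_ALPHA,
                      timepoints=DEFAULT_TIMEPOINTS):
    """One diffusion profile per region, seeding each region with pathology 1.

    Profile i uses f0 = indicator of region i, so its column at time t is
    column i of the heat kernel at t. All N profiles come from a single
    eigendecomposition.
    """
    timepoints = tuple(timepoints)
    if not timepoints:
        raise ValueError("timepoints must be non-empty")
    dk = DiffusionKernel(laplacian, alpha)
    K = dk.kernels(timepoints)          # (T, N, N)
    n = laplacian.n_regions
    profiles = []
    for i in range(n):
        f0 = np.zeros(n)
        f0[i] = 1.0
        profiles.append(DiffusionProfile(K[:, :, i].T, alpha, timepoints, f0))
    return profiles
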