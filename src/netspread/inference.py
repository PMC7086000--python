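"""Injury-epicenter inference from measured atrophy.

Given the healthy-template connectome Laplacian and one patient's measured
atrophy map y, the method finds the seed regions whose diffusion best
reproduces y:

1. screen every region as a single seed — correlate its diffusion profile
   with y at each time point, excluding the seed's own data point;
2. filter the per-seed best correlations R_i into an initial binary
   configuration (drop boundary-time optima; drop negative sub-median R;
   binarize the survivors);
3. greedy forward selection over that candidate pool, re-optimizing the best
   time index t_max for each trial seed set, followed by one backward pruning
   pass; seed data points are always excluded from the correlation so
   inferred seeds cannot simply replicate the most atrophied regions.

All correlations are Pearson. Undefined correlations (zero variance on the
non-seed points, e.g. every single-seed prediction at t = 0) are treated as
non-improvements. Ties break deterministically: smaller time index, lower
region index.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .connectome import LaplacianOperator
from .ndm import DEFAULT_ALPHA, DEFAULT_TIMEPOINTS, DiffusionKernel


@dataclass(frozen=True)
class SeedScreen:
    """Single-seed screening result.

    ``correlation_matrix[i, t]`` is the seed-excluded Pearson correlation
    between region i's diffusion profile at time index t and the measured
    atrophy; undefined entries are stored as 0 and flagged in ``undefined``.
    ``R[i]`` / ``t_best[i]`` are the best defined correlation per seed and
    its time index.
    """

    correlation_matrix: np.ndarray   # N x T
    R: np.ndarray                    # length N
    t_best: np.ndarray               # length N, int time indices
    undefined: np.ndarray            # N x T bool

    @property
    def n_regions(self) -> int:
        return self.correlation_matrix.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.correlation_matrix.shape[1]


@dataclass(frozen=True)
class EpicenterResult:
    """Inferred epicenter set for one patient."""

    seeds: np.ndarray                # length-N binary vector
    t_max: int                       # best-fit time index (interior)
    r_best: float                    # seed-excluded Pearson correlation
    r_squared: float
    predicted: np.ndarray            # length-N predicted atrophy at t_max
    search_trace: tuple = field(default=())   # ((seed tuple, t_max, r), ...)

    @property
    def seed_indices(self) -> tuple:
        return tuple(int(i) for i in np.where(self.seeds > 0)[0])


def correlation_excluding_seeds(predicted, measured, seeds) -> float:
    """Pearson correlation over non-seed regions only.

    Returns ``nan`` (the undefined marker, treated as a non-improvement by
    callers) when either restricted vector has zero variance.
    """
    predicted = np.asarray(predicted, dtype=float)
    measured = np.asarray(measured, dtype=float)
    mask = ~np.asarray(seeds, dtype=bool)
    if mask.sum() < 3:
        raise ValueError("need at least 3 non-seed regions for a correlation")
    p = predicted[mask]
    m = measured[mask]
    p = p - p.mean()
    m = m - m.mean()
    denom = math.sqrt(float(p @ p) * float(m @ m))
    if denom == 0.0:
        return float("nan")
    return float(np.clip((p @ m) / denom, -1.0, 1.0))


def screen_single_seeds(profiles, atrophy) -> SeedScreen:
    """Correlate every single-seed diffusion profile with measured atrophy.

    Parameters
    ----------
    profiles : list of DiffusionProfile
        Output of :func:`netspread.ndm.all_seed_profiles` (profile i seeded
        at region i).
    atrophy : AtrophyMap or array-like
        Measured atrophy y (loss-oriented).
    """
    y = np.asarray(getattr(atrophy, "y", atrophy), dtype=float)
    n = len(profiles)
    if y.shape != (n,):
        raise ValueError("atrophy length does not match number of profiles")
    if np.ptp(y) == 0:
        raise ValueError("measured atrophy is constant; no inference possible")
    T = profiles[0].n_timepoints
    corr = np.zeros((n, T))
    undef = np.zeros((n, T), dtype=bool)
    seed_mask = np.zeros(n, dtype=bool)
    for i, prof in enumerate(profiles):
        seed_mask[:] = False
        seed_mask[i] = True
        for t in range(T):
            r = correlation_excluding_seeds(prof.values[:, t], y, seed_mask)
            if math.isnan(r):
                undef[i, t] = True      # recorded as 0
            else:
                corr[i, t] = r
    masked = np.where(undef, -np.inf, corr)
    t_best = np.zeros(n, dtype=int)
    R = np.zeros(n)
    for i in range(n):
        if np.all(undef[i]):
            continue                    # R=0, t_best=0 placeholder
        t_best[i] = int(np.argmax(masked[i]))   # argmax takes smallest index on ties
        R[i] = masked[i, t_best[i]]
    return SeedScreen(corr, R, t_best, undef)


def initial_configuration(screen: SeedScreen) -> np.ndarray:
    """Filter the screening vector R into a binary starting configuration.

    In order: (1) zero R_i where the best time index sits on the grid
    boundary (0 or T-1 — a boundary optimum means the grid did not bracket
    the fit); (2) with the median of the resulting R vector, zero R_i that
    are both negative and below that median; (3) binarize: R_i > 0 becomes 1.
    """
    R = screen.R.copy()
    T = screen.n_timepoints
    R[(screen.t_best == 0) | (screen.t_best == T - 1)] = 0.0
    med = float(np.median(R))
    R[(R < 0) & (R < med)] = 0.0
    return (R > 0).astype(int)


def find_tmax(laplacian: LaplacianOperator, seeds, atrophy,
              alpha: float = DEFAULT_ALPHA,
              timepoints=DEFAULT_TIMEPOINTS,
              kernel: DiffusionKernel = None):
    """Best-fit interior time index for a given seed set.

    Simulates diffusion from the binary seed indicator and returns
    ``(t_max, r_best, predicted)`` where t_max maximizes the seed-excluded
    correlation over interior time indices (boundary indices 0 and T-1 are
    excluded, mirroring the screening rule). Ties go to the smaller index.
    """
    seeds = np.asarray(seeds)
    seed_mask = seeds.astype(bool)
    if not seed_mask.any():
        raise ValueError("seed set must be non-empty")
    y = np.asarray(getattr(atrophy, "y", atrophy), dtype=float)
    timepoints = tuple(timepoints)
    if len(timepoints) < 3:
        raise ValueError("need at least 3 timepoints to have an interior optimum")
    dk = kernel if kernel is not None else DiffusionKernel(laplacian, alpha)
    traj = dk.propagate(seed_mask.astype(float), timepoints)   # N x T
    mask = ~seed_mask
    if mask.sum() < 3:
        raise ValueError("need at least 3 non-seed regions for a correlation")
    # vectorized seed-excluded Pearson over interior time indices
    P = traj[mask, 1:-1]
    Pc = P - P.mean(axis=0)
    m = y[mask]
    mc = m - m.mean()
    denom = np.sqrt((Pc ** 2).sum(axis=0) * float(mc @ mc))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (Pc.T @ mc) / denom, -np.inf)
    r = np.clip(r, -1.0, 1.0, out=r) if np.all(np.isfinite(r)) else r
    if not np.any(r > -np.inf):
        raise ValueError("no valid interior time point (all correlations undefined)")
    best = int(np.argmax(r))            # smallest index on ties
    best_t = best + 1
    return best_t, float(min(r[best], 1.0)), traj[:, best_t].copy()


def optimize_seed_combination(laplacian: LaplacianOperator,
                              screen: SeedScreen,
                              atrophy,
                              alpha: float = DEFAULT_ALPHA,
                              timepoints=DEFAULT_TIMEPOINTS,
                              backward_prune: bool = True,
                              candidate_pool=None) -> EpicenterResult:
    """Search seed combinations for the highest seed-excluded correlation.

    The candidate pool is the initial configuration from the screening
    filters (fallback: the single region with the highest R when the filters
    zero everything out). Starting from the pool member with the highest
    single-seed R, greedy forward selection repeatedly adds the candidate
    whose inclusion most increases r_best — re-optimizing t_max for every
    trial set. When no single addition improves, one pair addition is
    attempted (two regions can improve the fit jointly without either
    helping alone); the search stops at the first full non-improvement. An
    optional backward
    pass then removes any member whose removal does not decrease r_best.
    Deterministic given its inputs.
    """
    n = screen.n_regions
    y = np.asarray(getattr(atrophy, "y", atrophy), dtype=float)
    timepoints = tuple(timepoints)
    dk = DiffusionKernel(laplacian, alpha)

    if candidate_pool is None:
        pool_vec = initial_configuration(screen)
        pool = [int(i) for i in np.where(pool_vec > 0)[0]]
        if not pool:
            pool = [int(np.argmax(screen.R))]
    else:
        pool = sorted(int(i) for i in np.asarray(candidate_pool).ravel())
        if not pool:
            raise ValueError("explicit candidate pool is empty")

    def evaluate(members):
        seeds = np.zeros(n, dtype=int)
        seeds[list(members)] = 1
        t, r, pred = find_tmax(laplacian, seeds, y, alpha, timepoints, kernel=dk)
        return seeds, t, r, pred

    # start from the pool member with the highest single-seed R (lower index on ties)
    start = int(pool[int(np.argmax([screen.R[i] for i in pool]))])
    current = [start]
    seeds, t_max, r_best, predicted = evaluate(current)
    trace = [(tuple(current), t_max, r_best)]

    # greedy forward selection, strict improvement only; when no single
    # addition improves, attempt one pair addition (captures seeds that only
    # help jointly) before stopping
    import itertools

    remaining = [i for i in pool if i != start]
    while remaining:
        best_gain, best_add, best_eval = 0.0, None, None
        for cand in remaining:                      # index order -> ties to lower index
            trial = sorted(current + [cand])
            try:
                ev = evaluate(trial)
            except ValueError:                      # fewer than 3 non-seed points etc.
                continue
            gain = ev[2] - r_best
            if gain > best_gain:
                best_gain, best_add, best_eval = gain, [cand], ev
        if best_add is None and len(remaining) >= 2:
            for pair in itertools.combinations(remaining, 2):
                trial = sorted(current + list(pair))
                try:
                    ev = evaluate(trial)
                except ValueError:
                    continue
                gain = ev[2] - r_best
                if gain > best_gain:
                    best_gain, best_add, best_eval = gain, list(pair), ev
        if best_add is None:
            break
        current = sorted(current + best_add)
        for cand in best_add:
            remaining.remove(cand)
        seeds, t_max, r_best, predicted = best_eval
        trace.append((tuple(current), t_max, r_best))

    if backward_prune and len(current) > 1:
        for member in list(current):               # one pass, index order
            if len(current) == 1:
                break
            trial = [i for i in current if i != member]
            try:
                ev = evaluate(trial)
            except ValueError:
                continue
            if ev[2] >= r_best:
                current = trial
                seeds, t_max, r_best, predicted = ev
                trace.append((tuple(current), t_max, r_best))

    return EpicenterResult(seeds, int(t_max), float(r_best), float(r_best) ** 2,
                           predicted, tuple(trace))


class EpicenterEstimator:
    """Scikit-learn style estimator: infer epicenters for a cohort.

    Parameters
    ----------
    connectome : Connectome
        Healthy-template connectome the diffusion runs on.
    alpha : float
        Diffusion rate (default 0.25).
    n_timepoints : int
        Length of the integer time grid 0..n_timepoints-1 (default 20).
    normalization : str
        Laplacian normalization, ``max-weight-scaled`` or ``combinatorial``.
    backward_prune : bool
        Run the backward pruning pass after greedy forward selection.

    ``fit(X)`` takes a patients-by-regions matrix of measured atrophy y and
    stores per-patient results in ``results_``, with convenience arrays
    ``seeds_`` (P x N binary), ``t_max_``, ``r_best_``, ``r_squared_`` and
    ``predicted_`` (P x N). ``predict()`` returns the predicted atrophy maps.
    """

    def __init__(self, connectome=None, alpha: float = DEFAULT_ALPHA,
                 n_timepoints: int = len(DEFAULT_TIMEPOINTS),
                 normalization: str = "max-weight-scaled",
                 backward_prune: bool = True):
        self.connectome = connectome
        self.alpha = alpha
        self.n_timepoints = n_timepoints
        self.normalization = normalization
        self.backward_prune = backward_prune

    def get_params(self, deep=True):
        return {"connectome": self.connectome, "alpha": self.alpha,
                "n_timepoints": self.n_timepoints,
                "normalization": self.normalization,
                "backward_prune": self.backward_prune}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y=None):
        from .connectome import graph_laplacian
        from .ndm import all_seed_profiles

        if self.connectome is None:
            raise ValueError("connectome must be set before fitting")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.connectome.n_regions:
            raise ValueError("atrophy matrix width does not match parcellation")
        timepoints = tuple(range(self.n_timepoints))
        lap = graph_laplacian(self.connectome, self.normalization)
        profiles = all_seed_profiles(lap, self.alpha, timepoints)
        self.laplacian_ = lap
        self.results_ = []
        for row in X:
            screen = screen_single_seeds(profiles, row)
            self.results_.append(optimize_seed_combination(
                lap, screen, row, self.alpha, timepoints,
                backward_prune=self.backward_prune))
        self.seeds_ = np.array([r.seeds for r in self.results_])
        self.t_max_ = np.array([r.t_max for r in self.results_])
        self.r_best_ = np.array([r.r_best for r in self.results_])
        self.r_squared_ = np.array([r.r_squared for r in self.results_])
        self.predicted_ = np.array([r.predicted for r in self.results_])
        return self

    def predict(self, X=None):
        if not hasattr(self, "predicted_"):
            raise ValueError("estimator is not fitted")
        return self.predicted_
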