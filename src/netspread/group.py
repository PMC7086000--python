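"""Group-level structure in predicted atrophy maps and clinical associations.

PCA (SVD of the mean-centered patients-by-regions matrix, regions as
variables) extracts orthogonal spatial components of the predicted
degeneration patterns. Associations between model fit and clinical
covariates use partial correlation implemented by double residualization:
regress both variables on the covariate (least squares with intercept) and
correlate the residuals; the two-sided p comes from the t distribution with
n - 3 degrees of freedom (n - 2 for the plain correlation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA


@dataclass(frozen=True)
class PCAResult:
    """Spatial principal components of a patients-by-regions matrix.

    ``components`` (K x N) are orthonormal loadings, signs fixed so each
    component's largest-magnitude loading is positive. ``scores`` (P x K)
    are the patient projections. ``explained_variance_fraction`` covers all
    min(P-1, N) components and sums to 1; the first K entries belong to the
    returned components.
    """

    components: np.ndarray
    explained_variance_fraction: np.ndarray
    scores: np.ndarray


@dataclass(frozen=True)
class AssociationResult:
    r: float
    p_value: float
    n: int
    covariates: tuple = ()


class SignFixedPCA(PCA):
    """PCA with a deterministic sign convention on the loadings.

    PCA signs are arbitrary; fixing each component so its largest-magnitude
    loading is positive makes outputs reproducible across libraries and runs.
    """

    def fit(self, X, y=None):
        super().fit(X, y)
        flip = np.sign(self.components_[np.arange(self.components_.shape[0]),
                                        np.argmax(np.abs(self.components_), axis=1)])
        flip[flip == 0] = 1.0
        self.components_ = self.components_ * flip[:, None]
        return self


def pca_predicted_maps(values, k: int = 5, patient_ids=None) -> PCAResult:
    """Principal spatial components of predicted atrophy maps.

    Parameters
    ----------
    values : (P, N) array
        Patients-by-regions predicted (or measured) atrophy.
    k : int
        Number of components to return (default 5; explained fractions are
        reported for all min(P-1, N) components regardless).
    """
    X = np.asarray(values, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 patients")
    n_full = min(X.shape[0] - 1, X.shape[1])
    if not 1 <= k <= n_full:
        raise ValueError(f"k must be in [1, {n_full}]")
    if np.allclose(X, X[0], atol=0):
        raise ValueError("constant matrix has zero total variance")
    pca = SignFixedPCA(n_components=n_full).fit(X)
    scores = pca.transform(X)
    return PCAResult(pca.components_[:k].copy(),
                     pca.explained_variance_ratio_.copy(),
                     scores[:, :k].copy())


def _residualize(v: np.ndarray, covariate: np.ndarray) -> np.ndarray:
    A = np.column_stack([np.ones_like(covariate), covariate])
    beta, *_ = np.linalg.lstsq(A, v, rcond=None)
    return v - A @ beta


def partial_correlation(x, y, covariate) -> AssociationResult:
    """Pearson correlation of x and y after removing a covariate from both."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    c = np.asarray(covariate, dtype=float)
    n = len(x)
    if not (len(y) == len(c) == n):
        raise ValueError("x, y and covariate must have equal length")
    if n < 4:
        raise ValueError("need at least 4 observations for a partial correlation")
    if np.ptp(c) == 0:
        raise ValueError("covariate is constant")
    rx = _residualize(x, c)
    ry = _residualize(y, c)
    sx = float(rx @ rx)
    sy = float(ry @ ry)
    # relative threshold: residual norm below ~1e-12 of the centered signal
    # means the variable is (numerically) an affine function of the covariate
    tol_x = 1e-24 * max(float((x - x.mean()) @ (x - x.mean())), np.finfo(float).tiny)
    tol_y = 1e-24 * max(float((y - y.mean()) @ (y - y.mean())), np.finfo(float).tiny)
    if sx <= tol_x or sy <= tol_y:
        raise ValueError("zero residual variance; partial correlation undefined")
    r = float(np.clip((rx @ ry) / np.sqrt(sx * sy), -1.0, 1.0))
    df = n - 3
    if abs(r) >= 1.0:
        p = 0.0
    else:
        tstat = r * np.sqrt(df / (1.0 - r * r))
        p = float(2 * stats.t.sf(abs(tstat), df))
    return AssociationResult(r, p, n, ("covariate",))


def plain_correlation(x, y) -> AssociationResult:
    """Pearson correlation with two-sided p (n - 2 degrees of freedom)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("length mismatch")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector; correlation undefined")
    res = stats.pearsonr(x, y)
    return AssociationResult(float(res.statistic), float(res.pvalue), len(x))


def fit_vs_time_since_injury(results, tsi, age) -> AssociationResult:
    """Model fit (r-squared) vs. time since injury, controlling for age."""
    r2 = np.array([r.r_squared for r in results], dtype=float)
    tsi = np.asarray(tsi, dtype=float)
    age = np.asarray(age, dtype=float)
    if not (len(tsi) == len(age) == len(r2)):
        raise ValueError("one covariate value per patient result required")
    out = partial_correlation(r2, tsi, age)
    return AssociationResult(out.r, out.p_value, out.n, ("age",))


def peaktime_vs_time_since_injury(results, tsi) -> AssociationResult:
    """Model peak time t_max vs. time since injury (plain correlation)."""
    tmax = np.array([r.t_max for r in results], dtype=float)
    tsi = np.asarray(tsi, dtype=float)
    if len(tmax) != len(tsi):
        raise ValueError("one tsi value per patient result required")
    if np.ptp(tmax) == 0:
        raise ValueError("t_max is constant across patients; correlation undefined")
    return plain_correlation(tmax, tsi)
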