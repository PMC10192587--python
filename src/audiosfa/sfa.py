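"""Slow feature analysis (linear and quadratic) with PCA and ICA baselines.

SFA finds instantaneous functions f_i of a multivariate time series x(t)
minimizing the slowness

    Delta_i = < (df_i/dt)^2 >_t

subject to zero mean, unit variance, and mutual decorrelation, with
features returned in ascending-Delta order. Linear SFA (lSFA) restricts
f_i to affine projections of the N input channels; quadratic SFA (qSFA)
first expands the input to all linear and pairwise-product monomials, so
its features are quadratic forms x^T V_i x with symmetric V_i — for the
42-channel cochlear representation that is a 903-dimensional space of
independent quadratic coefficients (945 monomial columns including the
linear terms; the constant is absorbed by mean subtraction).

The constrained problem is solved by mean subtraction, SVD whitening with
rank truncation (numerically stabler than solving the generalized
eigenproblem directly), and an eigendecomposition of the covariance of the
time-differenced whitened signal; the smallest eigenvalues are the Deltas.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

__all__ = [
    "FeatureSpace",
    "quadratic_expand",
    "quadratic_dim",
    "slowness",
    "fit_sfa",
    "fit_pca",
    "fit_ica",
    "project",
]

RANK_RTOL = 1e-7  # relative singular-value cutoff for whitening


@dataclass
class FeatureSpace:
    """A learned projection from (expanded) input space to M features.

    ``weights`` is E x M over the expanded basis, ``offset`` length M;
    projecting data Z (after expansion) gives ``Z @ weights + offset``.
    ``spectrum`` holds slowness Delta_i (SFA, ascending), explained variance
    (PCA, descending), or None (ICA). ``quadratic_monomials`` reports the
    count of independent symmetric-quadratic coefficients, N(N+1)/2.
    """

    algorithm: str  # lSFA | qSFA | PCA | ICA
    weights: np.ndarray
    offset: np.ndarray
    spectrum: np.ndarray | None
    input_dim: int
    expansion: str  # identity | quadratic
    n_kept: int
    rate: float = 1.0
    meta: dict = field(default_factory=dict)

    @property
    def expanded_dim(self) -> int:
        return self.weights.shape[0]

    @property
    def quadratic_monomials(self) -> int:
        return quadratic_dim(self.input_dim)


def quadratic_dim(n: int) -> int:
    """Number of independent symmetric-quadratic coefficients over n channels."""
    return n * (n + 1) // 2


def _as_matrix(X) -> tuple[np.ndarray, float, bool]:
    if hasattr(X, "values"):
        return np.asarray(X.values, dtype=np.float64), float(X.rate), \
            bool(getattr(X, "normalized", False))
    return np.asarray(X, dtype=np.float64), 1.0, False


def quadratic_expand(X, check_normalized: bool = True) -> np.ndarray:
    """All N linear plus N(N+1)/2 pairwise-product monomials per sample.

    Input channels must be z-scored (the expansion is meant to act on
    normalized cochlear responses); the constant monomial is omitted because
    mean subtraction absorbs it.
    """
    M, _, normalized = _as_matrix(X)
    if check_normalized and not normalized:
        mu = np.abs(M.mean(axis=0)).max()
        var = np.abs(M.var(axis=0) - 1.0).max()
        if mu > 1e-6 or var > 1e-3:
            raise ValueError("input must be normalized (zero mean, unit "
                             "variance per channel) before expansion")
    T, N = M.shape
    iu, ju = np.triu_indices(N)
    return np.hstack([M, M[:, iu] * M[:, ju]])


def slowness(f: np.ndarray, rate: float = 1.0) -> float:
    """Mean squared time derivative, first-difference discretization.

    For a unit-variance sinusoid of angular frequency w this converges to
    w**2 as sampling densifies.
    """
    f = np.asarray(f, dtype=np.float64)
    if f.size < 2:
        raise ValueError("need at least 2 samples")
    d = np.diff(f) * rate
    return float(np.mean(d**2))


def _expand(X_mat: np.ndarray, expansion: str, check: bool) -> np.ndarray:
    if expansion == "identity":
        return X_mat
    if expansion == "quadratic":
        return quadratic_expand(X_mat, check_normalized=check)
    raise ValueError(f"unknown expansion {expansion!r}")


def _whiten(Z: np.ndarray):
    T = Z.shape[0]
    mu = Z.mean(axis=0)
    Zc = Z - mu
    U, s, Vt = np.linalg.svd(Zc, full_matrices=False)
    rank = int(np.sum(s > RANK_RTOL * s[0]))
    # columns of W map original coords to whitened coords (unit variance,
    # population denominator)
    W = Vt[:rank].T * (np.sqrt(T) / s[:rank])
    return mu, W, rank, U[:, :rank] * np.sqrt(T)


def fit_sfa(X, expansion: str = "identity", n_features: int = 5) -> FeatureSpace:
    """Fit linear or quadratic SFA on a (normalized) cochleagram.

    Returns the ``n_features`` slowest features in ascending-Delta order.
    On the training data the features have zero mean, unit variance, and
    pairwise correlations at numerical zero. Raises if ``n_features``
    exceeds the numerical rank of the (expanded) data.
    """
    M, rate, normalized = _as_matrix(X)
    T, N = M.shape
    Z = _expand(M, expansion, check=normalized or expansion == "quadratic")
    mu, W, rank, Zw = _whiten(Z)
    if n_features > rank:
        raise ValueError(
            f"requested {n_features} features but numerical rank is {rank}")
    D = np.diff(Zw, axis=0) * rate
    Cdot = (D.T @ D) / D.shape[0]
    evals, evecs = np.linalg.eigh(Cdot)  # ascending
    sel = evecs[:, :n_features]
    weights = W @ sel
    # sign convention: the largest-|.| loading of each feature is positive
    for j in range(weights.shape[1]):
        i = np.argmax(np.abs(weights[:, j]))
        if weights[i, j] < 0:
            weights[:, j] = -weights[:, j]
    offset = -mu @ weights
    algo = "qSFA" if expansion == "quadratic" else "lSFA"
    return FeatureSpace(algorithm=algo, weights=weights, offset=offset,
                        spectrum=evals[:n_features].copy(), input_dim=N,
                        expansion=expansion, n_kept=n_features, rate=rate,
                        meta={"rank": rank, "expanded_dim": Z.shape[1],
                              "n_samples": T})


def fit_pca(X, n_features: int = 5) -> FeatureSpace:
    """PCA via SVD; descending explained-variance order."""
    M, rate, _ = _as_matrix(X)
    T, N = M.shape
    mu = M.mean(axis=0)
    U, s, Vt = np.linalg.svd(M - mu, full_matrices=False)
    rank = int(np.sum(s > RANK_RTOL * s[0]))
    if n_features > rank:
        raise ValueError(
            f"requested {n_features} features but numerical rank is {rank}")
    weights = Vt[:n_features].T
    for j in range(weights.shape[1]):
        i = np.argmax(np.abs(weights[:, j]))
        if weights[i, j] < 0:
            weights[:, j] = -weights[:, j]
    offset = -mu @ weights
    variances = (s[:n_features] ** 2) / T
    return FeatureSpace(algorithm="PCA", weights=weights, offset=offset,
                        spectrum=variances, input_dim=N, expansion="identity",
                        n_kept=n_features, rate=rate, meta={"rank": rank})


def fit_ica(X, n_features: int = 3, seed: int = 0,
            max_iter: int = 1000, tol: float = 1e-3,
            n_restarts: int = 3) -> FeatureSpace:
    """FastICA (whitened, fixed-point) with a deterministic seed.

    Three features by default: the stimuli contain at most three underlying
    sources (two foreground events and the background). Restarts with
    derived seeds on non-convergence, then raises with diagnostics.
    """
    M, rate, _ = _as_matrix(X)
    T, N = M.shape
    if n_features > N:
        raise ValueError("n_features cannot exceed the channel count")
    last_warning = None
    for attempt in range(n_restarts):
        ica = FastICA(n_components=n_features, whiten="unit-variance",
                      max_iter=max_iter, tol=tol,
                      random_state=int(seed) + attempt)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            ica.fit(M)
            conv = [w for w in caught if issubclass(w.category, ConvergenceWarning)]
        if not conv:
            weights = ica.components_.T  # M @ weights after centering
            mu = ica.mean_
            offset = -mu @ weights
            return FeatureSpace(algorithm="ICA", weights=weights, offset=offset,
                                spectrum=None, input_dim=N,
                                expansion="identity", n_kept=n_features,
                                rate=rate,
                                meta={"n_iter": int(ica.n_iter_),
                                      "seed": int(seed) + attempt})
        last_warning = conv[-1].message
    raise RuntimeError(
        f"FastICA failed to converge in {max_iter} iterations after "
        f"{n_restarts} restarts (tol={tol}): {last_warning}")


def project(space: FeatureSpace, X) -> np.ndarray:
    """Apply a learned feature space to data; returns a T x M matrix."""
    M, _, normalized = _as_matrix(X)
    if M.shape[1] != space.input_dim:
        raise ValueError(
            f"input has {M.shape[1]} channels, space expects {space.input_dim}")
    Z = _expand(M, space.expansion, check=False)
    return Z @ space.weights + space.offset
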