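"""RBF hidden-layer mapping and per-class moment estimation.

The hidden layer lifts a feature vector x into K Gaussian activations
f_k(x) = exp(-||x - c_k||^2 / sigma_k^2).  Centers come from k-means on the
training features (center placement is otherwise unconstrained by the
model); each width is the mean distance from its center to the two nearest
other centers, a standard heuristic that keeps neighbouring basis functions
overlapping.

Class moments (mean, covariance) of the mapped data feed the minimax
probability machine.  Covariances use the 1/N convention and receive a
small ridge because mapped features are highly collinear.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.cluster import KMeans

from .exceptions import ConfigurationError, InsufficientDataError, ShapeError


@dataclass(frozen=True)
class RBFMap:
    """K centers and widths defining the hidden-layer mapping."""

    centers: np.ndarray  # (K, d)
    widths: np.ndarray  # (K,)
    feature_names: tuple[str, ...] | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        widths = np.asarray(self.widths, dtype=float).ravel()
        if centers.shape[0] != widths.size or centers.shape[0] < 1:
            raise ConfigurationError("centers/widths count mismatch")
        if not np.all(np.isfinite(centers)):
            raise ConfigurationError("centers must be finite")
        if not np.all(widths > 0):
            raise ConfigurationError("every width must be > 0")
        object.__setattr__(self, "centers", centers)
        object.__setattr__(self, "widths", widths)

    @property
    def n_neurons(self) -> int:
        return self.centers.shape[0]

    @property
    def n_features(self) -> int:
        return self.centers.shape[1]

    def to_dict(self) -> dict:
        return {
            "K": self.n_neurons,
            "centers": self.centers.ravel().tolist(),  # row-major
            "widths": self.widths.tolist(),
            "feature_names": list(self.feature_names) if self.feature_names else None,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RBFMap":
        k = int(d["K"])
        centers = np.array(d["centers"], dtype=float).reshape(k, -1)
        names = tuple(d["feature_names"]) if d.get("feature_names") else None
        return cls(centers, np.array(d["widths"], dtype=float), names, d.get("seed"))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "RBFMap":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _width_heuristic(centers: np.ndarray) -> np.ndarray:
    """Mean distance from each center to its two nearest other centers
    (one for K=2; sigma = 1 for a single center).  Zero distances (duplicate
    centers) fall back to sigma = 1 to keep widths positive."""
    k = centers.shape[0]
    if k == 1:
        return np.ones(1)
    diff = centers[:, None, :] - centers[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=2))
    np.fill_diagonal(dist, np.inf)
    n_near = min(2, k - 1)
    widths = np.sort(dist, axis=1)[:, :n_near].mean(axis=1)
    widths[widths <= 0] = 1.0
    return widths


def fit_rbf_map(
    X: np.ndarray,
    n_neurons: int,
    seed: int,
    feature_names: tuple[str, ...] | None = None,
) -> RBFMap:
    """Fit centers (k-means) and widths on training feature vectors.

    Deterministic given the seed.  n_neurons = 1 degenerates to the data
    mean with width 1.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if n_neurons < 1:
        raise ConfigurationError("n_neurons must be >= 1")
    if n_neurons > n:
        raise ConfigurationError(
            f"n_neurons = {n_neurons} exceeds the {n} training vectors"
        )
    if n_neurons == 1:
        centers = X.mean(axis=0, keepdims=True)
    else:
        km = KMeans(n_clusters=n_neurons, random_state=seed, n_init=10)
        km.fit(X)
        centers = km.cluster_centers_
    return RBFMap(centers, _width_heuristic(centers), feature_names, seed)


def rbf_transform(rbf_map: RBFMap, X: np.ndarray) -> np.ndarray:
    """Map feature vectors into hidden-layer space; components in (0, 1].

    Accepts a single vector (returns shape (K,)) or a matrix (returns
    (n, K)).
    """
    X = np.asarray(X, dtype=float)
    single = X.ndim == 1
    X2 = np.atleast_2d(X)
    if X2.shape[1] != rbf_map.n_features:
        raise ShapeError(
            f"expected {rbf_map.n_features} features, got {X2.shape[1]}"
        )
    diff = X2[:, None, :] - rbf_map.centers[None, :, :]
    sq = (diff ** 2).sum(axis=2)
    out = np.exp(-sq / rbf_map.widths[None, :] ** 2)
    return out[0] if single else out


@dataclass(frozen=True)
class ClassMoments:
    """Sample mean and (ridge-regularized) covariance of one class's mapped data."""

    mean: np.ndarray
    covariance: np.ndarray
    n: int

    def __post_init__(self) -> None:
        mean = np.asarray(self.mean, dtype=float).ravel()
        cov = np.asarray(self.covariance, dtype=float)
        if cov.shape != (mean.size, mean.size):
            raise ConfigurationError("covariance shape does not match mean")
        if not np.allclose(cov, cov.T, atol=1e-10):
            raise ConfigurationError("covariance must be symmetric")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "covariance", cov)


RIDGE_REL = 1e-6
RIDGE_ABS = 1e-12


def estimate_moments(Z: np.ndarray, ridge_rel: float = RIDGE_REL) -> ClassMoments:
    """Mean and 1/N covariance of mapped vectors, plus ridge lambda*I.

    lambda = ridge_rel * trace/K + a tiny absolute floor, so point-mass
    classes still yield a positive-definite covariance.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    n, k = Z.shape
    if n < 2:
        raise InsufficientDataError(f"need >= 2 vectors to estimate moments, got {n}")
    mean = Z.mean(axis=0)
    centered = Z - mean
    cov = centered.T @ centered / n
    cov = 0.5 * (cov + cov.T)
    lam = ridge_rel * np.trace(cov) / k + RIDGE_ABS
    cov = cov + lam * np.eye(k)
    return ClassMoments(mean, cov, n)
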