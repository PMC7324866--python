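"""Binary minimax probability machine (MPM).

Given only the mean and covariance of each class, the MPM finds the
hyperplane w'x = b maximizing the distribution-free lower bound alpha on
the correct-classification probability of both classes:

    minimize  sqrt(w' S+ w) + sqrt(w' S- w)   s.t.  w'(mu+ - mu-) = 1

with  kappa* = 1/objective,  alpha* = kappa^2/(1+kappa^2)
            = 1 / (1 + (sqrt(w'S+w) + sqrt(w'S-w))^2),
and threshold  b* = w'mu+ - kappa* sqrt(w'S+w)  (so both classes attain the
same worst-case guarantee).  alpha doubles as a separability index between
the two classes: the closer to 1, the more reliably they separate.

The default solver is the classic iterative least-squares scheme: each step
minimizes the convex quadratic majorant

    w'S+w / (2 b+) + w'S-w / (2 b-) + const,   b± = sqrt(w'S± w) at the
    current iterate,

subject to the linear constraint, which is a single linear solve.  The
objective decreases monotonically and the problem is convex, so the scheme
converges to the global optimum.  A second, independent path
(``method="reduced"``) minimizes the objective on the constraint's null
space with scipy's BFGS and serves as a cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.optimize

from .exceptions import ConfigurationError, InseparableMeansError, ShapeError
from .rbfmap import ClassMoments

MAX_ITER = 200
TOL = 1e-8
_BETA_FLOOR = 1e-15


@dataclass(frozen=True)
class MPMModel:
    """One pair's separating hyperplane, separability index and metadata.

    ``class_pos`` is the class on the w'z >= b side (by convention the lower
    class index of the pair).  ``degenerate`` marks pairs whose means
    coincided: alpha is 0 and decisions fall back to distance-to-mean.
    """

    w: np.ndarray
    b: float
    alpha: float
    gamma: float
    class_pos: int
    class_neg: int
    converged: bool = True
    iterations: int = 0
    degenerate: bool = False
    mu_pos: np.ndarray | None = None
    mu_neg: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "w", np.asarray(self.w, dtype=float).ravel())
        if self.mu_pos is not None:
            object.__setattr__(self, "mu_pos", np.asarray(self.mu_pos, dtype=float))
        if self.mu_neg is not None:
            object.__setattr__(self, "mu_neg", np.asarray(self.mu_neg, dtype=float))
        if not self.degenerate and not 0.0 <= self.alpha < 1.0:
            raise ConfigurationError(f"alpha must be in [0, 1), got {self.alpha}")

    @property
    def pair(self) -> tuple[int, int]:
        return (self.class_pos, self.class_neg)

    def to_dict(self) -> dict:
        return {
            "class_pos": self.class_pos,
            "class_neg": self.class_neg,
            "w": self.w.tolist(),
            "b": self.b,
            "alpha": self.alpha,
            "gamma": self.gamma,
            "converged": self.converged,
            "iterations": self.iterations,
            "degenerate": self.degenerate,
            "mu_pos": self.mu_pos.tolist() if self.mu_pos is not None else None,
            "mu_neg": self.mu_neg.tolist() if self.mu_neg is not None else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MPMModel":
        return cls(
            w=np.array(d["w"], dtype=float),
            b=float(d["b"]),
            alpha=float(d["alpha"]),
            gamma=float(d["gamma"]),
            class_pos=int(d["class_pos"]),
            class_neg=int(d["class_neg"]),
            converged=bool(d["converged"]),
            iterations=int(d["iterations"]),
            degenerate=bool(d.get("degenerate", False)),
            mu_pos=None if d.get("mu_pos") is None else np.array(d["mu_pos"]),
            mu_neg=None if d.get("mu_neg") is None else np.array(d["mu_neg"]),
        )


def _objective(w: np.ndarray, cov_pos: np.ndarray, cov_neg: np.ndarray) -> float:
    return float(
        math.sqrt(max(w @ cov_pos @ w, 0.0)) + math.sqrt(max(w @ cov_neg @ w, 0.0))
    )


def _solve_mm(a: np.ndarray, cov_pos: np.ndarray, cov_neg: np.ndarray):
    """Iterative least-squares (majorize-minimize) on the MPM program."""
    k = a.size
    w = a / (a @ a)  # feasible start: w'a = 1
    obj = _objective(w, cov_pos, cov_neg)
    converged = False
    it = 0
    for it in range(1, MAX_ITER + 1):
        beta_p = max(math.sqrt(max(w @ cov_pos @ w, 0.0)), _BETA_FLOOR)
        beta_n = max(math.sqrt(max(w @ cov_neg @ w, 0.0)), _BETA_FLOOR)
        q = cov_pos / beta_p + cov_neg / beta_n
        try:
            c, low = scipy.linalg.cho_factor(q)
            qa = scipy.linalg.cho_solve((c, low), a)
        except scipy.linalg.LinAlgError:
            qa = np.linalg.solve(q + 1e-12 * np.trace(q) / k * np.eye(k), a)
        w_new = qa / (a @ qa)
        obj_new = _objective(w_new, cov_pos, cov_neg)
        if abs(obj - obj_new) <= TOL * (1.0 + obj_new):
            w, obj = w_new, obj_new
            converged = True
            break
        w, obj = w_new, obj_new
    return w, obj, converged, it


def _solve_reduced(a: np.ndarray, cov_pos: np.ndarray, cov_neg: np.ndarray):
    """Cross-check path: eliminate the constraint via a null-space basis of
    a' and minimize the (convex, unconstrained) reduced objective with BFGS."""
    k = a.size
    w0 = a / (a @ a)
    if k == 1:
        return w0, _objective(w0, cov_pos, cov_neg), True, 0
    basis = scipy.linalg.null_space(a.reshape(1, -1))  # (k, k-1)

    def f(u: np.ndarray) -> float:
        return _objective(w0 + basis @ u, cov_pos, cov_neg)

    res = scipy.optimize.minimize(
        f, np.zeros(k - 1), method="BFGS",
        options={"gtol": 1e-12, "maxiter": 2000},
    )
    w = w0 + basis @ res.x
    return w, _objective(w, cov_pos, cov_neg), bool(res.success), int(res.nit)


def solve_mpm(
    moments_pos: ClassMoments,
    moments_neg: ClassMoments,
    class_pos: int = 1,
    class_neg: int = 0,
    method: str = "mm",
) -> MPMModel:
    """Solve the MPM program for one pair of classes.

    Raises :class:`InseparableMeansError` when the class means coincide
    (callers building the pairwise bank map this to a degenerate alpha = 0
    model).
    """
    mu_p, mu_n = moments_pos.mean, moments_neg.mean
    if mu_p.shape != mu_n.shape:
        raise ShapeError("class moments have different dimensionality")
    a = mu_p - mu_n
    if np.linalg.norm(a) < 1e-12:
        raise InseparableMeansError(
            f"classes {class_pos} and {class_neg} have coincident means"
        )
    if method == "mm":
        w, obj, converged, it = _solve_mm(a, moments_pos.covariance, moments_neg.covariance)
    elif method == "reduced":
        w, obj, converged, it = _solve_reduced(a, moments_pos.covariance, moments_neg.covariance)
    else:
        raise ConfigurationError(f"unknown solver method {method!r}")
    gamma = 1.0 / obj if obj > 0 else math.inf
    alpha = alpha_index(w, moments_pos.covariance, moments_neg.covariance)
    beta_p = math.sqrt(max(w @ moments_pos.covariance @ w, 0.0))
    b = float(w @ mu_p - gamma * beta_p)
    return MPMModel(
        w=w, b=b, alpha=alpha, gamma=gamma,
        class_pos=class_pos, class_neg=class_neg,
        converged=converged, iterations=it,
        mu_pos=mu_p, mu_neg=mu_n,
    )


def alpha_index(w: np.ndarray, cov_pos: np.ndarray, cov_neg: np.ndarray) -> float:
    """Separability index alpha = 1/(1 + (sqrt(w'S+w) + sqrt(w'S-w))^2).

    At the optimal w this is the distribution-free lower bound on both
    classes' correct-classification probability.
    """
    w = np.asarray(w, dtype=float).ravel()
    if np.linalg.norm(w) == 0:
        raise ConfigurationError("alpha undefined for w = 0")
    obj = _objective(w, np.asarray(cov_pos), np.asarray(cov_neg))
    if obj == 0:
        return 1.0 - np.finfo(float).eps
    return 1.0 / (1.0 + obj * obj)


def mpm_decide(model: MPMModel, z: np.ndarray) -> int:
    """Classify one mapped vector: class_pos iff w'z >= b (ties to class_pos).

    Degenerate pairs fall back to distance-to-mean (ties again to
    class_pos).
    """
    z = np.asarray(z, dtype=float).ravel()
    if model.degenerate:
        if model.mu_pos is None or model.mu_neg is None:
            return model.class_pos
        d_pos = np.linalg.norm(z - model.mu_pos)
        d_neg = np.linalg.norm(z - model.mu_neg)
        return model.class_pos if d_pos <= d_neg else model.class_neg
    if z.shape != model.w.shape:
        raise ShapeError(f"expected dimension {model.w.size}, got {z.size}")
    return model.class_pos if float(model.w @ z) >= model.b else model.class_neg


def decision_margin(model: MPMModel, Z: np.ndarray) -> np.ndarray:
    """Signed margins w'z - b (positive favours class_pos); (n,) array."""
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if model.degenerate:
        d_pos = np.linalg.norm(Z - model.mu_pos, axis=1)
        d_neg = np.linalg.norm(Z - model.mu_neg, axis=1)
        return d_neg - d_pos
    if Z.shape[1] != model.w.size:
        raise ShapeError(f"expected dimension {model.w.size}, got {Z.shape[1]}")
    return Z @ model.w - model.b


def degenerate_model(
    mu_pos: np.ndarray, mu_neg: np.ndarray, class_pos: int, class_neg: int
) -> MPMModel:
    """alpha = 0 placeholder for a pair with coincident means."""
    mu_pos = np.asarray(mu_pos, dtype=float)
    return MPMModel(
        w=np.zeros_like(mu_pos), b=0.0, alpha=0.0, gamma=0.0,
        class_pos=class_pos, class_neg=class_neg,
        converged=True, iterations=0, degenerate=True,
        mu_pos=mu_pos, mu_neg=np.asarray(mu_neg, dtype=float),
    )
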