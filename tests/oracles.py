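"""Independent reference implementations used only by the tests.

Deliberately naive: explicit Python loops and enumeration, no shared code
with the package, so they can serve as oracles for the vectorized
implementations.
"""

from __future__ import annotations

import math
from itertools import permutations

import numpy as np
import scipy.linalg
import scipy.optimize


def apen_bruteforce(x, m: int, r: float) -> float:
    """Pincus ApEn via double loops: phi^m - phi^{m+1}, self-matches included."""
    x = list(map(float, x))
    n = len(x)

    def phi(mm):
        nt = n - mm + 1
        templates = [x[i : i + mm] for i in range(nt)]
        total = 0.0
        for i in range(nt):
            count = 0
            for j in range(nt):
                d = max(abs(a - b) for a, b in zip(templates[i], templates[j]))
                if d <= r:
                    count += 1
            total += math.log(count / nt)
        return total / nt

    return phi(m) - phi(m + 1)


def sampen_bruteforce(x, m: int, r: float) -> float | None:
    """Richman–Moorman SampEn via pair counting, self-matches excluded.

    Returns None when A or B is zero (entropy undefined).
    """
    x = list(map(float, x))
    n = len(x)
    nt = n - m

    def count_pairs(mm):
        templates = [x[i : i + mm] for i in range(nt)]
        c = 0
        for i in range(nt):
            for j in range(nt):
                if i == j:
                    continue
                d = max(abs(a - b) for a, b in zip(templates[i], templates[j]))
                if d <= r:
                    c += 1
        return c

    b = count_pairs(m)
    a = count_pairs(m + 1)
    if a == 0 or b == 0:
        return None
    return -math.log(a / b)


def permutation_entropy_bruteforce(x, m: int, tau: int = 1) -> float:
    """Normalized PE by explicit pattern enumeration; ties -> earlier index."""
    x = list(map(float, x))
    n_vec = len(x) - (m - 1) * tau
    counts = {p: 0 for p in permutations(range(m))}
    for t in range(n_vec):
        window = [x[t + k * tau] for k in range(m)]
        order = tuple(sorted(range(m), key=lambda i: (window[i], i)))
        counts[order] += 1
    h = 0.0
    for c in counts.values():
        if c:
            p = c / n_vec
            h -= p * math.log(p)
    return h / math.log(math.factorial(m))


def mpm_oracle(mu_pos, mu_neg, cov_pos, cov_neg):
    """Generic convex-solver reference for the MPM program.

    Minimizes sqrt(w'S+w) + sqrt(w'S-w) subject to w'(mu+ - mu-) = 1 with
    SLSQP on the full w (different path from the package's majorize-minimize
    and null-space solvers).  Returns (w, objective, alpha).
    """
    mu_pos = np.asarray(mu_pos, float)
    mu_neg = np.asarray(mu_neg, float)
    cov_pos = np.asarray(cov_pos, float)
    cov_neg = np.asarray(cov_neg, float)
    a = mu_pos - mu_neg

    def f(w):
        return math.sqrt(max(w @ cov_pos @ w, 0.0)) + math.sqrt(
            max(w @ cov_neg @ w, 0.0)
        )

    w0 = a / (a @ a)
    res = scipy.optimize.minimize(
        f,
        w0,
        method="SLSQP",
        constraints=[{"type": "eq", "fun": lambda w: w @ a - 1.0}],
        options={"maxiter": 2000, "ftol": 1e-14},
    )
    obj = f(res.x)
    return res.x, obj, 1.0 / (1.0 + obj * obj)


def random_psd(rng: np.random.Generator, k: int, scale: float = 1.0) -> np.ndarray:
    """Random symmetric positive-definite matrix with eigenvalues >= ~0.05."""
    q = rng.standard_normal((k, k))
    m = q @ q.T / k
    return scale * (m + 0.05 * np.eye(k))
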