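"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the library's own code paths (and numpy shortcuts
where the point is the formula): the variance oracle is a two-pass textbook
sum, the eigen oracle is power iteration with deflation.
"""

from __future__ import annotations

import math

import numpy as np


def two_pass_variance(values) -> float:
    """Textbook unbiased variance: explicit two-pass summation."""
    values = list(float(v) for v in values)
    n = len(values)
    if n < 2:
        raise ValueError("need at least 2 values")
    mean = sum(values) / n
    return sum((v - mean) ** 2 for v in values) / (n - 1)


def euclidean_displacements(coords) -> list[float]:
    """Hand-rolled consecutive Euclidean distances."""
    out = []
    for (x0, y0), (x1, y1) in zip(coords[:-1], coords[1:]):
        out.append(math.sqrt((x1 - x0) ** 2 + (y1 - y0) ** 2))
    return out


def power_iteration_eigh(matrix: np.ndarray, n_components: int = 2,
                         iters: int = 5000, seed: int = 0):
    """Leading eigenpairs of a symmetric PSD matrix by power iteration.

    Uses Hotelling deflation; returns (eigenvalues, eigenvectors) with
    eigenvectors in columns, each unit norm.
    """
    A = np.asarray(matrix, dtype=float).copy()
    rng = np.random.default_rng(seed)
    p = A.shape[0]
    evals, evecs = [], []
    for _ in range(n_components):
        v = rng.normal(size=p)
        v /= np.linalg.norm(v)
        for _ in range(iters):
            w = A @ v
            norm = np.linalg.norm(w)
            if norm == 0:
                break
            w /= norm
            if np.linalg.norm(w - v) < 1e-14:
                v = w
                break
            v = w
        lam = float(v @ A @ v)
        evals.append(lam)
        evecs.append(v)
        A = A - lam * np.outer(v, v)
    return np.array(evals), np.column_stack(evecs)


def bh_adjust(p_values) -> list[float]:
    """Hand Benjamini-Hochberg step-up: p_(i) * m / i with cumulative min."""
    p = list(map(float, p_values))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        adjusted[i] = running
    return adjusted
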