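"""Oblique factor rotation by gradient projection (quartimin/oblimin).

Implements the gradient-projection algorithm of Jennrich (2002) as laid out
by Bernaards & Jennrich (2005) for oblique rotation with the quartimin
criterion (oblimin with gamma = 0).
"""

from __future__ import annotations

import numpy as np
from scipy import linalg

__all__ = ["oblimin_rotate"]


def _quartimin(L: np.ndarray) -> tuple[float, np.ndarray]:
    """Quartimin criterion value and gradient with respect to the loadings."""
    L2 = L**2
    m = L.shape[1]
    N = np.ones((m, m)) - np.eye(m)
    X = L2 @ N
    f = float(np.sum(L2 * X) / 4.0)
    G = L * X
    return f, G


def oblimin_rotate(A: np.ndarray, max_iter: int = 1000, tol: float = 1e-7,
                   n_starts: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Rotate an unrotated loading matrix obliquely to quartimin simplicity.

    Returns the rotated pattern matrix and the factor correlation matrix
    Phi = T'T. The identity start can be a saddle point for symmetric
    loading patterns, so several extra starts from a fixed internal seed
    are tried and the lowest criterion value kept; the procedure is
    deterministic.
    """
    A = np.asarray(A, dtype=float)
    p, m = A.shape
    if m < 2:
        return A.copy(), np.ones((1, 1))

    rng = np.random.default_rng(1729)
    starts = [np.eye(m)]
    for _ in range(n_starts - 1):
        X = rng.standard_normal((m, m))
        starts.append(X / np.sqrt(np.sum(X**2, axis=0)))
    best = None
    for T0 in starts:
        L, Phi, f = _gpa_oblq(A, T0, max_iter, tol)
        if best is None or f < best[2]:
            best = (L, Phi, f)
    return best[0], best[1]


def _gpa_oblq(A: np.ndarray, T: np.ndarray, max_iter: int,
              tol: float) -> tuple[np.ndarray, np.ndarray, float]:
    p, m = A.shape
    T = T.copy()
    Ti = linalg.inv(T)
    L = A @ Ti.T
    f, Gq = _quartimin(L)
    G = -(L.T @ Gq @ Ti).T
    al = 1.0
    for _ in range(max_iter):
        Gp = G - T @ np.diag(np.sum(T * G, axis=0))
        s = np.sqrt(np.sum(Gp**2))
        if s < tol:
            break
        al *= 2.0
        for _ in range(30):
            X = T - al * Gp
            v = 1.0 / np.sqrt(np.sum(X**2, axis=0))
            Tt = X * v
            Ti = linalg.inv(Tt)
            L = A @ Ti.T
            ft, Gq = _quartimin(L)
            if ft < f - 0.5 * s**2 * al:
                break
            al /= 2.0
        T = Tt
        f = ft
        G = -(L.T @ Gq @ linalg.inv(T)).T
    Phi = T.T @ T
    return L, Phi, f
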