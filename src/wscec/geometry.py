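"""Bures-Wasserstein geometry on the manifold SPD(n).

The manifold of n-by-n symmetric positive-definite matrices carries a
Riemannian metric whose geodesic distance between two centred Gaussians
equals their L2 optimal-transport (Wasserstein) distance.  At a base point
``S`` the metric, the Riemann curvature tensor and the scalar curvature are
all expressed through the solution ``Gamma_S[Y]`` of the Sylvester equation

    S @ Gamma + Gamma @ S = Y,

which is solved entrywise in the eigenbasis of ``S``.

The scalar curvature is the full double trace of the curvature tensor over
a g-orthonormal basis of the n(n+1)/2-dimensional tangent space.  A closed
form in the eigenvalues of ``S`` is provided (:func:`scalar_curvature`)
together with a brute-force basis-sum oracle
(:func:`scalar_curvature_oracle`) used to validate it.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "SYM_TOL",
    "EIG_TOL",
    "is_spd",
    "spd_sqrt",
    "wasserstein_gaussian",
    "sylvester_gamma",
    "metric_gw",
    "curvature_tensor",
    "scalar_curvature",
    "scalar_curvature_oracle",
    "curvature_upper_bound",
]

# Centralised numerical tolerances.
SYM_TOL = 1e-12   # max asymmetry tolerated before symmetrisation is an error
EIG_TOL = 1e-12   # eigenvalues below this (relative to the largest) are not SPD


def _sym(S: np.ndarray) -> np.ndarray:
    return 0.5 * (S + S.T)


def is_spd(S: np.ndarray, tol: float = EIG_TOL) -> bool:
    """True if ``S`` is symmetric with all eigenvalues positive."""
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        return False
    if not np.allclose(S, S.T, atol=1e-8, rtol=0):
        return False
    lam = np.linalg.eigvalsh(_sym(S))
    return bool(lam[0] > tol * max(1.0, lam[-1]))


def _eigh_spd(S: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of an SPD matrix, eigenvalues ascending.

    Raises ``ValueError`` when the smallest eigenvalue is not positive.
    """
    S = _sym(np.asarray(S, dtype=float))
    lam, O = np.linalg.eigh(S)
    if lam[0] <= 0:
        raise ValueError(
            f"matrix is not positive definite (min eigenvalue {lam[0]:.3e})"
        )
    return lam, O


def spd_sqrt(S: np.ndarray) -> np.ndarray:
    """Unique SPD square root of an SPD matrix."""
    lam, O = _eigh_spd(S)
    return (O * np.sqrt(lam)) @ O.T


def wasserstein_gaussian(
    mu1: np.ndarray,
    sigma1: np.ndarray,
    mu2: np.ndarray,
    sigma2: np.ndarray,
) -> float:
    """L2 Wasserstein distance between two Gaussians N(mu1, sigma1), N(mu2, sigma2).

    Closed form::

        W^2 = ||mu1 - mu2||^2 + tr(S1 + S2 - 2 (S1^{1/2} S2 S1^{1/2})^{1/2})

    Symmetric in its arguments and zero iff the two Gaussians coincide.
    """
    mu1 = np.atleast_1d(np.asarray(mu1, dtype=float))
    mu2 = np.atleast_1d(np.asarray(mu2, dtype=float))
    sigma1 = np.atleast_2d(np.asarray(sigma1, dtype=float))
    sigma2 = np.atleast_2d(np.asarray(sigma2, dtype=float))
    root1 = spd_sqrt(sigma1)
    cross = _sym(root1 @ sigma2 @ root1)
    lam = np.linalg.eigvalsh(cross)
    # cross is PSD up to roundoff; clip tiny negative eigenvalues
    tr_cross = np.sqrt(np.clip(lam, 0.0, None)).sum()
    dmu2 = np.dot(mu1 - mu2, mu1 - mu2)
    w2 = dmu2 + np.trace(sigma1) + np.trace(sigma2) - 2.0 * tr_cross
    # w2 is a difference of traces; below the roundoff floor it is zero
    scale = dmu2 + np.trace(sigma1) + np.trace(sigma2)
    if w2 < 1e-13 * scale:
        return 0.0
    return float(np.sqrt(w2))


def sylvester_gamma(S: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Solve ``S @ G + G @ S = Y`` for ``G`` with ``S`` SPD.

    In the eigenbasis of ``S`` the solution is entrywise division by
    ``lam_i + lam_j``; this holds for arbitrary ``Y`` (the curvature tensor
    feeds an antisymmetric commutator through the same solve).
    """
    lam, O = _eigh_spd(S)
    Yt = O.T @ np.asarray(Y, dtype=float) @ O
    G = Yt / (lam[:, None] + lam[None, :])
    return O @ G @ O.T


def metric_gw(S: np.ndarray, X: np.ndarray, Y: np.ndarray) -> float:
    """Wasserstein metric ``g_W|_S(X, Y) = tr(Gamma_S[Y] X) / 2`` at base point S."""
    return 0.5 * float(np.trace(sylvester_gamma(S, Y) @ np.asarray(X, dtype=float)))


def curvature_tensor(S: np.ndarray, X: np.ndarray, Y: np.ndarray) -> float:
    """Riemann curvature ``<R(X, Y)X, Y>`` of the Wasserstein metric at S.

        R(X,Y,X,Y) = 3 tr( G[X] S G[ G[X]G[Y] - G[Y]G[X] ] S G[Y] ),

    with ``G = Gamma_S``.  Vanishes when X and Y are parallel and is
    invariant under simultaneous orthogonal conjugation of S, X, Y.
    """
    S = _sym(np.asarray(S, dtype=float))
    gx = sylvester_gamma(S, X)
    gy = sylvester_gamma(S, Y)
    comm = gx @ gy - gy @ gx
    return 3.0 * float(np.trace(gx @ S @ sylvester_gamma(S, comm) @ S @ gy))


def _curvature_traces(lam: np.ndarray) -> float:
    """Trace polynomial of the scalar curvature in the sorted spectrum."""
    n = lam.size
    U = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    U[iu] = 1.0 / (lam[iu[0]] + lam[iu[1]])
    A = U + U.T
    L = np.diag(lam)
    return float(np.trace(U @ L @ A + A @ L @ U + A @ L @ U @ L @ A))


def scalar_curvature(S: np.ndarray) -> float:
    """Wasserstein scalar curvature of SPD(n) at ``S``.

    Depends only on the spectrum: with eigenvalues sorted ascending,
    ``Lam = diag(lam)`` and ``U`` the strictly upper-triangular matrix with
    entries ``1 / (lam_i + lam_j)`` for ``i < j``,

        rho(S) = 6 tr( U Lam (U+U') + (U+U') Lam U + (U+U') Lam U Lam (U+U') ).

    The prefactor 6 makes this the genuine double sum of the curvature
    tensor over all ordered pairs of a g-orthonormal tangent basis (each
    unordered pair counted twice); it is pinned to
    :func:`scalar_curvature_oracle` by the test suite.  Strictly positive,
    scales as ``rho(c S) = rho(S) / c`` and obeys
    ``rho(S) < 3 n (n-1) / lam_min2(S)``.
    """
    lam, _ = _eigh_spd(S)
    return 6.0 * _curvature_traces(lam)


def _symmetric_basis(n: int) -> list[np.ndarray]:
    """Coordinate basis of the n(n+1)/2-dim space of symmetric matrices."""
    basis = []
    for i in range(n):
        E = np.zeros((n, n))
        E[i, i] = 1.0
        basis.append(E)
    for i in range(n):
        for j in range(i + 1, n):
            E = np.zeros((n, n))
            E[i, j] = E[j, i] = 1.0
            basis.append(E)
    return basis


def scalar_curvature_oracle(
    S: np.ndarray, basis: list[np.ndarray] | None = None
) -> float:
    """Brute-force scalar curvature: Gram-Schmidt + double curvature sum.

    Orthonormalises a basis of symmetric matrices with respect to
    :func:`metric_gw` at ``S`` and returns
    ``sum_{i,j} R(e_i, e_j, e_i, e_j)`` over all ordered pairs.  The result
    is basis-independent; intended for small n (test use).
    """
    S = _sym(np.asarray(S, dtype=float))
    n = S.shape[0]
    if basis is None:
        basis = _symmetric_basis(n)
    ortho: list[np.ndarray] = []
    for B in basis:
        B = np.asarray(B, dtype=float).copy()
        for E in ortho:
            B -= metric_gw(S, B, E) * E
        norm = metric_gw(S, B, B)
        if norm <= 0:
            raise ValueError("basis is not linearly independent")
        ortho.append(B / np.sqrt(norm))
    return float(
        sum(curvature_tensor(S, X, Y) for X in ortho for Y in ortho)
    )


def curvature_upper_bound(S: np.ndarray) -> float:
    """Analytic ceiling ``3 n (n-1) / lam_min2`` on the scalar curvature.

    ``lam_min2`` is the second-smallest eigenvalue of ``S``; the bound blows
    up only when the matrix degenerates in two or more directions, which is
    what makes curvature of well-embedded point clouds controllable.
    """
    lam, _ = _eigh_spd(S)
    n = lam.size
    if n < 2:
        raise ValueError("curvature bound requires n >= 2")
    return 3.0 * n * (n - 1) / lam[1]
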