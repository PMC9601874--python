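"""Local Gaussian statistics of a Euclidean point cloud.

Each point of an embedded cloud is assigned its k nearest neighbours
(Euclidean distance, the point itself excluded, ties broken by smaller
index), whose mean and *unnormalised* scatter matrix

    mu_i    = (1/k) sum_j N_ij
    sigma_i = sum_j (N_ij - mu_i)^T (N_ij - mu_i)

define a local Gaussian.  The scatter deliberately carries no 1/k factor:
a uniform rescaling would rescale every scalar curvature (rho(cS) =
rho(S)/c) and silently shift the diagnostic domain boxes.

Scatter matrices that are (near-)rank-deficient are regularised by adding a
small multiple of the identity so the downstream curvature formulas stay
finite; the number of regularised points is reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Neighborhood", "SPDCloudResult", "knn_indices", "local_gaussian", "spd_cloud"]

#: default eigenvalue floor, relative to the mean trace of the cloud's scatters
DEFAULT_EIG_FLOOR_REL = 1e-8


@dataclass(frozen=True)
class Neighborhood:
    center_index: int
    member_indices: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray


@dataclass(frozen=True)
class SPDCloudResult:
    """Ordered SPD matrices, one per source point, plus regularisation count."""

    matrices: np.ndarray          # shape (n_points, d, d)
    n_regularized: int
    eig_floor: float


def knn_indices(
    points: np.ndarray, i: int, k: int, include_self: bool = False
) -> np.ndarray:
    """Indices of the k nearest neighbours of point ``i``.

    Exact all-pairs search with a stable sort so that distance ties resolve
    to the smaller index; deterministic.  ``include_self`` counts the centre
    point as its own first neighbour.
    """
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    limit = n if include_self else n - 1
    if k >= limit + 1 and not include_self:
        raise ValueError(f"k={k} must be smaller than the cloud size {n}")
    if include_self and k > n:
        raise ValueError(f"k={k} exceeds the cloud size {n}")
    d2 = np.einsum("ij,ij->i", points - points[i], points - points[i])
    if not include_self:
        d2[i] = np.inf
    order = np.argsort(d2, kind="stable")
    return order[:k]


def local_gaussian(
    points: np.ndarray, i: int, k: int, include_self: bool = False
) -> Neighborhood:
    """Local mean and unnormalised scatter of the kNN neighbourhood of point i."""
    idx = knn_indices(points, i, k, include_self=include_self)
    nbrs = np.asarray(points, dtype=float)[idx]
    mu = nbrs.mean(axis=0)
    dev = nbrs - mu
    sigma = dev.T @ dev
    sigma = 0.5 * (sigma + sigma.T)
    return Neighborhood(center_index=i, member_indices=idx, mu=mu, sigma=sigma)


def spd_cloud(
    points: np.ndarray,
    k: int = 20,
    eig_floor: float | None = None,
    include_self: bool = False,
) -> SPDCloudResult:
    """SPD scatter matrix for every point of the cloud.

    Parameters
    ----------
    points : (n, d) array of embedded points.
    k : neighbourhood size (default 20).
    eig_floor : matrices whose smallest eigenvalue falls below this are
        regularised by adding ``eig_floor * I``.  Default: 1e-8 times the
        mean trace of the raw scatters (and never exactly zero).
    """
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    sigmas = np.stack([local_gaussian(points, i, k, include_self).sigma for i in range(n)])
    if eig_floor is None:
        mean_trace = float(np.trace(sigmas, axis1=1, axis2=2).mean())
        # eps (not tiny) floor: a fully degenerate cloud must still give
        # finite curvatures downstream
        eig_floor = DEFAULT_EIG_FLOOR_REL * max(mean_trace, np.finfo(float).eps)
    d = points.shape[1]
    n_reg = 0
    eye = np.eye(d)
    for j in range(n):
        lam_min = np.linalg.eigvalsh(sigmas[j])[0]
        if lam_min < eig_floor:
            sigmas[j] = sigmas[j] + eig_floor * eye
            n_reg += 1
    return SPDCloudResult(matrices=sigmas, n_regularized=n_reg, eig_floor=float(eig_floor))
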