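"""Curvature-sequence features: histogram and dispersion statistics.

For one beat, the scalar curvatures of its SPD cloud form a positive
sequence W = {w_i}.  The features are

* a histogram ``H(m, b)`` with half-open bins ``[m j, m (j+1))`` for
  ``j = 0 .. floor(b/m)`` (values at or beyond the next bin edge are
  excluded and counted separately);
* a dispersion pair ``cur = (cur1, cur2)``:

  - ``cur1`` is the median of ``U1 = {w in W : m s <= w <= b}``
    (transverse dispersion — where the curvature mass sits);
  - ``cur2`` is a corrected standard deviation of the column heights
    ``y_j`` for ``j >= s + 1`` (longitudinal dispersion — how uneven the
    columns are)::

        ybar = (sum of all counted mass in columns j >= s+1) / floor(b/m)
        cur2 = sqrt( sum_{j >= s+1} (y_j - ybar)^2 / (|U2| - s - 1) )

    with ``U2 = {j >= s+1 : y_j != 0}``.  When every column j >= 1 is
    nonzero and s = 0 this reduces to the textbook sample standard
    deviation of {y_j, j >= 1}; empty columns both enter the squared
    deviations and shrink the denominator, so vanishing columns amplify
    cur2 — the property the classifier relies on to separate concentrated
    from evenly spread histograms.

Degenerate cases (empty U1, non-positive denominator) yield a flagged,
unclassifiable result instead of NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import scalar_curvature

__all__ = [
    "CurvatureHistogram",
    "DispersionPoint",
    "wsc_sequence",
    "choose_b",
    "histogram",
    "dispersion",
]


@dataclass(frozen=True)
class CurvatureHistogram:
    m: float                 # bin width
    b: float                 # curvature ceiling
    counts: np.ndarray       # y_j for j = 0 .. floor(b/m)
    n_excluded: int          # values at or above the last bin edge

    @property
    def n_bins(self) -> int:
        return self.counts.size

    def bin_edges(self) -> np.ndarray:
        return self.m * np.arange(self.n_bins + 1)


@dataclass(frozen=True)
class DispersionPoint:
    """The (cur1, cur2) feature of one beat; ``valid`` is False when either
    statistic is undefined (empty U1 or non-positive cur2 denominator)."""

    cur1: float
    cur2: float
    valid: bool = True
    reason: str = ""


def wsc_sequence(matrices: np.ndarray) -> np.ndarray:
    """Scalar curvature of every matrix of an SPD cloud, in order."""
    return np.array([scalar_curvature(S) for S in matrices])


def choose_b(standard_curvatures: np.ndarray, epsilon: float, d: int) -> float:
    """Histogram ceiling: min(max standard curvature, 3 d (d-1) / epsilon).

    ``epsilon`` is the assumed floor on the second-smallest eigenvalue of
    the scatter matrices; 3 d (d-1) / epsilon is the analytic curvature cap
    under that floor.
    """
    w = np.asarray(standard_curvatures, dtype=float)
    if w.size == 0:
        raise ValueError("cannot choose ceiling from an empty curvature sequence")
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    return float(min(w.max(), 3.0 * d * (d - 1) / epsilon))


def histogram(W: np.ndarray, m: float, b: float) -> CurvatureHistogram:
    """Bin the curvature sequence into half-open width-m bins up to ceiling b."""
    if m <= 0 or b <= 0:
        raise ValueError("bin width m and ceiling b must be positive")
    W = np.asarray(W, dtype=float)
    n_bins = int(np.floor(b / m)) + 1
    inside = np.isfinite(W) & (W >= 0) & (W < m * n_bins)
    j = np.floor(W[inside] / m).astype(int)
    counts = np.bincount(np.minimum(j, n_bins - 1), minlength=n_bins)
    return CurvatureHistogram(
        m=float(m), b=float(b), counts=counts,
        n_excluded=int(W.size - counts.sum()),
    )


def dispersion(W: np.ndarray, H: CurvatureHistogram, s: int = 0) -> DispersionPoint:
    """Dispersion pair (cur1, cur2) of a curvature sequence and its histogram."""
    J = int(np.floor(H.b / H.m))
    if not 0 <= s <= J:
        raise ValueError(f"s={s} must lie in [0, floor(b/m)]={J}")
    W = np.asarray(W, dtype=float)
    u1 = W[(W >= H.m * s) & (W <= H.b)]
    if u1.size == 0:
        return DispersionPoint(np.nan, np.nan, valid=False, reason="empty U1")
    cur1 = float(np.median(u1))

    y = H.counts[s + 1 :]                      # columns j = s+1 .. J
    n_nonzero = int(np.count_nonzero(y))       # |U2|
    denom = n_nonzero - s - 1
    if denom <= 0:
        return DispersionPoint(
            cur1, np.nan, valid=False, reason="cur2 denominator non-positive"
        )
    ybar = y.sum() / J
    cur2 = float(np.sqrt(np.sum((y - ybar) ** 2) / denom))
    return DispersionPoint(cur1, cur2, valid=True)
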