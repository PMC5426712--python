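"""Information-content diagnostics of a profile correlation matrix.

Two points of a SAS profile with correlation rho share the Gaussian
mutual information MI = -1/2 ln(1 - rho^2) (nats).  High neighbor MI
means the curve is locally redundant; the *bandwidth* of the
correlation matrix - how far from the diagonal the correlation stays
above a threshold - is the same notion geometrically.  On globular
particles both diagnostics locate the information-richest region in the
mid-q band (q R_G roughly 3-6).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .thermal import CorrelationMatrix

__all__ = [
    "mutual_information",
    "neighbor_mi_profile",
    "bandwidth_profile",
    "BandwidthProfile",
    "min_correlation",
]

_MI_SATURATED = np.finfo(float).max


def mutual_information(rho, return_saturated: bool = False):
    """Gaussian mutual information -1/2 ln(1 - rho^2), in nats.

    |rho| >= 1 signals infinite information; such entries are returned
    as the largest representable float, with a boolean flag (same shape)
    when ``return_saturated`` is requested.
    """
    rho = np.asarray(rho, dtype=float)
    saturated = np.abs(rho) >= 1.0
    safe = np.where(saturated, 0.0, rho)
    mi = np.where(saturated, _MI_SATURATED, -0.5 * np.log1p(-(safe**2)))
    mi = np.where(np.isnan(rho), np.nan, mi)
    if not mi.shape:
        mi = float(mi)
        saturated = bool(saturated)
    if return_saturated:
        return mi, saturated
    return mi


def neighbor_mi_profile(c: CorrelationMatrix, offset: int = 1):
    """MI between q_i and q_(i+offset) along the profile.

    Returns ``(q, mi)`` with one value per valid i (q reported at q_i).
    High MI means low local information density.  Entries involving an
    undefined (q = 0) row are NaN.
    """
    if offset < 1:
        raise ValueError("offset must be >= 1")
    nq = len(c.q)
    if offset >= nq:
        raise ValueError("offset must be smaller than the grid length")
    rho = np.diagonal(c.rho, offset=offset)
    return c.q[: nq - offset], np.asarray(mutual_information(rho))


@dataclass
class BandwidthProfile:
    """Per-q half-width (A^-1) of the high-correlation diagonal band."""

    q: np.ndarray
    halfwidth: np.ndarray
    threshold: float


def bandwidth_profile(c: CorrelationMatrix, threshold: float = 0.5) -> BandwidthProfile:
    """Width of the contiguous diagonal band with rho >= threshold.

    For each q_i the band extends while the correlation with q_i stays
    at or above the threshold contiguously in both directions; the
    reported half-width is half the q-span of that run.  NaN (undefined)
    entries terminate the run.  An identity matrix gives 0 everywhere;
    an all-ones matrix gives the full half-span.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    nq = len(c.q)
    halfwidth = np.empty(nq)
    for i in range(nq):
        row = c.rho[i]
        if not np.isfinite(row[i]):
            halfwidth[i] = np.nan
            continue
        lo = i
        while lo > 0 and np.isfinite(row[lo - 1]) and row[lo - 1] >= threshold:
            lo -= 1
        hi = i
        while hi < nq - 1 and np.isfinite(row[hi + 1]) and row[hi + 1] >= threshold:
            hi += 1
        halfwidth[i] = 0.5 * (c.q[hi] - c.q[lo])
    return BandwidthProfile(c.q.copy(), halfwidth, threshold)


def min_correlation(c: CorrelationMatrix) -> tuple[float, float, float]:
    """Global minimum of the defined correlation entries.

    Returns ``(q_i, q_j, rho_min)`` with i <= j; ties are broken by the
    lexicographically smallest (q_i, q_j).
    """
    finite = np.isfinite(c.rho)
    if not finite.any():
        raise ValueError("correlation matrix has no defined entries")
    rmin = np.nanmin(c.rho)
    ii, jj = np.where((c.rho == rmin) & finite)
    # upper-triangle representative, lexicographic tie-break
    pairs = sorted((min(i, j), max(i, j)) for i, j in zip(ii, jj))
    i, j = pairs[0]
    return float(c.q[i]), float(c.q[j]), float(rmin)
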