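"""Exact single-structure Debye intensity and shared numerical kernels.

The orientationally averaged scattering intensity of a rigid structure is
the Debye double sum over atom pairs

    I(q) = sum_k sum_l f_k(q) f_l(q) sinc(q d_kl)

with sinc(x) = sin(x)/x and d_kl the Euclidean distance between atoms k
and l.  The derivative kernel sigma(x) = d/dx sinc(x) appears in all
covariance formulas.  Both kernels switch to short series near x = 0 so
that q = 0 is handled by the exact limit, never by division.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "ScatteringProfile",
    "sinc",
    "sigma_kernel",
    "distance_matrix",
    "debye_intensity",
    "default_q_grid",
]

_SMALL_X = 1e-4


def sinc(x):
    """sin(x)/x, exact at 0; series 1 - x^2/6 + x^4/120 for |x| < 1e-4."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < _SMALL_X
    safe = np.where(small, 1.0, x)
    out = np.where(small, 1.0 - x**2 / 6.0 + x**4 / 120.0, np.sin(safe) / safe)
    return out if out.shape else float(out)


def sigma_kernel(x):
    """sigma(x) = d/dx sinc(x) = (cos x - sin x / x) / x, exact 0 at 0.

    Series -x/3 + x^3/30 for |x| < 1e-4.
    """
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < _SMALL_X
    safe = np.where(small, 1.0, x)
    out = np.where(
        small,
        -x / 3.0 + x**3 / 30.0,
        (np.cos(safe) - np.sin(safe) / safe) / safe,
    )
    return out if out.shape else float(out)


def default_q_grid(q_min: float = 0.0, q_max: float = 0.5, n: int = 101) -> np.ndarray:
    """Default momentum-transfer grid: 101 points on [0, 0.5] A^-1."""
    return np.linspace(q_min, q_max, n)


@dataclass
class ScatteringProfile:
    """A scattering profile: q grid (A^-1), intensities, optional errors."""

    q: np.ndarray
    intensity: np.ndarray
    error: np.ndarray | None = None

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.q.ndim != 1 or self.q.shape != self.intensity.shape:
            raise ValueError("q and intensity must be equal-length 1-D arrays")
        if len(self.q) > 1 and np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing")
        if self.q[0] < 0:
            raise ValueError("q must be non-negative")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")
        if self.error is not None:
            self.error = np.asarray(self.error, dtype=float)
            if self.error.shape != self.q.shape:
                raise ValueError("error must match the q grid")

    def __len__(self) -> int:
        return len(self.q)


def distance_matrix(s) -> np.ndarray:
    """Symmetric matrix of pairwise Euclidean distances (A), zero diagonal."""
    if s.n_atoms == 1:
        return np.zeros((1, 1))
    return squareform(pdist(s.coords))


def debye_intensity(s, q_grid=None, ff=None) -> ScatteringProfile:
    """Exact Debye intensity of a rigid structure.

    The pair sum is computed over unordered pairs with a factor 2 plus
    the k = l diagonal (sinc(0) = 1), which equals the full ordered
    double sum.  I(0) = (sum_k f_k(0))^2 exactly.
    """
    from .form_factors import FormFactorModel

    q = default_q_grid() if q_grid is None else np.asarray(q_grid, dtype=float)
    ff = FormFactorModel() if ff is None else ff
    F = ff.table(s, q)  # (N, nq)
    n = s.n_atoms
    intensity = np.empty(len(q))
    if n == 1:
        intensity[:] = F[0] ** 2
        return ScatteringProfile(q, intensity)
    d = pdist(s.coords)  # unordered pairs, structure order
    iu, ju = np.triu_indices(n, k=1)
    for i, qi in enumerate(q):
        fq = F[:, i]
        intensity[i] = (fq**2).sum() + 2.0 * (fq[iu] * fq[ju] * sinc(qi * d)).sum()
    return ScatteringProfile(q, intensity)
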