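"""Analytic mean and covariance of SAS profiles under thermal motion.

Model: atom positions are independently, isotropically Gaussian about a
mean structure x0; atom k has variance tau_k^2 along each coordinate
(the Debye-Waller picture).  Under this model:

* the pair distance d_kl follows a 3-DOF noncentral chi distribution;
* E[sinc(q d_kl)] has the exact closed form
  sinc(q d0_kl) * exp(-q^2 (tau_k^2 + tau_l^2) / 2);
* the ensemble-mean intensity follows by linearity of expectation;
* the intensity covariance V(I(q_i), I(q_j)) decomposes, to second
  order in tau/d0, into an *autocovariance* (each pair distance with
  itself) and a *cross-covariance* (two distances sharing one atom),
  both built from the kernel sigma(x) = d/dx sinc(x).

Sum conventions
---------------
The covariance arises from a quadruple sum over ordered index pairs
(k,l) and (m,n).  Counting ordered tuples (and confirmed against the
Monte-Carlo oracle in :mod:`sascov.synthetic`): each unordered pair
{k,l} appears 2x2 = 4 times in the auto class, and each (shared atom,
{other, other}) configuration appears 4 times in the cross class.
Relative to sums written over ``sum_k sum_{l != k}`` (auto) and
``sum_k sum_{l != k} sum_{n != k,l}`` (cross), the implementation
therefore carries overall prefactors 2 and 4 respectively.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .debye import ScatteringProfile, debye_intensity, default_q_grid, distance_matrix, sigma_kernel, sinc
from .form_factors import FormFactorModel

__all__ = [
    "ProfileCovariance",
    "CorrelationMatrix",
    "ApproximationBreakdownError",
    "noncentral_chi_pdf",
    "noncentral_chi_cdf",
    "sinc_expectation",
    "mean_intensity",
    "mean_intensity_uniform",
    "mixture_mean_intensity",
    "geometric_nu",
    "bivariate_normal_approx",
    "covariance_matrix",
    "correlation_matrix",
]

AUTO_PREFACTOR = 2.0   # ordered-tuple count per unordered pair {k,l}
CROSS_PREFACTOR = 4.0  # ordered-tuple count per (shared atom, pair of partners)


class ApproximationBreakdownError(RuntimeError):
    """The second-order covariance produced an invalid (negative) variance."""


@dataclass
class ProfileCovariance:
    """Symmetric covariance of profile intensities on a shared q grid.

    ``auto``/``cross`` hold the decomposition when produced analytically.
    """

    q: np.ndarray
    cov: np.ndarray
    auto: np.ndarray | None = None
    cross: np.ndarray | None = None

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        n = len(self.q)
        if self.cov.shape != (n, n):
            raise ValueError("cov must be square on the q grid")
        scale = np.abs(self.cov).max()
        if scale > 0 and np.abs(self.cov - self.cov.T).max() > 1e-10 * scale:
            raise ValueError("cov must be symmetric")

    @property
    def sd(self) -> np.ndarray:
        """Per-q standard deviation sqrt(diag V); raises if diag < 0."""
        d = np.diag(self.cov)
        if np.any(d < -1e-12 * max(np.abs(d).max(), 1e-300)):
            raise ApproximationBreakdownError(
                "negative variance on the diagonal: the second-order "
                "(tau/d) approximation broke down for this structure"
            )
        return np.sqrt(np.clip(d, 0.0, None))


@dataclass
class CorrelationMatrix:
    """Profile correlation rho(q_i, q_j); NaN marks undefined (q = 0) rows."""

    q: np.ndarray
    rho: np.ndarray
    n_clamped: int = 0

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.rho = np.asarray(self.rho, dtype=float)
        if self.rho.shape != (len(self.q),) * 2:
            raise ValueError("rho must be square on the q grid")


# ---------------------------------------------------------------------------
# Distance distribution and the exact sinc expectation
# ---------------------------------------------------------------------------

def noncentral_chi_pdf(d, d0: float, tau_k: float, tau_l: float):
    """Density of the distance between two Gaussian-displaced atoms.

    The difference vector is Normal(mean separation d0, variance
    s^2 = tau_k^2 + tau_l^2 per coordinate); its norm follows the 3-DOF
    noncentral chi law

        p(d) = 1/sqrt(2 pi s^2) * (d/d0) *
               [exp(-(d-d0)^2 / 2s^2) - exp(-(d+d0)^2 / 2s^2)]
    """
    s2 = tau_k**2 + tau_l**2
    if s2 <= 0:
        raise ValueError("tau_k^2 + tau_l^2 must be positive (rigid pair has no density)")
    if d0 <= 0:
        raise ValueError("d0 must be positive")
    d = np.asarray(d, dtype=float)
    pref = d / (d0 * np.sqrt(2.0 * np.pi * s2))
    out = pref * (np.exp(-((d - d0) ** 2) / (2 * s2)) - np.exp(-((d + d0) ** 2) / (2 * s2)))
    out = np.where(d >= 0, out, 0.0)
    return out if out.shape else float(out)


def noncentral_chi_cdf(d, d0: float, tau_k: float, tau_l: float):
    """CDF matching :func:`noncentral_chi_pdf` (closed form)."""
    from scipy.stats import norm

    s2 = tau_k**2 + tau_l**2
    s = np.sqrt(s2)
    d = np.asarray(d, dtype=float)
    # integral of the pdf: Phi terms plus the Gaussian boundary terms
    a, b = (d - d0) / s, (d + d0) / s
    cdf = (
        norm.cdf(a) + norm.cdf(b) - 1.0
        + (s / (d0 * np.sqrt(2 * np.pi)))
        * (np.exp(-(b**2) / 2) - np.exp(-(a**2) / 2))
    )
    out = np.where(d > 0, np.clip(cdf, 0.0, 1.0), 0.0)
    return out if out.shape else float(out)


def sinc_expectation(q, d0: float, tau_k: float, tau_l: float):
    """Exact thermal average of sinc(q d) for one atom pair.

        E[sinc(q d)] = sinc(q d0) exp(-q^2 (tau_k^2 + tau_l^2) / 2)

    Holds without approximation for the Gaussian displacement model.
    """
    if d0 <= 0:
        raise ValueError("d0 must be positive")
    q = np.asarray(q, dtype=float)
    out = sinc(q * d0) * np.exp(-(q**2) * (tau_k**2 + tau_l**2) / 2.0)
    return out if out.shape else float(out)


# ---------------------------------------------------------------------------
# Mean intensity
# ---------------------------------------------------------------------------

def _require_tau(s):
    if s.tau is None:
        raise ValueError("structure has no thermal deviations; call assign_tau first")


def mean_intensity(s, q_grid=None, ff: FormFactorModel | None = None) -> ScatteringProfile:
    """Ensemble-mean intensity for per-atom tau.

    E[I(q)] = sum_kl f_k e^(-q^2 tau_k^2/2) f_l e^(-q^2 tau_l^2/2)
              sinc(q d0_kl)  +  sum_k (1 - e^(-q^2 tau_k^2)) f_k^2

    Self terms are exact (d_kk = 0 identically); reduces to the rigid
    Debye intensity when all tau = 0.
    """
    _require_tau(s)
    q = default_q_grid() if q_grid is None else np.asarray(q_grid, dtype=float)
    ff = FormFactorModel() if ff is None else ff
    F = ff.table(s, q)  # (N, nq)
    D = distance_matrix(s)
    tau2 = s.tau**2
    intensity = np.empty(len(q))
    for i, qi in enumerate(q):
        g = F[:, i] * np.exp(-(qi**2) * tau2 / 2.0)
        S = sinc(qi * D)
        intensity[i] = g @ S @ g + ((1.0 - np.exp(-(qi**2) * tau2)) * F[:, i] ** 2).sum()
    return ScatteringProfile(q, intensity)


def mean_intensity_uniform(s, tau: float, q_grid=None,
                           ff: FormFactorModel | None = None) -> ScatteringProfile:
    """Ensemble-mean intensity for uniform tau: a convex combination

        E[I(q)] = e^(-q^2 tau^2) I0(q) + (1 - e^(-q^2 tau^2)) sum_k f_k^2

    of the rigid profile I0 and the incoherent self-term floor.
    """
    if tau < 0:
        raise ValueError("tau must be non-negative")
    q = default_q_grid() if q_grid is None else np.asarray(q_grid, dtype=float)
    ff = FormFactorModel() if ff is None else ff
    rigid = debye_intensity(s, q, ff).intensity
    F = ff.table(s, q)
    floor = (F**2).sum(0)
    damp = np.exp(-(q**2) * tau**2)
    return ScatteringProfile(q, damp * rigid + (1.0 - damp) * floor)


def mixture_mean_intensity(components, q_grid=None,
                           ff: FormFactorModel | None = None) -> ScatteringProfile:
    """Weighted mixture of thermal-ensemble intensities.

    ``components`` is a list of ``(structure, tau, weight)``; weights
    must already sum to 1 (error, not silent renormalization).  Models
    a system that hops between conformations (e.g. a compact state A
    with small tau and an open state B with large tau) with no A-B
    interference.
    """
    if not components:
        raise ValueError("at least one mixture component required")
    weights = np.array([w for _, _, w in components], dtype=float)
    if np.any(weights < 0):
        raise ValueError("weights must be non-negative")
    if abs(weights.sum() - 1.0) > 1e-8:
        raise ValueError(f"weights must sum to 1 (got {weights.sum()!r})")
    q = default_q_grid() if q_grid is None else np.asarray(q_grid, dtype=float)
    total = np.zeros(len(q))
    for s, tau, w in components:
        total += w * mean_intensity_uniform(s, tau, q, ff).intensity
    return ScatteringProfile(q, total)


# ---------------------------------------------------------------------------
# Bivariate geometry of two distances sharing an atom
# ---------------------------------------------------------------------------

def geometric_nu(s, k: int, l: int, n: int) -> float:
    """cos of the angle at atom k between the bonds to atoms l and n."""
    if len({k, l, n}) != 3:
        raise ValueError("k, l, n must be distinct atom indices")
    u = s.coords[l] - s.coords[k]
    v = s.coords[n] - s.coords[k]
    du, dv = np.linalg.norm(u), np.linalg.norm(v)
    if du == 0 or dv == 0:
        raise ValueError("coincident atoms: zero distance in geometric_nu")
    return float(np.clip(u @ v / (du * dv), -1.0, 1.0))


def bivariate_normal_approx(d0_kl: float, d0_kn: float, nu: float,
                            tau_k: float, tau_l: float, tau_n: float):
    """Normal approximation to the joint law of (d_kl, d_kn).

    Valid when both mean distances are much larger than the taus; warns
    (does not fail) when tau/d0 > 0.2.  Returns the mean 2-vector

        d' = (d0_kl + (tau_k^2+tau_l^2)/d0_kl,
              d0_kn + (tau_k^2+tau_n^2)/d0_kn)

    and the covariance with diagonal (tau_k^2+tau_l^2, tau_k^2+tau_n^2)
    and off-diagonal nu * tau_k^2 (the shared atom couples the pair).
    """
    if d0_kl <= 0 or d0_kn <= 0:
        raise ValueError("mean distances must be positive")
    tmax = max(tau_k, tau_l, tau_n)
    if tmax / min(d0_kl, d0_kn) > 0.2:
        warnings.warn(
            "tau/d0 > 0.2: the small-variance normal approximation may be poor",
            RuntimeWarning,
            stacklevel=2,
        )
    mean = np.array([
        d0_kl + (tau_k**2 + tau_l**2) / d0_kl,
        d0_kn + (tau_k**2 + tau_n**2) / d0_kn,
    ])
    cov = np.array([
        [tau_k**2 + tau_l**2, nu * tau_k**2],
        [nu * tau_k**2, tau_k**2 + tau_n**2],
    ])
    return mean, cov


# ---------------------------------------------------------------------------
# Covariance and correlation
# ---------------------------------------------------------------------------

def covariance_matrix(s, q_grid=None, ff: FormFactorModel | None = None,
                      *, include_cross: bool = True, max_atoms: int = 2000,
                      force: bool = False) -> ProfileCovariance:
    """Second-order analytic covariance of the thermal-ensemble profile.

    V(I(q_i), I(q_j)) = V_auto + V_cross with kernels

        V0_ij(d)      = (tau_k^2 + tau_l^2) q_i q_j sigma(q_i d) sigma(q_j d)
        V_ij(d, d')   = nu tau_k^2 q_i q_j sigma(q_i d) sigma(q_j d')

    summed over unordered configurations with the ordered-tuple
    prefactors 2 (auto) and 4 (cross); see the module docstring.  Every
    entry carries the q_i q_j prefactor, so the q = 0 row and column
    vanish identically, and all entries -> 0 as the taus -> 0.

    The cross term is factorized through the vector sums
    A_k(q) = sum_l f_l(q) sigma(q d_kl) u_kl (u_kl the unit vector from
    k to l), which reduces its cost from O(N^3 |q|^2) to O(N^2 |q|) +
    O(N |q|^2).  Cost and memory are quadratic in N; structures above
    ``max_atoms`` are refused unless ``force=True``.
    """
    _require_tau(s)
    q = default_q_grid() if q_grid is None else np.asarray(q_grid, dtype=float)
    ff = FormFactorModel() if ff is None else ff
    n = s.n_atoms
    if n > max_atoms and not force:
        raise ValueError(
            f"analytic covariance for N={n} atoms exceeds max_atoms={max_atoms}; "
            "pass force=True to override"
        )
    nq = len(q)
    F = ff.table(s, q)  # (N, nq)
    D = distance_matrix(s)
    tau2 = s.tau**2

    if n < 2:
        zeros = np.zeros((nq, nq))
        return ProfileCovariance(q, zeros, auto=zeros.copy(), cross=zeros.copy())

    # unit vectors u[k, l] from atom k to atom l (zero on the diagonal)
    diff = s.coords[None, :, :] - s.coords[:, None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        U = diff / D[:, :, None]
    U[np.arange(n), np.arange(n)] = 0.0

    # per-q weighted sigma matrices M_q[k, l] = f_l(q) sigma(q d_kl)
    M = np.empty((nq, n, n))
    A = np.empty((nq, n, 3))
    for i, qi in enumerate(q):
        S = sigma_kernel(qi * D)
        np.fill_diagonal(S, 0.0)
        M[i] = F[:, i][None, :] * S
        A[i] = np.einsum("kl,klc->kc", M[i], U)

    auto = np.zeros((nq, nq))
    cross = np.zeros((nq, nq))
    for i in range(nq):
        for j in range(i, nq):
            P = M[i] * M[j]                      # (N, N)
            row = P.sum(axis=1)                  # sum_l f_l(qi) f_l(qj) sig sig
            col = P @ tau2                       # sum_l tau_l^2 (...)
            w = F[:, i] * F[:, j]
            a = AUTO_PREFACTOR * (w * (tau2 * row + col)).sum()
            auto[i, j] = auto[j, i] = q[i] * q[j] * a
            if include_cross and n >= 3:
                dot = np.einsum("kc,kc->k", A[i], A[j])
                c = CROSS_PREFACTOR * (w * tau2 * (dot - row)).sum()
                cross[i, j] = cross[j, i] = q[i] * q[j] * c
    return ProfileCovariance(q, auto + cross, auto=auto, cross=cross)


def correlation_matrix(cov: ProfileCovariance) -> CorrelationMatrix:
    """Correlation rho(q_i, q_j) = V_ij / sqrt(V_ii V_jj).

    Rows/columns with zero variance (always the case at q = 0, where
    I(0) counts electrons and cannot fluctuate) are marked NaN rather
    than imputed.  Entries are clamped to [-1, 1]; the number of clamped
    entries is reported, since the second-order covariance is not
    guaranteed positive semidefinite.
    """
    d = np.diag(cov.cov).copy()
    defined = d > 0
    bad = d < -1e-12 * max(np.abs(d).max(), 1e-300)
    if np.any(bad):
        raise ApproximationBreakdownError(
            "negative variance on the covariance diagonal at "
            f"q={cov.q[bad][:3]}: the second-order (tau/d) approximation "
            "broke down; reduce tau or use the numerical ensemble path"
        )
    sd = np.sqrt(np.where(defined, d, 1.0))
    rho = cov.cov / np.outer(sd, sd)
    rho[~defined, :] = np.nan
    rho[:, ~defined] = np.nan
    ii = np.where(defined)[0]
    rho[ii, ii] = 1.0
    finite = np.isfinite(rho)
    n_clamped = int((np.abs(rho[finite]) > 1.0).sum())
    rho[finite] = np.clip(rho[finite], -1.0, 1.0)
    return CorrelationMatrix(cov.q, rho, n_clamped=n_clamped)
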