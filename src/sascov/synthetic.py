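"""Toy structures, Monte-Carlo thermal ensembles, and brute-force oracles.

Everything here is deliberately simple and independent of the analytic
code paths: the MC estimators evaluate the Debye sum directly from
sampled coordinates (using ``numpy.sinc``, not the package kernels), so
agreement between :func:`mc_mean_cov` and the closed-form results of
:mod:`sascov.thermal` is evidence of correctness, not a tautology.

All randomness is driven by explicit integer seeds; identical seeds
give bit-identical ensembles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .debye import ScatteringProfile, default_q_grid
from .form_factors import FormFactorModel
from .structures import Structure
from .thermal import ProfileCovariance

__all__ = [
    "ToySpec",
    "make_toy_structure",
    "mc_sample_ensemble",
    "mc_mean_cov",
    "MCResult",
    "naive_debye_intensity",
    "oracle_allowance",
]


@dataclass(frozen=True)
class ToySpec:
    """Recipe for a deterministic toy structure.

    kind: 'random-cloud' (Gaussian cloud, SD = scale), 'globule'
    (uniform density in a ball of radius = scale), 'linear-chain'
    (atoms spaced `scale` apart on a line), or 'two-domain' (two
    tangent globules of radius = scale joined by a sparse linker;
    ``separation`` is the center-center distance, default 2.2 * scale).
    """

    kind: str
    n_atoms: int
    scale: float
    tau: float | tuple | None = None
    seed: int = 0
    separation: float | None = None
    element: str = "C"

    def __post_init__(self):
        if self.n_atoms < 1:
            raise ValueError("n_atoms must be >= 1")
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if self.kind not in {"random-cloud", "globule", "linear-chain", "two-domain"}:
            raise ValueError(f"unknown toy kind {self.kind!r}")


def _ball(rng, n, radius, center=(0.0, 0.0, 0.0)):
    """n points with uniform density in a ball (inverse-CDF radius)."""
    v = rng.standard_normal((n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    r = radius * rng.random(n) ** (1.0 / 3.0)
    return v * r[:, None] + np.asarray(center)


def make_toy_structure(spec: ToySpec) -> Structure:
    """Deterministic toy structure for the given spec."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_atoms
    if spec.kind == "random-cloud":
        coords = rng.standard_normal((n, 3)) * spec.scale
    elif spec.kind == "globule":
        coords = _ball(rng, n, spec.scale)
    elif spec.kind == "linear-chain":
        coords = np.zeros((n, 3))
        coords[:, 0] = np.arange(n) * spec.scale
    else:  # two-domain
        sep = 2.2 * spec.scale if spec.separation is None else spec.separation
        n_link = max(0, n // 20) if n >= 20 else 0
        n_dom = n - n_link
        n_a = n_dom // 2
        n_b = n_dom - n_a
        a = _ball(rng, n_a, spec.scale, center=(-sep / 2.0, 0.0, 0.0))
        b = _ball(rng, n_b, spec.scale, center=(+sep / 2.0, 0.0, 0.0))
        parts = [a, b]
        if n_link:
            t = (np.arange(n_link) + 0.5) / n_link
            link = np.zeros((n_link, 3))
            link[:, 0] = -sep / 2.0 + t * sep
            parts.append(link)
        coords = np.vstack(parts)
    tau = None
    if spec.tau is not None:
        tau = np.asarray(spec.tau, dtype=float)
        if tau.shape == ():
            tau = np.full(n, float(tau))
    return Structure(
        elements=[spec.element] * n,
        coords=coords,
        tau=tau,
        label=f"{spec.kind}(n={n}, scale={spec.scale}, seed={spec.seed})",
    )


def mc_sample_ensemble(s: Structure, n_samples: int, seed: int) -> list[Structure]:
    """Independent Gaussian-displacement conformers of ``s``.

    Each atom of each conformer is displaced independently along each
    coordinate with SD tau_k.
    """
    if s.tau is None:
        raise ValueError("structure has no thermal deviations; call assign_tau first")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_samples):
        disp = rng.standard_normal((s.n_atoms, 3)) * s.tau[:, None]
        c = s.copy()
        c.coords = s.coords + disp
        c.label = f"{s.label}|mc{i}"
        out.append(c)
    return out


def naive_debye_intensity(s: Structure, q_grid=None, ff: FormFactorModel | None = None) -> ScatteringProfile:
    """Triple-loop Debye sum: the O(N^2 |q|) reference implementation.

    Evaluates the full ordered double sum term by term with
    ``numpy.sinc``; intended for N <= 30 oracle checks only.
    """
    q = default_q_grid() if q_grid is None else np.asarray(q_grid, dtype=float)
    ff = FormFactorModel() if ff is None else ff
    n = s.n_atoms
    intensity = np.zeros(len(q))
    for i, qi in enumerate(q):
        f = [float(np.atleast_1d(ff.effective(s.elements[k], qi))[0]) for k in range(n)]
        total = 0.0
        for k in range(n):
            for l in range(n):
                d = float(np.linalg.norm(s.coords[k] - s.coords[l]))
                total += f[k] * f[l] * float(np.sinc(qi * d / np.pi))
        intensity[i] = total
    return ScatteringProfile(q, intensity)


@dataclass
class MCResult:
    """Monte-Carlo mean/covariance with jackknife standard errors."""

    mean: ScatteringProfile
    cov: ProfileCovariance
    mean_se: np.ndarray
    cov_se: np.ndarray
    n_samples: int


def _mc_intensities(s: Structure, q: np.ndarray, F: np.ndarray,
                    rng: np.random.Generator, n_samples: int,
                    batch: int = 2000) -> np.ndarray:
    """Sampled Debye intensities, shape (n_samples, n_q).

    Direct evaluation per conformer: perturb coordinates, form pair
    distances, sum f_k f_l sinc(q d) over unordered pairs (x2) plus the
    self terms.  Uses ``numpy.sinc`` on purpose (independent path).
    """
    n = s.n_atoms
    iu, ju = np.triu_indices(n, k=1)
    pair_f = F[iu] * F[ju]          # (n_pairs, nq)
    self_term = (F**2).sum(axis=0)  # (nq,)
    out = np.empty((n_samples, len(q)))
    done = 0
    while done < n_samples:
        m = min(batch, n_samples - done)
        disp = rng.standard_normal((m, n, 3)) * s.tau[None, :, None]
        x = s.coords[None] + disp
        d = np.linalg.norm(x[:, iu] - x[:, ju], axis=2)  # (m, n_pairs)
        # (m, n_pairs, nq) in one shot is fine at toy sizes
        sc = np.sinc(d[:, :, None] * q[None, None, :] / np.pi)
        out[done:done + m] = self_term + 2.0 * np.einsum("mpq,pq->mq", sc, pair_f)
        done += m
    return out


def mc_mean_cov(s: Structure, q_grid=None, ff: FormFactorModel | None = None,
                *, n_samples: int = 10000, seed: int = 0,
                n_blocks: int = 10) -> MCResult:
    """Brute-force MC estimate of the profile mean and covariance.

    Samples ``n_samples`` Gaussian-displacement conformers, evaluates
    each Debye profile directly, and returns the sample mean, unbiased
    sample covariance, and standard errors for every reported entry:
    the exact std/sqrt(n) formula for the mean, and a leave-one-block-out
    jackknife (default 10 blocks) for the covariance entries, where no
    closed-form SE exists.
    """
    if s.tau is None:
        raise ValueError("structure has no thermal deviations; call assign_tau first")
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    q = default_q_grid() if q_grid is None else np.asarray(q_grid, dtype=float)
    ff = FormFactorModel() if ff is None else ff
    F = ff.table(s, q)
    rng = np.random.default_rng(seed)
    I = _mc_intensities(s, q, F, rng, n_samples)

    mean = I.mean(axis=0)
    dev = I - mean
    cov = dev.T @ dev / (n_samples - 1)

    mean_se = I.std(axis=0, ddof=1) / np.sqrt(n_samples)

    # covariance SEs: jackknife over contiguous blocks
    edges = np.linspace(0, n_samples, n_blocks + 1, dtype=int)
    s1 = np.stack([I[a:b].sum(axis=0) for a, b in zip(edges[:-1], edges[1:])])
    s2 = np.stack([I[a:b].T @ I[a:b] for a, b in zip(edges[:-1], edges[1:])])
    counts = np.diff(edges)
    cov_loo = np.empty((n_blocks, len(q), len(q)))
    for b in range(n_blocks):
        m = n_samples - counts[b]
        mu = (s1.sum(axis=0) - s1[b]) / m
        ss = s2.sum(axis=0) - s2[b]
        cov_loo[b] = (ss - m * np.outer(mu, mu)) / (m - 1)
    fac = (n_blocks - 1) / n_blocks
    cov_se = np.sqrt(fac * ((cov_loo - cov_loo.mean(0)) ** 2).sum(0))

    return MCResult(
        mean=ScatteringProfile(q, mean),
        cov=ProfileCovariance(q, 0.5 * (cov + cov.T)),
        mean_se=mean_se,
        cov_se=cov_se,
        n_samples=n_samples,
    )


def oracle_allowance(q, tau: float, d_min: float, cov, C: float = 3.0) -> np.ndarray:
    """Second-order bias allowance for analytic-vs-MC covariance checks.

    The closed-form covariance truncates the delta-method expansion at
    second order in the atomic displacements; the neglected terms are of
    relative order (q tau)^2 (damping corrections) and (tau/d)^2
    (distance-distribution corrections).  The allowance per entry is

        C * ((q_i^2 + q_j^2) tau^2 + (tau/d_min)^2) * sqrt(V_ii V_jj)

    with ``d_min`` the smallest pair distance of the mean structure and
    C = 3 covering the O(1) coefficients of both term classes.  Oracle
    assertions use |analytic - MC| <= 3 * SE_MC + allowance.
    """
    q = np.asarray(q, dtype=float)
    cov = np.asarray(cov, dtype=float)
    scale = np.sqrt(np.outer(np.abs(np.diag(cov)), np.abs(np.diag(cov))))
    rel = (q[:, None] ** 2 + q[None, :] ** 2) * tau**2 + (tau / d_min) ** 2
    return C * rel * scale
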