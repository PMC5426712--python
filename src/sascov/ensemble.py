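"""Numerical mean, covariance, SD and confidence bands from conformer sets.

This is the empirical counterpart of :mod:`sascov.thermal`: instead of
the analytic Gaussian-motion theory it takes an explicit set of
conformers (an MD trajectory read as multi-model PDB, a deposited IDP
ensemble, or a Monte-Carlo sample), computes one Debye profile per
conformer on a shared q grid, and estimates the profile mean and
covariance from the sample.  For independent Gaussian motion the two
paths converge to each other as the sample grows and tau/d shrinks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .debye import ScatteringProfile, debye_intensity, default_q_grid
from .form_factors import FormFactorModel
from .thermal import ProfileCovariance

__all__ = [
    "EnsembleProfiles",
    "ensemble_profiles",
    "sample_mean_cov",
    "relative_sd",
    "RelativeSD",
    "confidence_band",
    "compare_to_experiment",
]


@dataclass
class EnsembleProfiles:
    """Per-conformer intensities on a shared q grid.

    ``intensities`` has shape (n_conformers, n_q); ``weights`` default
    to uniform and are normalized to sum to 1.
    """

    q: np.ndarray
    intensities: np.ndarray
    labels: list[str] | None = None
    weights: np.ndarray | None = None

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2 or self.intensities.shape[1] != len(self.q):
            raise ValueError("intensities must be (n_conformers, n_q)")
        m = self.intensities.shape[0]
        if self.labels is None:
            self.labels = [f"conformer{i}" for i in range(m)]
        if len(self.labels) != m:
            raise ValueError("one label per conformer required")
        if self.weights is None:
            self.weights = np.full(m, 1.0 / m)
        else:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != (m,) or np.any(self.weights < 0):
                raise ValueError("weights must be non-negative, one per conformer")
            total = self.weights.sum()
            if total <= 0:
                raise ValueError("weights must not all be zero")
            self.weights = self.weights / total

    @property
    def n_conformers(self) -> int:
        return self.intensities.shape[0]


def ensemble_profiles(structures, q_grid=None, ff: FormFactorModel | None = None) -> EnsembleProfiles:
    """One Debye profile per conformer, order preserved.

    Conformers may have different element sets (IDP ensembles sometimes
    do); only an empty list is an error.
    """
    structures = list(structures)
    if not structures:
        raise ValueError("at least one structure required")
    q = default_q_grid() if q_grid is None else np.asarray(q_grid, dtype=float)
    ff = FormFactorModel() if ff is None else ff
    intensities = np.empty((len(structures), len(q)))
    labels = []
    for i, s in enumerate(structures):
        intensities[i] = debye_intensity(s, q, ff).intensity
        labels.append(s.label or f"conformer{i}")
    return EnsembleProfiles(q, intensities, labels=labels)


def sample_mean_cov(e: EnsembleProfiles) -> tuple[ScatteringProfile, ProfileCovariance]:
    """Weighted sample mean and unbiased sample covariance.

    Uniform weights give the usual M-1 denominator; general weights use
    the effective-sample-size correction 1 / (1 - sum w_i^2).
    """
    if e.n_conformers < 2:
        raise ValueError("covariance needs at least 2 conformers")
    w = e.weights
    mean = w @ e.intensities
    dev = e.intensities - mean
    cov = (w[:, None] * dev).T @ dev
    denom = 1.0 - (w**2).sum()
    if denom <= 0:
        raise ValueError("degenerate weights: effective sample size is 1")
    cov /= denom
    cov = 0.5 * (cov + cov.T)
    return ScatteringProfile(e.q, mean), ProfileCovariance(e.q, cov)


@dataclass
class RelativeSD:
    """SD as a fraction of the mean intensity, with summary statistics."""

    profile: ScatteringProfile
    q_at_max: float
    max_value: float
    mean_value: float


def relative_sd(mean: ScatteringProfile, cov: ProfileCovariance) -> RelativeSD:
    """Per-q SD / mean (dimensionless), plus its grid mean and argmax."""
    if np.any(mean.intensity <= 0):
        raise ValueError("mean intensity must be positive everywhere")
    rel = cov.sd / mean.intensity
    imax = int(np.argmax(rel))
    return RelativeSD(
        profile=ScatteringProfile(mean.q, rel),
        q_at_max=float(mean.q[imax]),
        max_value=float(rel[imax]),
        mean_value=float(rel.mean()),
    )


def confidence_band(mean: ScatteringProfile, cov: ProfileCovariance,
                    level_sd: float = 1.0) -> tuple[ScatteringProfile, ScatteringProfile]:
    """Pointwise mean +/- level_sd * sqrt(diag V) band (1 sigma ~ 68%)."""
    if not np.array_equal(mean.q, cov.q):
        raise ValueError("mean and covariance must share the q grid")
    half = level_sd * cov.sd
    return (
        ScatteringProfile(mean.q, mean.intensity - half),
        ScatteringProfile(mean.q, mean.intensity + half),
    )


def compare_to_experiment(band, experimental: ScatteringProfile) -> pd.DataFrame:
    """Flag q points where ensemble spread exceeds the experimental error.

    ``band`` is a 1-sigma (lower, upper) pair; the ensemble SD is half
    the band width, linearly interpolated onto the experimental grid.
    Where the ensemble SD exceeds the experimental SD, ensemble
    averaging is detectable above the noise at that q.  Returns a per-q
    table with a ``flagged`` column; contiguous flagged runs can be read
    off directly.
    """
    if experimental.error is None:
        raise ValueError("experimental profile must carry per-point errors")
    lower, upper = band
    model_sd = 0.5 * (upper.intensity - lower.intensity)
    qe = experimental.q
    ens_sd = np.interp(qe, lower.q, model_sd)
    mean_i = np.interp(qe, lower.q, 0.5 * (upper.intensity + lower.intensity))
    flagged = ens_sd > experimental.error
    return pd.DataFrame({
        "q": qe,
        "ensemble_sd": ens_sd,
        "experimental_sd": experimental.error,
        "mean_intensity": mean_i,
        "flagged": flagged,
    })


def flagged_ranges(report: pd.DataFrame) -> list[tuple[float, float]]:
    """Contiguous q ranges where the ensemble spread dominates the noise."""
    ranges = []
    start = None
    for q, f in zip(report["q"], report["flagged"]):
        if f and start is None:
            start = q
        elif not f and start is not None:
            ranges.append((start, prev))
            start = None
        prev = q
    if start is not None:
        ranges.append((start, prev))
    return ranges
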