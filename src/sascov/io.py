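"""File formats: .dat profiles, dense-matrix text, npz containers.

* Scattering profiles use the common 3-column SAXS dialect
  ``q I [err]``, whitespace-separated, '#' comments.
* Covariance / correlation matrices go to plain text with a one-line
  q-grid header, or to a self-describing compressed npz container
  (arrays ``q``, ``cov``, ``auto``, ``cross``) that round-trips
  bit-exactly.
* Ensembles of profiles use the same npz dialect with arrays ``q``,
  ``intensities``, ``weights``, ``labels``.
"""

from __future__ import annotations

import numpy as np

from .debye import ScatteringProfile
from .ensemble import EnsembleProfiles
from .thermal import CorrelationMatrix, ProfileCovariance

__all__ = [
    "read_profile",
    "write_profile",
    "write_matrix_text",
    "read_matrix_text",
    "save_covariance",
    "load_covariance",
    "save_ensemble_profiles",
    "load_ensemble_profiles",
]


def read_profile(path) -> ScatteringProfile:
    """Read a 3-column ``q I [err]`` text profile ('#' comments)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) not in (2, 3):
                raise ValueError(f"expected 2 or 3 columns, got {len(parts)}: {line!r}")
            rows.append([float(x) for x in parts])
    if not rows:
        raise ValueError(f"no data rows in {path}")
    ncol = len(rows[0])
    if any(len(r) != ncol for r in rows):
        raise ValueError(f"inconsistent column counts in {path}")
    arr = np.array(rows)
    err = arr[:, 2] if ncol == 3 else None
    return ScatteringProfile(arr[:, 0], arr[:, 1], err)


def write_profile(profile: ScatteringProfile, path, header: str = "") -> None:
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        fh.write("# q intensity" + (" error" if profile.error is not None else "") + "\n")
        for i in range(len(profile)):
            row = f"{profile.q[i]:.8e} {profile.intensity[i]:.8e}"
            if profile.error is not None:
                row += f" {profile.error[i]:.8e}"
            fh.write(row + "\n")


def write_matrix_text(path, q, matrix, comment: str = "") -> None:
    """Dense matrix as text with a one-line '# q: ...' grid header."""
    q = np.asarray(q, dtype=float)
    matrix = np.asarray(matrix, dtype=float)
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        fh.write("# q: " + " ".join(f"{x:.8e}" for x in q) + "\n")
        for row in matrix:
            fh.write(" ".join(f"{x:.8e}" for x in row) + "\n")


def read_matrix_text(path) -> tuple[np.ndarray, np.ndarray]:
    q = None
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("# q:"):
                q = np.array([float(x) for x in line[4:].split()])
            elif line.startswith("#") or not line.strip():
                continue
            else:
                rows.append([float(x) for x in line.split()])
    if q is None:
        raise ValueError(f"missing '# q:' header in {path}")
    m = np.array(rows)
    if m.shape != (len(q), len(q)):
        raise ValueError(f"matrix shape {m.shape} does not match q grid of {len(q)}")
    return q, m


def save_covariance(cov: ProfileCovariance, path) -> None:
    """Compressed npz container with arrays q/cov/auto/cross (bit-exact)."""
    arrays = {"q": cov.q, "cov": cov.cov}
    if cov.auto is not None:
        arrays["auto"] = cov.auto
    if cov.cross is not None:
        arrays["cross"] = cov.cross
    np.savez_compressed(path, **arrays)


def load_covariance(path) -> ProfileCovariance:
    with np.load(path) as z:
        return ProfileCovariance(
            q=z["q"],
            cov=z["cov"],
            auto=z["auto"] if "auto" in z else None,
            cross=z["cross"] if "cross" in z else None,
        )


def save_correlation(corr: CorrelationMatrix, path) -> None:
    np.savez_compressed(path, q=corr.q, rho=corr.rho,
                        n_clamped=np.array(corr.n_clamped))


def load_correlation(path) -> CorrelationMatrix:
    with np.load(path) as z:
        return CorrelationMatrix(q=z["q"], rho=z["rho"],
                                 n_clamped=int(z["n_clamped"]))


def save_ensemble_profiles(e: EnsembleProfiles, path) -> None:
    np.savez_compressed(
        path, q=e.q, intensities=e.intensities, weights=e.weights,
        labels=np.array(e.labels, dtype=object),
    )


def load_ensemble_profiles(path) -> EnsembleProfiles:
    with np.load(path, allow_pickle=True) as z:
        return EnsembleProfiles(
            q=z["q"], intensities=z["intensities"], weights=z["weights"],
            labels=[str(x) for x in z["labels"]],
        )
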