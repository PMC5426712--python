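"""Atomic scattering form factors with a simplified solvent correction.

The vacuum form factor of element *E* is the standard four-Gaussian
(Cromer-Mann) fit

    f_vac(q) = sum_i a_i exp(-b_i (q / 4 pi)^2) + c

whose value at q = 0 is the electron count.  In solution the effective
factor subtracts an excluded-volume (dummy-atom) term scaled by ``c1``
and may add a crude hydration-shell constant scaled by ``c2``:

    f_eff(q) = f_vac(q) - c1 * rho_s * V exp(-q^2 V^(2/3) / (4 pi)) + c2 * h

with solvent electron density ``rho_s`` (0.334 e/A^3 for water) and
displaced volume ``V`` per element.  This is a deliberately simplified
stand-in for full solvation models (FoXS, CRYSOL): the hydration term is
a per-atom constant with no solvent-accessibility weighting (flagged
experimental), and no shell geometry is modelled.  All ensemble theory
in :mod:`sascov.thermal` is agnostic to the form-factor model - its
oracle tests run with constant factors f = 1.

A ``"X"`` pseudo-element with f = 1 (one "electron", zero volume) is
included for testing with point atoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "FormFactorModel",
    "vacuum_form_factor",
    "effective_form_factor",
    "load_coefficients",
    "point_model",
]

# element -> (a1..a4, b1..b4, c); International Tables four-Gaussian fits
CROMER_MANN = {
    "H": ((0.489918, 0.262003, 0.196767, 0.049879),
          (20.6593, 7.74039, 49.5519, 2.20159), 0.001305),
    "C": ((2.31000, 1.02000, 1.58860, 0.865000),
          (20.8439, 10.2075, 0.568700, 51.6512), 0.215600),
    "N": ((12.2126, 3.13220, 2.01250, 1.16630),
          (0.005700, 9.89330, 28.9975, 0.582600), -11.529),
    "O": ((3.04850, 2.28680, 1.54630, 0.867000),
          (13.2771, 5.70110, 0.323900, 32.9089), 0.250800),
    "P": ((6.43450, 4.17910, 1.78000, 1.49080),
          (1.90670, 27.1570, 0.526000, 68.1645), 1.11490),
    "S": ((6.90530, 5.20340, 1.43790, 1.58630),
          (1.46790, 22.2151, 0.253600, 56.1720), 0.866900),
    # point atom: f identically 1, for form-factor-agnostic tests
    "X": ((1.0, 0.0, 0.0, 0.0), (0.0, 0.0, 0.0, 0.0), 0.0),
}

# displaced solvent volumes, A^3 (Fraser-MacRae-Suzuki dummy-atom radii)
ATOMIC_VOLUMES = {
    "H": 5.15, "C": 16.44, "N": 2.49, "O": 9.13, "P": 5.73, "S": 19.86,
    "X": 0.0,
}


@dataclass(frozen=True)
class FormFactorModel:
    """Element -> f(q) evaluator with excluded-volume / hydration knobs.

    Defaults mirror a plain in-solution calculation: ``c1 = 1`` (full
    excluded-volume subtraction), ``c2 = 0`` (no hydration shell),
    water solvent density 0.334 e/A^3.
    """

    name: str = "cromer-mann"
    coefficients: dict = field(default_factory=lambda: dict(CROMER_MANN))
    volumes: dict = field(default_factory=lambda: dict(ATOMIC_VOLUMES))
    c1: float = 1.0
    c2: float = 0.0
    solvent_density: float = 0.334
    #: electrons added per atom by the crude c2 hydration constant (experimental)
    hydration_scale: float = 1.0

    def _check(self, element: str) -> str:
        e = element.upper()
        if e not in self.coefficients:
            raise KeyError(f"unknown element {element!r} in form-factor table {self.name!r}")
        return e

    def vacuum(self, element: str, q) -> np.ndarray | float:
        """Four-Gaussian vacuum form factor; f(0) = electron count."""
        e = self._check(element)
        a, b, c = self.coefficients[e]
        q = np.asarray(q, dtype=float)
        s2 = (q / (4.0 * np.pi)) ** 2
        f = c + sum(ai * np.exp(-bi * s2) for ai, bi in zip(a, b))
        return f if f.shape else float(f)

    def excluded_volume(self, element: str, q) -> np.ndarray | float:
        """Dummy-atom excluded-volume term rho_s V exp(-q^2 V^(2/3)/(4 pi))."""
        e = self._check(element)
        v = self.volumes.get(e, 0.0)
        q = np.asarray(q, dtype=float)
        g = self.solvent_density * v * np.exp(-(q**2) * v ** (2.0 / 3.0) / (4.0 * np.pi))
        return g if g.shape else float(g)

    def effective(self, element: str, q) -> np.ndarray | float:
        """Solvent-corrected form factor; equals ``vacuum`` when c1 = c2 = 0."""
        f = self.vacuum(element, q) - self.c1 * self.excluded_volume(element, q)
        if self.c2:
            f = f + self.c2 * self.hydration_scale
        return f

    def table(self, structure, q_grid) -> np.ndarray:
        """Per-atom effective factors, shape (n_atoms, n_q).

        Folded implicit hydrogens (``structure.n_hydrogens``) contribute
        additively: f = f_heavy + nH * f_H.
        """
        q = np.asarray(q_grid, dtype=float)
        cache: dict[str, np.ndarray] = {}
        for e in set(structure.elements):
            cache[e] = np.atleast_1d(np.asarray(self.effective(e, q)))
        F = np.stack([cache[e] for e in structure.elements])
        if structure.n_hydrogens is not None:
            fh = np.atleast_1d(np.asarray(self.effective("H", q)))
            F = F + structure.n_hydrogens[:, None] * fh[None, :]
        return F

    def with_params(self, **kwargs) -> "FormFactorModel":
        return replace(self, **kwargs)


def point_model() -> FormFactorModel:
    """Model with all corrections off: 'X' atoms scatter with f = 1."""
    return FormFactorModel(name="point", c1=0.0, c2=0.0)


_DEFAULT = FormFactorModel()


def vacuum_form_factor(element: str, q, model: FormFactorModel | None = None):
    return (_DEFAULT if model is None else model).vacuum(element, q)


def effective_form_factor(element: str, q, model: FormFactorModel | None = None):
    return (_DEFAULT if model is None else model).effective(element, q)


def load_coefficients(path) -> FormFactorModel:
    """Load an alternative coefficient table from a plain-text file.

    One element per line: ``El a1 a2 a3 a4 b1 b2 b3 b4 c volume``;
    '#' starts a comment.
    """
    coeffs, volumes = {}, {}
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 11:
                raise ValueError(f"expected 11 fields per line, got {len(parts)}: {line!r}")
            el = parts[0].upper()
            vals = [float(x) for x in parts[1:]]
            coeffs[el] = (tuple(vals[0:4]), tuple(vals[4:8]), vals[8])
            volumes[el] = vals[9]
    if not coeffs:
        raise ValueError(f"no coefficients found in {path}")
    return FormFactorModel(name=str(path), coefficients=coeffs, volumes=volumes)


def save_coefficients(model: FormFactorModel, path) -> None:
    """Write a model's coefficient table in the plain-text dialect."""
    with open(path, "w") as fh:
        fh.write("# element a1 a2 a3 a4 b1 b2 b3 b4 c volume\n")
        for el, (a, b, c) in model.coefficients.items():
            v = model.volumes.get(el, 0.0)
            fields = " ".join(f"{x:.6g}" for x in (*a, *b, c, v))
            fh.write(f"{el} {fields}\n")
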