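"""Atomic structures with per-atom thermal deviations.

A :class:`Structure` is a flat, ordered list of atoms: element symbols,
Cartesian coordinates in Angstrom, and an optional per-atom thermal
standard deviation ``tau`` (Angstrom, per coordinate).  ``tau`` is the
parameter of the isotropic Gaussian thermal model used throughout the
package: atom *k* is displaced independently along each coordinate with
variance ``tau_k**2``.

Atom order is preserved from the input file and is significant: pair
indices ``(k, l)`` used by the Debye sums and the covariance formulas are
defined by this order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Atom",
    "Structure",
    "read_pdb",
    "write_pdb",
    "assign_tau",
    "radius_of_gyration",
    "kabsch_align",
    "rmsd",
]

# 8*pi**2: conversion between crystallographic B-factors and tau**2
_B_PER_TAU2 = 8.0 * math.pi**2

#: electrons per neutral atom, for electron-count weighting
ELECTRON_COUNTS = {
    "H": 1, "C": 6, "N": 7, "O": 8, "P": 15, "S": 16,
    "FE": 26, "ZN": 30, "MG": 12, "CA": 20, "NA": 11, "CL": 17, "K": 19,
    "X": 1,  # point-atom pseudo-element
}

_WATER_RESNAMES = {"HOH", "WAT", "DOD", "H2O", "TIP", "TIP3", "SOL"}


@dataclass(frozen=True)
class Atom:
    """One atom: element symbol, position (A), thermal SD tau (A), weight."""

    element: str
    position: np.ndarray
    tau: float | None = None
    weight: float = 1.0

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,):
            raise ValueError("position must be a 3-vector")
        if not np.all(np.isfinite(pos)):
            raise ValueError("position components must be finite")
        if self.tau is not None and self.tau < 0:
            raise ValueError("tau must be non-negative")
        if not 0.0 <= self.weight <= 1.0:
            raise ValueError("weight must lie in [0, 1]")
        object.__setattr__(self, "position", pos)


@dataclass
class Structure:
    """Ordered atomic structure.

    Parameters
    ----------
    elements : sequence of str
        Element symbols, upper-case, one per atom.
    coords : (N, 3) array
        Cartesian coordinates in Angstrom.
    tau : (N,) array or None
        Per-atom thermal SD in Angstrom (per coordinate); ``None`` until
        assigned with :func:`assign_tau`.
    weights : (N,) array
        Occupancy-like weights in [0, 1], default 1.
    bfactors : (N,) array or None
        B-factors carried over from a PDB file, if any.
    n_hydrogens : (N,) array or None
        Implicit hydrogens folded onto each heavy atom (united-atom mode).
    label : str
        Free-text label.
    """

    elements: np.ndarray
    coords: np.ndarray
    tau: np.ndarray | None = None
    weights: np.ndarray | None = None
    bfactors: np.ndarray | None = None
    n_hydrogens: np.ndarray | None = None
    label: str = ""

    def __post_init__(self):
        self.elements = np.asarray([str(e).upper() for e in self.elements], dtype=object)
        self.coords = np.array(self.coords, dtype=float)
        n = len(self.elements)
        if n < 1:
            raise ValueError("a Structure needs at least 1 atom")
        if self.coords.shape != (n, 3):
            raise ValueError(f"coords must have shape ({n}, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if self.tau is not None:
            self.tau = np.array(self.tau, dtype=float)
            if self.tau.shape == ():
                self.tau = np.full(n, float(self.tau))
            if self.tau.shape != (n,):
                raise ValueError("tau must be scalar or per-atom")
            if np.any(self.tau < 0):
                raise ValueError("tau must be non-negative")
        if self.weights is None:
            self.weights = np.ones(n)
        else:
            self.weights = np.array(self.weights, dtype=float)
        if self.bfactors is not None:
            self.bfactors = np.array(self.bfactors, dtype=float)
        if self.n_hydrogens is not None:
            self.n_hydrogens = np.array(self.n_hydrogens, dtype=float)

    # -- basic queries -------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def atoms(self) -> list[Atom]:
        taus = self.tau if self.tau is not None else [None] * self.n_atoms
        return [
            Atom(e, p, t, w)
            for e, p, t, w in zip(self.elements, self.coords, taus, self.weights)
        ]

    @classmethod
    def from_atoms(cls, atoms: list[Atom], label: str = "") -> "Structure":
        if not atoms:
            raise ValueError("a Structure needs at least 1 atom")
        tau = None
        if all(a.tau is not None for a in atoms):
            tau = np.array([a.tau for a in atoms])
        return cls(
            elements=[a.element for a in atoms],
            coords=np.array([a.position for a in atoms]),
            tau=tau,
            weights=np.array([a.weight for a in atoms]),
            label=label,
        )

    def copy(self) -> "Structure":
        return Structure(
            elements=self.elements.copy(),
            coords=self.coords.copy(),
            tau=None if self.tau is None else self.tau.copy(),
            weights=self.weights.copy(),
            bfactors=None if self.bfactors is None else self.bfactors.copy(),
            n_hydrogens=None if self.n_hydrogens is None else self.n_hydrogens.copy(),
            label=self.label,
        )

    def centroid(self, weights: np.ndarray | None = None) -> np.ndarray:
        w = self.weights if weights is None else weights
        return (w[:, None] * self.coords).sum(0) / w.sum()

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "Structure":
        """Return a rigidly moved copy (rotation applied first)."""
        out = self.copy()
        if rotation is not None:
            out.coords = out.coords @ np.asarray(rotation, float).T
        if translation is not None:
            out.coords = out.coords + np.asarray(translation, float)
        return out


# ---------------------------------------------------------------------------
# PDB input / output
# ---------------------------------------------------------------------------

def _element_from_name(name: str) -> str:
    """Heuristic element guess from a PDB atom name (columns 13-16)."""
    stripped = "".join(ch for ch in name if ch.isalpha())
    if not stripped:
        return ""
    two = stripped[:2].upper()
    if two in ELECTRON_COUNTS and len(stripped) > 1 and not stripped[0].isdigit():
        # two-letter elements only when unambiguous (FE, ZN, ...)
        if two not in {"CA", "CL", "NA", "K"}:  # usually C-alpha etc. in proteins
            if two in {"FE", "ZN", "MG"}:
                return two
    return stripped[0].upper()


def read_pdb(path, model_policy: str = "first", *, include_het: bool = False,
             include_waters: bool = False, hydrogens: str = "keep"):
    """Read a PDB file into one :class:`Structure` or a list of them.

    Parameters
    ----------
    path : str or Path
        PDB file with at least one ATOM/HETATM record.
    model_policy : {"first", "all-models"}
        Return the first MODEL only, or one Structure per MODEL.
    include_het : bool
        Keep non-water HETATM records (default: exclude; solvation is
        handled via form-factor corrections, not explicit heteroatoms).
    include_waters : bool
        Keep water records (default: exclude).
    hydrogens : {"keep", "drop"}
        Keep explicit hydrogens as given, or drop them.
    """
    from Bio.PDB import PDBParser

    if model_policy not in ("first", "all-models"):
        raise ValueError(f"unknown model_policy {model_policy!r}")
    parser = PDBParser(QUIET=True)
    try:
        pdb = parser.get_structure("s", str(path))
    except FileNotFoundError:
        raise
    except Exception as exc:  # pragma: no cover - parser-specific messages
        raise ValueError(f"could not parse PDB file {path}: {exc}") from exc

    structures = []
    for imodel, model in enumerate(pdb):
        elements, coords, bfactors = [], [], []
        for chain in model:
            for residue in chain:
                hetflag = residue.id[0].strip()
                resname = residue.get_resname().strip().upper()
                is_water = hetflag == "W" or resname in _WATER_RESNAMES
                if is_water and not include_waters:
                    continue
                if hetflag and not is_water and not include_het:
                    continue
                for atom in residue:
                    elem = (atom.element or "").strip().upper()
                    if not elem:
                        elem = _element_from_name(atom.get_name())
                    if not elem:
                        raise ValueError(
                            f"cannot determine element for atom record "
                            f"{atom.get_full_id()!r} (name {atom.get_name()!r})"
                        )
                    if elem == "H" and hydrogens == "drop":
                        continue
                    elements.append(elem)
                    coords.append(atom.get_coord())
                    bfactors.append(atom.get_bfactor())
        if not elements:
            continue
        structures.append(
            Structure(
                elements=elements,
                coords=np.array(coords, dtype=float),
                bfactors=np.array(bfactors, dtype=float),
                label=f"{path}:model{imodel + 1}",
            )
        )

    if not structures:
        raise ValueError(f"zero atoms after filtering in {path}")
    if model_policy == "first":
        return structures[0]
    return structures


def write_pdb(structures, path) -> None:
    """Write one Structure (or a list, as MODEL blocks) to a PDB file.

    If ``tau`` is assigned it is stored in the B-factor column as
    ``8 * pi**2 * tau**2`` so that annotated structures round-trip.
    """
    if isinstance(structures, Structure):
        structures = [structures]
        multi = False
    else:
        structures = list(structures)
        multi = True
    with open(path, "w") as fh:
        for imodel, s in enumerate(structures, start=1):
            if multi:
                fh.write(f"MODEL     {imodel:4d}\n")
            if s.tau is not None:
                bfac = _B_PER_TAU2 * s.tau**2
            elif s.bfactors is not None:
                bfac = s.bfactors
            else:
                bfac = np.zeros(s.n_atoms)
            for i in range(s.n_atoms):
                e = s.elements[i]
                name = e if len(e) > 1 else f" {e}"
                x, y, z = s.coords[i]
                fh.write(
                    f"ATOM  {i % 99999 + 1:5d} {name:<4s}{'GLY':>3s} A"
                    f"{i % 9999 + 1:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                    f"{s.weights[i]:6.2f}{bfac[i]:6.2f}          {e:>2s}\n"
                )
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Thermal annotation
# ---------------------------------------------------------------------------

def assign_tau(s: Structure, mode: str = "uniform", value: float | None = None) -> Structure:
    """Return a copy of ``s`` with per-atom thermal SDs assigned.

    ``uniform`` sets every atom's tau to ``value`` (Angstrom).
    ``from-bfactor`` converts crystallographic B-factors via
    ``tau = sqrt(B / (8 pi^2))``.
    """
    out = s.copy()
    if mode == "uniform":
        if value is None or value < 0:
            raise ValueError("uniform mode needs a non-negative tau value")
        out.tau = np.full(s.n_atoms, float(value))
    elif mode == "from-bfactor":
        if s.bfactors is None:
            raise ValueError("from-bfactor mode needs B-factors")
        if np.any(s.bfactors < 0):
            raise ValueError("negative B-factor encountered")
        out.tau = np.sqrt(s.bfactors / _B_PER_TAU2)
    else:
        raise ValueError(f"unknown tau mode {mode!r}")
    return out


# ---------------------------------------------------------------------------
# Real-space diagnostics
# ---------------------------------------------------------------------------

def radius_of_gyration(s: Structure, weighting: str = "uniform") -> float:
    """Root-mean-square distance of atoms from the (weighted) centroid."""
    if weighting == "uniform":
        w = np.ones(s.n_atoms)
    elif weighting == "electron-count":
        try:
            w = np.array([float(ELECTRON_COUNTS[e]) for e in s.elements])
        except KeyError as exc:
            raise ValueError(f"no electron count for element {exc.args[0]!r}") from exc
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    center = (w[:, None] * s.coords).sum(0) / w.sum()
    r2 = ((s.coords - center) ** 2).sum(1)
    return float(np.sqrt((w * r2).sum() / w.sum()))


def rmsd(a: Structure, b: Structure) -> float:
    """Plain coordinate RMSD between equally sized structures (no fitting)."""
    if a.n_atoms != b.n_atoms:
        raise ValueError("structures must have equal atom counts")
    return float(np.sqrt(((a.coords - b.coords) ** 2).sum(1).mean()))


def kabsch_align(ensemble: list[Structure], reference: Structure) -> list[Structure]:
    """Rigid-body (Kabsch) superposition of each structure onto ``reference``.

    Least-squares optimal rotation + translation per structure.  Note that
    Debye intensities are invariant under rigid motion, so alignment only
    matters for real-space diagnostics, never for profiles.
    """
    from scipy.spatial.transform import Rotation

    ref_center = reference.coords.mean(0)
    ref0 = reference.coords - ref_center
    out = []
    for s in ensemble:
        if s.n_atoms != reference.n_atoms:
            raise ValueError("structures must have equal atom counts")
        center = s.coords.mean(0)
        rot, _ = Rotation.align_vectors(ref0, s.coords - center)
        aligned = s.copy()
        aligned.coords = rot.apply(s.coords - center) + ref_center
        out.append(aligned)
    return out
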