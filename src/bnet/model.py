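"""Domain types for crystal structures and damage metrics.

The central container is :class:`StructureModel`: the asymmetric unit of a
protein crystal as an ordered list of atoms, together with the unit cell,
space-group symmetry operators and refinement metadata.  All coordinates are
orthogonal Angstroms; fractional coordinates exist only transiently inside
the lattice-expansion step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np

HYDROGEN_ELEMENTS = frozenset({"H", "D"})


class BFactorModel(str, Enum):
    """How per-atom displacement parameters were refined."""

    PER_ATOM_ISO = "per_atom_iso"
    PER_ATOM_ANISO = "per_atom_aniso"
    PER_RESIDUE = "per_residue"
    FLAT = "flat"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class AtomRecord:
    """One modelled atom of the asymmetric unit.

    ``b_iso`` is the full isotropic B-factor in A^2 (for anisotropically
    refined atoms, the equivalent isotropic B).  ``occupancy`` is the
    fraction of sites occupied by this conformer.
    """

    serial: int
    element: str
    atom_name: str
    residue_name: str
    chain_id: str
    residue_seq: int
    insertion_code: str
    altloc: str
    xyz: np.ndarray
    occupancy: float
    b_iso: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValueError(
                f"atom {self.serial}: occupancy {self.occupancy} outside [0, 1]"
            )
        if self.b_iso < 0.0:
            raise ValueError(
                f"atom {self.serial}: negative isotropic B-factor {self.b_iso}"
            )
        object.__setattr__(self, "xyz", np.asarray(self.xyz, dtype=float))
        if self.xyz.shape != (3,):
            raise ValueError(f"atom {self.serial}: xyz must be a 3-vector")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in HYDROGEN_ELEMENTS

    @property
    def residue_key(self) -> tuple:
        """(chain, seqnum, icode, resname) — identifies the parent residue."""
        return (self.chain_id, self.residue_seq, self.insertion_code,
                self.residue_name)


@dataclass(frozen=True)
class SymmetryOp:
    """A space-group operator in the fractional-coordinate basis."""

    rotation: np.ndarray   # 3x3
    translation: np.ndarray  # 3-vector of fractions

    def __post_init__(self) -> None:
        object.__setattr__(self, "rotation",
                           np.asarray(self.rotation, dtype=float))
        object.__setattr__(self, "translation",
                           np.asarray(self.translation, dtype=float))
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise ValueError("symmetry operator must be 3x3 rotation + 3-vector")

    @property
    def is_identity(self) -> bool:
        return (np.array_equal(self.rotation, np.eye(3))
                and np.allclose(self.translation, 0.0))

    def apply(self, frac: np.ndarray) -> np.ndarray:
        """Apply to fractional coordinates (works on (3,) or (N, 3))."""
        return np.asarray(frac) @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "SymmetryOp":
        return cls(np.eye(3), np.zeros(3))


@dataclass
class CrystalCell:
    """Unit-cell parameters plus the space-group operators."""

    a: float
    b: float
    c: float
    alpha: float
    beta: float
    gamma: float
    symops: list = field(default_factory=lambda: [SymmetryOp.identity()])
    spacegroup_symbol: str = "P 1"

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell edges must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not (0.0 < ang < 180.0):
                raise ValueError(f"cell angle {ang} outside (0, 180)")
        if not any(op.is_identity for op in self.symops):
            raise ValueError("symmetry operators must include the identity")

    @property
    def orthogonalization_matrix(self) -> np.ndarray:
        """Standard crystallographic fractional->orthogonal matrix (PDB
        convention: a along x, b in the xy plane)."""
        al, be, ga = np.radians([self.alpha, self.beta, self.gamma])
        cos_al, cos_be, cos_ga = np.cos([al, be, ga])
        sin_ga = np.sin(ga)
        v = np.sqrt(1 - cos_al**2 - cos_be**2 - cos_ga**2
                    + 2 * cos_al * cos_be * cos_ga)
        return np.array([
            [self.a, self.b * cos_ga, self.c * cos_be],
            [0.0, self.b * sin_ga,
             self.c * (cos_al - cos_be * cos_ga) / sin_ga],
            [0.0, 0.0, self.c * v / sin_ga],
        ])

    def orthogonalize(self, frac: np.ndarray) -> np.ndarray:
        return np.asarray(frac) @ self.orthogonalization_matrix.T

    def fractionalize(self, xyz: np.ndarray) -> np.ndarray:
        inv = np.linalg.inv(self.orthogonalization_matrix)
        return np.asarray(xyz) @ inv.T


@dataclass
class StructureMetadata:
    """Experiment/refinement metadata used for eligibility screening."""

    pdb_id: str = "XXXX"
    resolution: Optional[float] = None       # A
    r_work: Optional[float] = None
    r_free: Optional[float] = None
    temperature: Optional[float] = None      # K
    deposition_year: Optional[int] = None
    molecular_mass: Optional[float] = None   # Da
    b_factor_model: BFactorModel = BFactorModel.UNKNOWN

    def __post_init__(self) -> None:
        if self.resolution is not None and self.resolution <= 0:
            raise ValueError(f"resolution {self.resolution} must be > 0")
        if self.r_free is not None and not (0.0 <= self.r_free <= 1.0):
            raise ValueError(f"r_free {self.r_free} outside [0, 1]")


@dataclass
class StructureModel:
    """The asymmetric unit: atoms + cell + metadata."""

    atoms: list
    cell: CrystalCell
    metadata: StructureMetadata = field(default_factory=StructureMetadata)

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("structure contains no atoms")
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise ValueError("atom serial numbers are not unique")

    def included_atoms(self) -> list:
        """Atoms that enter metric computation: non-hydrogen, occupancy > 0."""
        return [a for a in self.atoms
                if not a.is_hydrogen and a.occupancy > 0.0]

    def atom_by_serial(self, serial: int) -> AtomRecord:
        for a in self.atoms:
            if a.serial == serial:
                return a
        raise KeyError(f"no atom with serial {serial}")
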