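"""Deterministic toy crystal structures with controllable damage.

The generator builds pseudo-protein chains of Asp/Glu/Asn/Gln/Ala residues
on a coarse self-avoiding lattice path inside a P1 cell, assigns a baseline
B-factor field that *decreases* with local packing (so the packing-density
normalisation has something real to remove), and then multiplies the
Asp/Glu carboxyl-oxygen B-factors by a damage factor — emulating the
B-factor inflation produced when decarboxylated side chains are refined at
full occupancy.  Ground-truth damaged serials are returned alongside the
model, and identical specs (including the seed) give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .model import (AtomRecord, CrystalCell, StructureMetadata,
                    StructureModel)

RESIDUE_SPACING = 6.0      # A between consecutive lattice path nodes
CELL_PADDING = 15.0        # A of empty cell beyond the chain extent
MIN_B = 2.0                # A^2 floor keeps every B-factor positive
COORD_JITTER = 0.15        # A of positional jitter breaking grid degeneracy

# atom-name -> offset from the CA lattice node, per residue type
_BACKBONE = [("N", (-1.3, 0.8, 0.0)), ("CA", (0.0, 0.0, 0.0)),
             ("C", (1.3, 0.8, 0.0)), ("O", (1.9, 1.9, 0.3))]
_SIDECHAINS = {
    "ALA": [("CB", (0.0, -1.5, 0.6))],
    "LEU": [("CB", (0.0, -1.5, 0.6)), ("CG", (0.6, -2.7, 0.3)),
            ("CD1", (1.8, -3.0, 0.6)), ("CD2", (-0.2, -3.6, -0.3))],
    "ASP": [("CB", (0.0, -1.5, 0.6)), ("CG", (0.6, -2.7, 0.3)),
            ("OD1", (1.8, -3.0, 0.6)), ("OD2", (-0.2, -3.6, -0.3))],
    "GLU": [("CB", (0.0, -1.5, 0.6)), ("CG", (0.6, -2.7, 0.3)),
            ("CD", (0.4, -3.9, 0.8)), ("OE1", (1.4, -4.5, 1.1)),
            ("OE2", (-0.8, -4.3, 0.8))],
    "ASN": [("CB", (0.0, -1.5, 0.6)), ("CG", (0.6, -2.7, 0.3)),
            ("OD1", (1.8, -3.0, 0.6)), ("ND2", (-0.2, -3.6, -0.3))],
    "GLN": [("CB", (0.0, -1.5, 0.6)), ("CG", (0.6, -2.7, 0.3)),
            ("CD", (0.4, -3.9, 0.8)), ("OE1", (1.4, -4.5, 1.1)),
            ("NE2", (-0.8, -4.3, 0.8))],
}
CARBOXYL_OXYGENS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}

# dose (MGy) -> damage factor: factor = 1 + slope * dose * _DOSE_CALIBRATION.
# The constant converts a target B_net-per-MGy gradient into the carboxyl
# B-factor inflation per MGy that produces roughly that gradient on the
# default fixture (B_net responds super-linearly to the inflation factor).
_DOSE_CALIBRATION = 0.3


@dataclass(frozen=True)
class FixtureSpec:
    """Everything that determines a synthetic structure (incl. the seed)."""

    n_chains: int = 2
    residues_per_chain: int = 75
    composition: dict = field(default_factory=lambda: {
        # Asp/Glu/Asn/Gln at their typical frequencies in globular
        # proteins; Leu/Ala stand in for the remaining bulk
        "ASP": 0.055, "GLU": 0.068, "ASN": 0.04, "GLN": 0.04,
        "LEU": 0.40, "ALA": 0.397})
    cell: Optional[CrystalCell] = None    # default: P1, extent + 15 A
    baseline_b: float = 20.0              # A^2
    packing_coupling: float = 4.0         # A^2 per crowding z-score
    damage_factor: float = 1.0
    noise_sd: float = 3.0                 # A^2 (~15% of the baseline B)
    seed: int = 0
    pdb_id: str = "SYN1"
    resolution: float = 2.0
    temperature: float = 100.0
    r_work: float = 0.18
    r_free: float = 0.22


def _residue_sequence(spec: FixtureSpec, rng: np.random.Generator) -> list:
    """Per-chain residue list with largest-remainder composition counts
    (so Asp/Glu counts are exact, not sampled), shuffled deterministically."""
    n = spec.residues_per_chain
    names = list(spec.composition)
    weights = np.array([spec.composition[k] for k in names], dtype=float)
    weights = weights / weights.sum()
    counts = np.floor(weights * n).astype(int)
    remainder = weights * n - counts
    for i in np.argsort(-remainder)[: n - counts.sum()]:
        counts[i] += 1
    seq = [name for name, c in zip(names, counts) for _ in range(c)]
    rng.shuffle(seq)
    return seq


def _snake_path(n_nodes: int) -> np.ndarray:
    """Self-avoiding path through a cubic grid (boustrophedon ordering)."""
    side = int(np.ceil(n_nodes ** (1 / 3)))
    nodes = []
    for iz in range(side):
        for iy in range(side):
            xs = range(side) if iy % 2 == 0 else range(side - 1, -1, -1)
            if iz % 2 == 1:
                xs = reversed(list(xs))
            for ix in xs:
                nodes.append((ix, iy, iz))
                if len(nodes) == n_nodes:
                    return np.array(nodes, dtype=float) * RESIDUE_SPACING
    return np.array(nodes, dtype=float) * RESIDUE_SPACING


def generate_fixture(spec: FixtureSpec) -> tuple:
    """Build one synthetic structure.

    Returns ``(StructureModel, damaged_serials)`` where the serial list
    labels the Asp/Glu carboxyl oxygens whose B-factors were inflated
    (empty when damage_factor == 1).
    """
    if spec.residues_per_chain < 10:
        raise ValueError("residues_per_chain must be >= 10")
    if spec.damage_factor < 1.0:
        raise ValueError("damage_factor must be >= 1")
    rng = np.random.default_rng(spec.seed)

    total_res = spec.n_chains * spec.residues_per_chain
    path = _snake_path(total_res)

    names, residues, chains, seqnums, positions = [], [], [], [], []
    node = 0
    for ci in range(spec.n_chains):
        chain_id = chr(ord("A") + ci % 26)
        seq = _residue_sequence(spec, rng)
        for ri, resname in enumerate(seq):
            base = path[node]
            node += 1
            for atom_name, off in _BACKBONE + _SIDECHAINS[resname]:
                names.append(atom_name)
                residues.append(resname)
                chains.append(chain_id)
                seqnums.append(ri + 1)
                positions.append(base + np.asarray(off))
    positions = np.asarray(positions)
    positions += rng.normal(0.0, COORD_JITTER, positions.shape)
    positions -= positions.min(axis=0) - 2.0   # keep fractionals in [0, 1)

    cell = spec.cell
    if cell is None:
        extent = positions.max(axis=0) + 2.0
        cell = CrystalCell(*(extent + CELL_PADDING), 90.0, 90.0, 90.0)
    frac = cell.fractionalize(positions)
    if frac.min() < 0 or frac.max() >= 1.0:
        raise ValueError("cell too small: chain does not fit the unit cell")

    # baseline B anti-correlated with local crowding (7 A neighbour count)
    tree = cKDTree(positions)
    crowd = tree.query_ball_point(positions, 7.0,
                                  return_length=True).astype(float)
    z = (crowd - crowd.mean()) / max(crowd.std(), 1e-9)
    b = (spec.baseline_b - spec.packing_coupling * z
         + rng.normal(0.0, spec.noise_sd, len(positions)))
    b = np.maximum(b, MIN_B)

    # heterogeneous damage: decarboxylation recruits a minority of sites
    # strongly while the rest stay near-intact, so each carboxyl-oxygen
    # site gets a fixed bimodal susceptibility u — with probability 0.3 a
    # strongly damaged site (u in [0.7, 1]), otherwise barely affected
    # (u in [0, 0.25]).  The site's B is inflated by
    # 1 + (damage_factor - 1) * u; sites with u >= 0.5 (majority-
    # converted) are the labelled "damaged" atoms.
    carboxyl = [i for i in range(len(names))
                if names[i] in CARBOXYL_OXYGENS.get(residues[i], ())]
    strong = rng.uniform(0.0, 1.0, len(carboxyl)) < 0.3
    magnitude = rng.uniform(0.0, 1.0, len(carboxyl))
    susceptibility = np.where(strong, 0.7 + 0.3 * magnitude,
                              0.25 * magnitude)
    if spec.damage_factor > 1.0:
        b[carboxyl] *= 1.0 + (spec.damage_factor - 1.0) * susceptibility
        damaged_serials = [i + 1 for i, u in zip(carboxyl, susceptibility)
                           if u >= 0.5]
    else:
        damaged_serials = []

    atoms = [AtomRecord(serial=i + 1, element=names[i][0],
                        atom_name=names[i], residue_name=residues[i],
                        chain_id=chains[i], residue_seq=seqnums[i],
                        insertion_code="", altloc="", xyz=positions[i],
                        occupancy=1.0, b_iso=float(b[i]))
             for i in range(len(names))]
    metadata = StructureMetadata(
        pdb_id=spec.pdb_id, resolution=spec.resolution,
        r_work=spec.r_work, r_free=spec.r_free,
        temperature=spec.temperature)
    return StructureModel(atoms=atoms, cell=cell, metadata=metadata), \
        damaged_serials


def dose_to_damage_factor(dose: float, slope: float,
                          factor_cap: Optional[float] = None) -> float:
    """Fixed monotone map from absorbed dose (MGy) to carboxyl B inflation."""
    factor = 1.0 + _DOSE_CALIBRATION * slope * dose
    if factor_cap is not None:
        factor = min(factor, factor_cap)
    return factor


def generate_damage_series(spec: FixtureSpec, doses,
                           slope: float = 0.1,
                           factor_cap: Optional[float] = None) -> list:
    """A damage series: one crystal, increasing dose.

    All structures share the spec's seed (identical backbone and baseline
    B-field); only the carboxyl-oxygen inflation grows with dose, mapped
    through :func:`dose_to_damage_factor` so that the fitted B_net-vs-dose
    gradient approximates ``slope`` (in MGy^-1).  ``factor_cap`` caps the
    inflation, reproducing the plateau seen once the damage-prone sites of
    a real crystal are exhausted.  Returns ``[(dose, StructureModel), ...]``.
    """
    doses = [float(d) for d in doses]
    if len(doses) < 3:
        raise ValueError("a damage series needs >= 3 doses")
    if any(b <= a for a, b in zip(doses, doses[1:])):
        raise ValueError("doses must be strictly increasing")
    series = []
    for i, dose in enumerate(doses):
        factor = dose_to_damage_factor(dose, slope, factor_cap)
        model, _ = generate_fixture(replace(
            spec, damage_factor=factor,
            pdb_id=f"{spec.pdb_id[:3]}{i:x}".upper()))
        series.append((dose, model))
    return series


def generate_cohort(n: int, resolution_range=(1.0, 3.4),
                    coupling: float = 0.0, seed: int = 0,
                    residues_per_chain: int = 90) -> list:
    """Synthetic cohort spanning a resolution grid.

    ``coupling`` sets a monotone B_net-resolution dependence: positive
    values make worse-resolution (larger A) structures more damaged,
    negative values the reverse, 0 leaves damage independent of resolution.
    The other metadata covariates carry independent noise.  Returns a list
    of ``(structure_id, StructureModel, extra_metadata)`` triples.
    """
    if n < 10:
        raise ValueError("cohort size must be >= 10")
    rng = np.random.default_rng(seed)
    lo, hi = resolution_range
    resolutions = np.linspace(lo, hi, n)
    entries = []
    for i in range(n):
        t = (resolutions[i] - lo) / (hi - lo)
        ramp = t if coupling >= 0 else 1.0 - t
        factor = 1.0 + abs(coupling) * ramp + rng.uniform(0.0, 0.15)
        spec = FixtureSpec(
            n_chains=1,
            residues_per_chain=residues_per_chain + int(rng.integers(0, 16)),
            damage_factor=factor, seed=int(rng.integers(2**31)),
            pdb_id=f"S{i:04d}",
            resolution=float(np.round(resolutions[i], 3)),
            temperature=float(rng.uniform(85.0, 115.0)),
            r_work=float(rng.uniform(0.14, 0.24)),
            r_free=float(rng.uniform(0.18, 0.30)),
        )
        model, _ = generate_fixture(spec)
        extra = {
            "molecular_mass": float(len(model.atoms) * 13.5
                                    + rng.normal(0.0, 200.0)),
            "bfactor_restraint_weight": float(rng.lognormal(0.0, 0.5)),
            "deposition_year": int(rng.integers(1995, 2021)),
        }
        entries.append((spec.pdb_id, model, extra))
    return entries
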