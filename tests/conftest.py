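"""Shared fixtures: synthetic structures generated once per session."""

from __future__ import annotations

import numpy as np
import pytest

from bnet import (CrystalCell, FixtureSpec, StructureMetadata,
                  StructureModel, SymmetryOp, generate_fixture)
from bnet.model import AtomRecord


def make_atom(serial, xyz, b_iso=15.0, element="C", atom_name="CA",
              residue_name="ALA", chain_id="A", residue_seq=None,
              occupancy=1.0, altloc=""):
    return AtomRecord(
        serial=serial, element=element, atom_name=atom_name,
        residue_name=residue_name, chain_id=chain_id,
        residue_seq=residue_seq if residue_seq is not None else serial,
        insertion_code="", altloc=altloc, xyz=np.asarray(xyz, dtype=float),
        occupancy=occupancy, b_iso=b_iso)


def make_model(atoms, cell=None, metadata=None):
    if cell is None:
        cell = CrystalCell(100.0, 100.0, 100.0, 90.0, 90.0, 90.0)
    return StructureModel(atoms=list(atoms), cell=cell,
                          metadata=metadata or StructureMetadata())


def make_residue(serials_start, resname, base_xyz, b_iso=15.0,
                 chain_id="A", residue_seq=1, occupancy=1.0):
    """A pseudo-residue with correctly named side-chain oxygens."""
    names = {
        "ASP": [("CB", "C"), ("CG", "C"), ("OD1", "O"), ("OD2", "O")],
        "GLU": [("CB", "C"), ("CG", "C"), ("CD", "C"), ("OE1", "O"),
                ("OE2", "O")],
        "ASN": [("CB", "C"), ("CG", "C"), ("OD1", "O"), ("ND2", "N")],
        "GLN": [("CB", "C"), ("CG", "C"), ("CD", "C"), ("OE1", "O"),
                ("NE2", "N")],
        "ALA": [("CB", "C")],
    }[resname]
    base = np.asarray(base_xyz, dtype=float)
    atoms = [make_atom(serials_start, base, b_iso=b_iso, element="C",
                       atom_name="CA", residue_name=resname,
                       chain_id=chain_id, residue_seq=residue_seq,
                       occupancy=occupancy)]
    for i, (name, elem) in enumerate(names):
        atoms.append(make_atom(
            serials_start + 1 + i, base + (i + 1) * 0.9, b_iso=b_iso,
            element=elem, atom_name=name, residue_name=resname,
            chain_id=chain_id, residue_seq=residue_seq,
            occupancy=occupancy))
    return atoms


twofold = SymmetryOp(np.diag([-1.0, 1.0, -1.0]), np.zeros(3))


@pytest.fixture(scope="session")
def null_fixture():
    return generate_fixture(FixtureSpec())


@pytest.fixture(scope="session")
def null_model(null_fixture):
    return null_fixture[0]


@pytest.fixture(scope="session")
def damaged_fixture():
    from dataclasses import replace
    return generate_fixture(replace(FixtureSpec(), damage_factor=2.0))


@pytest.fixture(scope="session")
def damaged_model(damaged_fixture):
    return damaged_fixture[0]


@pytest.fixture(scope="session")
def null_pipeline(null_model):
    from bnet import compute_bnet_for_structure
    return compute_bnet_for_structure(null_model)


@pytest.fixture(scope="session")
def damaged_pipeline(damaged_model):
    from bnet import compute_bnet_for_structure
    return compute_bnet_for_structure(damaged_model)


def random_blob_model(rng, n_atoms=200, cell_edge=30.0, symops=None):
    """Random atom positions in a compact cell; tests lattice counting."""
    cell = CrystalCell(cell_edge, cell_edge, cell_edge, 90.0, 90.0, 90.0,
                       symops=symops or [SymmetryOp.identity()])
    xyz = rng.uniform(2.0, cell_edge - 2.0, (n_atoms, 3))
    atoms = [make_atom(i + 1, xyz[i], b_iso=float(rng.uniform(5, 50)))
             for i in range(n_atoms)]
    return make_model(atoms, cell=cell)
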