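"""Reading and writing crystal-structure coordinate files.

Coordinate parsing is delegated to gemmi, which understands both legacy PDB
and PDBx/mmCIF (including the PDB-REDO dialect).  Refinement metadata
(resolution, R-factors, data-collection temperature) is extracted here
directly from mmCIF tags or REMARK records, because minimal files — such as
the synthetic fixtures used in testing — often lack the fully-formed header
blocks gemmi's own metadata parser expects.
"""

from __future__ import annotations

import logging
import math
import re
from pathlib import Path
from typing import Optional

import gemmi
import numpy as np
import pandas as pd

from .model import (
    AtomRecord,
    BFactorModel,
    CrystalCell,
    StructureMetadata,
    StructureModel,
    SymmetryOp,
)

logger = logging.getLogger(__name__)

_EIGHT_PI_SQ = 8.0 * math.pi**2


class StructureParseError(ValueError):
    """A coordinate file could not be turned into a usable StructureModel."""


def _detect_format(path: Path, fmt: str) -> str:
    if fmt != "auto":
        return fmt
    suffix = path.suffix.lower()
    if suffix in (".cif", ".mmcif"):
        return "mmcif"
    if suffix in (".pdb", ".ent"):
        return "pdb"
    # fall back on content sniffing: mmCIF files start with "data_"
    with open(path) as fh:
        head = fh.read(64)
    return "mmcif" if head.lstrip().startswith("data_") else "pdb"


def _gemmi_op_to_symop(op: gemmi.Op) -> SymmetryOp:
    den = float(gemmi.Op.DEN)
    rot = np.array(op.rot, dtype=float) / den
    tran = np.array(op.tran, dtype=float) / den
    if not np.all(np.isin(rot, (-1.0, 0.0, 1.0))):
        logger.warning("non-standard symmetry operator %s (rotation entries "
                       "outside {-1, 0, 1})", op.triplet())
    return SymmetryOp(rot, tran)


def _symops_from_cif(block: gemmi.cif.Block) -> Optional[list]:
    """Explicit symmetry-operator records take precedence over the symbol."""
    for tag in ("_space_group_symop.operation_xyz",
                "_symmetry_equiv.pos_as_xyz",
                "_symmetry_equiv_pos_as_xyz"):
        triplets = [gemmi.cif.as_string(v) for v in block.find_loop(tag)]
        if not triplets:
            v = block.find_value(tag)
            if v is not None:
                triplets = [gemmi.cif.as_string(v)]
        if triplets:
            return [_gemmi_op_to_symop(gemmi.Op(t)) for t in triplets]
    return None


def _resolve_symops(st: gemmi.Structure,
                    block: Optional[gemmi.cif.Block]) -> tuple:
    """Return (symops, spacegroup symbol); explicit records > symbol lookup."""
    if block is not None:
        ops = _symops_from_cif(block)
        if ops:
            return ops, st.spacegroup_hm or "P 1"
    sg = st.find_spacegroup()
    if sg is None:
        raise StructureParseError(
            f"cannot resolve space group: no explicit symmetry-operator "
            f"records and symbol {st.spacegroup_hm!r} is not recognised "
            f"(missing/invalid CRYST1 or _symmetry records)")
    ops = [_gemmi_op_to_symop(op) for op in sg.operations()]
    return ops, sg.hm


def _cif_number(block: gemmi.cif.Block, *tags: str) -> Optional[float]:
    for tag in tags:
        v = block.find_value(tag)
        if v is None:
            values = [gemmi.cif.as_string(x) for x in block.find_loop(tag)]
            v = values[0] if values else None
        if v is not None and v not in ("?", "."):
            try:
                return float(gemmi.cif.as_string(v))
            except ValueError:
                continue
    return None


def _metadata_from_cif(block: gemmi.cif.Block, pdb_id: str) -> StructureMetadata:
    year = None
    for tag in ("_pdbx_database_status.recvd_initial_deposition_date",
                "_database_PDB_rev.date_original"):
        v = block.find_value(tag)
        if v is None:
            values = [gemmi.cif.as_string(x) for x in block.find_loop(tag)]
            v = values[0] if values else None
        if v and v not in ("?", "."):
            m = re.match(r"(\d{4})", gemmi.cif.as_string(v))
            if m:
                year = int(m.group(1))
                break
    return StructureMetadata(
        pdb_id=pdb_id,
        resolution=_cif_number(block, "_refine.ls_d_res_high",
                               "_reflns.d_resolution_high"),
        r_work=_cif_number(block, "_refine.ls_R_factor_R_work",
                           "_refine.ls_R_factor_obs"),
        r_free=_cif_number(block, "_refine.ls_R_factor_R_free"),
        temperature=_cif_number(block, "_diffrn.ambient_temp"),
        deposition_year=year,
        molecular_mass=_cif_number(block, "_entity.formula_weight"),
    )


_PDB_RES_RE = re.compile(r"REMARK   2 RESOLUTION\.\s+([\d.]+)\s+ANGSTROM")
_PDB_RWORK_RE = re.compile(r"REMARK   3\s+R VALUE\s+\(WORKING SET\)\s*:\s*([\d.]+)")
_PDB_RFREE_RE = re.compile(r"REMARK   3\s+FREE R VALUE\s*:\s*([\d.]+)")
_PDB_TEMP_RE = re.compile(r"REMARK 200\s+TEMPERATURE\s+\(KELVIN\)\s*:\s*([\d.]+)")
_PDB_HEADER_RE = re.compile(r"^HEADER.{44}(\d{2}-[A-Z]{3}-(\d{2,4}))")


def _metadata_from_pdb_text(text: str, pdb_id: str) -> StructureMetadata:
    def search(rx):
        m = rx.search(text)
        return float(m.group(1)) if m else None

    year = None
    m = _PDB_HEADER_RE.search(text)
    if m:
        yy = int(m.group(2))
        year = yy if yy > 100 else (1900 + yy if yy > 50 else 2000 + yy)
    return StructureMetadata(
        pdb_id=pdb_id,
        resolution=search(_PDB_RES_RE),
        r_work=search(_PDB_RWORK_RE),
        r_free=search(_PDB_RFREE_RE),
        temperature=search(_PDB_TEMP_RE),
        deposition_year=year,
    )


def _classify_bfactor_model(atoms: list, any_aniso: bool) -> BFactorModel:
    b = np.array([a.b_iso for a in atoms if not a.is_hydrogen])
    if len(b) == 0:
        return BFactorModel.UNKNOWN
    if np.std(b) < 1e-6:
        return BFactorModel.FLAT
    per_res: dict = {}
    for a in atoms:
        if a.is_hydrogen:
            continue
        per_res.setdefault(a.residue_key, []).append(a.b_iso)
    multi = [vals for vals in per_res.values() if len(vals) > 1]
    if multi and all(np.ptp(vals) < 1e-6 for vals in multi):
        return BFactorModel.PER_RESIDUE
    return BFactorModel.PER_ATOM_ANISO if any_aniso else BFactorModel.PER_ATOM_ISO


def read_structure(path, fmt: str = "auto") -> StructureModel:
    """Read a PDB or mmCIF coordinate file into a :class:`StructureModel`.

    Coordinates are returned in orthogonal Angstroms (gemmi applies the
    standard orthogonalisation to mmCIF fractional records where needed).
    Symmetry operators come from explicit records in the file where present,
    otherwise from the space-group symbol.  Hydrogens are retained but
    flagged; anisotropically refined atoms contribute their equivalent
    isotropic B.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _detect_format(path, fmt)

    block = None
    if fmt == "mmcif":
        try:
            doc = gemmi.cif.read(str(path))
            block = doc.sole_block()
            st = gemmi.make_structure_from_block(block)
        except (RuntimeError, ValueError) as exc:
            raise StructureParseError(f"{path}: mmCIF parse failed: {exc}")
    else:
        try:
            st = gemmi.read_pdb(str(path))
        except (RuntimeError, ValueError) as exc:
            raise StructureParseError(f"{path}: PDB parse failed: {exc}")

    if not st.cell.is_crystal():
        raise StructureParseError(
            f"{path}: no usable unit cell (missing CRYST1 / _cell records)")

    symops, sg_symbol = _resolve_symops(st, block)
    cell = CrystalCell(st.cell.a, st.cell.b, st.cell.c,
                       st.cell.alpha, st.cell.beta, st.cell.gamma,
                       symops=symops, spacegroup_symbol=sg_symbol)

    if len(st) == 0:
        raise StructureParseError(f"{path}: file contains no models")
    model0 = st[0]

    atoms = []
    any_aniso = False
    serial = 0
    for chain in model0:
        for res in chain:
            for at in res:
                serial += 1
                b_iso = at.b_iso
                if at.aniso.nonzero():
                    any_aniso = True
                    if b_iso <= 0:
                        b_iso = _EIGHT_PI_SQ * at.aniso.trace() / 3.0
                if b_iso < 0:
                    raise StructureParseError(
                        f"{path}: atom serial {at.serial} has negative "
                        f"B-factor {b_iso}")
                atoms.append(AtomRecord(
                    serial=serial,
                    element=at.element.name,
                    atom_name=at.name,
                    residue_name=res.name,
                    chain_id=chain.name,
                    residue_seq=res.seqid.num,
                    insertion_code=res.seqid.icode.strip(),
                    altloc=at.altloc if at.altloc != "\x00" else "",
                    xyz=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    occupancy=min(max(at.occ, 0.0), 1.0),
                    b_iso=b_iso,
                ))
    if not atoms:
        raise StructureParseError(f"{path}: file contains no atoms")

    pdb_id = (st.name or path.stem)[:20]
    if fmt == "mmcif":
        metadata = _metadata_from_cif(block, pdb_id)
    else:
        metadata = _metadata_from_pdb_text(path.read_text(), pdb_id)
    metadata.b_factor_model = _classify_bfactor_model(atoms, any_aniso)

    return StructureModel(atoms=atoms, cell=cell, metadata=metadata)


def model_to_gemmi(model: StructureModel) -> gemmi.Structure:
    """Build a gemmi Structure mirroring the StructureModel (for writing)."""
    st = gemmi.Structure()
    st.name = model.metadata.pdb_id
    c = model.cell
    st.cell = gemmi.UnitCell(c.a, c.b, c.c, c.alpha, c.beta, c.gamma)
    st.spacegroup_hm = c.spacegroup_symbol
    gm = gemmi.Model("1")
    chains: dict = {}
    order: list = []
    for a in model.atoms:
        ch = chains.get(a.chain_id)
        if ch is None:
            ch = gemmi.Chain(a.chain_id)
            chains[a.chain_id] = ch
            order.append(a.chain_id)
        res_id = (a.residue_seq, a.insertion_code, a.residue_name)
        if len(ch) == 0 or (ch[-1].seqid.num, ch[-1].seqid.icode.strip(),
                            ch[-1].name) != res_id:
            res = gemmi.Residue()
            res.name = a.residue_name
            res.seqid = gemmi.SeqId(a.residue_seq, a.insertion_code or " ")
            ch.add_residue(res)
        res = ch[-1]
        at = gemmi.Atom()
        at.name = a.atom_name
        at.element = gemmi.Element(a.element)
        at.pos = gemmi.Position(*a.xyz)
        at.occ = a.occupancy
        at.b_iso = a.b_iso
        at.serial = a.serial
        at.altloc = a.altloc or "\x00"
        res.add_atom(at)
    for chain_id in order:
        gm.add_chain(chains[chain_id])
    st.add_model(gm)
    st.setup_entities()
    return st


def write_structure(model: StructureModel, path, fmt: str = "auto") -> None:
    """Write the model as PDB or mmCIF; mmCIF additionally carries the
    refinement metadata tags read back by :func:`read_structure`."""
    path = Path(path)
    fmt = _detect_format(path, fmt) if fmt == "auto" else fmt
    st = model_to_gemmi(model)
    if fmt == "pdb":
        lines = []
        md = model.metadata
        if md.resolution is not None:
            lines.append(f"REMARK   2 RESOLUTION.    {md.resolution:.2f} "
                         f"ANGSTROMS.")
        if md.r_work is not None:
            lines.append(f"REMARK   3   R VALUE            (WORKING SET) : "
                         f"{md.r_work:.3f}")
        if md.r_free is not None:
            lines.append(f"REMARK   3   FREE R VALUE                     : "
                         f"{md.r_free:.3f}")
        if md.temperature is not None:
            lines.append(f"REMARK 200  TEMPERATURE           (KELVIN) : "
                         f"{md.temperature:.0f}")
        body = st.make_pdb_string()
        path.write_text("\n".join(lines) + ("\n" if lines else "") + body)
    else:
        doc = st.make_mmcif_document()
        blk = doc.sole_block()
        md = model.metadata
        if md.resolution is not None:
            blk.set_pair("_refine.ls_d_res_high", f"{md.resolution:.3f}")
        if md.r_work is not None:
            blk.set_pair("_refine.ls_R_factor_R_work", f"{md.r_work:.4f}")
        if md.r_free is not None:
            blk.set_pair("_refine.ls_R_factor_R_free", f"{md.r_free:.4f}")
        if md.temperature is not None:
            blk.set_pair("_diffrn.ambient_temp", f"{md.temperature:.1f}")
        doc.write_file(str(path))


def write_bdamage_coordinates(model: StructureModel, bdamage, path) -> None:
    """Write a PDB file with each atom's B_Damage in the B-factor column.

    Lets any molecular viewer colour the structure by B_Damage.  Values are
    rounded to 2 decimals (the column width); values above 999.99 are
    clamped with a warning.  Hydrogens and occupancy-zero atoms, which have
    no B_Damage, are written with 0.00.
    """
    per_atom = bdamage.per_atom
    missing = [a.serial for a in model.included_atoms()
               if a.serial not in per_atom]
    if missing:
        raise ValueError(
            f"atoms missing from B_Damage result: serials {missing}")
    st = model_to_gemmi(model)
    for chain in st[0]:
        for res in chain:
            for at in res:
                entry = per_atom.get(at.serial)
                value = entry.bdamage if entry is not None else 0.0
                if value > 999.99:
                    logger.warning("B_Damage %.2f for atom %d clamped to "
                                   "999.99 (PDB column width)", value,
                                   at.serial)
                    value = 999.99
                at.b_iso = value
    st.write_pdb(str(path))


def atoms_to_dataframe(model: StructureModel) -> pd.DataFrame:
    """Per-atom records as a DataFrame (CSV-export friendly)."""
    rows = [{
        "serial": a.serial, "atom_name": a.atom_name, "element": a.element,
        "residue_name": a.residue_name, "chain_id": a.chain_id,
        "residue_seq": a.residue_seq, "altloc": a.altloc,
        "x": a.xyz[0], "y": a.xyz[1], "z": a.xyz[2],
        "occupancy": a.occupancy, "b_iso": a.b_iso,
        "is_hydrogen": a.is_hydrogen,
    } for a in model.atoms]
    return pd.DataFrame(rows)
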