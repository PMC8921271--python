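"""Per-atom B_Damage: B-factors normalised by packing-density environment.

B-factor values inside a structure cannot be compared directly: buried atoms
are held rigid by their neighbours while surface atoms are mobile.  B_Damage
removes this by ranking atoms by packing density and dividing each atom's
B-factor by the mean B-factor of the atoms whose packing density is most
similar — a contiguous sliding window in the ranking.  An atom whose
B-factor is high *for its environment* (a candidate damage site) gets
B_Damage well above 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .lattice import PackingDensityResult
from .model import StructureModel

DEFAULT_WINDOW_FRACTION = 0.02
DEFAULT_MIN_WINDOW = 11


@dataclass(frozen=True)
class AtomBDamage:
    """B_Damage of one atom, with the window that defined its environment."""

    packing_density: int
    window_serials: tuple
    bdamage: float


@dataclass
class BDamageResult:
    """serial -> :class:`AtomBDamage`, plus the all-atom median."""

    per_atom: dict
    median_all: float
    window_size: int

    @property
    def values(self) -> np.ndarray:
        return np.array([e.bdamage for e in self.per_atom.values()])

    def as_dataframe(self, model: StructureModel) -> pd.DataFrame:
        rows = []
        for a in model.included_atoms():
            e = self.per_atom.get(a.serial)
            if e is None:
                continue
            rows.append({
                "serial": a.serial, "atom_name": a.atom_name,
                "residue_name": a.residue_name, "chain_id": a.chain_id,
                "residue_seq": a.residue_seq,
                "packing_density": e.packing_density,
                "window_size": len(e.window_serials),
                "b_iso": a.b_iso, "bdamage": e.bdamage,
            })
        return pd.DataFrame(rows)


def compute_bdamage(model: StructureModel,
                    pd_result: PackingDensityResult,
                    window_fraction: float = DEFAULT_WINDOW_FRACTION,
                    min_window: int = DEFAULT_MIN_WINDOW) -> BDamageResult:
    """Compute B_Damage for every non-hydrogen, occupancy>0 atom.

    Atoms are sorted by (packing density, serial); atom j's "similar
    environment" is the window of ``w = max(min_window, round(
    window_fraction * N))`` consecutive atoms centred on j's rank, shifted
    inward at the ends so it always holds exactly ``w`` members (``w``
    capped at N).  B_Damage_j = B_j / mean(B over the window, j included).
    """
    atoms = [a for a in model.included_atoms()
             if a.serial in pd_result.counts]
    missing = [a.serial for a in model.included_atoms()
               if a.serial not in pd_result.counts]
    if missing:
        raise ValueError(
            f"packing density missing for serials {missing[:10]}")
    n = len(atoms)
    if n < min_window:
        raise ValueError(
            f"structure has only {n} included atoms; at least "
            f"{min_window} are needed for the sliding-window environment")
    bad = [a.serial for a in atoms if a.b_iso <= 0]
    if bad:
        raise ValueError(
            f"non-positive B-factors for serials {bad[:10]}; "
            f"B_Damage is undefined")

    order = sorted(atoms, key=lambda a: (pd_result.counts[a.serial],
                                         a.serial))
    b = np.array([a.b_iso for a in order])
    w = min(n, max(min_window, int(round(window_fraction * n))))

    csum = np.concatenate([[0.0], np.cumsum(b)])
    per_atom = {}
    for i, a in enumerate(order):
        start = min(max(i - (w - 1) // 2, 0), n - w)
        mean_b = (csum[start + w] - csum[start]) / w
        per_atom[a.serial] = AtomBDamage(
            packing_density=pd_result.counts[a.serial],
            window_serials=tuple(x.serial for x in order[start:start + w]),
            bdamage=a.b_iso / mean_b,
        )
    values = np.array([per_atom[a.serial].bdamage for a in order])
    return BDamageResult(per_atom=per_atom,
                         median_all=float(np.median(values)),
                         window_size=w)


def summarise_distribution(bd: BDamageResult) -> dict:
    """Descriptive statistics of the per-structure B_Damage distribution."""
    v = bd.values
    if v.size == 0:
        raise ValueError("empty B_Damage result")
    sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
    return {
        "n": int(v.size),
        "median": float(np.median(v)),
        "mean": float(np.mean(v)),
        "sd": sd,
        "skew": float(stats.skew(v)) if v.size > 2 and sd > 0 else 0.0,
    }
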