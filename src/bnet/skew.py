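"""The B_net metric: a per-structure summary of specific radiation damage.

Aspartate/glutamate decarboxylation is among the earliest-onset chemical
changes X-rays induce in cryo-cooled protein crystals.  When a damaged,
partly decarboxylated side chain is refined at full occupancy, its carboxyl
oxygens' B-factors — and hence their B_Damage values — inflate.  B_net
captures this as an asymmetry statistic: fit a Gaussian kernel density
estimate to the B_Damage values of the Asp/Glu side-chain carboxyl oxygens,
split its area at the median B_Damage of *all* atoms in the structure, and
report the ratio

    B_net = (area above the median) / (area below the median).

An undamaged structure gives B_net near 1; damage pushes it up.  The same
construction applied to Asn/Gln side-chain amide oxygens — chemically
similar but not subject to decarboxylation — serves as a negative control.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.stats import gaussian_kde

from .bdamage import BDamageResult, compute_bdamage
from .lattice import expand_lattice, packing_density
from .model import StructureModel

logger = logging.getLogger(__name__)

DEFAULT_MIN_OXYGENS = 20       # eligibility floor for Asp/Glu selections
DEFAULT_MIN_CONTROL = 10       # floor for the Asn/Gln control variant
KDE_POINTS = 100               # grid points -> 99 trapeziums
GRID_PADDING_BANDWIDTHS = 3.0  # grid spans [min-3h, max+3h]

# selection tables: residue code -> side-chain oxygen atom names
_ASP_GLU = {
    "ASP": ("OD1", "OD2"), "DAS": ("OD1", "OD2"),   # DAS = D-aspartate
    "GLU": ("OE1", "OE2"), "DGL": ("OE1", "OE2"),   # DGL = D-glutamate
}
_ASN_GLN = {"ASN": ("OD1",), "GLN": ("OE1",)}


@dataclass
class CarboxylSelection:
    """Serials of the side-chain oxygen atoms a B_net variant is built on."""

    serials: list
    selection_mode: str   # "asp_glu" or "asn_gln"

    @property
    def count(self) -> int:
        return len(self.serials)


@dataclass
class BnetResult:
    """B_net together with everything needed to audit it."""

    bnet: float
    area_below: float          # A in B_net = B / A
    area_above: float          # B
    median_all: float
    kde_grid: np.ndarray       # 100 abscissae
    kde_density: np.ndarray    # matching ordinates
    bandwidth: float           # Scott bandwidth actually used
    n_selected: int
    selection_mode: str
    warnings: list = field(default_factory=list)

    @property
    def bnet_3sf(self) -> float:
        if not math.isfinite(self.bnet) or self.bnet == 0:
            return self.bnet
        return float(f"{self.bnet:.3g}")


def select_oxygens(model: StructureModel,
                   mode: str = "asp_glu") -> CarboxylSelection:
    """Pick the side-chain oxygen atoms of the requested residue class.

    ``asp_glu``: OD1/OD2 of Asp (and D-Asp), OE1/OE2 of Glu (and D-Glu).
    ``asn_gln``: the single amide oxygen OD1 of Asn / OE1 of Gln.
    Zero-occupancy atoms are excluded; altloc copies are each selected.
    """
    try:
        table = {"asp_glu": _ASP_GLU, "asn_gln": _ASN_GLN}[mode]
    except KeyError:
        raise ValueError(f"unknown selection mode {mode!r}")
    serials = [a.serial for a in model.atoms
               if not a.is_hydrogen and a.occupancy > 0.0
               and a.atom_name in table.get(a.residue_name, ())]
    return CarboxylSelection(serials=serials, selection_mode=mode)


def scott_bandwidth(values: np.ndarray) -> float:
    """1-D Scott rule: sample standard deviation times n^(-1/5)."""
    return float(np.std(values, ddof=1) * len(values) ** (-1.0 / 5.0))


def compute_bnet(bd: BDamageResult, sel: CarboxylSelection,
                 min_oxygens: int = DEFAULT_MIN_OXYGENS) -> BnetResult:
    """B_net from a structure's B_Damage values and an oxygen selection.

    The Gaussian KDE (Scott bandwidth h = sigma-hat * n^(-1/5)) is evaluated
    on 100 equally spaced points spanning [min - 3h, max + 3h] of the
    selected values, giving 99 trapeziums.  The trapezium into which the
    all-atom median B_Damage falls counts towards the below-median area A;
    B_net = B / A with B the remaining area.
    """
    if sel.count < min_oxygens:
        raise ValueError(
            f"structure ineligible: {sel.count} selected "
            f"{sel.selection_mode} oxygens, need >= {min_oxygens}")
    missing = [s for s in sel.serials if s not in bd.per_atom]
    if missing:
        raise ValueError(
            f"selected serials without B_Damage values: {missing[:10]}")
    values = np.array([bd.per_atom[s].bdamage for s in sel.serials])
    if np.std(values, ddof=1) == 0.0:
        raise ValueError(
            f"degenerate B_Damage distribution: all {sel.count} selected "
            f"values equal {values[0]}; the KDE bandwidth would be zero")

    h = scott_bandwidth(values)
    grid = np.linspace(values.min() - GRID_PADDING_BANDWIDTHS * h,
                       values.max() + GRID_PADDING_BANDWIDTHS * h,
                       KDE_POINTS)
    kde = gaussian_kde(values)  # scipy's default is the Scott factor
    density = kde(grid)

    dx = grid[1] - grid[0]
    trapezia = 0.5 * (density[:-1] + density[1:]) * dx
    total = float(trapezia.sum())

    median = bd.median_all
    warnings: list = []
    if median < grid[0]:
        area_below, area_above = 0.0, total
    elif median >= grid[-1]:
        area_below, area_above = total, 0.0
    else:
        k = int(np.searchsorted(grid, median, side="right")) - 1
        area_below = float(trapezia[:k + 1].sum())
        area_above = float(trapezia[k + 1:].sum())

    if area_below == 0.0:
        warnings.append(
            "below-median area is zero (all-atom median lies left of the "
            "KDE grid); B_net reported as +inf")
        bnet_value = math.inf
    else:
        bnet_value = area_above / area_below
    if area_above == 0.0 and area_below > 0.0:
        warnings.append(
            "above-median area is zero (all-atom median lies right of the "
            "KDE grid); B_net reported as 0")
    for w in warnings:
        logger.warning("%s", w)

    return BnetResult(bnet=bnet_value, area_below=area_below,
                      area_above=area_above, median_all=median,
                      kde_grid=grid, kde_density=density, bandwidth=h,
                      n_selected=sel.count,
                      selection_mode=sel.selection_mode, warnings=warnings)


def compute_bnet_for_structure(
        model: StructureModel,
        radius: float = 7.0,
        window_fraction: float = 0.02,
        min_window: int = 11,
        min_oxygens: int = DEFAULT_MIN_OXYGENS,
        min_control: int = DEFAULT_MIN_CONTROL,
        bd: Optional[BDamageResult] = None,
) -> tuple:
    """Full single-structure pipeline.

    Runs lattice expansion -> packing density -> B_Damage -> B_net for the
    Asp/Glu selection, plus the Asn/Gln control variant when at least
    ``min_control`` amide oxygens are present (otherwise the control is
    absent, not an error).  Returns ``(asp_glu_result, asn_gln_result_or_
    None, bdamage_result)``.
    """
    if bd is None:
        try:
            ctx = expand_lattice(model, radius=radius)
            pd_result = packing_density(ctx, radius=radius)
        except Exception as exc:
            raise RuntimeError(f"lattice-expansion stage failed: {exc}") from exc
        try:
            bd = compute_bdamage(model, pd_result,
                                 window_fraction=window_fraction,
                                 min_window=min_window)
        except Exception as exc:
            raise RuntimeError(f"B_Damage stage failed: {exc}") from exc

    sel = select_oxygens(model, "asp_glu")
    try:
        result = compute_bnet(bd, sel, min_oxygens=min_oxygens)
    except Exception as exc:
        raise RuntimeError(f"B_net stage failed: {exc}") from exc

    control = None
    sel_control = select_oxygens(model, "asn_gln")
    if sel_control.count >= min_control:
        try:
            control = compute_bnet(bd, sel_control,
                                   min_oxygens=min_control)
        except ValueError as exc:
            logger.warning("Asn/Gln control unavailable: %s", exc)
    else:
        logger.info("Asn/Gln control skipped: %d amide oxygens < %d",
                    sel_control.count, min_control)
    return result, control, bd
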