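"""Cohort-level screening: eligibility filters, resolution-windowed
B_net-percentiles, dose-series fits and covariate correlations.

B_net is a B-factor-derived quantity, so it is only meaningful for
structures whose B-factors can carry a damage signal: cryo-cooled
(80-120 K), refined with per-atom B-factors, resolution 3.5 A or better,
R_free <= 0.4, fully occupied Asp/Glu side chains, and at least 20 Asp/Glu
carboxyl oxygens to support the KDE.  Because B_net correlates with
resolution, cross-resolution comparison uses a percentile rank computed
within the window of the 1000 structures closest in resolution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .model import StructureModel
from .skew import compute_bnet_for_structure, select_oxygens

logger = logging.getLogger(__name__)

TEMPERATURE_RANGE = (80.0, 120.0)   # K
MAX_RESOLUTION = 3.5                # A, "3.5 A or better"
MAX_RFREE = 0.4
MIN_CARBOXYL_OXYGENS = 20
FLAT_B_SD = 1e-6                    # A^2; below this the B-field is flat
FULL_OCCUPANCY_TOL = 1e-3

BNET_FLAG_THRESHOLD = 3.0           # advisory: "merits further inspection"
PERCENTILE_FLAG_THRESHOLD = 0.95
DEFAULT_PERCENTILE_WINDOW = 1000

# residue codes that mark a nucleic-acid component in a polymer chain
_NUCLEOTIDES = frozenset({"A", "C", "G", "U", "I", "N",
                          "DA", "DC", "DG", "DT", "DU", "DI", "DN"})

EIGHT_COVARIATES = ("resolution", "r_work", "r_free", "temperature",
                    "molecular_mass", "n_carboxyl_oxygens",
                    "pct_asp_glu_residues", "bfactor_restraint_weight")


@dataclass
class EligibilityReport:
    """Per-criterion verdicts; ``None`` means the input lacked the data."""

    criteria: dict
    failure_reasons: list = field(default_factory=list)

    @property
    def overall(self) -> bool:
        return all(v is True for v in self.criteria.values())


def _asp_glu_full_occupancy(model: StructureModel) -> bool:
    """True when every Asp/Glu side-chain site sums to occupancy ~1 across
    its conformers."""
    sums: dict = {}
    for a in model.atoms:
        if a.residue_name in ("ASP", "DAS", "GLU", "DGL") and not a.is_hydrogen:
            key = (a.chain_id, a.residue_seq, a.insertion_code, a.atom_name)
            sums[key] = sums.get(key, 0.0) + a.occupancy
    if not sums:
        return True
    return all(s >= 1.0 - FULL_OCCUPANCY_TOL for s in sums.values())


def _per_atom_bfactors(model: StructureModel) -> bool:
    """Reject flat and per-residue B-factor fields (heuristic)."""
    b = np.array([a.b_iso for a in model.included_atoms()])
    if b.size == 0 or np.std(b) < FLAT_B_SD:
        return False
    per_res: dict = {}
    for a in model.included_atoms():
        per_res.setdefault(a.residue_key, []).append(a.b_iso)
    multi = [v for v in per_res.values() if len(v) > 1]
    if multi and all(np.ptp(v) < FLAT_B_SD for v in multi):
        return False   # constant within every residue: per-residue model
    return True


def check_eligibility(model: StructureModel,
                      min_oxygens: int = MIN_CARBOXYL_OXYGENS
                      ) -> EligibilityReport:
    """Evaluate every cohort filter; always returns a report, never raises.

    Boundary conventions: resolution <= 3.5 A, R_free <= 0.4, temperature
    within the closed range [80, 120] K, and >= 20 Asp/Glu side-chain
    oxygens all pass.
    """
    md = model.metadata
    sel = select_oxygens(model, "asp_glu")
    has_asp_glu = any(a.residue_name in ("ASP", "DAS", "GLU", "DGL")
                      for a in model.atoms)
    criteria = {
        "is_protein_no_nucleic": not any(
            a.residue_name in _NUCLEOTIDES for a in model.atoms),
        "temperature_in_80_120K": (
            None if md.temperature is None
            else TEMPERATURE_RANGE[0] <= md.temperature <= TEMPERATURE_RANGE[1]),
        "resolution_le_3p5": (None if md.resolution is None
                              else md.resolution <= MAX_RESOLUTION),
        "rfree_le_0p4": (None if md.r_free is None
                         else md.r_free <= MAX_RFREE),
        "per_atom_bfactors_not_flat": _per_atom_bfactors(model),
        "asp_glu_full_occupancy": _asp_glu_full_occupancy(model),
        "ge_20_carboxyl_oxygens": sel.count >= min_oxygens,
        "has_asp_glu": has_asp_glu,
    }
    reasons = []
    for name, verdict in criteria.items():
        if verdict is None:
            reasons.append(f"{name}: required metadata absent")
        elif verdict is False:
            reasons.append(name)
    return EligibilityReport(criteria=criteria, failure_reasons=reasons)


def bnet_percentile(table: pd.DataFrame,
                    window_size: int = DEFAULT_PERCENTILE_WINDOW
                    ) -> pd.DataFrame:
    """Add a ``bnet_percentile`` column ranking each structure among peers
    of similar resolution.

    For structure s: the ``window_size`` structures closest in resolution
    (distance ties all included) define a closed resolution range; the
    comparison set is every cohort structure inside that range; the
    percentile is the fraction of the comparison set with bnet <= bnet(s),
    so the top structure of its window scores exactly 1.
    """
    if len(table) < 2:
        raise ValueError("percentile ranking needs a cohort of >= 2 rows")
    if "bnet" not in table or "resolution" not in table:
        raise ValueError("cohort table must have 'bnet' and 'resolution'")
    window_size = min(window_size, len(table))
    out = table.copy()
    res = out["resolution"].to_numpy(dtype=float)
    bnet_vals = out["bnet"].to_numpy(dtype=float)
    percentiles = np.full(len(out), np.nan)
    for i in range(len(out)):
        if not np.isfinite(res[i]):
            logger.warning("row %s: resolution missing, percentile skipped",
                           out.index[i])
            continue
        dist = np.abs(res - res[i])
        valid = np.isfinite(dist)
        dsorted = np.sort(dist[valid])
        threshold = dsorted[min(window_size, valid.sum()) - 1]
        window = valid & (dist <= threshold)   # boundary ties all included
        lo, hi = res[window].min(), res[window].max()
        comparison = valid & (res >= lo) & (res <= hi)
        percentiles[i] = (np.sum(bnet_vals[comparison] <= bnet_vals[i])
                          / comparison.sum())
    out["bnet_percentile"] = percentiles
    return out


def structure_covariates(model: StructureModel) -> dict:
    """Metadata + composition columns for one cohort row."""
    md = model.metadata
    n_res = len({a.residue_key for a in model.atoms})
    n_asp_glu = len({a.residue_key for a in model.atoms
                     if a.residue_name in ("ASP", "DAS", "GLU", "DGL")})
    return {
        "resolution": md.resolution,
        "r_work": md.r_work,
        "r_free": md.r_free,
        "temperature": md.temperature,
        "molecular_mass": md.molecular_mass,
        "n_carboxyl_oxygens": select_oxygens(model, "asp_glu").count,
        "pct_asp_glu_residues": 100.0 * n_asp_glu / n_res if n_res else None,
        "deposition_year": md.deposition_year,
    }


def build_cohort_table(entries, radius: float = 7.0,
                       window_fraction: float = 0.02,
                       min_window: int = 11,
                       min_oxygens: int = MIN_CARBOXYL_OXYGENS,
                       skip_ineligible: bool = False) -> pd.DataFrame:
    """Run the single-structure pipeline over ``(id, model, extra)`` triples
    and assemble the per-structure metric table.

    ``extra`` supplies covariates not derivable from coordinates (dose,
    restraint weight, ...).  With ``skip_ineligible`` the eligibility
    filters are applied first and failing structures are dropped (their ids
    logged); otherwise eligibility is the caller's concern.
    """
    rows = []
    for structure_id, model, extra in entries:
        if skip_ineligible:
            report = check_eligibility(model, min_oxygens=min_oxygens)
            if not report.overall:
                logger.info("cohort: %s ineligible (%s)", structure_id,
                            "; ".join(report.failure_reasons))
                continue
        result, control, _ = compute_bnet_for_structure(
            model, radius=radius, window_fraction=window_fraction,
            min_window=min_window, min_oxygens=min_oxygens)
        row = {"structure_id": structure_id,
               "bnet": result.bnet,
               "bnet_asn_gln": control.bnet if control else None}
        row.update(structure_covariates(model))
        row.update(extra or {})
        rows.append(row)
    if not rows:
        raise ValueError("cohort table is empty")
    return pd.DataFrame(rows).set_index("structure_id")


@dataclass
class DoseSeriesFit:
    """Least-squares line through one damage series' (dose, B_net) points."""

    series_id: str
    gradient: float      # per MGy
    y_intercept: float
    r_squared: float
    n_points: int
    excluded_points: list = field(default_factory=list)


def fit_dose_series(points, series_id: str = "",
                    exclude_above_dose: Optional[float] = None
                    ) -> DoseSeriesFit:
    """Ordinary least squares of B_net on dose (MGy).

    ``exclude_above_dose`` drops high-dose points from the fit — the
    standard treatment when B_net plateaus once most damage-prone sites in
    the crystal have already reacted.
    """
    points = [(float(d), float(b)) for d, b in points]
    excluded = []
    if exclude_above_dose is not None:
        excluded = [p for p in points if p[0] > exclude_above_dose]
        points = [p for p in points if p[0] <= exclude_above_dose]
    if len(points) < 3:
        raise ValueError(
            f"dose series needs >= 3 points after exclusions, "
            f"got {len(points)}")
    doses = np.array([p[0] for p in points])
    values = np.array([p[1] for p in points])
    if np.ptp(doses) == 0:
        raise ValueError("all doses identical: degenerate design")
    fit = stats.linregress(doses, values)
    return DoseSeriesFit(
        series_id=series_id,
        gradient=float(fit.slope),
        y_intercept=float(fit.intercept),
        r_squared=float(fit.rvalue ** 2),
        n_points=len(points),
        excluded_points=[(d, b, f"dose > {exclude_above_dose} MGy")
                         for d, b in excluded],
    )


def summarise_fit_consistency(fits) -> dict:
    """Relative standard deviations (sample SD / |mean|) of the fitted
    gradients and intercepts across damage series."""
    if len(fits) < 2:
        raise ValueError("need >= 2 fits to summarise consistency")

    def rel_sd(values):
        values = np.asarray(values, dtype=float)
        sd = float(np.std(values, ddof=1))
        mean = float(np.mean(values))
        if mean == 0.0:
            return {"relative_sd": None, "absolute_sd": sd,
                    "zero_mean": True}
        return {"relative_sd": sd / abs(mean), "absolute_sd": sd,
                "zero_mean": False}

    return {
        "gradient": rel_sd([f.gradient for f in fits]),
        "y_intercept": rel_sd([f.y_intercept for f in fits]),
        "n_series": len(fits),
    }


def spearman_matrix(table: pd.DataFrame, target: str = "bnet",
                    covariates=EIGHT_COVARIATES) -> dict:
    """Spearman rank correlation of the target metric with each covariate.

    Missing values are dropped per covariate; a covariate constant across
    the cohort (rho undefined) is reported as None.
    """
    if target not in table:
        raise ValueError(f"target column {target!r} not in table")
    result = {}
    for cov in covariates:
        if cov not in table:
            result[cov] = None
            continue
        pair = table[[target, cov]].apply(
            pd.to_numeric, errors="coerce").dropna()
        pair = pair[np.isfinite(pair).all(axis=1)]
        if len(pair) < 3 or pair[cov].nunique() < 2 \
                or pair[target].nunique() < 2:
            result[cov] = None
            continue
        rho, _ = stats.spearmanr(pair[target], pair[cov])
        result[cov] = float(rho)
    return result


def flag_suspect(row) -> bool:
    """Advisory flag: B_net > 3.0 and/or B_net-percentile > 0.95 merit
    further inspection.  Never filters data; strict inequalities."""
    bnet_value = row["bnet"] if "bnet" in row else None
    if bnet_value is None or np.isnan(bnet_value):
        raise ValueError("flag_suspect requires a bnet value")
    pct = row.get("bnet_percentile") if hasattr(row, "get") else None
    flagged = bnet_value > BNET_FLAG_THRESHOLD
    if pct is not None and np.isfinite(pct):
        flagged = flagged or pct > PERCENTILE_FLAG_THRESHOLD
    return bool(flagged)
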