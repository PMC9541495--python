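"""Thermodynamic summaries: free-energy tables, tandem-phosphosite
cooperativity, fold enhancements and cross-technique concordance.

For a tandem (doubly phosphorylated) peptide whose two sites bind with
free energies dG_A and dG_B individually, additivity would predict
dG_tandem = dG_A + dG_B. The cooperativity term

    ddG = dG_tandem - (dG_A + dG_B)

classifies the interaction: ddG < -tol positively cooperative, |ddG| <= tol
additive, ddG > tol negatively cooperative (less than additive).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .binding import T_STANDARD, delta_g

__all__ = [
    "Affinity",
    "CoopSummary",
    "cooperativity",
    "fold_enhancement",
    "concordance_table",
    "delta_g_table",
]


@dataclass(frozen=True)
class Affinity:
    """A dissociation constant that may be only a lower bound (">value")."""

    kd: float  # molar
    lower_bound: bool = False

    def __str__(self):
        prefix = "> " if self.lower_bound else ""
        return f"{prefix}{self.kd:.3g} M"


@dataclass(frozen=True)
class CoopSummary:
    """Cooperativity of tandem-site binding relative to additivity."""

    dg_site_a: float       # kJ/mol
    dg_site_b: float
    dg_tandem: float
    ddg_coop: float        # dG_tandem - (dG_A + dG_B)
    classification: str
    tol: float


def cooperativity(dg_a: float, dg_b: float, dg_ab: float, tol: float = 1.0) -> CoopSummary:
    """Classify tandem binding as positively cooperative, additive or
    negatively cooperative (less than additive).

    All energies in kJ/mol at the same temperature; *tol* (kJ/mol, default
    1.0, about the fit-error scale of typical ITC energies) is the additivity
    band. Symmetric in the two single sites.
    """
    ddg = dg_ab - (dg_a + dg_b)
    if ddg < -tol:
        cls = "positively cooperative"
    elif ddg > tol:
        cls = "negatively cooperative (less than additive)"
    else:
        cls = "additive"
    return CoopSummary(dg_site_a=dg_a, dg_site_b=dg_b, dg_tandem=dg_ab,
                       ddg_coop=ddg, classification=cls, tol=tol)


def fold_enhancement(kd_reference: float, kd_enhanced: float, sig_figs: int | None = None):
    """Affinity fold-enhancement Kd_reference / Kd_enhanced.

    Optionally rounded to *sig_figs* significant figures (e.g. a ratio of
    204 reported as "~200-fold" at one significant figure).
    """
    if kd_reference <= 0 or kd_enhanced <= 0:
        raise ValueError("dissociation constants must be positive")
    ratio = kd_reference / kd_enhanced
    if sig_figs is None:
        return ratio
    if ratio == 0:
        return 0.0
    exponent = math.floor(math.log10(abs(ratio)))
    return round(ratio, -exponent + sig_figs - 1)


def concordance_table(fits: dict) -> pd.DataFrame:
    """Cross-technique Kd concordance.

    *fits* maps peptide id -> {technique: Affinity or float (molar)}. The
    output has one row per peptide with each technique's Kd, lower-bound
    flags rendered as ``"> value"``, and the maximum pairwise
    fold-difference among available point estimates (NaN with fewer than
    two point estimates). Differences are reported, not judged.
    """
    rows = []
    techniques = sorted({t for v in fits.values() for t in v})
    for pid, by_tech in fits.items():
        row = {"peptide_id": pid}
        points = []
        for tech in techniques:
            aff = by_tech.get(tech)
            if aff is None:
                row[f"Kd_{tech}"] = None
                continue
            if not isinstance(aff, Affinity):
                aff = Affinity(float(aff))
            row[f"Kd_{tech}"] = str(aff)
            if not aff.lower_bound:
                points.append(aff.kd)
        if len(points) >= 2:
            row["max_fold_difference"] = max(points) / min(points)
        else:
            row["max_fold_difference"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def delta_g_table(kd_map: dict, T: float = T_STANDARD) -> pd.DataFrame:
    """Free-energy table ΔG = RT ln(Kd) in kJ/mol, one decimal place.

    *kd_map* maps label -> Kd in molar (or :class:`Affinity`); lower-bound
    Kds propagate as lower-bound ΔG (binding at least this weak).
    """
    rows = []
    for label, aff in kd_map.items():
        if not isinstance(aff, Affinity):
            aff = Affinity(float(aff))
        dg = round(delta_g(aff.kd, T), 1)
        rows.append({
            "label": label,
            "Kd": str(aff),
            "dG_kJ_mol": dg,
            "bound": "lower" if aff.lower_bound else "",
        })
    return pd.DataFrame(rows)
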