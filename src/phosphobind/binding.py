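"""Equilibrium and kinetic binding models shared by the fitting pipelines
and the synthetic-data generators.

All concentrations are molar; protein concentrations follow the 14-3-3
*monomer* convention throughout (each protomer carries one amphipathic
groove, so the monomer concentration equals the binding-site concentration
for a fully dimeric protein). Unit conversions happen only at I/O.

The module provides

* the tight-binding quadratic for a 1:1 equilibrium with ligand depletion,
* a coupled monomer/dimer mass-action solver (the brute-force oracle for
  the quadratic, and the forward model for bivalent/avidity scenarios),
* 1:1 Langmuir association/dissociation kinetics and the steady-state
  binding hyperbola used for SPR,
* thermodynamic conversions ΔG = RT·ln(Kd) and −TΔS = ΔG − ΔH.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "R_GAS",
    "T_STANDARD",
    "CoupledMechanism",
    "MassActionError",
    "bound_ligand_quadratic",
    "fraction_bound_curve",
    "solve_mass_action",
    "langmuir_association",
    "langmuir_dissociation",
    "steady_state_response",
    "delta_g",
    "entropic_term",
]

#: Gas constant, J/(mol*K)
R_GAS = 8.314
#: Default assay temperature (25 C), kelvin
T_STANDARD = 298.15


class MassActionError(RuntimeError):
    """Raised when the coupled mass-action solver fails its residual check."""


def bound_ligand_quadratic(K, X, FL):
    """Bound-tracer concentration for a 1:1 equilibrium with depletion.

    Solves ``L + X <-> LX`` exactly for the complex concentration given the
    dissociation constant *K*, total binding-site concentration *X* and
    total fluorescent-ligand (tracer) concentration *FL*:

        y = ((K + X + FL) - sqrt((K + X + FL)^2 - 4*X*FL)) / 2

    evaluated in the numerically stable form ``2*X*FL / (b + sqrt(b^2 -
    4*X*FL))`` to avoid cancellation when binding is weak.

    Parameters
    ----------
    K : float
        Dissociation constant (M), ``K >= 0``.
    X : float or array_like
        Total binding-site concentration (M, monomer convention).
    FL : float
        Total tracer concentration (M), ``FL > 0``.

    Returns
    -------
    float or ndarray
        Complex concentration, always within ``[0, min(X, FL)]``.
    """
    K = float(K)
    FL = float(FL)
    X = np.asarray(X, dtype=float)
    if K < 0:
        raise ValueError(f"dissociation constant must be >= 0, got {K}")
    if FL <= 0:
        raise ValueError(f"tracer concentration must be > 0, got {FL}")
    if np.any(X < 0):
        raise ValueError("binding-site concentrations must be >= 0")
    b = K + X + FL
    disc = b * b - 4.0 * X * FL
    if np.any(disc < -1e-12 * b * b):
        raise MassActionError("negative discriminant in tight-binding quadratic")
    disc = np.maximum(disc, 0.0)
    y = 2.0 * X * FL / (b + np.sqrt(disc))
    if y.ndim == 0:
        return float(y)
    return y


def fraction_bound_curve(K, FL, X_series):
    """Fraction of tracer bound along a titration of binding sites.

    Returns ``bound_ligand_quadratic(K, X, FL) / FL`` for each concentration
    in *X_series*; monotone non-decreasing in X and -> 1 as X -> infinity.
    """
    X = np.asarray(X_series, dtype=float)
    return bound_ligand_quadratic(K, X, FL) / float(FL)


@dataclass(frozen=True)
class CoupledMechanism:
    """Coupled monomer/dimer binding mechanism for the mass-action solver.

    Parameters
    ----------
    kdim : float
        Monomer-monomer dimerization dissociation constant [M]^2/[D] (M).
        ``0`` means fully dimeric, ``inf`` means fully monomeric.
    kd_site : float
        Intrinsic per-groove, per-phosphosite dissociation constant (M).
    alpha_bridge : float or None
        Effective molarity (M) for intramolecular engagement of the second
        phosphosite of an already-bound bivalent peptide; the intramolecular
        step then has the dimensionless equilibrium ``alpha_bridge/kd_site``.
        Only meaningful for ``valency == 2``.
    valency : int
        Number of phosphosites per peptide (1 or 2).
    """

    kdim: float
    kd_site: float
    alpha_bridge: float | None = None
    valency: int = 1

    def __post_init__(self):
        if self.kdim < 0:
            raise ValueError("kdim must be >= 0")
        if self.kd_site <= 0:
            raise ValueError("kd_site must be > 0")
        if self.valency not in (1, 2):
            raise ValueError("valency must be 1 or 2")
        if self.valency == 2 and (self.alpha_bridge is None or self.alpha_bridge <= 0):
            raise ValueError("alpha_bridge must be positive for valency 2")


def _species_at_free_ligand(mech: CoupledMechanism, monomer_total: float, l: float):
    """Species concentrations given free-ligand concentration *l*.

    Monomer conservation is closed-form (quadratic in free monomer), so only
    the ligand conservation needs an outer root find.
    """
    s = mech.valency
    k = mech.kd_site
    sl = s * l / k
    bridge = 2.0 * mech.alpha_bridge * l / (k * k) if s == 2 else 0.0
    phi_m = 1.0 + sl                       # monomer binding partition
    phi_d = (1.0 + sl) ** 2 + bridge       # dimer (two grooves) partition

    if mech.kdim == 0.0:
        m = 0.0
        d = monomer_total / (2.0 * phi_d)
    elif math.isinf(mech.kdim):
        m = monomer_total / phi_m
        d = 0.0
    else:
        # (2 phi_d / kdim) m^2 + phi_m m - M_tot = 0, stable positive root
        a = 2.0 * phi_d / mech.kdim
        m = 2.0 * monomer_total / (phi_m + math.sqrt(phi_m * phi_m + 4.0 * a * monomer_total))
        d = m * m / mech.kdim

    ml = s * m * l / k
    dl = 2.0 * d * sl            # one peptide dangling from one groove
    dl2 = d * sl * sl            # two peptides, one per groove
    dlb = 2.0 * d * mech.alpha_bridge * l / (k * k) if s == 2 else 0.0
    return {"M": m, "D": d, "L": l, "ML": ml, "DL": dl, "DL2": dl2, "DLb": dlb}


def _bound_peptide(sp):
    return sp["ML"] + sp["DL"] + 2.0 * sp["DL2"] + sp["DLb"]


def solve_mass_action(mech: CoupledMechanism, monomer_total: float, peptide_total: float):
    """Solve the coupled monomer/dimer/peptide equilibrium exactly.

    Species: free monomer M, free dimer D, free peptide L, monomer-peptide
    ML, dimer with one peptide in one groove DL, dimer with a peptide in
    each groove DL2, and (valency 2) the bridged complex DLb where one
    peptide spans both grooves of a dimer.

    Returns a dict with all species concentrations plus ``bound_ligand``
    (total peptide in complexes) and ``bridged_fraction`` (fraction of
    bound peptide that is bridged). Conservation residuals are verified to
    ``1e-10 x totals``; violation raises :class:`MassActionError`.
    """
    if monomer_total < 0 or peptide_total < 0:
        raise ValueError("totals must be >= 0")
    if peptide_total == 0.0:
        sp = _species_at_free_ligand(mech, monomer_total, 0.0)
    else:
        def g(l):
            sp = _species_at_free_ligand(mech, monomer_total, l)
            return peptide_total - l - _bound_peptide(sp)

        lo = peptide_total * 1e-16
        if g(lo) <= 0.0:
            l_free = lo
        else:
            l_free = brentq(g, lo, peptide_total, xtol=1e-300, rtol=8.9e-16, maxiter=200)
        sp = _species_at_free_ligand(mech, monomer_total, l_free)

    m_res = abs(monomer_total - (sp["M"] + sp["ML"] + 2.0 * (sp["D"] + sp["DL"] + sp["DL2"] + sp["DLb"])))
    l_res = abs(peptide_total - (sp["L"] + _bound_peptide(sp)))
    tol = 1e-10 * max(monomer_total, peptide_total, 1e-300)
    if m_res > tol or l_res > tol:
        raise MassActionError(
            f"conservation residuals exceed tolerance: monomer {m_res:.3e}, peptide {l_res:.3e}"
        )
    bound = _bound_peptide(sp)
    sp["bound_ligand"] = bound
    sp["bridged_fraction"] = sp["DLb"] / bound if bound > 0 else 0.0
    return sp


def langmuir_association(t, kon, koff, C, Rmax):
    """1:1 Langmuir association-phase response.

    R(t) = Req * (1 - exp(-(kon*C + koff)*t)), Req = Rmax*C/(C + koff/kon).
    """
    t = np.asarray(t, dtype=float)
    kobs = kon * C + koff
    req = Rmax * C / (C + koff / kon)
    return req * (1.0 - np.exp(-kobs * t))


def langmuir_dissociation(t, koff, R0):
    """Dissociation-phase response R(t) = R0*exp(-koff*t), t from injection end."""
    t = np.asarray(t, dtype=float)
    return R0 * np.exp(-koff * t)


def steady_state_response(C, Kd, Rmax):
    """Steady-state (end-of-injection) binding hyperbola Req = Rmax*C/(Kd + C)."""
    C = np.asarray(C, dtype=float)
    return Rmax * C / (Kd + C)


def delta_g(Kd, T=T_STANDARD):
    """Standard binding free energy ΔG = RT·ln(Kd), in kJ/mol.

    *Kd* is in molar (so Kd = 1 M gives the standard-state reference 0).
    """
    Kd = np.asarray(Kd, dtype=float)
    if np.any(Kd <= 0):
        raise ValueError("Kd must be > 0 for a free-energy calculation")
    out = R_GAS * T * np.log(Kd) / 1000.0
    if out.ndim == 0:
        return float(out)
    return out


def entropic_term(delta_g_val, delta_h):
    """Entropic contribution −TΔS = ΔG − ΔH (both in kJ/mol at the same T)."""
    return delta_g_val - delta_h
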