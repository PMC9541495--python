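"""Synthetic instrument data with known ground truth.

Three generators emulate the assays used to characterize 14-3-3 binding to
phosphorylated hDMX/hDM2 peptides:

* a direct FA titration — fixed 50 nM FAM-labelled tracer, half-fold serial
  dilution of 14-3-3 (monomer concentration), triplicate wells; the
  generator composes the true anisotropy from the binding model and inverts
  the intensity equations to emit raw parallel/perpendicular channels;
* an ITC titration of peptide into protein (one-site forward model with
  dilution bookkeeping; the bivalent variant halves the site concentration,
  one peptide spanning both protomers of a dimer);
* multicycle SPR sensorgrams from the 1:1 Langmuir model, 11-point dilution
  from 10x Kd, 1 min association / 4 min dissociation.

Noise is additive Gaussian, independent per channel/injection/timepoint
(fractional for FA channels, fraction-of-largest-heat for ITC, absolute RU
for SPR), seeded for exact replay.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import warnings

import numpy as np
import pandas as pd

from .binding import (
    CoupledMechanism,
    fraction_bound_curve,
    langmuir_association,
    langmuir_dissociation,
    solve_mass_action,
)
from .itc import ITCExperiment, itc_forward
from .spr import Sensorgram

__all__ = [
    "SingleSite",
    "TwoEvent",
    "FAPlateDesign",
    "ITCDesign",
    "SPRDesign",
    "gen_fa_titration",
    "gen_itc",
    "gen_spr",
]


@dataclass(frozen=True)
class SingleSite:
    """Single 1:1 binding event with dissociation constant *kd* (M)."""

    kd: float


@dataclass(frozen=True)
class TwoEvent:
    """Two sequential binding events, kd1 < kd2 (M)."""

    kd1: float
    kd2: float

    def __post_init__(self):
        if not self.kd1 < self.kd2:
            raise ValueError("two-event mechanism requires kd1 < kd2")


@dataclass(frozen=True)
class FAPlateDesign:
    """Plate layout and optics for a direct FA titration.

    Anisotropy plateaus: ``r_free`` for free tracer, ``r_bound_event1``
    after the first binding event, ``r_bound_event2`` after the second
    (two-event curves only). ``noise_sd`` is the fractional Gaussian noise
    applied independently to each channel of each well.
    """

    tracer_conc: float = 50e-9
    top_conc: float = 500e-6
    dilution_factor: float = 2.0
    n_points: int = 24
    replicates: int = 3
    G: float = 1.0
    lam: float = 1.0
    r_free: float = 0.06
    r_bound_event1: float = 0.24
    r_bound_event2: float = 0.34
    intensity_scale: float = 1e5
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.tracer_conc <= 0 or self.top_conc <= 0:
            raise ValueError("concentrations must be positive")
        if self.n_points < 6:
            raise ValueError("need at least 6 titration points")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def concentrations(self):
        """Serial-dilution concentrations, ascending (M)."""
        c = self.top_conc / self.dilution_factor ** np.arange(self.n_points)
        return c[::-1].copy()


def _true_anisotropy(design: FAPlateDesign, mechanism, conc):
    """Ground-truth anisotropy and total fraction bound at each concentration."""
    FL = design.tracer_conc
    if isinstance(mechanism, SingleSite):
        fb1 = fraction_bound_curve(mechanism.kd, FL, conc)
        r = design.r_free + (design.r_bound_event1 - design.r_free) * fb1
        return r, fb1
    if isinstance(mechanism, TwoEvent):
        fb1 = fraction_bound_curve(mechanism.kd1, FL, conc)
        fb2 = fraction_bound_curve(mechanism.kd2, FL, conc)
        r = (design.r_free
             + (design.r_bound_event1 - design.r_free) * fb1
             + (design.r_bound_event2 - design.r_bound_event1) * fb2)
        return r, fb1
    if isinstance(mechanism, CoupledMechanism):
        fb = np.array([
            solve_mass_action(mechanism, c, FL)["bound_ligand"] / FL for c in conc
        ])
        r = design.r_free + (design.r_bound_event1 - design.r_free) * fb
        return r, fb
    raise TypeError(f"unsupported mechanism {mechanism!r}")


def gen_fa_titration(design: FAPlateDesign, mechanism) -> pd.DataFrame:
    """Generate a raw FA plate table (per-well S and P channels).

    The true anisotropy r(c) is composed from the binding mechanism and the
    design plateaus, then inverted to channels at constant total intensity
    (lambda = 1) or intensity interpolated by fraction bound (lambda != 1):

        S = I*(1 + 2r)/3,  P = I*(1 - r)/(3G)

    so that I = 2*P*G + S and r = (S - P*G)/I hold exactly before noise.

    Returns a DataFrame with columns ``concentration_M``, ``replicate``,
    ``S``, ``P``.
    """
    rng = np.random.default_rng(design.seed)
    conc = design.concentrations()
    r, fb = _true_anisotropy(design, mechanism, conc)
    intensity = design.intensity_scale * (1.0 + (design.lam - 1.0) * fb)

    rows = []
    for rep in range(1, design.replicates + 1):
        S = intensity * (1.0 + 2.0 * r) / 3.0
        P = intensity * (1.0 - r) / (3.0 * design.G)
        if design.noise_sd > 0:
            S = S * (1.0 + rng.normal(0.0, design.noise_sd, size=S.shape))
            P = P * (1.0 + rng.normal(0.0, design.noise_sd, size=P.shape))
        rows.append(pd.DataFrame({
            "concentration_M": conc, "replicate": rep, "S": S, "P": P,
        }))
    return pd.concat(rows, ignore_index=True)


@dataclass(frozen=True)
class ITCDesign:
    """ITC titration design with ground-truth parameters.

    Default geometry: 200 uL cell at 20 uM protein (monomer), 200 uM
    peptide syringe, 20 x 2 uL injections. ``mechanism='bivalent'`` halves
    the binding-site concentration (one peptide occupying both protomers of
    a dimer). ``heat_noise_sd`` is Gaussian noise as a fraction of the
    largest |heat|.
    """

    cell_volume: float = 200e-6
    cell_conc: float = 20e-6
    syringe_conc: float = 200e-6
    injection_volumes: tuple = tuple([2e-6] * 20)
    T: float = 298.15
    true_kd: float = 870e-9
    true_dh: float = -16.1         # kJ/mol
    mechanism: str = "monovalent"  # or "bivalent"
    heat_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.syringe_conc <= self.cell_conc:
            raise ValueError("syringe concentration must exceed cell concentration")
        if len(self.injection_volumes) < 10:
            raise ValueError("need at least 10 injections")
        if self.mechanism not in ("monovalent", "bivalent"):
            raise ValueError("mechanism must be 'monovalent' or 'bivalent'")

    def experiment(self, heats=None) -> ITCExperiment:
        return ITCExperiment(
            cell_volume=self.cell_volume, cell_conc=self.cell_conc,
            syringe_conc=self.syringe_conc,
            injection_volumes=np.asarray(self.injection_volumes),
            heats=heats, heat_unit="uJ", T=self.T,
        )


def gen_itc(design: ITCDesign) -> pd.DataFrame:
    """Generate an ITC injection table (columns injection, volume_L, heat,
    unit='uJ').

    Warns when the schedule does not carry the cumulative molar ratio past
    2 (under-saturating design).
    """
    rng = np.random.default_rng(design.seed)
    exp = design.experiment()
    site_factor = 0.5 if design.mechanism == "bivalent" else 1.0
    heats_j = itc_forward(design.true_kd, design.true_dh, site_factor, exp)
    if exp.final_molar_ratio() < 2.0 * site_factor:
        warnings.warn("syringe concentration too low to reach saturating molar ratio")
    heats_uj = heats_j * 1e6
    if design.heat_noise_sd > 0:
        scale = np.max(np.abs(heats_uj))
        heats_uj = heats_uj + rng.normal(0.0, design.heat_noise_sd * scale, size=heats_uj.shape)
    return pd.DataFrame({
        "injection": np.arange(1, len(heats_uj) + 1),
        "volume_L": np.asarray(design.injection_volumes),
        "heat": heats_uj,
        "unit": "uJ",
    })


@dataclass(frozen=True)
class SPRDesign:
    """Multicycle SPR design with ground-truth kinetics.

    ``conc_series`` defaults to an 11-point half-fold dilution from 10x the
    true Kd (= koff/kon). ``noise_sd`` is absolute Gaussian response noise
    in RU.
    """

    true_kon: float = 3.89e5      # 1/(M s)
    true_koff: float = 0.1208     # 1/s
    rmax: float = 100.0           # RU
    conc_series: tuple | None = None
    association_s: float = 60.0
    dissociation_s: float = 240.0
    sampling_hz: float = 2.5
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if min(self.true_kon, self.true_koff, self.rmax) <= 0:
            raise ValueError("kinetic parameters must be positive")

    def concentrations(self):
        if self.conc_series is not None:
            return np.asarray(self.conc_series, dtype=float)
        kd = self.true_koff / self.true_kon
        return 10.0 * kd / 2.0 ** np.arange(11)


def gen_spr(design: SPRDesign) -> list[Sensorgram]:
    """Generate one noiseless-model + noise sensorgram per concentration.

    Each cycle starts from baseline 0 (complete surface regeneration);
    association runs for ``association_s`` seconds, dissociation starts at
    the end-of-injection response.
    """
    rng = np.random.default_rng(design.seed)
    dt = 1.0 / design.sampling_hz
    t = np.arange(0.0, design.association_s + design.dissociation_s + dt / 2, dt)
    out = []
    for C in design.concentrations():
        assoc = t <= design.association_s
        resp = np.empty_like(t)
        resp[assoc] = langmuir_association(t[assoc], design.true_kon, design.true_koff,
                                           C, design.rmax)
        r_end = langmuir_association(design.association_s, design.true_kon,
                                     design.true_koff, C, design.rmax)
        resp[~assoc] = langmuir_dissociation(t[~assoc] - design.association_s,
                                             design.true_koff, r_end)
        if design.noise_sd > 0:
            resp = resp + rng.normal(0.0, design.noise_sd, size=resp.shape)
        out.append(Sensorgram(time=t, response=resp, conc=float(C),
                              t_inject_start=0.0, t_inject_end=design.association_s))
    return out
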