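"""One-set-of-sites ITC model: forward isotherm and least-squares fit.

The experiment titrates peptide (syringe) into protein (cell). Each
injection of volume dV into a cell of working volume V0 dilutes the cell
contents by (1 - dV/V0) and adds syringe material; the bound-complex
concentration after each injection follows the tight-binding quadratic
with binding-site concentration n*[cell protein]. The measured heat of
injection i uses the standard displaced-volume (mean-concentration)
correction

    q_i = Q_i - Q_{i-1} + (dV_i/V0) * (Q_i + Q_{i-1})/2,
    Q_i = dH * V0 * [bound]_i,

i.e. material expelled during the injection is assigned the mean of the
pre- and post-injection composition. Fitted parameters are Kd, dH and the
stoichiometry n (sites per cell molecule); ΔG = RT ln Kd and
−TΔS = ΔG − ΔH follow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np

from .binding import R_GAS, T_STANDARD, bound_ligand_quadratic, delta_g, entropic_term

__all__ = [
    "ITCExperiment",
    "ITCFit",
    "ReliabilityWarning",
    "itc_forward",
    "fit_itc",
    "OneSiteITCModel",
    "ITCResults",
]

_UNIT_TO_J = {"J": 1.0, "uJ": 1e-6, "ucal": 4.184e-6, "cal": 4.184}


class ReliabilityWarning(UserWarning):
    """c-value outside the window where Kd is well determined."""


@dataclass
class ITCExperiment:
    """Injection schedule and (optionally) measured heats.

    ``heats`` are per-injection heats in the unit named by ``heat_unit``
    (``'uJ'``, ``'ucal'``, ``'J'`` or ``'cal'``); internally everything is
    converted to joules.
    """

    cell_volume: float              # litres (working volume V0)
    cell_conc: float                # molar protein in cell
    syringe_conc: float             # molar peptide in syringe
    injection_volumes: np.ndarray   # litres, one per injection
    heats: np.ndarray | None = None
    heat_unit: str = "uJ"
    T: float = T_STANDARD

    def __post_init__(self):
        self.injection_volumes = np.asarray(self.injection_volumes, dtype=float)
        if self.heats is not None:
            self.heats = np.asarray(self.heats, dtype=float)
            if len(self.heats) != len(self.injection_volumes):
                raise ValueError("heats and injection_volumes must have equal length")
        if self.syringe_conc <= self.cell_conc:
            raise ValueError("syringe concentration must exceed cell concentration")
        if self.heat_unit not in _UNIT_TO_J:
            raise ValueError(f"unknown heat unit {self.heat_unit!r}")

    def heats_joules(self):
        return self.heats * _UNIT_TO_J[self.heat_unit]

    def final_molar_ratio(self):
        """Cumulative syringe/cell molar ratio after the last injection."""
        P = self.cell_conc
        L = 0.0
        for dV in self.injection_volumes:
            f = 1.0 - dV / self.cell_volume
            P *= f
            L = L * f + self.syringe_conc * dV / self.cell_volume
        return L / P


def itc_forward(kd: float, dh_kj: float, n: float, exp: ITCExperiment):
    """Predicted per-injection heats (joules) for the one-site model.

    Parameters are the dissociation constant *kd* (M), molar enthalpy
    *dh_kj* (kJ/mol of peptide bound) and stoichiometry *n* (sites per cell
    molecule).
    """
    V0 = exp.cell_volume
    dh = dh_kj * 1000.0  # J/mol
    P = exp.cell_conc
    L = 0.0
    Q_prev = 0.0
    heats = np.empty(len(exp.injection_volumes))
    for i, dV in enumerate(exp.injection_volumes):
        f = 1.0 - dV / V0
        P *= f
        L = L * f + exp.syringe_conc * dV / V0
        sites = n * P
        bound = bound_ligand_quadratic(kd, sites, L) if L > 0 else 0.0
        Q = dh * V0 * bound
        heats[i] = Q - Q_prev + (dV / V0) * (Q + Q_prev) / 2.0
        Q_prev = Q
    return heats


@dataclass
class ITCFit:
    """Fitted one-site ITC parameters with derived thermodynamics."""

    kd: float
    kd_stderr: float | None
    dh: float                 # kJ/mol
    dh_stderr: float | None
    n: float
    n_stderr: float | None
    dg: float                 # kJ/mol
    minus_tds: float          # kJ/mol; dg == dh + minus_tds by construction
    c_value: float
    residual_rms: float
    lmfit_result: object = field(repr=False, default=None)


def fit_itc(exp: ITCExperiment, *, discard_first: bool = False) -> ITCFit:
    """Least-squares fit of the one-set-of-sites model to injection heats.

    ``discard_first`` drops the first injection (common practice for the
    syringe-tip mixing anomaly). Emits :class:`ReliabilityWarning` when the
    c-value ``n*[cell]/Kd`` falls outside [1, 1000].
    """
    if exp.heats is None:
        raise ValueError("experiment carries no measured heats")
    if len(exp.injection_volumes) < 10:
        raise ValueError("need at least 10 injections for a reliable one-site fit")
    obs = exp.heats_joules()
    skip = 1 if discard_first else 0
    scale = np.max(np.abs(obs[skip:]))
    if scale == 0:
        raise ValueError("all heats are zero; nothing to fit")

    dh_guess = obs[skip] / (exp.cell_volume * exp.syringe_conc
                            * exp.injection_volumes[skip] / exp.cell_volume) / 1000.0
    # crude but adequate: assume the first retained injection binds fully

    def resid(params):
        kd = 10.0 ** params["log10_kd"].value
        model = itc_forward(kd, params["dh"].value, params["n"].value, exp)
        return (model[skip:] - obs[skip:]) / scale

    params = lmfit.Parameters()
    params.add("log10_kd", value=float(np.log10(exp.cell_conc / 10.0)), min=-15, max=0)
    params.add("dh", value=float(dh_guess) if np.isfinite(dh_guess) and dh_guess != 0 else -10.0)
    params.add("n", value=1.0, min=0.05, max=5.0)
    out = lmfit.minimize(resid, params, method="leastsq")
    if not out.success:
        raise RuntimeError(f"ITC fit failed to converge: {out.message}")

    log_kd = out.params["log10_kd"]
    kd = 10.0 ** log_kd.value
    kd_err = kd * np.log(10.0) * log_kd.stderr if log_kd.stderr is not None else None
    dh = out.params["dh"].value
    n = out.params["n"].value
    dg = delta_g(kd, exp.T)
    c = n * exp.cell_conc / kd
    if not 1.0 <= c <= 1000.0:
        warnings.warn(
            f"c-value {c:.3g} outside [1, 1000]; Kd is poorly determined", ReliabilityWarning
        )
    return ITCFit(
        kd=kd, kd_stderr=kd_err,
        dh=dh, dh_stderr=out.params["dh"].stderr,
        n=n, n_stderr=out.params["n"].stderr,
        dg=dg, minus_tds=entropic_term(dg, dh),
        c_value=c,
        residual_rms=float(np.sqrt(np.mean(out.residual ** 2)) * scale),
        lmfit_result=out,
    )


class OneSiteITCModel:
    """statsmodels-style wrapper around :func:`fit_itc`."""

    def __init__(self, experiment: ITCExperiment, *, discard_first: bool = False):
        self.experiment = experiment
        self.discard_first = discard_first

    @classmethod
    def from_dataframe(cls, df, *, cell_volume, cell_conc, syringe_conc,
                       T=T_STANDARD, discard_first=False):
        """Build from a table with columns ``volume_L``, ``heat`` and ``unit``."""
        unit = str(df["unit"].iloc[0]) if "unit" in df else "uJ"
        exp = ITCExperiment(
            cell_volume=cell_volume, cell_conc=cell_conc, syringe_conc=syringe_conc,
            injection_volumes=df["volume_L"].to_numpy(),
            heats=df["heat"].to_numpy(), heat_unit=unit, T=T,
        )
        return cls(exp, discard_first=discard_first)

    def predict(self, kd, dh, n):
        return itc_forward(kd, dh, n, self.experiment)

    def fit(self) -> "ITCResults":
        return ITCResults(self, fit_itc(self.experiment, discard_first=self.discard_first))


class ITCResults:
    """One-site ITC fit results: Kd, ΔH, n and the derived ΔG / −TΔS."""

    def __init__(self, model: OneSiteITCModel, fit: ITCFit):
        self.model = model
        self._fit = fit

    kd = property(lambda self: self._fit.kd)
    kd_stderr = property(lambda self: self._fit.kd_stderr)
    dh = property(lambda self: self._fit.dh)
    dh_stderr = property(lambda self: self._fit.dh_stderr)
    n = property(lambda self: self._fit.n)
    n_stderr = property(lambda self: self._fit.n_stderr)
    dg = property(lambda self: self._fit.dg)
    minus_tds = property(lambda self: self._fit.minus_tds)
    c_value = property(lambda self: self._fit.c_value)

    def summary(self) -> str:
        f = self._fit
        fmt = lambda v, e: f"{v:.4g}" + (f" +/- {e:.2g}" if e is not None else "")
        return "\n".join([
            "One-set-of-sites ITC fit",
            "=" * 46,
            f"Kd                 {fmt(f.kd, f.kd_stderr)} M",
            f"dH                 {fmt(f.dh, f.dh_stderr)} kJ/mol",
            f"n (sites/molecule) {fmt(f.n, f.n_stderr)}",
            f"dG                 {f.dg:.1f} kJ/mol",
            f"-TdS               {f.minus_tds:.1f} kJ/mol",
            f"c-value            {f.c_value:.3g}",
        ])

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        exp = self.model.experiment
        idx = np.arange(1, len(exp.injection_volumes) + 1)
        ax.plot(idx, exp.heats_joules() * 1e6, "o", label="data")
        model = itc_forward(self._fit.kd, self._fit.dh, self._fit.n, exp) * 1e6
        ax.plot(idx, model, "-", label="one-site fit")
        ax.set_xlabel("injection")
        ax.set_ylabel("heat (uJ)")
        ax.legend()
        return ax
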