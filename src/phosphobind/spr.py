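"""SPR sensorgram fitting: global 1:1 Langmuir kinetics and steady-state
affinity.

A multicycle experiment injects the analyte over the same immobilized
surface at a dilution series of concentrations; cycles share kon, koff and
Rmax (single surface), so the kinetic fit is a global least squares over
all cycles with three parameters. The steady-state route fits the
end-of-injection responses against concentration with the binding
hyperbola Req = Rmax*C/(Kd + C).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np

from .binding import langmuir_association, langmuir_dissociation, steady_state_response

__all__ = [
    "Sensorgram",
    "KineticsTooFastError",
    "NonSaturatingWarning",
    "KineticFit",
    "SteadyStateFit",
    "fit_kinetic",
    "fit_steady_state",
    "KineticModel",
    "SteadyStateModel",
]


class KineticsTooFastError(RuntimeError):
    """Association equilibrates within one sample interval on every cycle;
    only steady-state affinity can be determined."""


class NonSaturatingWarning(UserWarning):
    """Top analyte concentration is low relative to the fitted Kd."""


@dataclass
class Sensorgram:
    """One SPR cycle: response versus time at a single analyte concentration.

    ``t_inject_start``/``t_inject_end`` delimit the association phase;
    samples after ``t_inject_end`` are the dissociation phase.
    """

    time: np.ndarray          # seconds, strictly increasing
    response: np.ndarray      # RU
    conc: float               # molar analyte
    t_inject_start: float = 0.0
    t_inject_end: float = 60.0

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if not self.t_inject_start < self.t_inject_end:
            raise ValueError("phases must be ordered: injection start < end")

    def association_mask(self):
        return (self.time >= self.t_inject_start) & (self.time <= self.t_inject_end)

    def end_response(self, window_frac: float = 0.05) -> float:
        """Mean response over the final *window_frac* of the association phase."""
        mask = self.association_mask()
        t = self.time[mask]
        r = self.response[mask]
        t0 = self.t_inject_end - window_frac * (self.t_inject_end - self.t_inject_start)
        sel = t >= t0
        if not sel.any():
            sel = np.zeros_like(t, bool)
            sel[-1] = True
        return float(np.mean(r[sel]))


def _model_cycle(sg: Sensorgram, kon, koff, rmax):
    t = sg.time
    out = np.zeros_like(t)
    assoc = sg.association_mask()
    ta = t[assoc] - sg.t_inject_start
    out[assoc] = langmuir_association(ta, kon, koff, sg.conc, rmax)
    dis = t > sg.t_inject_end
    if dis.any():
        r_end = langmuir_association(sg.t_inject_end - sg.t_inject_start,
                                     kon, koff, sg.conc, rmax)
        out[dis] = langmuir_dissociation(t[dis] - sg.t_inject_end, koff, r_end)
    return out


def _check_resolvable(sensorgrams):
    """Raise when every cycle reaches ~equilibrium by its first association
    sample (no kinetic information at the sampling resolution)."""
    for sg in sensorgrams:
        mask = sg.association_mask()
        t = sg.time[mask]
        r = sg.response[mask]
        if len(t) < 3:
            continue
        r_end = sg.end_response()
        if r_end <= 0:
            continue
        rising = np.nonzero(r >= 0.95 * r_end)[0]
        first_hit = rising[0] if len(rising) else len(r) - 1
        if first_hit > 1:
            return  # at least one cycle shows resolvable curvature
    raise KineticsTooFastError(
        "association reaches equilibrium within one sample interval on every "
        "cycle; fit steady-state affinity instead"
    )


@dataclass
class KineticFit:
    kon: float                # 1/(M s)
    kon_stderr: float | None
    koff: float               # 1/s
    koff_stderr: float | None
    rmax: float
    kd_kinetic: float         # koff/kon, molar
    residual_rms: float
    lmfit_result: object = field(repr=False, default=None)


def fit_kinetic(sensorgrams) -> KineticFit:
    """Global 1:1 Langmuir fit across all cycles (shared kon, koff, Rmax)."""
    sensorgrams = list(sensorgrams)
    if len(sensorgrams) < 5:
        raise ValueError("need at least 5 concentrations for a global kinetic fit")
    _check_resolvable(sensorgrams)

    r_top = max(sg.end_response() for sg in sensorgrams)
    c_mid = float(np.median([sg.conc for sg in sensorgrams]))

    def resid(params):
        kon = 10.0 ** params["log10_kon"].value
        koff = 10.0 ** params["log10_koff"].value
        rmax = params["rmax"].value
        chunks = [_model_cycle(sg, kon, koff, rmax) - sg.response for sg in sensorgrams]
        return np.concatenate(chunks) / max(r_top, 1e-12)

    params = lmfit.Parameters()
    params.add("log10_kon", value=float(np.log10(1.0 / c_mid / 60.0)), min=0, max=12)
    params.add("log10_koff", value=-1.0, min=-7, max=3)
    params.add("rmax", value=1.2 * r_top, min=0)
    out = lmfit.minimize(resid, params, method="leastsq")
    if not out.success:
        raise RuntimeError(f"kinetic fit failed to converge: {out.message}")

    kon = 10.0 ** out.params["log10_kon"].value
    koff = 10.0 ** out.params["log10_koff"].value
    kon_err = (kon * np.log(10.0) * out.params["log10_kon"].stderr
               if out.params["log10_kon"].stderr is not None else None)
    koff_err = (koff * np.log(10.0) * out.params["log10_koff"].stderr
                if out.params["log10_koff"].stderr is not None else None)
    return KineticFit(
        kon=kon, kon_stderr=kon_err, koff=koff, koff_stderr=koff_err,
        rmax=out.params["rmax"].value, kd_kinetic=koff / kon,
        residual_rms=float(np.sqrt(np.mean(out.residual ** 2)) * r_top),
        lmfit_result=out,
    )


@dataclass
class SteadyStateFit:
    kd: float
    kd_stderr: float | None
    rmax: float
    responses: np.ndarray
    concentrations: np.ndarray
    lower_bound_only: bool = False
    lmfit_result: object = field(repr=False, default=None)


def fit_steady_state(sensorgrams, *, window_frac: float = 0.05) -> SteadyStateFit:
    """Fit end-of-injection responses versus concentration to the binding
    hyperbola. Sets ``lower_bound_only`` when the series never reaches the
    fitted Kd, and warns when the top concentration is below 2x Kd."""
    sensorgrams = list(sensorgrams)
    if len(sensorgrams) < 5:
        raise ValueError("need at least 5 concentrations spanning Kd")
    C = np.array([sg.conc for sg in sensorgrams])
    R = np.array([sg.end_response(window_frac) for sg in sensorgrams])
    order = np.argsort(C)
    C, R = C[order], R[order]

    def resid(params):
        kd = 10.0 ** params["log10_kd"].value
        return steady_state_response(C, kd, params["rmax"].value) - R

    params = lmfit.Parameters()
    params.add("log10_kd", value=float(np.log10(np.median(C))), min=-15, max=0)
    params.add("rmax", value=float(1.5 * R.max()), min=0)
    out = lmfit.minimize(resid, params, method="leastsq")
    if not out.success:
        raise RuntimeError(f"steady-state fit failed to converge: {out.message}")
    kd = 10.0 ** out.params["log10_kd"].value
    kd_err = (kd * np.log(10.0) * out.params["log10_kd"].stderr
              if out.params["log10_kd"].stderr is not None else None)
    lower_bound = bool(C.max() < kd)
    if C.max() < 2.0 * kd:
        warnings.warn(
            f"top concentration {C.max():.3g} M is below 2x the fitted Kd {kd:.3g} M",
            NonSaturatingWarning,
        )
    return SteadyStateFit(kd=kd, kd_stderr=kd_err, rmax=out.params["rmax"].value,
                          responses=R, concentrations=C,
                          lower_bound_only=lower_bound, lmfit_result=out)


class KineticModel:
    """Global 1:1 kinetic model over a multicycle sensorgram set."""

    def __init__(self, sensorgrams):
        self.sensorgrams = list(sensorgrams)

    def fit(self) -> "KineticResults":
        return KineticResults(self, fit_kinetic(self.sensorgrams))


class KineticResults:
    def __init__(self, model, fit: KineticFit):
        self.model = model
        self._fit = fit

    kon = property(lambda self: self._fit.kon)
    kon_stderr = property(lambda self: self._fit.kon_stderr)
    koff = property(lambda self: self._fit.koff)
    koff_stderr = property(lambda self: self._fit.koff_stderr)
    rmax = property(lambda self: self._fit.rmax)
    kd_kinetic = property(lambda self: self._fit.kd_kinetic)

    def summary(self) -> str:
        f = self._fit
        return "\n".join([
            "Global 1:1 Langmuir kinetic fit",
            "=" * 46,
            f"kon                {f.kon:.4g} 1/(M s)",
            f"koff               {f.koff:.4g} 1/s",
            f"Rmax               {f.rmax:.4g} RU",
            f"Kd (koff/kon)      {f.kd_kinetic:.4g} M",
            f"residual RMS       {f.residual_rms:.3g} RU",
        ])

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for sg in self.model.sensorgrams:
            ax.plot(sg.time, sg.response, ".", ms=2)
            ax.plot(sg.time, _model_cycle(sg, self._fit.kon, self._fit.koff, self._fit.rmax),
                    "k-", lw=0.8)
        ax.set_xlabel("time (s)")
        ax.set_ylabel("response (RU)")
        return ax


class SteadyStateModel:
    """Steady-state affinity model over end-of-injection responses."""

    def __init__(self, sensorgrams, *, window_frac: float = 0.05):
        self.sensorgrams = list(sensorgrams)
        self.window_frac = window_frac

    def fit(self) -> "SteadyStateResults":
        return SteadyStateResults(self, fit_steady_state(self.sensorgrams,
                                                         window_frac=self.window_frac))


class SteadyStateResults:
    def __init__(self, model, fit: SteadyStateFit):
        self.model = model
        self._fit = fit

    kd = property(lambda self: self._fit.kd)
    kd_stderr = property(lambda self: self._fit.kd_stderr)
    rmax = property(lambda self: self._fit.rmax)
    lower_bound_only = property(lambda self: self._fit.lower_bound_only)

    def summary(self) -> str:
        f = self._fit
        bound = "  (lower bound only)" if f.lower_bound_only else ""
        return "\n".join([
            "Steady-state affinity fit",
            "=" * 46,
            f"Kd                 {f.kd:.4g} M{bound}",
            f"Rmax               {f.rmax:.4g} RU",
            f"concentrations     {len(f.concentrations)}",
        ])

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        f = self._fit
        ax.plot(f.concentrations, f.responses, "o", label="end-of-injection")
        xs = np.logspace(np.log10(f.concentrations.min()), np.log10(f.concentrations.max()), 200)
        ax.plot(xs, steady_state_response(xs, f.kd, f.rmax), "-", label="hyperbola")
        ax.set_xscale("log")
        ax.set_xlabel("analyte (M)")
        ax.set_ylabel("Req (RU)")
        ax.legend()
        return ax
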