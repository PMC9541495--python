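"""Fluorescence-anisotropy titration analysis.

Processing chain for a direct titration (fixed fluorescent tracer, protein
titrated in a serial dilution):

1. per-well total intensity and anisotropy, I = 2*P*G + S and
   r = (S - P*G)/I, aggregated to mean +/- SD per concentration;
2. logistic fit on log10(concentration) to locate the free/bound anisotropy
   plateaus r_min and r_max;
3. conversion of anisotropy to fraction bound,
   Lb = (r - rmin) / (lambda*(rmax - r) + r - rmin), which with intensity
   ratio lambda = 1 reduces to linear rescaling;
4. tight-binding quadratic fit of bound tracer versus total protein to
   obtain Kd, exact under tracer depletion (Kd comparable to the tracer
   concentration).

Doubly phosphorylated peptides give biphasic dose-response curves; these
are decomposed by splitting the concentration axis between the two
transitions and fitting each event separately to the same 1:1 chain
(stepwise Kd1 < Kd2).

Model/Results wrappers (`SingleSiteModel`, `BiphasicModel`) expose this
chain statsmodels-style; the individual steps remain available as
functions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np
import pandas as pd

from .binding import bound_ligand_quadratic

__all__ = [
    "AnisotropyCurve",
    "LogisticFit",
    "SingleSiteFit",
    "BiphasicFit",
    "DataQualityError",
    "SaturationNotReachedError",
    "SingleTransitionWarning",
    "compute_anisotropy",
    "fit_logistic",
    "to_fraction_bound",
    "fit_single_site",
    "fit_biphasic",
    "SingleSiteModel",
    "BiphasicModel",
]


class DataQualityError(ValueError):
    """Raised for physically impossible plate reads (non-positive intensity)."""


class SaturationNotReachedError(RuntimeError):
    """The titration does not reach its upper plateau; only a Kd lower bound
    can be stated (reported on the exception as ``kd_lower_bound``)."""

    def __init__(self, msg, kd_lower_bound=None):
        super().__init__(msg)
        self.kd_lower_bound = kd_lower_bound


class SingleTransitionWarning(UserWarning):
    """A biphasic fit was requested but only one transition was detected."""


@dataclass
class AnisotropyCurve:
    """Anisotropy versus titrant concentration, aggregated over replicates."""

    concentrations: np.ndarray  # molar, strictly increasing
    r_mean: np.ndarray
    r_sd: np.ndarray
    tracer_conc: float          # molar
    G: float = 1.0
    lam: float = 1.0            # I_bound / I_unbound
    n_replicates: int = 3

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.r_mean = np.asarray(self.r_mean, dtype=float)
        self.r_sd = np.asarray(self.r_sd, dtype=float)
        if np.any(np.diff(self.concentrations) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        if np.any(self.r_sd < 0):
            raise ValueError("replicate SDs must be >= 0")

    def subset(self, mask) -> "AnisotropyCurve":
        return AnisotropyCurve(
            self.concentrations[mask], self.r_mean[mask], self.r_sd[mask],
            self.tracer_conc, self.G, self.lam, self.n_replicates,
        )


def compute_anisotropy(plate_table: pd.DataFrame, *, tracer_conc: float,
                       G: float = 1.0, lam: float = 1.0) -> AnisotropyCurve:
    """Per-well anisotropy from parallel/perpendicular reads, aggregated.

    *plate_table* needs columns ``concentration_M``, ``replicate``, ``S``
    (parallel) and ``P`` (perpendicular). For each well I = 2*P*G + S and
    r = (S - P*G)/I; wells are then averaged per concentration across
    replicates (mean and sample SD).
    """
    if G <= 0:
        raise ValueError("grating factor G must be > 0")
    df = plate_table.copy()
    I = 2.0 * df["P"] * G + df["S"]
    bad = I <= 0
    if bad.any():
        row = df[bad].iloc[0]
        raise DataQualityError(
            f"non-positive total intensity at concentration {row['concentration_M']:.3e} M, "
            f"replicate {row['replicate']}"
        )
    df["r"] = (df["S"] - df["P"] * G) / I
    grouped = df.groupby("concentration_M")["r"].agg(["mean", "std", "count"]).reset_index()
    grouped = grouped.sort_values("concentration_M")
    sd = grouped["std"].to_numpy()
    sd = np.where(np.isnan(sd), 0.0, sd)
    return AnisotropyCurve(
        concentrations=grouped["concentration_M"].to_numpy(),
        r_mean=grouped["mean"].to_numpy(),
        r_sd=sd,
        tracer_conc=tracer_conc,
        G=G,
        lam=lam,
        n_replicates=int(grouped["count"].max()),
    )


@dataclass
class LogisticFit:
    """Sigmoid window fit on the log10 concentration axis."""

    rmin: float
    rmax: float
    logx0: float
    residual_rms: float
    lmfit_result: object = field(repr=False, default=None)

    def predict(self, x):
        """Model anisotropy at log10 concentration *x*."""
        x = np.asarray(x, dtype=float)
        return self.rmin + (self.rmax - self.rmin) / (1.0 + 10.0 ** (self.logx0 - x))


def _logistic(x, rmin, rmax, logx0):
    return rmin + (rmax - rmin) / (1.0 + 10.0 ** (logx0 - x))


def fit_logistic(curve: AnisotropyCurve, *, check_saturation: bool = True) -> LogisticFit:
    """Fit the increasing sigmoid r(x) = rmin + (rmax-rmin)/(1+10^(logx0-x)).

    Raises :class:`SaturationNotReachedError` when the data never approach
    the upper plateau (transition span below the replicate-noise floor, or
    the fitted midpoint lying at/beyond the top concentration), mirroring
    titrations reportable only as "Kd greater than" a limiting value.
    """
    x = np.log10(curve.concentrations)
    r = curve.r_mean
    if len(x) < 6:
        raise ValueError("need at least 6 concentrations for a logistic window fit")
    span = r.max() - r.min()
    noise = float(np.median(curve.r_sd))

    model = lmfit.Model(_logistic)
    params = model.make_params(rmin=r.min(), rmax=r.max(), logx0=float(np.median(x)))
    params["logx0"].set(min=x.min() - 3, max=x.max() + 3)
    out = model.fit(r, params, x=x)
    rmin, rmax = out.params["rmin"].value, out.params["rmax"].value
    logx0 = out.params["logx0"].value
    fit = LogisticFit(rmin=rmin, rmax=rmax, logx0=logx0,
                      residual_rms=float(np.sqrt(np.mean(out.residual ** 2))),
                      lmfit_result=out)

    if check_saturation:
        fitted_span = rmax - rmin
        if fitted_span <= max(3.0 * noise, 0.0) and span <= 3.0 * noise:
            raise SaturationNotReachedError(
                "no binding transition above the replicate-noise floor",
                kd_lower_bound=float(curve.concentrations[-1]),
            )
        # upper plateau must be approached within the sampled range
        top_gap = rmax - fit.predict(x[-1])
        if logx0 >= x[-1] or top_gap > max(3.0 * noise, 0.05 * fitted_span):
            raise SaturationNotReachedError(
                "titration ends before the upper anisotropy plateau; "
                f"Kd can only be bounded below by ~{curve.concentrations[-1]:.3g} M",
                kd_lower_bound=float(curve.concentrations[-1]),
            )
    if fit.rmax <= fit.rmin:
        raise SaturationNotReachedError("fitted window is not increasing",
                                        kd_lower_bound=float(curve.concentrations[-1]))
    return fit


def to_fraction_bound(curve: AnisotropyCurve, fit: LogisticFit):
    """Convert anisotropy to fraction bound via the window fit.

    Lb = (r - rmin) / (lambda*(rmax - r) + r - rmin); values are clipped to
    [0, 1] and the number of clipped points returned alongside.

    Returns
    -------
    (ndarray, int)
        Fraction-bound series and the count of clipped points.
    """
    if fit.rmax == fit.rmin:
        raise ValueError("degenerate anisotropy window: rmax == rmin")
    r = curve.r_mean
    lam = curve.lam
    fb = (r - fit.rmin) / (lam * (fit.rmax - r) + r - fit.rmin)
    clipped = int(np.sum((fb < 0) | (fb > 1)))
    return np.clip(fb, 0.0, 1.0), clipped


@dataclass
class SingleSiteFit:
    """Tight-binding 1:1 fit result."""

    kd: float                # molar
    kd_stderr: float | None
    logistic: LogisticFit
    fraction_bound: np.ndarray = field(repr=False, default=None)
    clipped_points: int = 0
    concentration_window: tuple = None
    lmfit_result: object = field(repr=False, default=None)


def _fit_kd(X, FL, bound, kd_init):
    params = lmfit.Parameters()
    params.add("log10_kd", value=float(np.log10(max(kd_init, 1e-14))), min=-15, max=0)

    def resid(p):
        return bound_ligand_quadratic(10.0 ** p["log10_kd"].value, X, FL) - bound

    out = lmfit.minimize(resid, params, method="leastsq")
    if not out.success:
        raise RuntimeError(f"single-site fit failed to converge: {out.message}")
    return out


def _r_from_fb(fb, rmin, rmax, lam):
    """Intensity-weighted anisotropy of a free/bound tracer mixture
    (inverse of the fraction-bound conversion)."""
    wb = lam * fb
    return (rmin * (1.0 - fb) + rmax * wb) / ((1.0 - fb) + wb)


def fit_single_site(curve: AnisotropyCurve, fraction_bound=None, *,
                    logistic: LogisticFit | None = None) -> SingleSiteFit:
    """Fit the tight-binding quadratic to bound tracer versus total protein.

    The fraction-bound series (from :func:`to_fraction_bound`) is multiplied
    by the tracer concentration and fitted with Kd free (log-parameterized
    for positivity); the standard error comes from the fit covariance.

    A sigmoid only approximates the tight-binding shape, so the logistic
    plateaus seed a refinement in which rmin, rmax and Kd are fitted
    jointly against the anisotropy; on noiseless data this recovers the
    generating parameters exactly. Passing an explicit *fraction_bound*
    series skips the refinement and fits Kd alone.
    """
    if logistic is None:
        logistic = fit_logistic(curve)
    FL = curve.tracer_conc
    X = curve.concentrations
    r = curve.r_mean
    lam = curve.lam

    if fraction_bound is not None:
        fb = np.asarray(fraction_bound, dtype=float)
        clipped = int(np.sum((fb < 0) | (fb > 1)))
        fb = np.clip(fb, 0.0, 1.0)
        half_idx = int(np.argmin(np.abs(fb - 0.5)))
        out = _fit_kd(X, FL, fb * FL, X[half_idx])
        rmin, rmax = logistic.rmin, logistic.rmax
    else:
        fb0 = np.clip((r - logistic.rmin)
                      / (lam * (logistic.rmax - r) + r - logistic.rmin), 0.0, 1.0)
        half_idx = int(np.argmin(np.abs(fb0 - 0.5)))
        kd0 = _fit_kd(X, FL, fb0 * FL, X[half_idx])

        def resid(p):
            fbm = bound_ligand_quadratic(10.0 ** p["log10_kd"].value, X, FL) / FL
            return _r_from_fb(fbm, p["rmin"].value, p["rmax"].value, lam) - r

        params = lmfit.Parameters()
        params.add("log10_kd", value=kd0.params["log10_kd"].value, min=-15, max=0)
        params.add("rmin", value=logistic.rmin)
        params.add("rmax", value=logistic.rmax)
        out = lmfit.minimize(resid, params, method="leastsq")
        if not out.success:
            raise RuntimeError(f"single-site fit failed to converge: {out.message}")
        rmin, rmax = out.params["rmin"].value, out.params["rmax"].value
        fb = (r - rmin) / (lam * (rmax - r) + r - rmin)
        clipped = int(np.sum((fb < 0) | (fb > 1)))
        fb = np.clip(fb, 0.0, 1.0)

    log_kd = out.params["log10_kd"]
    kd = 10.0 ** log_kd.value
    stderr = None
    if log_kd.stderr is not None:
        stderr = kd * np.log(10.0) * log_kd.stderr
    window = LogisticFit(rmin=float(rmin), rmax=float(rmax), logx0=logistic.logx0,
                         residual_rms=logistic.residual_rms,
                         lmfit_result=logistic.lmfit_result)
    return SingleSiteFit(
        kd=kd, kd_stderr=stderr, logistic=window,
        fraction_bound=fb, clipped_points=clipped,
        concentration_window=(float(X[0]), float(X[-1])), lmfit_result=out,
    )


@dataclass
class BiphasicFit:
    """Stepwise decomposition of a two-transition dose-response curve."""

    kd1: float
    kd2: float
    split_conc: float
    event1: SingleSiteFit
    event2: SingleSiteFit


def _smooth(y, window=3):
    if len(y) < window:
        return y
    kernel = np.ones(window) / window
    pad = window // 2
    ypad = np.concatenate([np.full(pad, y[0]), y, np.full(pad, y[-1])])
    return np.convolve(ypad, kernel, mode="valid")


def _double_logistic(x, r0, a1, a2, m1, delta):
    m2 = m1 + delta
    return (r0 + a1 / (1.0 + 10.0 ** (m1 - x)) + a2 / (1.0 + 10.0 ** (m2 - x)))


def detect_split(curve: AnisotropyCurve, *, min_separation: float = 1.0):
    """Locate the boundary between two binding events.

    Compares a single increasing sigmoid against a sum of two sigmoids on
    the log10 concentration axis. Two events are accepted when both fitted
    amplitudes clear the noise floor (3x the median replicate SD, and at
    least 3% of the total span each) with midpoints at least
    *min_separation* decades apart; the split is then the flattest point of
    the two-sigmoid model between the midpoints. Returns the split
    concentration, or None when only one transition is detectable.
    """
    x = np.log10(curve.concentrations)
    r = curve.r_mean
    span = r.max() - r.min()
    if span <= 0 or len(x) < 10:
        return None
    noise = float(np.median(curve.r_sd))

    rs = _smooth(r, 3)
    dr = np.gradient(rs, x)
    m1_init = float(x[int(np.argmax(dr))])

    model = lmfit.Model(_double_logistic)
    params = model.make_params(r0=r.min(), a1=0.7 * span, a2=0.3 * span,
                               m1=m1_init, delta=2.0)
    params["a1"].set(min=0.0)
    params["a2"].set(min=0.0)
    params["m1"].set(min=x.min() - 1, max=x.max() + 1)
    params["delta"].set(min=min_separation, max=(x.max() - x.min()) + 2)
    try:
        out = model.fit(r, params, x=x)
    except Exception:
        return None
    a1, a2 = out.params["a1"].value, out.params["a2"].value
    m1 = out.params["m1"].value
    m2 = m1 + out.params["delta"].value
    floor = max(3.0 * noise, 0.03 * span)
    if a1 < floor or a2 < floor or m2 > x.max() + 0.5:
        return None
    grid = np.linspace(m1, m2, 200)
    dgrid = np.gradient(_double_logistic(grid, out.params["r0"].value, a1, a2,
                                         m1, out.params["delta"].value), grid)
    split = float(10.0 ** grid[int(np.argmin(dgrid))])
    lo = np.sum(curve.concentrations <= split)
    if lo < 6 or len(curve.concentrations) - lo < 6:
        return None  # too few points on one side for event-local windows
    return split


def fit_biphasic(curve: AnisotropyCurve, *, split_conc: float | None = None):
    """Stepwise 1:1 fits of a biphasic titration (tandem-phosphosite tracer).

    Each binding event is fitted independently with event-local plateaus:
    event 1 on concentrations <= split, event 2 on >= split, each through
    the full logistic -> fraction-bound -> quadratic chain. When only one
    transition is detectable the routine falls back to a plain
    :class:`SingleSiteFit` and emits :class:`SingleTransitionWarning`.
    """
    if split_conc is None:
        split_conc = detect_split(curve)
    if split_conc is None:
        warnings.warn("only one transition detected; falling back to a single-site fit",
                      SingleTransitionWarning)
        return fit_single_site(curve)

    c = curve.concentrations
    FL = curve.tracer_conc
    low_mask = c <= split_conc
    high_mask = c >= split_conc
    low = curve.subset(low_mask)
    high = curve.subset(high_mask)

    def corrected(base: AnisotropyCurve, delta_r):
        fixed = base.subset(np.ones(len(base.concentrations), bool))
        fixed.r_mean = base.r_mean + delta_r
        return fixed

    def event_span(fit: SingleSiteFit):
        return fit.logistic.rmax - fit.logistic.rmin

    # The two events overlap slightly around the split, so each event is
    # fitted on data corrected for the other's modelled contribution,
    # alternating until both are self-consistent.
    ev2 = fit_single_site(high, logistic=fit_logistic(high, check_saturation=False))
    ev1 = None
    for _ in range(2):
        leak2 = event_span(ev2) * bound_ligand_quadratic(ev2.kd, low.concentrations, FL) / FL
        low_c = corrected(low, -leak2)
        ev1 = fit_single_site(low_c, logistic=fit_logistic(low_c, check_saturation=False))
        deficit1 = event_span(ev1) * (1.0 - bound_ligand_quadratic(ev1.kd, high.concentrations, FL) / FL)
        high_c = corrected(high, deficit1)
        ev2 = fit_single_site(high_c, logistic=fit_logistic(high_c, check_saturation=False))
    leak2 = event_span(ev2) * bound_ligand_quadratic(ev2.kd, low.concentrations, FL) / FL
    low_c = corrected(low, -leak2)
    ev1 = fit_single_site(low_c, logistic=fit_logistic(low_c, check_saturation=False))

    kd1, kd2 = sorted([ev1.kd, ev2.kd])
    if kd1 != ev1.kd:
        ev1, ev2 = ev2, ev1

    # Final polish: refit the additive two-event model on the whole curve
    # with the stepwise estimates as the starting point. This removes the
    # residual boundary error of the split and uses every concentration for
    # both constants.
    def resid(p):
        f1 = bound_ligand_quadratic(10.0 ** p["log10_kd1"].value, c, FL) / FL
        f2 = bound_ligand_quadratic(10.0 ** p["log10_kd2"].value, c, FL) / FL
        model = (p["r0"].value
                 + (p["r1"].value - p["r0"].value) * f1
                 + (p["r2"].value - p["r1"].value) * f2)
        return model - curve.r_mean

    params = lmfit.Parameters()
    params.add("log10_kd1", value=float(np.log10(kd1)), min=-15, max=0)
    params.add("log10_kd2", value=float(np.log10(kd2)), min=-15, max=0)
    params.add("r0", value=ev1.logistic.rmin)
    params.add("r1", value=ev1.logistic.rmax)
    params.add("r2", value=ev2.logistic.rmax)
    out = lmfit.minimize(resid, params, method="leastsq")
    if out.success:
        j1 = 10.0 ** out.params["log10_kd1"].value
        j2 = 10.0 ** out.params["log10_kd2"].value
        if j1 < j2:
            kd1, kd2 = j1, j2
    return BiphasicFit(kd1=kd1, kd2=kd2, split_conc=float(split_conc),
                       event1=ev1, event2=ev2)


# ---------------------------------------------------------------------------
# Model/Results interface


class SingleSiteModel:
    """1:1 tight-binding model for a direct FA titration.

    Parameters
    ----------
    curve : AnisotropyCurve
        Aggregated titration data (see :func:`compute_anisotropy` or
        :meth:`from_plate`).
    """

    def __init__(self, curve: AnisotropyCurve):
        self.curve = curve

    @classmethod
    def from_plate(cls, plate_table, *, tracer_conc, G=1.0, lam=1.0):
        return cls(compute_anisotropy(plate_table, tracer_conc=tracer_conc, G=G, lam=lam))

    def fit(self) -> "SingleSiteResults":
        logistic = fit_logistic(self.curve)
        fit = fit_single_site(self.curve, logistic=logistic)
        return SingleSiteResults(self, fit)


class SingleSiteResults:
    """Results of a single-site FA fit; carries Kd, its standard error and
    the anisotropy window used for the fraction-bound conversion."""

    def __init__(self, model: SingleSiteModel, fit: SingleSiteFit):
        self.model = model
        self._fit = fit

    @property
    def kd(self):
        return self._fit.kd

    @property
    def kd_stderr(self):
        return self._fit.kd_stderr

    @property
    def rmin(self):
        return self._fit.logistic.rmin

    @property
    def rmax(self):
        return self._fit.logistic.rmax

    @property
    def fraction_bound(self):
        return self._fit.fraction_bound

    @property
    def clipped_points(self):
        return self._fit.clipped_points

    def summary(self) -> str:
        f = self._fit
        err = f"{f.kd_stderr:.3g}" if f.kd_stderr is not None else "n/a"
        lines = [
            "Fluorescence anisotropy 1:1 tight-binding fit",
            "=" * 46,
            f"Kd                 {f.kd:.4g} M  (stderr {err})",
            f"r_min / r_max      {f.logistic.rmin:.4f} / {f.logistic.rmax:.4f}",
            f"log10 midpoint     {f.logistic.logx0:.3f}",
            f"tracer             {self.model.curve.tracer_conc:.3g} M",
            f"window             {f.concentration_window[0]:.3g} - {f.concentration_window[1]:.3g} M",
            f"clipped points     {f.clipped_points}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        c = self.model.curve
        ax.errorbar(c.concentrations, c.r_mean, yerr=c.r_sd, fmt="o", label="data")
        xs = np.logspace(np.log10(c.concentrations[0]), np.log10(c.concentrations[-1]), 200)
        ax.plot(xs, self._fit.logistic.predict(np.log10(xs)), "-", label="logistic window")
        ax.set_xscale("log")
        ax.set_xlabel("[14-3-3 monomer] (M)")
        ax.set_ylabel("anisotropy r")
        ax.legend()
        return ax


class BiphasicModel:
    """Stepwise two-event model for biphasic FA titrations."""

    def __init__(self, curve: AnisotropyCurve, *, split_conc: float | None = None):
        self.curve = curve
        self.split_conc = split_conc

    @classmethod
    def from_plate(cls, plate_table, *, tracer_conc, G=1.0, lam=1.0, split_conc=None):
        return cls(compute_anisotropy(plate_table, tracer_conc=tracer_conc, G=G, lam=lam),
                   split_conc=split_conc)

    def fit(self):
        fit = fit_biphasic(self.curve, split_conc=self.split_conc)
        if isinstance(fit, SingleSiteFit):
            return SingleSiteResults(SingleSiteModel(self.curve), fit)
        return BiphasicResults(self, fit)


class BiphasicResults:
    """Stepwise Kd1 < Kd2 from a two-event decomposition."""

    def __init__(self, model: BiphasicModel, fit: BiphasicFit):
        self.model = model
        self._fit = fit

    @property
    def kd1(self):
        return self._fit.kd1

    @property
    def kd2(self):
        return self._fit.kd2

    @property
    def split_conc(self):
        return self._fit.split_conc

    @property
    def event1(self):
        return self._fit.event1

    @property
    def event2(self):
        return self._fit.event2

    def summary(self) -> str:
        f = self._fit
        return "\n".join([
            "Fluorescence anisotropy stepwise biphasic fit",
            "=" * 46,
            f"Kd1 (event 1)      {f.kd1:.4g} M",
            f"Kd2 (event 2)      {f.kd2:.4g} M",
            f"split conc         {f.split_conc:.4g} M",
            f"event 1 window     {f.event1.logistic.rmin:.4f} - {f.event1.logistic.rmax:.4f}",
            f"event 2 window     {f.event2.logistic.rmin:.4f} - {f.event2.logistic.rmax:.4f}",
        ])
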