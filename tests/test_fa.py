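"""FA pipeline: anisotropy arithmetic, window fits, fraction-bound
conversion, tight-binding and biphasic fits."""

import numpy as np
import pandas as pd
import pytest

import phosphobind as pb
from phosphobind.anisotropy import (
    DataQualityError,
    LogisticFit,
    SaturationNotReachedError,
    SingleTransitionWarning,
    compute_anisotropy,
    detect_split,
    fit_logistic,
    to_fraction_bound,
)

TRUE_KD = 98.8e-9
TRUE_KD1, TRUE_KD2 = 30e-9, 10.7e-6


def _plate(rows):
    return pd.DataFrame(rows, columns=["concentration_M", "replicate", "S", "P"])


class TestComputeAnisotropy:
    def test_direct_arithmetic(self):
        # S=3, P=1, G=1 -> I=5, r=0.4
        t = _plate([[1e-9, 1, 3.0, 1.0]])
        curve = compute_anisotropy(t, tracer_conc=50e-9)
        assert curve.r_mean[0] == pytest.approx(0.4)

    def test_unpolarized_and_fully_polarized_limits(self):
        t = _plate([[1e-9, 1, 2.0, 2.0], [2e-9, 1, 5.0, 0.0]])
        curve = compute_anisotropy(t, tracer_conc=50e-9)
        assert curve.r_mean[0] == pytest.approx(0.0)
        assert curve.r_mean[1] == pytest.approx(1.0)

    def test_nonpositive_intensity_names_the_well(self):
        t = _plate([[1e-9, 2, -3.0, 1.0]])
        with pytest.raises(DataQualityError, match="replicate 2"):
            compute_anisotropy(t, tracer_conc=50e-9)

    def test_replicates_aggregate_to_mean_and_sd(self):
        t = _plate([[1e-9, 1, 3.0, 1.0], [1e-9, 2, 3.5, 1.0]])
        curve = compute_anisotropy(t, tracer_conc=50e-9)
        assert len(curve.concentrations) == 1
        assert curve.r_sd[0] > 0

    def test_gain_invariance(self, single_site_plate):
        """Multiplying all channels by a common gain leaves r unchanged."""
        scaled = single_site_plate.copy()
        scaled[["S", "P"]] *= 7.3
        c1 = compute_anisotropy(single_site_plate, tracer_conc=50e-9)
        c2 = compute_anisotropy(scaled, tracer_conc=50e-9)
        np.testing.assert_allclose(c1.r_mean, c2.r_mean, rtol=1e-12)

    def test_duplicate_replicate_rows_do_not_move_the_fit(self, single_site_plate):
        doubled = pd.concat([single_site_plate, single_site_plate], ignore_index=True)
        k1 = pb.SingleSiteModel.from_plate(single_site_plate, tracer_conc=50e-9).fit().kd
        k2 = pb.SingleSiteModel.from_plate(doubled, tracer_conc=50e-9).fit().kd
        assert k1 == pytest.approx(k2, rel=1e-9)


class TestLogisticWindow:
    def test_noiseless_round_trip_recovers_plateaus(self, single_site_plate):
        # the sigmoid window alone lands close; the refined window of the
        # full fit recovers the generating plateaus to better than 0.5%
        curve = compute_anisotropy(single_site_plate, tracer_conc=50e-9)
        fit = fit_logistic(curve)
        assert fit.rmin == pytest.approx(0.06, rel=0.02)
        assert fit.rmax == pytest.approx(0.24, rel=0.02)
        res = pb.SingleSiteModel(curve).fit()
        assert res.rmin == pytest.approx(0.06, rel=0.005)
        assert res.rmax == pytest.approx(0.24, rel=0.005)

    def test_truncated_curve_raises_saturation_error(self):
        design = pb.FAPlateDesign(top_conc=100e-6, n_points=20, noise_sd=0.0, seed=2)
        plate = pb.gen_fa_titration(design, pb.SingleSite(kd=31.6e-6))
        curve = compute_anisotropy(plate, tracer_conc=design.tracer_conc)
        with pytest.raises(SaturationNotReachedError) as err:
            fit_logistic(curve)
        assert err.value.kd_lower_bound == pytest.approx(100e-6, rel=1e-6)

    def test_truncated_noisy_curve_reports_lower_bound_only(self):
        """Emulates the '>250 uM'-style entries: weak binder sampled below
        saturation yields a bound, not a Kd."""
        design = pb.FAPlateDesign(top_conc=100e-6, n_points=20, noise_sd=0.01, seed=2)
        plate = pb.gen_fa_titration(design, pb.SingleSite(kd=31.6e-6))
        with pytest.raises(SaturationNotReachedError):
            pb.SingleSiteModel.from_plate(plate, tracer_conc=design.tracer_conc).fit()


class TestFractionBound:
    def test_endpoints_and_midpoint_with_unit_lambda(self):
        curve = pb.AnisotropyCurve(
            concentrations=np.logspace(-9, -5, 5),
            r_mean=np.array([0.06, 0.06, 0.15, 0.24, 0.24]),
            r_sd=np.zeros(5), tracer_conc=50e-9)
        fit = LogisticFit(rmin=0.06, rmax=0.24, logx0=-7.0, residual_rms=0.0)
        fb, clipped = to_fraction_bound(curve, fit)
        assert fb[0] == 0.0 and fb[-1] == 1.0
        assert fb[2] == pytest.approx(0.5)
        assert clipped == 0

    def test_degenerate_window_rejected(self):
        curve = pb.AnisotropyCurve(
            concentrations=np.logspace(-9, -5, 5), r_mean=np.full(5, 0.1),
            r_sd=np.zeros(5), tracer_conc=50e-9)
        fit = LogisticFit(rmin=0.1, rmax=0.1, logx0=-7.0, residual_rms=0.0)
        with pytest.raises(ValueError):
            to_fraction_bound(curve, fit)


class TestSingleSiteFit:
    def test_noiseless_round_trip(self, single_site_plate, rel):
        res = pb.SingleSiteModel.from_plate(single_site_plate, tracer_conc=50e-9).fit()
        assert rel(res.kd, TRUE_KD) < 1e-3

    def test_quadratic_unbiased_where_hyperbola_is_biased(self):
        """Tracer-limited regime (Kd < FL): the depletion-aware quadratic
        stays on target while a naive hyperbola fit lands high."""
        import lmfit

        design = pb.FAPlateDesign(noise_sd=0.0, seed=3)
        plate = pb.gen_fa_titration(design, pb.SingleSite(kd=5e-9))
        res = pb.SingleSiteModel.from_plate(plate, tracer_conc=design.tracer_conc).fit()
        assert abs(res.kd - 5e-9) / 5e-9 < 1e-3

        curve = compute_anisotropy(plate, tracer_conc=design.tracer_conc)
        fb = (curve.r_mean - 0.06) / (0.24 - 0.06)

        def resid(p):
            kd = 10.0 ** p["lk"].value
            return curve.concentrations / (kd + curve.concentrations) - fb

        pars = lmfit.Parameters()
        pars.add("lk", value=-8.3, min=-12, max=-3)
        out = lmfit.minimize(resid, pars, method="leastsq")
        naive = 10.0 ** out.params["lk"].value
        assert naive > 3.0 * 5e-9  # hyperbola reports the tracer conc scale, not Kd

    def test_summary_mentions_kd(self, single_site_plate):
        res = pb.SingleSiteModel.from_plate(single_site_plate, tracer_conc=50e-9).fit()
        assert "Kd" in res.summary()


class TestBiphasic:
    def test_noiseless_round_trip(self, two_event_plate, rel):
        res = pb.BiphasicModel.from_plate(two_event_plate, tracer_conc=50e-9).fit()
        assert rel(res.kd1, TRUE_KD1) < 0.01
        assert rel(res.kd2, TRUE_KD2) < 0.01
        assert res.kd1 < res.split_conc < res.kd2

    def test_split_detected_between_midpoints(self, two_event_plate):
        curve = compute_anisotropy(two_event_plate, tracer_conc=50e-9)
        split = detect_split(curve)
        assert split is not None
        assert TRUE_KD1 < split < TRUE_KD2

    def test_single_transition_falls_back_with_warning(self, single_site_plate):
        model = pb.BiphasicModel.from_plate(single_site_plate, tracer_conc=50e-9)
        with pytest.warns(SingleTransitionWarning):
            res = model.fit()
        assert hasattr(res, "kd") and not hasattr(res, "kd1")

    def test_manual_split_honoured(self, two_event_plate, rel):
        res = pb.BiphasicModel.from_plate(two_event_plate, tracer_conc=50e-9,
                                          split_conc=1e-6).fit()
        assert res.split_conc == pytest.approx(1e-6)
        assert rel(res.kd1, TRUE_KD1) < 0.01
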