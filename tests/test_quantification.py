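"""SUVr computation and the Centiloid calibration algebra."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from centiloid.phantom import PhantomSpec, render_pet
from centiloid.quantification import (CentiloidAnchors, DEFAULT_ANCHORS,
                                      TracerCalibration, VOISet,
                                      centiloid_from_pib, centiloid_from_tracer,
                                      coefficient_registry, compose_equation,
                                      compute_suvr, fit_calibration,
                                      get_calibration, level1_qc,
                                      pib_equivalent_suvr)
from centiloid.volume_io import MaskVolume, Volume


class TestComputeSuvr:
    def _uniform_case(self):
        aff = np.diag([3.0, 3.0, 3.0, 1.0])
        data = np.ones((12, 12, 12))
        data[2:5] = 1.5
        target = np.zeros_like(data)
        target[2:5] = 1
        ref = np.zeros_like(data)
        ref[8:11] = 1
        vol = Volume(data, aff)
        vois = VOISet(MaskVolume(target, aff), MaskVolume(ref, aff))
        return vol, vois

    def test_uniform_compartments(self):
        vol, vois = self._uniform_case()
        res = compute_suvr(vol, vois)
        assert res.suvr == pytest.approx(1.5, abs=1e-12)
        assert res.suvr == pytest.approx(res.target_mean / res.reference_mean)

    def test_global_scaling_invariance(self):
        vol, vois = self._uniform_case()
        scaled = Volume(vol.data * 3.7, vol.affine)
        assert compute_suvr(scaled, vois).suvr == pytest.approx(
            compute_suvr(vol, vois).suvr, rel=1e-12)

    def test_phantom_ad_anchor_recovery(self):
        """Noiseless burden-1 phantom measures the AD-100 anchor 2.088."""
        vol, truth = render_pet(PhantomSpec(burden=1.0, psf_fwhm=0, noise_sd=0))
        res = compute_suvr(vol, truth.masks)
        assert res.suvr == pytest.approx(2.088, rel=0.005)

    def test_nan_inside_voi_rejected(self):
        vol, vois = self._uniform_case()
        vol.data[3, 3, 3] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            compute_suvr(vol, vois)

    def test_nonpositive_reference_rejected(self):
        vol, vois = self._uniform_case()
        vol.data[8:11] = 0.0
        with pytest.raises(ValueError, match="reference"):
            compute_suvr(vol, vois)

    def test_overlapping_vois_rejected(self):
        aff = np.eye(4)
        m = np.zeros((8, 8, 8))
        m[2:6] = 1
        with pytest.raises(ValueError, match="overlap"):
            VOISet(MaskVolume(m, aff), MaskVolume(m.copy(), aff))


class TestCentiloidAlgebra:
    def test_anchor_identities(self):
        assert centiloid_from_pib(1.014) == pytest.approx(0.0, abs=1e-12)
        assert centiloid_from_pib(2.088) == pytest.approx(100.0, abs=1e-12)
        assert centiloid_from_pib(1.551) == pytest.approx(50.0, abs=1e-9)

    def test_pib_equivalent_inverts_the_calibration_line(self):
        calib = get_calibration("FMM", "standard")
        assert pib_equivalent_suvr(calib.intercept + calib.slope * 1.0,
                                   calib) == pytest.approx(1.0, abs=1e-12)

    def test_fbp_standard_yc0_equivalence(self):
        # (1.0413 - 0.511) / 0.523 lands on the young-control anchor
        calib = get_calibration("FBP", "standard")
        assert pib_equivalent_suvr(1.0413, calib) == pytest.approx(1.014, abs=5e-4)

    def test_nav_standard_ad_anchor_round_trip(self):
        calib = get_calibration("NAV", "standard")
        tracer_suvr = 1.046 * 2.088 - 0.035
        assert pib_equivalent_suvr(tracer_suvr, calib) == pytest.approx(2.088, abs=1e-9)

    def test_tracer_centiloid_zero_at_mapped_anchor(self):
        for calib, _ in [(c, None) for c in coefficient_registry()[0]]:
            s0 = calib.intercept + calib.slope * DEFAULT_ANCHORS.yc0_mean
            assert centiloid_from_tracer(s0, calib) == pytest.approx(0.0, abs=1e-9)
            s100 = calib.intercept + calib.slope * DEFAULT_ANCHORS.ad100_mean
            assert centiloid_from_tracer(s100, calib) == pytest.approx(100.0, abs=1e-9)

    def test_pib_nonstandard_published_offset(self):
        calib = get_calibration("PiB", "nonstandard")
        assert centiloid_from_tracer(1.034, calib) == pytest.approx(0.0, abs=0.1)

    def test_fmm_standard_published_offset(self):
        calib = get_calibration("FMM", "standard")
        assert centiloid_from_tracer(0.999, calib) == pytest.approx(0.0, abs=0.1)


class TestComposeEquation:
    def test_identity_calibration_reduces_to_anchor_equation(self):
        eq = compose_equation(TracerCalibration("PiB", "standard", 1.0, 0.0))
        assert eq.offset == pytest.approx(DEFAULT_ANCHORS.yc0_mean)
        assert eq.divisor == pytest.approx(
            DEFAULT_ANCHORS.ad100_mean - DEFAULT_ANCHORS.yc0_mean)

    @pytest.mark.parametrize("tracer,pipeline,offset", [
        ("PiB", "nonstandard", 1.034),
        ("FBP", "nonstandard", 1.109),
    ])
    def test_published_offsets(self, tracer, pipeline, offset):
        eq = compose_equation(get_calibration(tracer, pipeline))
        assert round(eq.offset, 3) == offset

    def test_composed_equation_equals_two_step_conversion(self):
        rng = np.random.default_rng(0)
        suvrs = rng.uniform(0.8, 3.0, size=1000)
        for calib in coefficient_registry()[0]:
            eq = compose_equation(calib)
            np.testing.assert_allclose(
                eq(suvrs), centiloid_from_tracer(suvrs, calib),
                rtol=1e-12, atol=1e-9)


class TestFitCalibration:
    def test_noiseless_line_recovered_exactly(self):
        x = np.linspace(1.0, 2.5, 10)
        y = 0.770 * x + 0.218
        calib = fit_calibration(x, y, "FMM", "standard")
        assert calib.slope == pytest.approx(0.770, abs=1e-12)
        assert calib.intercept == pytest.approx(0.218, abs=1e-12)
        assert calib.r2 == pytest.approx(1.0, abs=1e-12)

    def test_synthetic_cohort_slope_recovery(self):
        """n=74 anchor-mixture cohort: FMM slope recovered within 0.05."""
        rng = np.random.default_rng(42)
        pib = np.concatenate([rng.normal(1.014, 0.047, 37),
                              rng.normal(2.088, 0.209, 37)])
        fmm = 0.770 * pib + 0.218 + rng.normal(0, 0.06, 74)
        calib = fit_calibration(pib, fmm, "FMM", "standard")
        assert calib.slope == pytest.approx(0.770, abs=0.05)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            fit_calibration([1.0, 2.0], [1.0, 2.0], "PiB", "nonstandard")

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            fit_calibration([1.0, 1.0, 1.0], [1.0, 2.0, 3.0], "PiB", "nonstandard")


class TestLevel1QC:
    def test_replication_triple_passes(self):
        verdict = level1_qc(0.997, 0.166, 0.999)
        assert verdict.passed

    def test_slope_out_of_range_fails_on_slope_only(self):
        verdict = level1_qc(1.03, 0.0, 0.999)
        assert not verdict.slope_ok and verdict.intercept_ok and verdict.r2_ok

    def test_boundaries(self):
        assert level1_qc(1.02, 0.0, 0.999).slope_ok        # inclusive
        assert level1_qc(0.98, -2.0, 0.999).passed         # inclusive
        assert not level1_qc(1.0, 0.0, 0.98).r2_ok         # strict

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            level1_qc(np.nan, 0.0, 0.99)


class TestRegistry:
    def test_all_tracer_pipeline_pairs_present(self):
        calibs, anchors = coefficient_registry()
        assert len(calibs) == 10
        assert anchors.yc0_mean == 1.014 and anchors.ad100_mean == 2.088

    def test_fmm_standard_slope(self):
        assert get_calibration("FMM", "standard").slope == 0.770

    def test_pib_standard_is_identity(self):
        calib = get_calibration("PiB", "standard")
        assert (calib.slope, calib.intercept) == (1.0, 0.0)

    def test_unknown_key_lists_options(self):
        with pytest.raises(KeyError, match="tracers"):
            get_calibration("XYZ", "standard")

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(suvr=st.floats(0.5, 4.0))
    def test_round_trip_tracer_to_pib_and_back(self, suvr):
        calib = get_calibration("FBB", "nonstandard")
        pib = pib_equivalent_suvr(suvr, calib)
        assert calib.slope * pib + calib.intercept == pytest.approx(suvr, rel=1e-12)


def test_anchor_ordering_enforced():
    with pytest.raises(ValueError):
        CentiloidAnchors(yc0_mean=2.0, ad100_mean=1.0)
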