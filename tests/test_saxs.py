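"""SAXS branch: background model, Kratky transform, peak fit, d_cc."""

import math

import numpy as np
import pytest

from cellscatter import (
    DomainError,
    NoPeakError,
    SAXSBackgroundModel,
    SAXSConfig,
    ScatteringProfile,
    ValidationError,
    analyze_saxs,
    center_to_center_distance,
    default_saxs_truth,
    fit_kratky_peak,
    fit_saxs_background,
    generate_saxs_profile,
    kratky_transform,
    subtract_background,
)
from cellscatter.waxs import gaussian

TWO_PI = 2 * math.pi


def _saxs_profile(q, intensity, **kw):
    return ScatteringProfile(q=q, intensity=intensity, modality="SAXS", **kw)


QGRID = np.linspace(0.01, 0.3, 400)


class TestBackgroundFit:
    def test_pure_power_law_recovered_exactly(self):
        prof = _saxs_profile(QGRID, 2.5 * QGRID**-4.0)
        model = fit_saxs_background(prof)
        assert model.prefactor == pytest.approx(2.5, rel=1e-6)
        assert model.constant <= 1e-6
        assert model.exponent == 4.0

    def test_power_law_plus_constant(self):
        prof = _saxs_profile(QGRID, 1.0 * QGRID**-4.0 + 0.05)
        model = fit_saxs_background(prof)
        assert model.prefactor == pytest.approx(1.0, rel=0.01)
        assert model.constant == pytest.approx(0.05, rel=0.01)

    def test_free_alpha_recovers_exponent(self):
        prof = _saxs_profile(QGRID, 0.8 * QGRID**-3.2 + 1e-9)
        model = fit_saxs_background(prof, alpha="free")
        assert model.exponent == pytest.approx(3.2, rel=0.02)
        assert model.prefactor == pytest.approx(0.8, rel=0.05)

    def test_empty_low_q_window_rejected(self):
        q = np.linspace(0.05, 0.3, 100)  # no points below 0.03
        with pytest.raises(ValidationError, match="low-q"):
            fit_saxs_background(_saxs_profile(q, q**-4.0))

    def test_overlapping_windows_rejected(self):
        with pytest.raises(ValidationError, match="overlap"):
            fit_saxs_background(
                _saxs_profile(QGRID, QGRID**-4.0),
                low_q_window=(0.01, 0.2),
                high_q_window=(0.1, 0.3),
            )

    def test_background_only_truth_gives_near_zero_peak_free_fit(self):
        # generator example: peak only, no power law, no constant
        truth = default_saxs_truth(noise_fraction=0.0)
        peak_only = truth.replace(saxs_background=(0.0, 4.0, 0.0))
        prof, _ = generate_saxs_profile(peak_only, seed=0)
        model = fit_saxs_background(prof)
        # ≈ 0 relative to the peak intensity scale (the far Gaussian tail
        # leaves a ~1e-4 residue in the high-q constant window)
        peak_scale = prof.intensity.max()
        assert model.prefactor * prof.q.min() ** -4 < 1e-3 * peak_scale
        assert model.constant < 1e-3 * peak_scale


class TestSubtraction:
    def test_self_consistent_residual(self):
        prof = _saxs_profile(QGRID, 1.3 * QGRID**-4.0 + 0.02)
        model = fit_saxs_background(prof)
        resid = subtract_background(prof, model)
        assert abs(resid.intensity.mean()) < 1e-6 * prof.intensity.mean()

    def test_recovers_injected_peak(self):
        peak = gaussian(QGRID, 1.0, 0.157, 0.06) / QGRID**2
        prof = _saxs_profile(QGRID, 0.002 * QGRID**-4.0 + 0.5 + peak)
        model = fit_saxs_background(prof)
        resid = subtract_background(prof, model)
        sel = (QGRID > 0.1) & (QGRID < 0.22)
        np.testing.assert_allclose(resid.intensity[sel], peak[sel], rtol=0.01, atol=1e-4)

    def test_zero_model_is_identity(self):
        prof = _saxs_profile(QGRID, np.exp(-QGRID))
        model = SAXSBackgroundModel(prefactor=0.0, exponent=4.0, constant=0.0)
        out = subtract_background(prof, model)
        np.testing.assert_array_equal(out.intensity, prof.intensity)

    def test_negative_fraction_recorded(self):
        prof = _saxs_profile(QGRID, np.full(QGRID.size, 0.1))
        model = SAXSBackgroundModel(prefactor=0.0, exponent=4.0, constant=0.2)
        out = subtract_background(prof, model)
        assert out.diagnostics["frac_negative_after_subtraction"] == 1.0


class TestKratkyTransform:
    def test_inverse_square_is_flat(self):
        out = kratky_transform(_saxs_profile(QGRID, 1.0 / QGRID**2))
        np.testing.assert_allclose(out.intensity, 1.0, rtol=1e-12)

    def test_zero_stays_zero(self):
        out = kratky_transform(_saxs_profile(QGRID, np.zeros_like(QGRID)))
        np.testing.assert_array_equal(out.intensity, 0.0)

    def test_sigma_scaled_by_q_squared(self):
        prof = _saxs_profile(QGRID, np.ones_like(QGRID), sigma=np.ones_like(QGRID))
        out = kratky_transform(prof)
        np.testing.assert_allclose(out.sigma, QGRID**2, rtol=1e-14)

    def test_kratky_space_peak_round_trip(self):
        # a peak defined as Gaussian in q²I, taken to I by /q², transforms back
        intensity = gaussian(QGRID, 2.0, 0.157, 0.06) / QGRID**2
        out = kratky_transform(_saxs_profile(QGRID, intensity))
        assert QGRID[np.argmax(out.intensity)] == pytest.approx(0.157, abs=np.diff(QGRID)[0])
        np.testing.assert_allclose(out.intensity, gaussian(QGRID, 2.0, 0.157, 0.06), atol=1e-12)


class TestKratkyPeakFit:
    def test_noiseless_gaussian_recovered(self):
        kratky = _saxs_profile(QGRID, gaussian(QGRID, 1.0, 0.157, 0.06))
        peak = fit_kratky_peak(kratky)
        assert peak.center == pytest.approx(0.157, rel=1e-4)
        assert peak.fwhm == pytest.approx(0.06, rel=1e-3)
        assert not peak.ambiguous

    def test_tied_maxima_choose_lower_q_and_flag(self):
        q = np.linspace(0.05, 0.25, 201)
        y = np.zeros_like(q)
        y[50] = y[150] = 1.0  # two identical spikes
        peak = fit_kratky_peak(_saxs_profile(q, y), window=(0.05, 0.25))
        assert peak.ambiguous
        assert peak.center < q[100]

    def test_monotone_curve_has_no_peak(self):
        with pytest.raises(NoPeakError):
            fit_kratky_peak(_saxs_profile(QGRID, -QGRID), window=(0.05, 0.25))

    def test_bragg_identity_holds_exactly(self):
        kratky = _saxs_profile(QGRID, gaussian(QGRID, 1.0, 0.12, 0.05))
        peak = fit_kratky_peak(kratky)
        assert peak.d_cc * peak.center == pytest.approx(TWO_PI, rel=1e-14)


class TestCenterToCenter:
    def test_fibril_scale(self):
        assert center_to_center_distance(0.157) == pytest.approx(40.0203, abs=1e-3)

    def test_identity_point(self):
        assert center_to_center_distance(TWO_PI) == pytest.approx(1.0)

    def test_six_nm_correspondence(self):
        assert center_to_center_distance(0.1) == pytest.approx(62.8319, abs=1e-3)

    def test_domain_error(self):
        with pytest.raises(DomainError):
            center_to_center_distance(0.0)


class TestAnalyzeSAXS:
    def test_noiseless_full_pipeline(self, saxs_truth_noiseless, saxs_profile_noiseless):
        res = analyze_saxs(saxs_profile_noiseless)
        assert abs(res.d_cc - saxs_truth_noiseless.d_cc) / saxs_truth_noiseless.d_cc < 1e-3

    def test_one_percent_noise_within_two_percent(self):
        truth = default_saxs_truth(noise_fraction=0.01)
        profile, _ = generate_saxs_profile(truth, seed=42)
        res = analyze_saxs(profile)
        assert abs(res.d_cc - truth.d_cc) / truth.d_cc < 0.02

    def test_background_only_raises_no_peak(self):
        prof = _saxs_profile(QGRID, 0.002 * QGRID**-4.0 + 0.5)
        with pytest.raises(NoPeakError, match="kratky-peak"):
            analyze_saxs(prof)

    def test_intensity_scale_invariance(self, saxs_profile_noiseless):
        r1 = analyze_saxs(saxs_profile_noiseless)
        r2 = analyze_saxs(saxs_profile_noiseless.scaled(13.7))
        assert r2.peak.center == pytest.approx(r1.peak.center, rel=1e-9)
        assert r2.d_cc == pytest.approx(r1.d_cc, rel=1e-9)

    def test_monotone_mapping_of_spacing(self, saxs_truth_noiseless):
        f = 1.22
        qp, fw, amp = saxs_truth_noiseless.saxs_peak
        shifted = saxs_truth_noiseless.replace(saxs_peak=(qp / f, fw, amp))
        p1, _ = generate_saxs_profile(saxs_truth_noiseless, seed=0)
        p2, _ = generate_saxs_profile(shifted, seed=0)
        r1, r2 = analyze_saxs(p1), analyze_saxs(p2)
        assert r2.peak.center == pytest.approx(r1.peak.center / f, rel=0.005)
        assert r2.d_cc == pytest.approx(r1.d_cc * f, rel=0.005)

    def test_recovery_over_seeds(self):
        truth = default_saxs_truth(noise_fraction=0.01)
        errs = []
        for seed in range(20):
            profile, _ = generate_saxs_profile(truth, seed=seed)
            errs.append(abs(analyze_saxs(profile).d_cc - truth.d_cc) / truth.d_cc)
        assert np.median(errs) < 0.02

    def test_nm_reporting_consistency(self, saxs_profile_noiseless):
        res = analyze_saxs(saxs_profile_noiseless)
        assert res.d_cc_nm == pytest.approx(res.d_cc / 10.0, rel=1e-14)
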