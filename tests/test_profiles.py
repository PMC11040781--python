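"""Profile container, text I/O, normalization and replicate reduction."""

import numpy as np
import pytest

from cellscatter import (
    DetectorGeometry,
    ParseError,
    ScatteringProfile,
    StateError,
    ValidationError,
    average_profiles,
    normalize_exposure,
    read_profile,
    subtract_empty_holder,
    write_profile,
)


class TestContainer:
    def test_rejects_nonpositive_q(self):
        with pytest.raises(ValidationError):
            ScatteringProfile(q=np.linspace(0, 1, 10), intensity=np.ones(10))

    def test_rejects_short_and_mismatched(self):
        with pytest.raises(ValidationError):
            ScatteringProfile(q=np.linspace(0.1, 1, 5), intensity=np.ones(5))
        with pytest.raises(ValidationError):
            ScatteringProfile(q=np.linspace(0.1, 1, 10), intensity=np.ones(9))

    def test_rejects_negative_sigma(self):
        q = np.linspace(0.1, 1, 10)
        with pytest.raises(ValidationError):
            ScatteringProfile(q=q, intensity=np.ones(10), sigma=-np.ones(10))


class TestIO:
    def test_round_trip_full_precision(self, simple_profile, tmp_path):
        path = tmp_path / "p.dat"
        write_profile(simple_profile, path)
        back = read_profile(path)
        np.testing.assert_array_equal(back.q, simple_profile.q)
        np.testing.assert_array_equal(back.intensity, simple_profile.intensity)
        np.testing.assert_array_equal(back.sigma, simple_profile.sigma)
        assert back.modality == "SAXS"
        assert back.sample_id == "s1"
        assert back.condition == "reference"
        assert back.replicate == 1
        assert back.normalized

    def test_three_column_file(self, tmp_path):
        path = tmp_path / "p.dat"
        rows = "\n".join(f"{0.01 * (k + 1)} {k} {0.1}" for k in range(100))
        path.write_text("# comment\n" + rows + "\n")
        prof = read_profile(path)
        assert len(prof) == 100
        assert prof.sigma is not None

    def test_no_sigma_writes_two_columns(self, tmp_path):
        q = np.linspace(0.1, 1, 10)
        prof = ScatteringProfile(q=q, intensity=q**2, modality="WAXS")
        path = write_profile(prof, tmp_path / "p.dat")
        ncols = len(path.read_text().strip().splitlines()[-1].split())
        assert ncols == 2
        assert read_profile(path).sigma is None

    def test_descending_q_sorted_with_intensities(self, tmp_path):
        path = tmp_path / "p.dat"
        q = np.linspace(1.0, 0.1, 10)
        path.write_text("\n".join(f"{qv},{qv * 2}" for qv in q))
        prof = read_profile(path)
        assert np.all(np.diff(prof.q) > 0)
        np.testing.assert_allclose(prof.intensity, prof.q * 2)

    def test_malformed_row_names_line(self, tmp_path):
        path = tmp_path / "p.dat"
        path.write_text("0.1 1\n0.2 oops\n0.3 3\n")
        with pytest.raises(ParseError, match=":2:"):
            read_profile(path)

    def test_duplicate_q_rejected(self, tmp_path):
        path = tmp_path / "p.dat"
        path.write_text("\n".join(f"{qv} 1" for qv in [0.1, 0.2, 0.2, 0.3] * 3))
        with pytest.raises(ValidationError, match="duplicate"):
            read_profile(path)


class TestNormalizeExposure:
    def test_divides_by_exposure_times_flux(self):
        geo = DetectorGeometry(
            distance=600, pixel_size=0.075, beam_center=(0, 0), exposure=1000.0, flux_factor=4.5
        )
        q = np.linspace(0.01, 0.3, 10)
        prof = ScatteringProfile(q=q, intensity=np.full(10, 9000.0))
        out = normalize_exposure(prof, geo)
        np.testing.assert_allclose(out.intensity, 2.0)

    def test_waxs_reference_beam(self):
        # the wide-angle reference exposure of the emulated instrument
        geo = DetectorGeometry(
            distance=55, pixel_size=0.075, beam_center=(0, 0), exposure=2400.0, flux_factor=1.0
        )
        q = np.linspace(0.5, 2.5, 10)
        prof = ScatteringProfile(q=q, intensity=np.full(10, 2400.0), modality="WAXS")
        out = normalize_exposure(prof, geo)
        np.testing.assert_allclose(out.intensity, 1.0)

    def test_double_normalization_rejected(self):
        geo = DetectorGeometry(distance=600, pixel_size=0.075, beam_center=(0, 0), exposure=10.0)
        prof = ScatteringProfile(q=np.linspace(0.01, 0.3, 10), intensity=np.ones(10))
        once = normalize_exposure(prof, geo)
        with pytest.raises(StateError):
            normalize_exposure(once, geo)


class TestEmptyHolderSubtraction:
    @staticmethod
    def _prof(q, i, **kw):
        kw.setdefault("normalized", True)
        return ScatteringProfile(q=q, intensity=i, **kw)

    def test_self_subtraction_is_zero(self, simple_profile):
        out = subtract_empty_holder(simple_profile, simple_profile, scale=1.0)
        np.testing.assert_allclose(out.intensity, 0.0, atol=1e-12)

    def test_scale_zero_is_identity(self, simple_profile):
        out = subtract_empty_holder(simple_profile, simple_profile, scale=0.0)
        np.testing.assert_array_equal(out.intensity, simple_profile.intensity)

    def test_recovers_truth_from_sum(self):
        q = np.linspace(0.02, 0.3, 200)
        truth = np.exp(-30 * q)
        empty = 0.3 + 0.1 * q
        qe = np.linspace(0.015, 0.32, 157)  # different grid forces interpolation
        sample = self._prof(q, truth + np.interp(q, qe, 0.3 + 0.1 * qe))
        empty_prof = self._prof(qe, 0.3 + 0.1 * qe)
        out = subtract_empty_holder(sample, empty_prof)
        np.testing.assert_allclose(out.intensity, truth, rtol=1e-3, atol=1e-6)

    def test_readding_background_restores_input(self, simple_profile):
        empty = self._prof(simple_profile.q, 0.1 + 0.2 * simple_profile.q)
        out = subtract_empty_holder(simple_profile, empty, scale=0.7)
        restored = out.intensity + 0.7 * empty.intensity
        np.testing.assert_allclose(restored, simple_profile.intensity, rtol=1e-12)

    def test_requires_per_second_units(self, simple_profile):
        raw = ScatteringProfile(
            q=simple_profile.q, intensity=simple_profile.intensity, normalized=False
        )
        with pytest.raises(StateError):
            subtract_empty_holder(raw, simple_profile)

    def test_insufficient_overlap_rejected(self, simple_profile):
        empty = self._prof(np.linspace(0.4, 0.5, 20), np.ones(20))
        with pytest.raises(ValidationError, match="90%"):
            subtract_empty_holder(simple_profile, empty)

    def test_negative_values_retained_and_counted(self, simple_profile):
        empty = self._prof(simple_profile.q, simple_profile.intensity + 1.0)
        out = subtract_empty_holder(simple_profile, empty)
        assert np.all(out.intensity < 0)
        assert out.diagnostics["n_negative"] == len(out)

    def test_sigma_added_in_quadrature(self, simple_profile):
        empty = self._prof(
            simple_profile.q,
            np.zeros_like(simple_profile.q),
            sigma=np.full_like(simple_profile.q, 0.02),
        )
        out = subtract_empty_holder(simple_profile, empty)
        np.testing.assert_allclose(out.sigma, np.hypot(0.01, 0.02), rtol=1e-6)


class TestAverageProfiles:
    def _prof(self, value, modality="SAXS"):
        q = np.linspace(0.05, 0.5, 50)
        return ScatteringProfile(q=q, intensity=np.full(50, float(value)), modality=modality)

    def test_identical_profiles_mean_equal_sigma_zero(self):
        out = average_profiles([self._prof(2.0)] * 3)
        np.testing.assert_allclose(out.intensity, 2.0)
        np.testing.assert_allclose(out.sigma, 0.0, atol=1e-14)

    def test_closed_form_mean_and_sd(self):
        out = average_profiles([self._prof(v) for v in (1, 2, 3)])
        np.testing.assert_allclose(out.intensity, 2.0)
        np.testing.assert_allclose(out.sigma, 1.0)

    def test_mean_of_noisy_replicates_beats_each(self):
        rng = np.random.default_rng(42)
        q = np.linspace(0.05, 0.5, 200)
        truth = np.exp(-3 * q)
        reps = [
            ScatteringProfile(q=q, intensity=truth * (1 + 0.05 * rng.standard_normal(q.size)))
            for _ in range(3)
        ]
        avg = average_profiles(reps)
        rms = lambda p: np.sqrt(np.mean((p.intensity - truth) ** 2))
        assert rms(avg) < min(rms(p) for p in reps)

    def test_single_profile_rejected(self):
        with pytest.raises(ValidationError, match="pass"):
            average_profiles([self._prof(1.0)])

    def test_mixed_modality_rejected(self):
        with pytest.raises(ValidationError, match="modality"):
            average_profiles([self._prof(1.0), self._prof(1.0, modality="WAXS")])
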