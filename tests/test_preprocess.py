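import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from rppgvitals import preprocess as pp
from rppgvitals.errors import DegenerateSignalError, ValidationError

finite_series = hnp.arrays(
    float, st.integers(8, 64),
    elements=st.floats(-100, 100, allow_nan=False),
)


class TestNormalise:
    def test_examples(self):
        np.testing.assert_allclose(pp.l2_normalise([3, 4]), [0.6, 0.8])
        np.testing.assert_allclose(pp.l2_normalise([1]), [1.0])

    def test_unit_norm(self, rng):
        out = pp.l2_normalise(rng.normal(size=100))
        assert np.linalg.norm(out) == pytest.approx(1.0, abs=1e-12)

    def test_zero_signal_rejected(self):
        with pytest.raises(DegenerateSignalError):
            pp.l2_normalise(np.zeros(5))


class TestInterpolate:
    def test_linear_function_stays_linear(self):
        np.testing.assert_allclose(
            pp.interpolate_even([0, 1, 3], [0, 1, 3]), [0, 1.5, 3]
        )

    def test_even_grid_is_identity(self):
        x = np.array([2.0, -1.0, 4.0, 0.0])
        np.testing.assert_allclose(pp.interpolate_even(x, [0, 10, 20, 30]), x)

    def test_matches_piecewise_linear_oracle(self):
        x, t = np.array([0.0, 10.0, 10.0]), np.array([0.0, 1.0, 2.0])
        grid = np.linspace(0, 2, 3)
        expected = [np.interp(g, t, x) for g in grid]  # brute-force evaluation
        np.testing.assert_allclose(pp.interpolate_even(x, t), expected)

    def test_duplicate_timestamps_rejected(self):
        with pytest.raises(ValidationError):
            pp.interpolate_even([1, 2, 3], [0, 1, 1])


class TestHamming:
    def test_endpoint_attenuation(self):
        out = pp.apply_hamming([1.0, 1.0, 1.0])
        np.testing.assert_allclose(out, [0.08, 1.0, 0.08], atol=1e-12)

    def test_matches_window_formula(self):
        L = 5
        w = 0.54 - 0.46 * np.cos(2 * np.pi * np.arange(L) / (L - 1))
        np.testing.assert_allclose(pp.apply_hamming(np.full(L, 2.0)), 2 * w)

    def test_length_one_rejected(self):
        with pytest.raises(DegenerateSignalError):
            pp.apply_hamming([1.0])


class TestFilters:
    def test_median_examples(self):
        np.testing.assert_array_equal(pp.median_filter([1, 9, 1], 3), [1, 1, 1])
        x = np.array([4.0, 2.0, 7.0])
        np.testing.assert_array_equal(pp.median_filter(x, 1), x)

    def test_median_matches_bruteforce_oracle(self, rng):
        x = rng.normal(size=50)
        k = 3
        padded = np.concatenate([[0.0], x, [0.0]])  # zero-padded edges
        expected = [np.median(padded[i : i + k]) for i in range(len(x))]
        np.testing.assert_allclose(pp.median_filter(x, k), expected)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValidationError):
            pp.median_filter([1, 2, 3], 2)

    def test_smooth_examples(self):
        c = np.full(6, 3.3)
        np.testing.assert_allclose(pp.smooth(c), c)
        assert pp.smooth([0, 0, 5, 0, 0], 5)[2] == 1.0

    def test_smooth_matches_bruteforce_oracle(self, rng):
        x = rng.normal(size=40)
        w = 5
        expected = [x[max(0, i - 2) : i + 3].mean() for i in range(len(x))]
        np.testing.assert_allclose(pp.smooth(x, w), expected)


class TestDetrendAndUpsample:
    def test_line_removed_exactly(self):
        np.testing.assert_allclose(pp.detrend_linear([1, 2, 3, 4]), np.zeros(4), atol=1e-12)

    def test_added_line_is_removed_exactly(self):
        # linearity: adding any straight line must not change the result
        # (a sampled sinusoid itself is NOT exactly orthogonal to a line on a
        # finite grid, so only the difference is pinned down to 1e-9)
        t = np.arange(100)
        x = np.sin(2 * np.pi * t / 20)  # five full periods
        detrended = pp.detrend_linear(x)
        np.testing.assert_allclose(
            pp.detrend_linear(x + 0.5 * t + 3), detrended, atol=1e-9
        )
        assert detrended.mean() == pytest.approx(0.0, abs=1e-12)
        assert np.polyfit(t, detrended, 1)[0] == pytest.approx(0.0, abs=1e-12)

    def test_upsample_doubles_length_and_preserves_constant(self):
        assert len(pp.upsample_fft(np.arange(128.0))) == 256
        out = pp.upsample_fft(np.full(32, 7.0))
        np.testing.assert_allclose(out, 7.0, atol=1e-9)

    def test_upsample_roundtrip_on_bandlimited_tone(self):
        t = np.arange(64)
        x = np.sin(2 * np.pi * 4 * t / 64)
        np.testing.assert_allclose(pp.upsample_fft(x, 2)[::2], x, atol=1e-6)

    def test_bad_factor_rejected(self):
        with pytest.raises(ValidationError):
            pp.upsample_fft([1, 2], 0)


class TestTechniqueRegistry:
    timestamps = np.arange(32) * 100.0

    def test_type1_is_identity(self, rng):
        x = rng.normal(size=32)
        np.testing.assert_array_equal(pp.apply_technique(x, self.timestamps, 1), x)

    def test_type2_is_normalise(self):
        out = pp.apply_technique(np.array([3.0, 4.0]), np.array([0.0, 100.0]), 2)
        np.testing.assert_allclose(out, [0.6, 0.8])

    @pytest.mark.parametrize("type_id", [3, 4, 5, 6, 7])
    def test_all_types_finite_and_unit_norm(self, type_id, rng):
        x = rng.normal(size=32) + 50
        out = pp.apply_technique(x, self.timestamps, type_id)
        assert np.all(np.isfinite(out))
        assert np.linalg.norm(out) == pytest.approx(1.0, abs=1e-9)

    def test_type6_removes_trend(self, rng):
        x = rng.normal(size=64) + 0.3 * np.arange(64)
        out = pp.apply_technique(x, np.arange(64) * 50.0, 6)
        slope = np.polyfit(np.arange(len(out)), out, 1)[0]
        # hamming tapering dominates; the fitted slope must be tiny vs signal scale
        assert abs(slope) < 1e-3

    def test_type7_doubles_length(self, rng):
        x = rng.normal(size=30)
        assert len(pp.apply_technique(x, np.arange(30) * 100.0, 7)) == 60

    def test_unknown_type_rejected(self):
        with pytest.raises(ValidationError):
            pp.apply_technique([1.0, 2.0], [0.0, 1.0], 9)

    @given(finite_series)
    def test_registry_outputs_finite(self, x):
        t = np.arange(len(x)) * 50.0
        for type_id in (1, 2, 5, 6):
            try:
                out = pp.apply_technique(x, t, type_id)
            except DegenerateSignalError:
                continue  # all-zero draws cannot be normalised
            assert np.all(np.isfinite(out))

    @pytest.mark.parametrize("fps,expected", [(30, 6), (15, 6), (12, 7), (3, 7)])
    def test_auto_selection(self, fps, expected):
        assert pp.select_technique_auto(fps) == expected
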