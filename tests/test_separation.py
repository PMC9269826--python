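import numpy as np
import pytest

import rppgvitals as rv
from rppgvitals.errors import ValidationError
from rppgvitals.io import ChannelSeries
from rppgvitals.jade import jade
from rppgvitals.separation import Candidate, SeparationSpec, align_channels, separate


def two_source_mixture(T=900, fs=30.0):
    """Well-conditioned 2x2 mixture of two in-band tones."""
    t = np.arange(T) / fs
    sources = np.vstack([np.sin(2 * np.pi * 1.2 * t), np.sin(2 * np.pi * 0.5 * t)])
    A = np.array([[1.0, 0.6], [0.4, 1.0]])
    return A @ sources, sources


def best_match_correlations(components, sources):
    """For each source, the best |Pearson r| over all components (brute force)."""
    out = []
    for s in sources:
        out.append(max(abs(np.corrcoef(c, s)[0, 1]) for c in components))
    return out


class TestSeparate:
    def test_none_returns_inputs(self, rng):
        X = rng.normal(size=(2, 50))
        cands = separate(X, SeparationSpec(method="none"))
        assert len(cands) == 2
        np.testing.assert_array_equal(np.vstack([c.values for c in cands]), X)

    @pytest.mark.parametrize("method", ["fastica", "jade"])
    def test_ica_recovers_two_tone_mixture(self, method):
        X, sources = two_source_mixture()
        cands = separate(X, SeparationSpec(method=method, seed=0))
        comps = [c.values for c in cands]
        assert all(r >= 0.95 for r in best_match_correlations(comps, sources))

    def test_pca_orders_by_variance_and_conserves_it(self, rng):
        a = 2.0 * rng.normal(size=400)  # variance 4
        b = rng.normal(size=400)  # variance 1
        X = np.vstack([a, b])
        cands = separate(X, SeparationSpec(method="pca"))
        variances = [c.values.var() for c in cands]
        assert variances[0] >= variances[1]
        assert sum(variances) == pytest.approx(X.var(axis=1, ddof=0).sum(), rel=1e-6)

    def test_pca_ica_recovers_mixture(self):
        X, sources = two_source_mixture()
        cands = separate(X, SeparationSpec(method="pca_ica", seed=0))
        comps = [c.values for c in cands]
        assert all(r >= 0.95 for r in best_match_correlations(comps, sources))

    def test_candidate_count_is_n(self, rng):
        X = rng.normal(size=(5, 200))
        for method in ("none", "fastica", "pca", "pca_ica", "jade"):
            assert len(separate(X, SeparationSpec(method=method, seed=1))) == 5

    def test_deterministic_given_seed(self, rng):
        X = rng.normal(size=(3, 300))
        spec = SeparationSpec(method="fastica", seed=7)
        out1 = separate(X, spec)
        out2 = separate(X, SeparationSpec(method="fastica", seed=7))
        for a, b in zip(out1, out2):
            np.testing.assert_array_equal(a.values, b.values)

    def test_spectral_embedding_returns_series(self, rng):
        X, _ = two_source_mixture(T=300)
        cands = separate(X, SeparationSpec(method="spectral_embedding", seed=0))
        assert all(len(c.values) == 300 and c.finite for c in cands)

    def test_repeats_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            spec = SeparationSpec(method="fastica", repeats=5)
        assert spec.repeats == 3

    def test_per_channel_mode_tags_channels(self, rng):
        X = rng.normal(size=(2, 100))
        cands = separate(X, SeparationSpec(method="none", mode="per_channel"),
                         labels=["R", "G"])
        assert [c.provenance for c in cands] == [
            "none[per_channel]:R", "none[per_channel]:G",
        ]

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValidationError):
            separate(rng.normal(size=(5, 4)), SeparationSpec())


class TestJadeDirect:
    def test_jade_needs_matrix(self):
        with pytest.raises(ValidationError):
            jade(np.arange(10.0).reshape(10, 1).T[0])

    def test_three_source_recovery(self, rng):
        t = np.arange(1200) / 30
        S = np.vstack([
            np.sin(2 * np.pi * 1.1 * t),
            np.sign(np.sin(2 * np.pi * 0.4 * t)),
            rng.uniform(-1, 1, len(t)),
        ])
        A = rng.normal(size=(3, 3)) + np.eye(3)
        comps = jade(A @ S)
        assert all(r >= 0.9 for r in best_match_correlations(comps, S[:2]))


class TestAlignChannels:
    def _region(self, ts_colour, ts_ir, f=1.2):
        region = {}
        for name in ("R", "G", "B", "Gy"):
            region[name] = ChannelSeries(
                timestamps=ts_colour,
                values=np.sin(2 * np.pi * f * ts_colour / 1000),
                channel=name,
            )
        region["IR"] = ChannelSeries(
            timestamps=ts_ir, values=np.sin(2 * np.pi * f * ts_ir / 1000), channel="IR"
        )
        return region

    def test_identical_timestamps_pass_through(self):
        ts = np.arange(0, 15000, 1000 / 30)
        region = self._region(ts, ts.copy())
        X, grid, labels = align_channels(region, (0, 15000))
        np.testing.assert_allclose(X[labels.index("IR")], region["IR"].values, atol=1e-9)

    def test_mixed_rates_share_colour_length(self):
        ts_c = np.arange(0, 15000, 1000 / 30)
        ts_i = np.arange(0, 15000, 1000 / 15)
        X, grid, _ = align_channels(self._region(ts_c, ts_i), (0, 15000))
        assert X.shape == (5, len(ts_c))

    def test_resampled_ir_correlates_with_colour(self):
        ts_c = np.arange(0, 15000, 1000 / 30)
        ts_i = np.arange(0, 15000, 1000 / 12)
        X, _, labels = align_channels(self._region(ts_c, ts_i), (0, 15000))
        r = np.corrcoef(X[labels.index("R")], X[labels.index("IR")])[0, 1]
        assert r >= 0.99

    def test_sparse_stream_rejected(self):
        ts_c = np.arange(0, 15000, 1000 / 30)
        region = self._region(ts_c, np.array([0.0]))
        with pytest.raises(ValidationError):
            align_channels(region, (0, 15000))
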