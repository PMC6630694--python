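import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from pcgkit.features import (FEATURE_NAMES, FeatureConfig, extract_features,
                             freq_features, mfcc_features, preemphasize,
                             time_features)


class TestTimeFeatures:
    def test_small_example(self):
        vals = dict(zip(FEATURE_NAMES[:10], time_features([1, 2, 3, 4])))
        assert vals["mean"] == 2.5
        assert vals["median"] == 2.5
        assert vals["p25"] == 1.75  # linear interpolation rule
        assert vals["p75"] == 3.25
        assert vals["iqr"] == vals["p75"] - vals["p25"]

    def test_symmetric_sample_zero_skewness(self):
        assert time_features([-2, -1, 1, 2])[7] == pytest.approx(0.0, abs=1e-12)

    def test_gaussian_excess_kurtosis_near_zero(self):
        x = np.random.default_rng(42).standard_normal(100_000)
        assert time_features(x)[8] == pytest.approx(0.0, abs=0.05)

    def test_constant_cycle_degenerate_moments(self):
        vals = time_features(np.full(100, 0.7))
        names = FEATURE_NAMES[:10]
        d = dict(zip(names, vals))
        assert d["skewness"] == 0.0
        assert d["kurtosis"] == 0.0
        assert d["shannon_entropy"] == 0.0
        assert d["std"] == 0.0

    def test_matches_straight_line_oracles(self, rng):
        x = rng.standard_normal(500).tolist()
        vals = dict(zip(FEATURE_NAMES[:10], time_features(x, FeatureConfig())))
        assert vals["mean"] == pytest.approx(oracles.mean(x), abs=1e-8)
        assert vals["std"] == pytest.approx(oracles.std_n_minus_1(x), abs=1e-8)
        assert vals["mad"] == pytest.approx(oracles.mean_abs_dev(x), abs=1e-8)
        assert vals["p25"] == pytest.approx(oracles.percentile_linear(x, 25), abs=1e-8)
        assert vals["p75"] == pytest.approx(oracles.percentile_linear(x, 75), abs=1e-8)
        assert vals["skewness"] == pytest.approx(oracles.skewness(x), abs=1e-8)
        assert vals["kurtosis"] == pytest.approx(oracles.excess_kurtosis(x), abs=1e-8)
        assert vals["shannon_entropy"] == pytest.approx(
            oracles.shannon_entropy_hist(x, 32), abs=1e-8)


class TestFreqFeatures:
    def _tone(self, freq, dur=1.0, fs=2000):
        return np.sin(2 * np.pi * freq * np.arange(int(dur * fs)) / fs)

    def test_pure_tone_fmax_and_ratio(self):
        sen, f_max, _mag, ratio = freq_features(self._tone(100), sample_rate_hz=2000)
        assert f_max == pytest.approx(100.0)
        assert ratio >= 0.99
        assert sen < 0.1

    def test_white_noise_high_entropy(self, rng):
        x = rng.standard_normal(2000)
        sen = freq_features(x, sample_rate_hz=2000)[0]
        assert sen > 0.9

    def test_matches_straight_line_oracles(self, rng):
        x = rng.standard_normal(1000)
        sen, f_max, mag, ratio = freq_features(x, sample_rate_hz=2000)
        assert sen == pytest.approx(oracles.spectral_entropy(x), abs=1e-8)
        assert f_max == pytest.approx(oracles.f_max(x, 2000), abs=1e-8)
        assert ratio == pytest.approx(oracles.energy_ratio(x, 2000, 10.0), abs=1e-8)

    def test_zero_cycle_rejected(self):
        with pytest.raises(ValueError):
            freq_features(np.zeros(100), sample_rate_hz=2000)


class TestMFCC:
    def test_preemphasis_formula(self):
        assert np.allclose(preemphasize(np.array([1.0, 1.0, 1.0])),
                           [1.0, 0.05, 0.05])

    def test_matches_brute_force_oracle(self, rng):
        cfg = FeatureConfig(mfcc_whole_cycle=True)
        x = rng.standard_normal(300)
        got = mfcc_features(x, cfg, sample_rate_hz=2000)
        expected = oracles.mfcc_single_frame(
            preemphasize(x, 0.95), 2000, cfg.mfcc_n_mel_filters,
            cfg.mfcc_fmin_hz, cfg.mfcc_fmax_hz, 256, 13, cfg.log_floor)
        assert np.max(np.abs(got - np.asarray(expected))) < 1e-8

    def test_multiframe_matches_frame_loop(self, rng):
        cfg = FeatureConfig()
        x = rng.standard_normal(1200)
        got = mfcc_features(x, cfg, sample_rate_hz=2000)
        pre = preemphasize(x, 0.95)
        frames = [pre[i * 20:i * 20 + 50] for i in range(1 + (1200 - 50) // 20)]
        per_frame = [oracles.mfcc_single_frame(f, 2000, 26, 20.0, 600.0, 256,
                                               13, cfg.log_floor)
                     for f in frames]
        assert np.max(np.abs(got - np.mean(per_frame, axis=0))) < 1e-8

    def test_scaling_only_shifts_zeroth_coefficient(self, rng):
        x = 0.5 + 0.2 * rng.standard_normal(600)  # keep energies above the floor
        a = mfcc_features(x, sample_rate_hz=2000)
        b = mfcc_features(2 * x, sample_rate_hz=2000)
        assert np.max(np.abs(a - b)) < 1e-6

    def test_too_short_cycle_rejected(self):
        with pytest.raises(ValueError):
            mfcc_features(np.ones(16), sample_rate_hz=2000)


class TestExtractFeatures:
    def test_27_finite_named_values(self, normal_record):
        from pcgkit.pipeline import record_to_cycles
        cyc = record_to_cycles(normal_record)[0]
        fv = extract_features(cyc)
        assert len(fv) == 27
        assert len(set(fv.names)) == 27
        assert fv.names == FEATURE_NAMES
        assert np.all(np.isfinite(fv.values))

    def test_deterministic(self, rng):
        x = rng.standard_normal(900)
        a = extract_features(x, sample_rate_hz=2000)
        b = extract_features(x, sample_rate_hz=2000)
        assert np.array_equal(a.values, b.values)

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(scale=st.floats(0.1, 10.0), seed=st.integers(0, 100))
    def test_scale_behaviour(self, scale, seed):
        """Location/scale features scale linearly; shape features and the
        spectral peak are scale-invariant."""
        x = np.random.default_rng(seed).standard_normal(400)
        base = extract_features(x, sample_rate_hz=2000).as_dict()
        scaled = extract_features(scale * x, sample_rate_hz=2000).as_dict()
        for name in ("std", "mad", "iqr"):
            assert scaled[name] == pytest.approx(scale * base[name], rel=1e-9)
        assert scaled["mean"] == pytest.approx(scale * base["mean"], rel=1e-6,
                                               abs=1e-12)
        for name in ("skewness", "kurtosis", "shannon_entropy",
                     "spectral_entropy", "f_max", "energy_ratio"):
            assert scaled[name] == pytest.approx(base[name], rel=1e-6, abs=1e-9)

    def test_batch_order_independence(self, rng):
        rows = [rng.standard_normal(500) for _ in range(5)]
        feats = [extract_features(r, sample_rate_hz=2000).values for r in rows]
        perm = [2, 0, 4, 1, 3]
        feats_perm = [extract_features(rows[i], sample_rate_hz=2000).values
                      for i in perm]
        for j, i in enumerate(perm):
            assert np.array_equal(feats_perm[j], feats[i])
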