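"""C0 complexity, sample entropy and wavelet features against oracles."""

import math

import numpy as np
import pytest
import pywt
from hypothesis import given, strategies as st

from gaitnld import Group
from gaitnld.nld_features import (
    FeatureConfig,
    c0_complexity,
    extract_all,
    sample_entropy,
    spectral_regular_part,
    wavelet_coeff_feature,
    wavelet_energy_profile,
)

from conftest import make_record


def sampen_oracle(x, m, r):
    """Exhaustive O(N^2) pair count, self-matches excluded."""
    n = len(x)
    nt = n - m
    b = a = 0
    for i in range(nt):
        for j in range(i + 1, nt):
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) <= r:
                b += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    a += 1
    if a == 0 or b == 0:
        return math.inf
    return -math.log(a / b)


class TestSpectralRegularPart:
    def test_constant_fully_regular(self):
        x = np.full(32, 3.7)
        dec = spectral_regular_part(x, 5.0)
        np.testing.assert_allclose(dec.regular_part, x, atol=1e-12)
        assert dec.kept_bins == 1

    def test_exact_bin_sinusoid_keeps_conjugate_pair(self):
        t = np.arange(256)
        x = np.sin(2 * np.pi * 7 * t / 256)
        dec = spectral_regular_part(x, 5.0)
        assert dec.kept_bins == 2
        np.testing.assert_allclose(dec.regular_part, x, atol=1e-10)

    def test_white_noise_keeps_few_bins(self):
        # broadband: power spread thinly, few bins exceed 5x the mean
        for seed in range(100):
            x = np.random.default_rng(seed).standard_normal(1024)
            dec = spectral_regular_part(x, 5.0)
            assert dec.kept_bins < 1024 // 8

    def test_bad_threshold_errors(self):
        with pytest.raises(ValueError):
            spectral_regular_part(np.ones(16), 0.0)


class TestC0Complexity:
    def test_constant_is_zero(self):
        assert c0_complexity(np.full(64, 2.0)) == 0.0

    def test_exact_bin_sinusoid_near_zero(self):
        t = np.arange(256)
        assert c0_complexity(np.sin(2 * np.pi * 7 * t / 256), 5.0) < 1e-10

    def test_white_noise_near_one(self):
        vals = [
            c0_complexity(np.random.default_rng(s).standard_normal(1024), 5.0)
            for s in range(100)
        ]
        assert 0.8 < np.mean(vals) <= 1.0

    @given(st.integers(0, 50))
    def test_bounds_and_monotone_in_r(self, seed):
        x = np.random.default_rng(seed).normal(1.0, 0.3, size=128)
        prev = -1.0
        for r in (0.5, 1.0, 2.0, 5.0, 10.0, 50.0):
            c = c0_complexity(x, r)
            assert 0.0 <= c <= 1.0
            assert c >= prev - 1e-12  # larger threshold keeps fewer bins
            prev = c

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            c0_complexity(np.zeros(16))


class TestSampleEntropy:
    def test_constant_is_zero(self):
        assert sample_entropy(np.full(30, 1.5), 2, 0.1) == 0.0

    def test_periodic_sequence_matches_oracle(self):
        x = [1, 2, 3, 1, 2, 3, 1, 2, 3]
        expected = sampen_oracle(x, 2, 0.5)
        assert expected == 0.0  # perfectly repeating template
        assert sample_entropy(np.array(x, float), 2, 0.5) == expected

    @pytest.mark.parametrize("n", [10, 25, 50, 100, 200])
    @pytest.mark.parametrize("m", [1, 2])
    def test_exact_agreement_with_exhaustive_oracle(self, n, m):
        rng = np.random.default_rng(n * 10 + m)
        for _ in range(3):
            x = rng.normal(size=n)
            r = 0.2 * float(np.std(x, ddof=1))
            assert sample_entropy(x, m, r) == sampen_oracle(list(x), m, r)

    def test_shuffled_sine_no_less_entropic_than_sine(self):
        t = np.arange(512)
        sine = np.sin(2 * np.pi * 4 * t / 512)
        se_sine = sample_entropy(sine)
        wins = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            se_shuf = sample_entropy(rng.permutation(sine))
            wins += se_shuf >= se_sine
        assert wins == 100

    def test_bad_m_errors(self):
        with pytest.raises(ValueError):
            sample_entropy(np.ones(10), 0, 0.1)

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            sample_entropy(np.ones(3), 2, 0.1)


class TestWaveletFeatures:
    @staticmethod
    def _coeff_shapes(n=320, levels=3):
        template = pywt.wavedec(np.zeros(n), "db4", level=levels, mode="periodization")
        return [c.shape for c in template]

    def test_single_band_energy_zero_entropy(self):
        # all energy in the approximation band
        shapes = self._coeff_shapes()
        coeffs = [np.ones(shapes[0])] + [np.zeros(s) for s in shapes[1:]]
        x = pywt.waverec(coeffs, "db4", mode="periodization")
        prof = wavelet_energy_profile(x, "db4", 3)
        assert prof.entropy < 1e-8
        assert prof.relative_energies.sum() == pytest.approx(1.0, abs=1e-12)

    def test_uniform_band_energy_ln_j_entropy(self):
        # a signal whose 4 bands carry exactly equal energy
        rng = np.random.default_rng(0)
        coeffs = []
        for s in self._coeff_shapes():
            c = rng.standard_normal(s)
            coeffs.append(c / np.linalg.norm(c))  # unit energy per band
        x = pywt.waverec(coeffs, "db4", mode="periodization")
        prof = wavelet_energy_profile(x, "db4", 3)
        assert prof.n_levels == 4
        assert prof.entropy == pytest.approx(math.log(4), abs=1e-8)

    def test_entropy_bounded_by_ln_bands_and_probs_sum_to_one(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            x = rng.normal(1.0, 0.2, size=256)
            prof = wavelet_energy_profile(x, "db4", 4)
            assert prof.relative_energies.sum() == pytest.approx(1.0, abs=1e-12)
            assert 0.0 <= prof.entropy <= math.log(prof.n_levels) + 1e-12

    def test_noise_more_entropic_than_slow_sinusoid(self):
        t = np.arange(512)
        sine = 1 + 0.1 * np.sin(2 * np.pi * 2 * t / 512)
        se_sine = wavelet_energy_profile(sine, "db4", 4).entropy
        wins = 0
        for seed in range(100):
            noise = np.random.default_rng(seed).standard_normal(512)
            wins += wavelet_energy_profile(noise, "db4", 4).entropy > se_sine
        assert wins >= 99

    def test_excess_levels_error(self):
        with pytest.raises(ValueError, match="exceeds"):
            wavelet_energy_profile(np.ones(32), "db4", 6)

    def test_coeff_constant_zero_and_scale_invariant(self):
        assert wavelet_coeff_feature(np.full(64, 3.0), "db4", 2) < 1e-12
        x = np.random.default_rng(1).normal(1.0, 0.2, size=256)
        f1 = wavelet_coeff_feature(x, "db4", 4)
        f2 = wavelet_coeff_feature(7.5 * x, "db4", 4)
        assert f2 == pytest.approx(f1, rel=1e-12)

    def test_coeff_noise_exceeds_ramp(self):
        n = 512
        ramp = np.linspace(1.0, 2.0, n)
        f_ramp = wavelet_coeff_feature(ramp, "db4", 4)
        wins = 0
        for seed in range(100):
            noise = 1.5 + 0.3 * np.random.default_rng(seed).standard_normal(n)
            wins += wavelet_coeff_feature(noise, "db4", 4) > f_ramp
        assert wins == 100

    def test_zero_rms_errors(self):
        with pytest.raises(ValueError):
            wavelet_coeff_feature(np.zeros(64), "db4", 2)


class TestExtractAll:
    def test_counts_ten_raw_plus_five_ratio(self):
        rec = make_record(n=64)
        feats, skipped = extract_all(rec)
        assert len(feats) == 15
        assert skipped == []
        kinds = {f.series_kind for f in feats}
        assert sum(k.startswith("ratio_") for k in kinds) == 5

    def test_short_series_skipped_with_reason(self):
        rec = make_record(n=8)
        feats, skipped = extract_all(rec)
        assert feats == []
        assert len(skipped) == 15
        assert all("too short" in reason for _, reason in skipped)

    def test_identical_sides_give_constant_ratio_features(self):
        rec = make_record(n=64)
        for kind in list(rec.series):
            if kind.side.value == "right":
                left = next(
                    k for k in rec.series
                    if k.side.value == "left" and k.phase == kind.phase and k.unit == kind.unit
                )
                rec.series[kind] = rec.series[left].copy()
        feats, _ = extract_all(rec)
        for f in feats:
            if f.series_kind.startswith("ratio_"):
                assert f.c0 == 0.0
                assert f.sampen == 0.0
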