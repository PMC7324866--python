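import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eegmpm import (
    EEGSegment,
    EntropyParams,
    InsufficientDataError,
    UndefinedEntropyError,
    approximate_entropy,
    coarse_grain,
    extract_features,
    feature_table,
    generate_segment,
    multiscale_permutation_entropy,
    normalize_segment,
    permutation_entropy,
    sample_entropy,
    wave_coefficient,
    wavelet_decompose,
)
from oracles import apen_bruteforce, permutation_entropy_bruteforce, sampen_bruteforce


class TestWaveletDecompose:
    def test_zero_in_zero_out(self):
        bands = wavelet_decompose(np.zeros(1024), "db4", 4)
        assert len(bands) == 5
        for b in bands:
            assert np.all(b == 0.0)

    def test_subband_count(self):
        seg = generate_segment("healthy", 1024, 173.61, seed=0)
        assert len(wavelet_decompose(seg, "db4", 4)) == 5
        assert len(wavelet_decompose(seg, "db4", 0)) == 1

    def test_energy_preserved_orthogonal(self, rng):
        x = rng.standard_normal(1024)
        bands = wavelet_decompose(x, "db4", 4)
        e_in = np.sum(x ** 2)
        e_out = sum(np.sum(b ** 2) for b in bands)
        assert e_out == pytest.approx(e_in, rel=1e-8)

    def test_too_short_errors(self):
        with pytest.raises(InsufficientDataError):
            wavelet_decompose(np.ones(8), "db4", 4)


class TestWaveCoefficient:
    def test_constant_is_zero(self):
        assert wave_coefficient(np.full(50, 2.5)) == 0.0

    def test_hand_example(self):
        assert wave_coefficient(np.array([0.0, 1.0, 0.0, 1.0])) == pytest.approx(1.0)

    @settings(derandomize=True, max_examples=30)
    @given(
        st.lists(st.floats(-50, 50), min_size=2, max_size=40),
        st.floats(0, 10),
        st.floats(-100, 100),
    )
    def test_homogeneous_and_translation_invariant(self, xs, c, shift):
        a = np.array(xs)
        base = wave_coefficient(a)
        assert wave_coefficient(c * a) == pytest.approx(c * base, rel=1e-9, abs=1e-9)
        assert wave_coefficient(a + shift) == pytest.approx(base, rel=1e-9, abs=1e-9)

    def test_too_short(self):
        with pytest.raises(InsufficientDataError):
            wave_coefficient(np.array([1.0]))


class TestApproximateEntropy:
    def test_huge_tolerance_gives_zero(self, rng):
        x = rng.standard_normal(60)
        assert approximate_entropy(x, 2, float(np.ptp(x)) + 1.0) == pytest.approx(0.0)

    def test_constant_sequence_zero(self):
        assert approximate_entropy(np.full(50, 1.0), 2, 0.3) == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(size=100)
        r = 0.2 * x.std()
        assert approximate_entropy(x, 2, r) == pytest.approx(
            apen_bruteforce(x, 2, r), abs=1e-12
        )

    def test_too_short(self):
        with pytest.raises(InsufficientDataError):
            approximate_entropy(np.array([1.0, 2.0, 3.0]), 2, 0.2)


class TestSampleEntropy:
    def test_periodic_sequence_zero(self):
        # period 2 <= m = 2, tolerance above point spacing: every m-match extends
        x = np.tile([0.0, 1.0], 30)
        assert sample_entropy(x, 2, 0.1) == pytest.approx(0.0)

    def test_no_matches_errors(self):
        x = np.arange(10.0) ** 2  # spacing grows, no pairs within r
        with pytest.raises(UndefinedEntropyError):
            sample_entropy(x, 2, 0.5)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce(self, seed):
        rng = np.random.default_rng(100 + seed)
        x = rng.standard_normal(200)
        r = 0.2 * x.std()
        expected = sampen_bruteforce(x, 2, r)
        assert expected is not None
        assert sample_entropy(x, 2, r) == pytest.approx(expected, abs=1e-12)


class TestCoarseGrain:
    def test_hand_example(self):
        assert np.allclose(coarse_grain(np.array([1.0, 2, 3, 4]), 2), [1.5, 3.5])

    def test_scale_one_identity(self, rng):
        x = rng.standard_normal(37)
        assert np.array_equal(coarse_grain(x, 1), x)

    def test_full_scale_is_mean(self, rng):
        x = rng.standard_normal(16)
        assert coarse_grain(x, 16) == pytest.approx(x.mean())

    def test_remainder_dropped(self):
        out = coarse_grain(np.arange(7.0), 3)
        assert np.allclose(out, [1.0, 4.0])

    def test_scale_too_large(self):
        with pytest.raises(InsufficientDataError):
            coarse_grain(np.arange(4.0), 5)


class TestPermutationEntropy:
    def test_monotone_sequence_zero(self):
        assert permutation_entropy(np.arange(50.0), 3) == 0.0

    def test_alternating_m2_maximal(self):
        x = np.array([0.0, 1.0] * 10 + [0.0])  # equal up/down pattern counts
        assert permutation_entropy(x, 2) == pytest.approx(1.0)

    def test_constant_signal_single_pattern(self):
        assert permutation_entropy(np.zeros(30), 3) == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(200 + seed)
        x = rng.standard_normal(150)
        assert permutation_entropy(x, 3, 1) == pytest.approx(
            permutation_entropy_bruteforce(x, 3, 1), abs=1e-12
        )

    @settings(derandomize=True, max_examples=25)
    @given(st.lists(st.floats(-10, 10), min_size=10, max_size=60))
    def test_bounded_in_unit_interval(self, xs):
        h = permutation_entropy(np.array(xs), 3)
        assert 0.0 <= h <= 1.0

    def test_invariant_under_monotone_transform(self, rng):
        x = rng.standard_normal(120)
        h = permutation_entropy(x, 3)
        assert permutation_entropy(np.exp(x), 3) == pytest.approx(h, abs=1e-12)
        assert permutation_entropy(3.0 * x + 7.0, 3) == pytest.approx(h, abs=1e-12)


class TestMultiscalePE:
    def test_scale_one_equals_plain_pe(self, rng):
        x = rng.standard_normal(300)
        params = EntropyParams(scales=(1,))
        out = multiscale_permutation_entropy(x, params)
        assert out.shape == (1,)
        assert out[0] == pytest.approx(permutation_entropy(x, params.mpe_m, params.tau))

    def test_white_noise_near_one_at_scale_one(self):
        rng = np.random.default_rng(99)
        x = rng.standard_normal(4096)
        out = multiscale_permutation_entropy(x, EntropyParams())
        assert out[0] > 0.95

    def test_constant_signal_zero_everywhere(self):
        out = multiscale_permutation_entropy(np.zeros(100), EntropyParams())
        assert np.all(out == 0.0)


class TestExtractFeatures:
    def test_vector_length_and_names(self):
        seg = normalize_segment(generate_segment("healthy", 1024, 173.61, seed=1))
        fv = extract_features(seg)
        # (levels+1) wave coefficients + ApEn + SampEn + one MPE per scale
        assert len(fv.values) == 5 + 1 + 1 + 5
        assert fv.names[:5] == ("wc_d1", "wc_d2", "wc_d3", "wc_d4", "wc_a4")
        assert fv.names[5:7] == ("apen", "sampen")
        assert all(np.isfinite(fv.values))

    def test_deterministic(self):
        seg = normalize_segment(generate_segment("ictal", 1024, 173.61, seed=2))
        a = extract_features(seg)
        b = extract_features(seg)
        assert np.array_equal(a.values, b.values)

    def test_ictal_has_higher_low_band_wave_coefficient(self):
        # 3-5 Hz rhythmic activity lands in the final approximation band
        ictal_wc, healthy_wc = [], []
        for seed in range(50):
            for name, store in (("ictal", ictal_wc), ("healthy", healthy_wc)):
                seg = normalize_segment(
                    generate_segment(name, 1024, 173.61, seed=seed)
                )
                fv = extract_features(seg)
                store.append(fv.values[fv.names.index("wc_a4")])
        assert np.mean(ictal_wc) > np.mean(healthy_wc)

    def test_errors_carry_feature_name(self):
        seg = EEGSegment(np.sin(np.arange(64.0)), fs=100.0)
        with pytest.raises(Exception, match="mpe"):
            extract_features(seg, EntropyParams(scales=(1, 64)))


def test_feature_table_layout(small_dataset):
    segs = [normalize_segment(s) for s in small_dataset[:6]]
    df = feature_table(segs)
    assert list(df.columns[-2:]) == ["label", "source_id"]
    assert len(df) == 6
    assert df["label"].tolist() == [s.label for s in small_dataset[:6]]
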