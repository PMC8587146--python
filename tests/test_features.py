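"""Feature extraction against independent brute-force oracles."""

import numpy as np
import pytest

import fusionhar as fh
from fusionhar.features import (
    Spectrum,
    amplitude_spectrum,
    build_feature_matrix,
    crossing_count,
    frequency_domain_features,
    time_domain_features,
)
from fusionhar.preprocessing import extract_windows, upsample_record

# ---------------------------------------------------------------------------
# independent naive oracles (scalar loops, no vectorization shortcuts)


def naive_crossings(x):
    sign = 0
    count = 0
    for v in x:
        s = int(v > 0) - int(v < 0)
        if s == 0:
            s = sign  # a zero adopts the previous nonzero sign
        if sign != 0 and s != 0 and s != sign:
            count += 1
        if s != 0:
            sign = s
    return count


def naive_time_features(x):
    n = len(x)
    mean = sum(x) / n
    var = sum((v - mean) ** 2 for v in x) / n
    return {
        "mean": mean,
        "min": min(x),
        "max": max(x),
        "median": float(np.median(x)),
        "std": var**0.5,
        "zero_crossings": float(naive_crossings(x)),
        "mean_crossings": float(naive_crossings([v - mean for v in x])),
    }


def naive_dft_amplitudes(x, rate_hz):
    """O(N^2) one-sided DFT amplitude spectrum."""
    n = len(x)
    n_bins = n // 2 + 1
    freqs, amps = [], []
    for k in range(n_bins):
        re = sum(x[t] * np.cos(-2 * np.pi * k * t / n) for t in range(n))
        im = sum(x[t] * np.sin(-2 * np.pi * k * t / n) for t in range(n))
        a = (re**2 + im**2) ** 0.5 / n
        if k != 0 and not (n % 2 == 0 and k == n_bins - 1):
            a *= 2
        freqs.append(k * rate_hz / n)
        amps.append(a)
    return np.array(freqs), np.array(amps)


def naive_freq_features(freqs, amps, kind):
    """Full-scan oracle with the explicit lowest-frequency tie rule."""
    n = len(amps)
    mean = sum(amps) / n
    out = {
        "mean": mean,
        "min": min(amps),
        "std": (sum((a - mean) ** 2 for a in amps) / n) ** 0.5,
        "median": float(np.median(amps)),
        "mean_crossings": float(naive_crossings([a - mean for a in amps])),
        "dc_component": amps[0],
    }
    i_max = 0
    for i in range(n):
        if amps[i] > amps[i_max]:
            i_max = i
    if kind == "BIO":
        out["max"] = amps[i_max]
        out["dominant_frequency"] = freqs[i_max]
        return out
    if i_max == 0:
        i2 = 1
        for i in range(1, n):
            if amps[i] > amps[i2]:
                i2 = i
    else:
        i2 = None
        for i in range(n):
            if i == i_max:
                continue
            if i2 is None or amps[i] > amps[i2]:
                i2 = i
    out["second_max"] = amps[i2]
    out["dominant_frequency"] = freqs[i2]
    return out


# ---------------------------------------------------------------------------


class TestTimeDomain:
    def test_alternating_window(self):
        f = time_domain_features(np.array([1.0, -1.0, 1.0, -1.0]))
        assert f == {
            "mean": 0.0, "min": -1.0, "max": 1.0, "median": 0.0,
            "std": 1.0, "zero_crossings": 3.0, "mean_crossings": 3.0,
        }

    def test_constant_window(self):
        f = time_domain_features(np.array([2.0, 2.0, 2.0]))
        assert f["std"] == 0.0
        assert f["zero_crossings"] == 0.0
        assert f["mean_crossings"] == 0.0

    def test_short_window_rejected(self):
        with pytest.raises(ValueError):
            time_domain_features(np.array([1.0]))

    def test_matches_naive_oracle_on_random_windows(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 200))
            x = rng.normal(0, 1, n)
            if rng.random() < 0.3:  # exercise exact zeros and ties
                x = np.round(x, 1)
            got = time_domain_features(x)
            want = naive_time_features(list(x))
            for k in want:
                assert got[k] == pytest.approx(want[k], abs=1e-12), k

    def test_zero_adopts_previous_sign(self):
        # 1, 0, -1 is one crossing (the zero carries +), 1, 0, 1 is none
        assert crossing_count(np.array([1.0, 0.0, -1.0])) == 1
        assert crossing_count(np.array([1.0, 0.0, 1.0])) == 0
        assert crossing_count(np.array([0.0, 0.0, 1.0, -1.0])) == 1


class TestSpectrum:
    def test_constant_signal_is_pure_dc(self):
        spec = amplitude_spectrum(np.full(100, 3.7), 64.0)
        assert spec.amplitudes[0] == pytest.approx(3.7, abs=1e-9)
        assert np.all(np.abs(spec.amplitudes[1:]) < 1e-9)

    def test_bin_aligned_cosine_amplitude(self):
        n, rate, a, f = 448, 64.0, 2.0, 4.0
        t = np.arange(n) / rate
        spec = amplitude_spectrum(a * np.cos(2 * np.pi * f * t), rate)
        k = int(f * n / rate)
        assert spec.frequencies_hz[k] == pytest.approx(4.0)
        assert spec.amplitudes[k] == pytest.approx(a, abs=1e-9)
        mask = np.ones(len(spec.amplitudes), dtype=bool)
        mask[k] = False
        assert np.all(spec.amplitudes[mask] < 1e-9)

    def test_dc_equals_time_mean(self, rng):
        x = rng.normal(2.0, 1.0, 321)
        spec = amplitude_spectrum(x, 64.0)
        assert spec.amplitudes[0] == pytest.approx(abs(np.mean(x)), abs=1e-12)

    def test_matches_naive_dft(self, rng):
        """FFT path equals the O(N^2) DFT oracle on random windows."""
        for _ in range(50):
            n = int(rng.integers(2, 64))
            x = rng.normal(0, 1, n)
            spec = amplitude_spectrum(x, 64.0)
            freqs, amps = naive_dft_amplitudes(list(x), 64.0)
            np.testing.assert_allclose(spec.amplitudes, amps, atol=1e-8)
            np.testing.assert_allclose(spec.frequencies_hz, freqs, atol=1e-12)


class TestFrequencyDomain:
    def _spec(self, pairs):
        freqs, amps = zip(*pairs)
        return Spectrum(np.array(freqs), np.array(amps))

    def test_acc_second_max_convention(self):
        spec = self._spec([(0.0, 3.0), (2.0, 0.01), (4.0, 2.0), (6.0, 0.02)])
        f = frequency_domain_features(spec, "ACC")
        assert f["dc_component"] == 3.0
        assert f["second_max"] == 2.0
        assert f["dominant_frequency"] == 4.0

    def test_acc_fallback_when_dc_not_max(self):
        # global max at 2 Hz; second-largest overall is the DC bin
        spec = self._spec([(0.0, 1.5), (2.0, 5.0), (4.0, 1.0)])
        f = frequency_domain_features(spec, "ACC")
        assert f["second_max"] == 1.5
        assert f["dominant_frequency"] == 0.0

    def test_bio_global_max_convention(self):
        spec = self._spec([(0.0, 0.5), (1.2, 5.0), (2.4, 0.1)])
        f = frequency_domain_features(spec, "BIO")
        assert f["max"] == 5.0
        assert f["dominant_frequency"] == 1.2

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            frequency_domain_features(self._spec([(0.0, 1.0), (1.0, 2.0)]), "ACC")

    def test_matches_naive_full_scan(self, rng):
        for _ in range(50):
            n = int(rng.integers(3, 80))
            amps = np.abs(rng.normal(0, 1, n))
            if rng.random() < 0.3:
                amps = np.round(amps, 1)  # force ties
            freqs = np.arange(n) * 64.0 / (2 * (n - 1))
            spec = Spectrum(freqs, amps)
            for kind in ("ACC", "BIO"):
                got = frequency_domain_features(spec, kind)
                want = naive_freq_features(list(freqs), list(amps), kind)
                for k in want:
                    assert got[k] == pytest.approx(want[k], abs=1e-12), (kind, k)


@pytest.fixture(scope="module")
def windows(small_record):
    return extract_windows(upsample_record(small_record), 7.0)


class TestBuildMatrix:

    def test_75_columns(self, windows):
        mat = build_feature_matrix(windows)
        feats = [c for c in mat.columns if "." in c]
        assert len(feats) == 75
        assert len(set(feats)) == 75

    def test_row_order_preserved(self, windows):
        mat = build_feature_matrix(windows)
        assert len(mat) == len(windows)
        acts = [w.activity for w in windows]
        assert list(mat["activity"]) == acts

    def test_entry_matches_direct_computation(self, windows):
        mat = build_feature_matrix(windows)
        w = windows.windows[3]
        expected = time_domain_features(w.blocks["ECG"])["std"]
        assert mat.iloc[3]["ECG.time.std"] == pytest.approx(expected, rel=1e-12)

    def test_acc_dc_dominates_under_gravity(self, windows):
        """With a ~1 g gravity offset the ACC DC bin exceeds all other bins."""
        mat = build_feature_matrix(windows)
        for ax in ("ACC-X", "ACC-Y", "ACC-Z"):
            dominant = mat[f"{ax}.freq.dc_component"] > mat[f"{ax}.freq.second_max"]
            assert dominant.mean() > 0.95

    def test_time_order_invariants(self, windows):
        mat = build_feature_matrix(windows)
        for ch in ("ACC-X", "ECG", "PPG"):
            assert (mat[f"{ch}.time.max"] >= mat[f"{ch}.time.median"]).all()
            assert (mat[f"{ch}.time.median"] >= mat[f"{ch}.time.min"]).all()
            assert (mat[f"{ch}.time.std"] >= 0).all()
            assert (mat[f"{ch}.freq.min"] >= 0).all()
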