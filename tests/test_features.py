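"""Feature extraction against independent oracles.

Each non-trivial feature is checked against a brute-force or closed-form
reference implemented here, independently of the library code path.
"""

import numpy as np
import pytest

from ctglearn import FHRRecord, SampEnConfig, ValidationError, extract_features
from ctglearn.features import (
    DegenerateInputError,
    FEATURE_NAMES,
    compute_baseline,
    compute_box_dimension,
    compute_dfa,
    compute_fpeak,
    compute_ltv,
    compute_poincare,
    compute_rms,
    compute_sampen,
    compute_stv,
    detect_episodes,
    poincare_autocovariance,
)

FS = 4.0


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def sampen_bruteforce(x, m, r):
    """Exhaustive O(N^2) template counting with Chebyshev distance,
    self-matches excluded."""
    n = len(x)
    b = a = 0
    for i in range(n - m):
        for j in range(i + 1, n - m):
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) <= r:
                b += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    a += 1
    return -np.log(a / b)


def stv_bruteforce(x, fs):
    """Double loop over minutes and 2.5-s subintervals."""
    spm, sub = int(60 * fs), int(2.5 * fs)
    h = spm // sub
    out = []
    for t in range(len(x) // spm):
        block = x[t * spm : (t + 1) * spm]
        means = [np.mean(block[j * sub : (j + 1) * sub]) for j in range(h)]
        out.append(np.mean([abs(means[j] - means[j + 1]) for j in range(h - 1)]))
    return np.mean(out)


def pink_noise(n, rng):
    """1/f noise by spectral synthesis: random phases, amplitude ~ f^-1/2."""
    freqs = np.fft.rfftfreq(n)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** -0.5
    phases = rng.uniform(0, 2 * np.pi, freqs.size)
    spectrum = amp * np.exp(1j * phases)
    x = np.fft.irfft(spectrum, n)
    return x / np.std(x)


# ---------------------------------------------------------------------------
# baseline and episodes
# ---------------------------------------------------------------------------

class TestBaseline:
    def test_constant(self):
        res = compute_baseline(np.full(100, 140.0))
        assert res.vbm == 140.0 and res.rbl == 140.0

    def test_clipping_arithmetic(self):
        """90% at 140, 10% at 165: the excursion clips to vbm+10 and RBL is
        the mean of the clipped vector (direct arithmetic)."""
        x = np.array([140.0] * 90 + [165.0] * 10)
        res = compute_baseline(x)
        vbm = x.mean()
        clipped = np.clip(x, vbm - 10, vbm + 10)
        assert res.vbm == pytest.approx(vbm)
        assert res.rbl == pytest.approx(clipped.mean())
        assert np.all(res.clipped_signal <= vbm + 10)
        assert abs(res.rbl - res.vbm) <= 10

    def test_symmetric_excursions(self):
        x = np.concatenate([np.full(50, 120.0), np.full(50, 160.0)])
        assert compute_baseline(x).rbl == pytest.approx(140.0)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            compute_baseline(np.array([]))


class TestEpisodes:
    def _plateau_signal(self, spans):
        """Flat 140 bpm with (offset_bpm, duration_s) plateaus appended."""
        parts = []
        for off, dur in spans:
            parts.append(np.full(int(30 * FS), 140.0))
            parts.append(np.full(int(dur * FS), 140.0 + off))
        parts.append(np.full(int(30 * FS), 140.0))
        return np.concatenate(parts)

    def test_single_acceleration(self):
        x = self._plateau_signal([(20, 20)])
        res = detect_episodes(x, rbl=140.0, fs=FS)
        assert (res.acc_total, res.dec_total) == (1, 0)

    def test_subthreshold_duration(self):
        x = self._plateau_signal([(20, 10)])
        assert detect_episodes(x, rbl=140.0, fs=FS).acc_total == 0

    def test_two_decelerations(self):
        x = self._plateau_signal([(-20, 16), (-20, 16)])
        res = detect_episodes(x, rbl=140.0, fs=FS)
        assert (res.acc_total, res.dec_total) == (0, 2)

    def test_exact_15s_tie_counts(self):
        x = self._plateau_signal([(15, 15)])
        assert detect_episodes(x, rbl=140.0, fs=FS).acc_total == 1

    def test_translation_invariance(self, rng):
        x = self._plateau_signal([(20, 20), (-20, 18)]) + rng.normal(0, 1, 0).sum()
        r1 = detect_episodes(x, 140.0, FS)
        r2 = detect_episodes(x + 37.0, 140.0 + 37.0, FS)
        assert (r1.acc_total, r1.dec_total) == (r2.acc_total, r2.dec_total)


# ---------------------------------------------------------------------------
# variability
# ---------------------------------------------------------------------------

class TestVariability:
    def test_constant_zero(self):
        assert compute_stv(np.full(480, 140.0), FS).stv == 0.0
        assert compute_ltv(np.full(480, 140.0), FS) == 0.0

    def test_alternating_subinterval_means(self):
        """Successive 2.5-s means 140, 142, 140, ... give STV = 2."""
        sub = int(2.5 * FS)
        pattern = np.concatenate([np.full(sub, 140.0), np.full(sub, 142.0)])
        x = np.tile(pattern, 12 * 2)  # 2 minutes
        assert compute_stv(x, FS).stv == pytest.approx(2.0)

    def test_stv_matches_bruteforce(self, rng):
        x = 140 + 10 * rng.standard_normal(int(3 * 60 * FS) + 37)  # partial minute
        assert compute_stv(x, FS).stv == pytest.approx(stv_bruteforce(x, FS), rel=1e-12)

    def test_ltv_block_ranges(self):
        one = np.linspace(130, 150, int(60 * FS))
        assert compute_ltv(one, FS) == pytest.approx(20.0)
        two = np.concatenate([np.linspace(0, 10, 240), np.linspace(0, 30, 240)])
        assert compute_ltv(two, FS) == pytest.approx(20.0)

    def test_translation_and_scaling(self, rng):
        x = 140 + 10 * rng.standard_normal(960)
        assert compute_stv(x + 13.0, FS).stv == pytest.approx(compute_stv(x, FS).stv)
        assert compute_ltv(x + 13.0, FS) == pytest.approx(compute_ltv(x, FS))
        assert compute_ltv(140 + 3 * (x - 140), FS) == pytest.approx(3 * compute_ltv(x, FS))

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError):
            compute_stv(np.full(100, 140.0), FS)


# ---------------------------------------------------------------------------
# RMS and sample entropy
# ---------------------------------------------------------------------------

class TestRms:
    @pytest.mark.parametrize(
        "x,expected", [([5.0] * 10, 5.0), ([3.0, 4.0], np.sqrt(12.5)), ([0.0] * 5, 0.0)]
    )
    def test_values(self, x, expected):
        assert compute_rms(np.array(x)) == pytest.approx(expected)


class TestSampEn:
    def test_constant_zero(self):
        assert compute_sampen(np.full(50, 140.0)) == 0.0

    @pytest.mark.parametrize("n,seed", [(60, 0), (120, 1), (200, 2)])
    def test_matches_bruteforce(self, n, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(n)
        cfg = SampEnConfig(m=2, r_factor=0.2)
        r = 0.2 * np.std(x)
        assert compute_sampen(x, cfg) == pytest.approx(sampen_bruteforce(x, 2, r), abs=1e-12)

    def test_m1_matches_bruteforce(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(80)
        r = 0.3 * np.std(x)
        assert compute_sampen(x, SampEnConfig(m=1, r_factor=0.3)) == pytest.approx(
            sampen_bruteforce(x, 1, r), abs=1e-12
        )

    def test_iid_noise_large_n(self):
        """For iid Gaussian noise the match probabilities are analytic in
        principle; here we check a Monte-Carlo stabilised value: SampEn of
        N(0,1) noise at m=2, r=0.2 sd is ~2.2 with small spread."""
        vals = [
            compute_sampen(np.random.default_rng(s).standard_normal(5000))
            for s in range(5)
        ]
        assert 2.0 < np.mean(vals) < 2.4

    def test_no_matches_degenerate(self):
        x = np.geomspace(1.0, 1e6, 20)  # exploding spacing: no template matches
        with pytest.raises(DegenerateInputError):
            compute_sampen(x, SampEnConfig(m=2, r_factor=1e-6))

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError):
            compute_sampen(np.array([1.0, 2.0, 3.0]))


# ---------------------------------------------------------------------------
# spectral peak
# ---------------------------------------------------------------------------

class TestFpeak:
    def test_single_tone(self):
        t = np.arange(4096) / FS
        x = 140 + np.sin(2 * np.pi * 0.5 * t)
        res = compute_fpeak(x, FS)
        bin_width = res.frequencies[1] - res.frequencies[0]
        assert abs(res.fpeak - 0.5) <= bin_width

    def test_two_tones_larger_wins(self):
        t = np.arange(4096) / FS
        x = 140 + 3 * np.sin(2 * np.pi * 0.2 * t) + 1 * np.sin(2 * np.pi * 0.7 * t)
        res = compute_fpeak(x, FS)
        bin_width = res.frequencies[1] - res.frequencies[0]
        assert abs(res.fpeak - 0.2) <= bin_width

    def test_matches_independent_welch(self, rng):
        """White noise: peak equals the argmax of an independently computed
        Welch PSD over the same samples."""
        from scipy.signal import welch

        x = rng.standard_normal(2048)
        res = compute_fpeak(x, FS)
        f, p = welch(x - x.mean(), fs=FS, window="hamming", nperseg=256, noverlap=128,
                     detrend="constant")
        assert res.fpeak == f[1:][np.argmax(p[1:])]

    def test_peak_never_dc(self, rng):
        x = rng.standard_normal(1024) + 1000.0
        assert compute_fpeak(x, FS).fpeak > 0.0

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError):
            compute_fpeak(np.full(100, 140.0), FS)


# ---------------------------------------------------------------------------
# Poincare
# ---------------------------------------------------------------------------

class TestPoincare:
    def test_constant_all_zero(self):
        res = compute_poincare(np.full(50, 140.0))
        assert (res.sd1, res.sd2, res.sd_ratio) == (0.0, 0.0, 0.0)

    def test_alternating_hand_value(self):
        """Raw intervals alternating +1/-1 about a mean: successive
        differences are +-2, so SDSD = 2 and SD1 = sqrt(2) (population SD)."""
        x = 10.0 + np.array([1.0, -1.0] * 20 + [1.0])  # even diff count: zero-mean
        res = compute_poincare(x, mode="raw")
        assert res.sdsd == pytest.approx(2.0)
        assert res.sd1 == pytest.approx(np.sqrt(2.0))

    @pytest.mark.parametrize("mode", ["raw", "nn"])
    def test_sd1_sdsd_identity(self, rng, mode):
        x = 140 + 10 * rng.standard_normal(500)
        res = compute_poincare(x, mode=mode)
        assert res.sd1 ** 2 == pytest.approx(0.5 * res.sdsd ** 2, rel=1e-9)

    @pytest.mark.parametrize("mode", ["raw", "nn"])
    def test_autocovariance_identity(self, rng, mode):
        """SD1^2 equals the lag-0 minus lag-1 autocovariance of the interval
        series (computed over the Poincare pairs)."""
        x = 140 + 10 * rng.standard_normal(400)
        res = compute_poincare(x, mode=mode)
        y0, y1 = poincare_autocovariance(x, mode=mode)
        assert res.sd1 ** 2 == pytest.approx(y0 - y1, rel=1e-9, abs=1e-15)

    def test_sd_ratio_is_ellipse_area(self, rng):
        x = 140 + 5 * rng.standard_normal(300)
        res = compute_poincare(x)
        assert res.sd_ratio == pytest.approx(np.pi * res.sd1 * res.sd2)

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError):
            compute_poincare(np.array([140.0, 141.0]))


# ---------------------------------------------------------------------------
# fractal features
# ---------------------------------------------------------------------------

class TestBoxDimension:
    def test_line_dimension(self):
        x = np.linspace(0.0, 100.0, 4096)
        assert compute_box_dimension(x) == pytest.approx(1.0, abs=0.05)

    def test_constant_convention(self):
        assert compute_box_dimension(np.full(1024, 140.0)) == 1.0

    def test_brownian_dimension(self):
        """fBm with Hurst 0.5 is Brownian motion; its graph has dimension
        D = 2 - H = 1.5. Averaged over replicates."""
        vals = [
            compute_box_dimension(np.cumsum(np.random.default_rng(s).standard_normal(4096)))
            for s in range(100)
        ]
        assert np.mean(vals) == pytest.approx(1.5, abs=0.1)

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError):
            compute_box_dimension(np.zeros(32))


class TestDfa:
    def test_white_noise_exponent(self):
        vals = [
            compute_dfa(np.random.default_rng(s).standard_normal(4096))
            for s in range(100)
        ]
        assert np.mean(vals) == pytest.approx(0.5, abs=0.05)

    def test_pink_noise_exponent(self):
        vals = [
            compute_dfa(pink_noise(4096, np.random.default_rng(s))) for s in range(100)
        ]
        assert np.mean(vals) == pytest.approx(1.0, abs=0.1)

    def test_brownian_exponent(self):
        vals = [
            compute_dfa(np.cumsum(np.random.default_rng(s).standard_normal(4096)))
            for s in range(100)
        ]
        assert np.mean(vals) == pytest.approx(1.5, abs=0.1)

    def test_constant_degenerate(self):
        with pytest.raises(DegenerateInputError):
            compute_dfa(np.full(1024, 140.0))

    def test_bad_scales_rejected(self):
        with pytest.raises(ValidationError):
            compute_dfa(np.random.default_rng(0).standard_normal(100), scales=[2, 4, 8, 16])


# ---------------------------------------------------------------------------
# the assembled vector
# ---------------------------------------------------------------------------

class TestExtractFeatures:
    def _record(self, seed=0):
        rng = np.random.default_rng(seed)
        n = int(6 * 60 * FS)
        t = np.arange(n) / FS
        x = 140 + 5 * np.sin(2 * np.pi * t / 300) + 2 * rng.standard_normal(n)
        return FHRRecord("t", x, fs=FS)

    def test_shape_contract(self):
        vec = extract_features(self._record())
        d = vec.to_dict()
        assert tuple(d) == FEATURE_NAMES
        assert all(np.isfinite(v) for v in d.values())

    def test_determinism(self):
        a = extract_features(self._record(3)).to_array()
        b = extract_features(self._record(3)).to_array()
        assert np.array_equal(a, b)

    def test_unpreprocessed_rejected(self):
        sig = np.full(2000, 140.0)
        sig[10] = np.nan
        with pytest.raises(ValidationError):
            extract_features(FHRRecord("t", sig, fs=FS))
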