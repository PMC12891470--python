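"""Stability-metric tests: brute-force oracles, closed forms, invariances."""
import math

import numpy as np
import pytest

from gaitstab.errors import ParameterError
from gaitstab.events import trim_transient_strides
from gaitstab.metrics import (MetricConfig, compute_all, harmonic_ratio,
                              rms_normalized, rqa, sample_entropy,
                              short_term_lyapunov, time_normalize_strides)
from gaitstab.synthetic import default_harmonics, simulate_trunk_acceleration
from gaitstab.types import GaitEvents


# ----------------------------------------------------------------------
# Brute-force oracles (independent O(n^2) implementations)
# ----------------------------------------------------------------------

def sampen_oracle(x, m, r):
    """Double-loop template counting, Chebyshev distance."""
    x = np.asarray(x, float)
    n = len(x)
    nt = n - m
    b = a = 0
    for i in range(nt):
        for j in range(i + 1, nt):
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) <= r:
                b += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    a += 1
    if b == 0:
        return math.nan
    return -math.log(a / b) if a else math.inf


def rqa_oracle(x, dim, delay, radius, lmin, theiler):
    """Explicit recurrence matrix + diagonal-line scan.  %DET is computed
    over diagonals long enough to host a line of length lmin."""
    x = np.asarray(x, float)
    x = x - x.mean()
    n = len(x) - (dim - 1) * delay
    emb = np.array([[x[i + k * delay] for k in range(dim)] for i in range(n)])
    rec_pts = allowed = in_lines = det_pts = 0
    for off in range(theiler + 1, n):
        diag = [np.linalg.norm(emb[i] - emb[i + off]) <= radius
                for i in range(n - off)]
        allowed += len(diag)
        rec_pts += sum(diag)
        if len(diag) < lmin:
            continue
        det_pts += sum(diag)
        run = 0
        for v in diag + [False]:
            if v:
                run += 1
            else:
                if run >= lmin:
                    in_lines += run
                run = 0
    p_rec = 100.0 * rec_pts / allowed
    p_det = math.nan if det_pts == 0 else 100.0 * in_lines / det_pts
    return p_rec, p_det


# ----------------------------------------------------------------------
# RMS
# ----------------------------------------------------------------------

class TestRms:
    def test_constant_is_zero(self):
        assert rms_normalized(np.full(100, 3.7), 1.3) == 0.0

    def test_sinusoid_closed_form(self):
        t = np.linspace(0, 10, 2000, endpoint=False)
        amp, speed = 2.5, 1.2
        x = amp * np.sin(2 * np.pi * 3 * t)
        expected = (amp / np.sqrt(2)) / speed**2
        assert rms_normalized(x, speed) == pytest.approx(expected, rel=1e-3)

    def test_speed_squared_normalization(self):
        x = np.random.default_rng(0).standard_normal(500)
        assert rms_normalized(x, 2.0) == pytest.approx(rms_normalized(x, 1.0) / 4)

    def test_rejects_nonpositive_speed(self):
        with pytest.raises(ParameterError):
            rms_normalized(np.ones(10), 0.0)


# ----------------------------------------------------------------------
# Harmonic ratio
# ----------------------------------------------------------------------

class TestHarmonicRatio:
    def test_step_frequency_sinusoid_dominates(self):
        fs, f = 100.0, 1.0
        t = np.arange(1000) / fs  # exactly 10 strides
        x = np.sin(2 * np.pi * 2 * f * t)  # step frequency = 2x stride
        assert harmonic_ratio(x, f, fs, "AP") > 100

    def test_stride_frequency_sinusoid_is_tiny(self):
        fs, f = 100.0, 1.0
        t = np.arange(1000) / fs
        x = np.sin(2 * np.pi * f * t)
        assert harmonic_ratio(x, f, fs, "AP") < 0.01

    def test_equal_harmonics_give_unity(self):
        fs, f = 100.0, 1.0
        t = np.arange(1000) / fs
        x = sum(np.cos(2 * np.pi * k * f * t) for k in range(1, 21))
        for axis in ("AP", "ML", "VT"):
            assert harmonic_ratio(x, f, fs, axis) == pytest.approx(1.0, abs=1e-6)

    def test_ml_axis_inverts_ratio(self):
        fs, f = 100.0, 1.0
        t = np.arange(1000) / fs
        x = np.sin(2 * np.pi * 2 * f * t) + 0.1 * np.sin(2 * np.pi * f * t)
        assert harmonic_ratio(x, f, fs, "AP") > 1 > harmonic_ratio(x, f, fs, "ML")

    def test_amplitude_scale_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(1000)
        a = harmonic_ratio(x, 1.0, 100.0, "AP")
        b = harmonic_ratio(5.0 * x, 1.0, 100.0, "AP")
        assert a == pytest.approx(b, rel=1e-9)


# ----------------------------------------------------------------------
# Sample entropy
# ----------------------------------------------------------------------

class TestSampleEntropy:
    def test_constant_series_is_zero(self):
        assert sample_entropy(np.full(300, 2.0)) == 0.0

    def test_small_series_matches_oracle_exactly(self):
        x = [1, 2, 3, 1, 2, 3, 1, 2, 3, 1, 2, 3]
        assert sample_entropy(np.array(x, float), m=2, r=0.5) == \
            pytest.approx(sampen_oracle(x, 2, 0.5), abs=0)

    @pytest.mark.parametrize("seed", range(4))
    def test_random_series_matches_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(200)
        r = 0.2 * np.std(x)
        assert sample_entropy(x, m=2, r=r) == pytest.approx(
            sampen_oracle(x, 2, r), abs=1e-12)

    def test_periodic_below_shuffled(self):
        """SampEn(periodic) < SampEn(permuted) in >=95/100 seeded trials."""
        t = np.arange(300) / 100.0
        periodic = np.sin(2 * np.pi * 2 * t) + 0.5 * np.sin(2 * np.pi * 4 * t)
        base = sample_entropy(periodic)
        wins = 0
        for seed in range(100):
            shuffled = np.random.default_rng(seed).permutation(periodic)
            wins += base < sample_entropy(shuffled)
        assert wins >= 95

    def test_offset_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(250)
        assert sample_entropy(x) == pytest.approx(sample_entropy(x + 100.0),
                                                  rel=1e-9)


# ----------------------------------------------------------------------
# RQA
# ----------------------------------------------------------------------

class TestRqa:
    def test_constant_series_fully_recurrent(self):
        rec, det = rqa(np.full(200, 1.5))
        assert rec == 100.0 and det == 100.0

    def test_matches_brute_force_oracle(self):
        cfg = MetricConfig(rqa_dim=3, rqa_delay=4, rqa_min_diag=2)
        for seed in range(3):
            rng = np.random.default_rng(seed)
            x = rng.standard_normal(150)
            xc = x - x.mean()
            emb_n = len(x) - (cfg.rqa_dim - 1) * cfg.rqa_delay
            emb = np.column_stack([xc[k * cfg.rqa_delay: k * cfg.rqa_delay + emb_n]
                                   for k in range(cfg.rqa_dim)])
            ctr = emb - emb.mean(axis=0)
            radius = cfg.rqa_radius_factor * np.sqrt(np.mean(np.sum(ctr**2, axis=1)))
            expected = rqa_oracle(x, cfg.rqa_dim, cfg.rqa_delay, radius,
                                  cfg.rqa_min_diag, cfg.rqa_delay)
            got = rqa(x, cfg)
            assert got[0] == pytest.approx(expected[0], abs=1e-9)
            assert got[1] == pytest.approx(expected[1], abs=1e-9)

    def test_clean_sinusoid_highly_deterministic(self):
        t = np.arange(600) / 100.0
        _, det = rqa(np.sin(2 * np.pi * 2 * t))
        assert det >= 95

    def test_noise_less_deterministic_than_sinusoid(self):
        t = np.arange(600) / 100.0
        _, det_sin = rqa(np.sin(2 * np.pi * 2 * t))
        _, det_noise = rqa(np.random.default_rng(0).standard_normal(600))
        assert det_noise < det_sin


# ----------------------------------------------------------------------
# Short-term Lyapunov
# ----------------------------------------------------------------------

class TestLyapunov:
    def _periodic_strides(self, noise_sd=0.0, seed=0):
        sig = simulate_trunk_acceleration(1.0, 16, 100.0, seed=seed,
                                          jitter=0.0, noise_sd=noise_sd)
        bounds = np.round(np.asarray(sig.meta["stride_bounds"]) * 100).astype(int)
        return sig.ap, bounds

    def test_noiseless_periodic_is_stable(self):
        x, bounds = self._periodic_strides()
        assert abs(short_term_lyapunov(x, bounds)) <= 0.05

    def test_noise_increases_divergence(self):
        x0, b0 = self._periodic_strides(0.0)
        clean = short_term_lyapunov(x0, b0)
        x1, b1 = self._periodic_strides(0.12, seed=1)  # ~10% of signal amplitude
        assert short_term_lyapunov(x1, b1) > clean

    def test_time_normalization_lengths(self):
        x = np.arange(350, dtype=float)
        bounds = np.array([0, 120, 230, 350])
        y = time_normalize_strides(x, bounds, 100)
        assert len(y) == 300


# ----------------------------------------------------------------------
# compute_all
# ----------------------------------------------------------------------

class TestComputeAll:
    def test_deterministic_on_same_signal(self, clean_signal):
        sig, ev = clean_signal
        trimmed = trim_transient_strides(ev)
        a = compute_all(sig, trimmed, 1.0)
        b = compute_all(sig, trimmed, 1.0)
        assert a.values == b.values

    def test_rms_speed_scaling_exact(self, clean_signal):
        sig, ev = clean_signal
        trimmed = trim_transient_strides(ev)
        at1 = compute_all(sig, trimmed, 1.0)
        at08 = compute_all(sig, trimmed, 0.8)
        for ax in ("AP", "ML", "VT"):
            assert at08[f"RMS_{ax}"] == pytest.approx(at1[f"RMS_{ax}"] / 0.64)
            assert at08[f"HR_{ax}"] == at1[f"HR_{ax}"]  # speed-independent

    def test_offset_invariance(self, clean_signal):
        sig, ev = clean_signal
        trimmed = trim_transient_strides(ev)
        base = compute_all(sig, trimmed, 1.0)
        shifted = type(sig)(fs=sig.fs, ap=sig.ap + 9.81, ml=sig.ml - 3.0,
                            vt=sig.vt + 1.0)
        moved = compute_all(shifted, trimmed, 1.0)
        for k in base.values:
            assert moved[k] == pytest.approx(base[k], rel=1e-6, abs=1e-9)

    def test_degenerate_hr_flagged_missing(self):
        sig = simulate_trunk_acceleration(1.0, 20, 100.0, seed=0,
                                          harmonics=default_harmonics(0.0),
                                          jitter=0.0, noise_sd=0.0)
        ic = np.round(np.asarray(sig.meta["ic_times"]) * 100).astype(int)
        ev = GaitEvents(ic, np.round(np.asarray(sig.meta["to_times"]) * 100).astype(int),
                        100.0)
        feats = compute_all(sig, trim_transient_strides(ev), 1.0)
        assert feats["HR_AP"] == math.inf
        assert "HR_AP" in feats.missing
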