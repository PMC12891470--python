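"""Tests of the synthetic-cohort generators against independent oracles."""
import numpy as np
import pytest
from scipy import stats

from gaitstab.errors import ParameterError
from gaitstab.synthetic import (CohortSpec, default_harmonics,
                                simulate_classification_cohort,
                                simulate_regression_cohort,
                                simulate_trunk_acceleration)


def _band_energy(x, fs, freq, half_width=0.15):
    """FFT oracle: spectral energy within +/- half_width Hz of freq."""
    spec = np.abs(np.fft.rfft(x - x.mean())) ** 2
    freqs = np.fft.rfftfreq(len(x), 1.0 / fs)
    return spec[(freqs > freq - half_width) & (freqs < freq + half_width)].sum()


class TestTrunkSignal:
    def test_seeded_determinism(self):
        a = simulate_trunk_acceleration(1.0, 20, 100.0, seed=7)
        b = simulate_trunk_acceleration(1.0, 20, 100.0, seed=7)
        for ax in ("ap", "ml", "vt"):
            np.testing.assert_array_equal(a.axis(ax), b.axis(ax))

    def test_even_odd_harmonic_structure(self):
        """AP/VT energy concentrates at even stride harmonics, ML at odd."""
        sig = simulate_trunk_acceleration(1.0, 20, 100.0, seed=0,
                                          jitter=0.0, noise_sd=0.0)
        for ax, dominant in (("ap", 2.0), ("vt", 2.0), ("ml", 1.0)):
            e_dom = _band_energy(sig.axis(ax), 100.0, dominant)
            e_other = _band_energy(sig.axis(ax), 100.0, 3.0 - dominant)
            assert e_dom > e_other

    def test_noise_increases_rms(self):
        """Doubling noise_sd strictly increases raw RMS (20 seeds)."""
        for seed in range(20):
            lo = simulate_trunk_acceleration(1.0, 16, 100.0, seed=seed, noise_sd=0.1)
            hi = simulate_trunk_acceleration(1.0, 16, 100.0, seed=seed, noise_sd=0.2)
            rms = lambda s: np.sqrt(np.mean((s.ap - s.ap.mean()) ** 2))  # noqa: E731
            assert rms(hi) > rms(lo)

    @pytest.mark.parametrize("kwargs", [
        {"stride_freq": 0.0}, {"stride_freq": -1.0},
        {"stride_freq": 1.0, "fs": 30.0}, {"stride_freq": 1.0, "n_strides": 10},
    ])
    def test_parameter_errors(self, kwargs):
        with pytest.raises(ParameterError):
            simulate_trunk_acceleration(**kwargs)


class TestClassificationCohort:
    def test_label_counts_exact(self, cohort):
        features, _ = cohort
        counts = features["group"].value_counts()
        assert counts["PwS"] == 71 and counts["HC"] == 39

    def test_empirical_effect_size_in_band(self, cohort):
        """Cohen's d on RMS_VT lands in the sampling band around 0.7."""
        features, _ = cohort
        pws = features.loc[features.group == "PwS", "RMS_VT"]
        hc = features.loc[features.group == "HC", "RMS_VT"]
        sp = np.sqrt(((len(pws) - 1) * pws.var(ddof=1) + (len(hc) - 1) * hc.var(ddof=1))
                     / (len(pws) + len(hc) - 2))
        d = (pws.mean() - hc.mean()) / sp
        assert 0.4 <= d <= 1.0

    def test_null_cohort_type_one_calibration(self):
        """d=0 gives non-significant Welch tests in >=90% of replicates."""
        ok = 0
        n_rep = 100
        for seed in range(n_rep):
            f, _, _ = simulate_classification_cohort(
                CohortSpec(seed=seed, effect_size_d=0.0))
            pws = f.loc[f.group == "PwS", "RMS_VT"]
            hc = f.loc[f.group == "HC", "RMS_VT"]
            _, p = stats.ttest_ind(pws, hc, equal_var=False)
            ok += p >= 0.05
        assert ok >= 0.90 * n_rep

    def test_welch_power_at_default_effect(self):
        """d=0.7 at n=110 rejects in >=80% of 200 replicates."""
        rejected = 0
        n_rep = 200
        for seed in range(n_rep):
            f, _, _ = simulate_classification_cohort(CohortSpec(seed=seed))
            pws = f.loc[f.group == "PwS", "RMS_VT"]
            hc = f.loc[f.group == "HC", "RMS_VT"]
            _, p = stats.ttest_ind(pws, hc, equal_var=False)
            rejected += p < 0.05
        assert rejected >= 0.80 * n_rep


def _brute_force_breakpoint(x, y, candidates):
    """Independent changepoint oracle: grid-search least squares over a
    continuous two-segment fit."""
    best_b, best_sse = candidates[0], np.inf
    for b in candidates:
        design = np.column_stack([np.ones_like(x),
                                  np.minimum(x - b, 0), np.maximum(x - b, 0)])
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        sse = np.sum((design @ beta - y) ** 2)
        if sse < best_sse:
            best_b, best_sse = b, sse
    return best_b


class TestRegressionCohort:
    def test_noiseless_speed_continuity_at_breakpoint(self):
        table, p = simulate_regression_cohort(CohortSpec(seed=0), n=500,
                                              noise_scale=0.0)
        x = table.even_speed.to_numpy()
        y = table.uneven_speed.to_numpy()
        order = np.argsort(x)
        # no jump: consecutive points around the kink stay close
        assert np.max(np.abs(np.diff(y[order]))) < 0.05

    def test_noiseless_hr_plateau_saturates(self):
        spec = CohortSpec(seed=0)
        table, _ = simulate_regression_cohort(spec, n=400, noise_scale=0.0)
        sat = table[table.even_HR_AP >= 1.6]
        assert len(sat) > 10
        assert np.allclose(sat.uneven_HR_AP, spec.hr_plateau)

    def test_breakpoint_recovered_by_changepoint_oracle(self):
        table, _ = simulate_regression_cohort(CohortSpec(seed=3), n=200)
        candidates = np.linspace(0.45, 1.15, 141)
        b = _brute_force_breakpoint(table.even_speed.to_numpy(),
                                    table.uneven_speed.to_numpy(), candidates)
        assert abs(b - 0.8) <= 0.1

    def test_ushape_and_plateau_recovered_by_direct_fits(self):
        spec = CohortSpec(seed=5)
        table, _ = simulate_regression_cohort(spec, n=200)
        a, b, _ = np.polyfit(table.Ang_IC_ankle, table.uneven_SampEn_AP, 2)
        assert a > 0
        assert abs(-b / (2 * a) - spec.ushape_center) <= 2.0
        sat = table[table.even_HR_AP >= spec.hr_plateau + 0.2]
        assert abs(sat.uneven_HR_AP.mean() - spec.hr_plateau) <= 0.15

    def test_generative_params_returned(self):
        _, params = simulate_regression_cohort(CohortSpec(seed=0), n=50)
        assert params["breakpoint_speed"] == 0.8
        assert params["hr_plateau"] == 1.5


def test_spec_validation():
    with pytest.raises(ParameterError):
        CohortSpec(n_pws=0)
    with pytest.raises(ParameterError):
        CohortSpec(breakpoint_speed=5.0)
    with pytest.raises(ParameterError):
        CohortSpec(effect_size_d=float("nan"))


def test_harmonic_template_odd_weight_monotone():
    hi = default_harmonics(2.0)
    lo = default_harmonics(0.5)
    assert hi["ap"][1] > lo["ap"][1]
    assert hi["ap"][2] == lo["ap"][2]
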