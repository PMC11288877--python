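"""Metrics, significance testing, ERP summaries and QC diagnostics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from errpsim import evaluate
from errpsim.evaluate import (
    balanced_accuracy,
    baseline_rms_distribution,
    compare_paired,
    erp_image,
    find_peaks,
    grand_average,
    permutation_test,
    pointwise_fdr_mask,
    single_trial_spectra,
)
from errpsim.simulator import EpochsData


class TestBalancedAccuracy:
    def test_arithmetic_mean_of_rates(self):
        y = np.array(["error"] * 10 + ["correct"] * 10)
        pred = y.copy()
        pred[:3] = "correct"  # 3 missed errors -> TPR 0.7
        pred[10] = "error"  # 1 false alarm -> TNR 0.9
        m = balanced_accuracy(y, pred)
        assert (m.tpr, m.tnr) == (0.7, 0.9)
        assert m.bacc == pytest.approx(0.8)

    def test_perfect_prediction(self):
        y = np.array(["error", "correct", "error", "correct"])
        m = balanced_accuracy(y, y)
        assert tuple(m) == (1.0, 1.0, 1.0)

    def test_majority_predictor_scores_chance(self):
        y = np.array(["error"] * 20 + ["correct"] * 80)
        m = balanced_accuracy(y, np.array(["correct"] * 100))
        assert tuple(m) == (0.0, 1.0, 0.5)

    def test_single_class_truth_rejected(self):
        with pytest.raises(ValueError):
            balanced_accuracy(np.array(["error"] * 5), np.array(["error"] * 5))

    def test_random_predictor_is_chance_level_despite_imbalance(self, rng):
        # bACC of a coin-flip predictor converges to 0.5 at 20% prevalence
        y = np.array(["error"] * 2000 + ["correct"] * 8000)
        pred = rng.choice(["error", "correct"], size=10_000)
        assert balanced_accuracy(y, pred).bacc == pytest.approx(0.5, abs=0.03)


class TestPermutationTest:
    def test_minimum_p_value_with_plus_one_estimator(self, rng):
        labels = np.array(["error"] * 10 + ["correct"] * 40)
        values = (labels == "error").astype(float)  # perfectly informative
        p, obs, null = permutation_test(
            lambda lab: float(np.mean(values[lab == "error"])), labels,
            n_perm=1000, rng=rng)
        assert obs == 1.0
        assert p == pytest.approx(1 / 1001)

    def test_constant_statistic_gives_p_one(self, rng):
        labels = np.array(["error"] * 5 + ["correct"] * 20)
        p, _, _ = permutation_test(lambda lab: 0.5, labels, n_perm=50, rng=rng)
        assert p == 1.0

    def test_null_p_values_super_uniform(self):
        # calibration: under a label-independent statistic the p-values must
        # be (super-)uniform over the permutation quantiles
        rng = np.random.default_rng(0)
        n_perm = 99
        ps = []
        for _ in range(50):
            values = rng.normal(size=30)
            labels = np.array(["error"] * 10 + ["correct"] * 20)
            p, _, _ = permutation_test(
                lambda lab: float(values[lab == "error"].mean()), labels,
                n_perm=n_perm, rng=rng)
            ps.append(p)
        _, ks_p = stats.kstest(ps, stats.uniform.cdf)
        assert ks_p > 0.01
        # the small-alpha tail must not be anti-conservative
        for alpha in (0.05, 0.1):
            assert np.mean(np.array(ps) <= alpha) <= alpha + 0.1

    def test_too_few_permutations_rejected(self, rng):
        with pytest.raises(ValueError):
            permutation_test(lambda lab: 0.0, np.array(["error", "correct"] * 5),
                             n_perm=10, rng=rng)


class TestComparePaired:
    def test_uniform_positive_shift_gives_exact_sign_test_p(self, rng):
        b = rng.normal(size=10)
        a = b + 1.0
        assert compare_paired(a, b, "A-greater") == pytest.approx(1 / 1024)

    def test_identical_samples_degenerate(self):
        x = np.arange(6, dtype=float)
        with pytest.raises(ValueError, match="degenerate"):
            compare_paired(x, x)

    def test_two_sided_matches_enumeration_oracle(self, rng):
        # brute-force the exact null: all 2^n sign assignments of |d| ranks
        d = rng.normal(size=8)
        d = d[d != 0]
        n = d.size
        ranks = stats.rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        null = [np.sum(ranks[np.array(signs, dtype=bool)])
                for signs in itertools.product([0, 1], repeat=n)]
        null = np.asarray(null)
        mean_w = n * (n + 1) / 4
        p_oracle = np.mean(np.abs(null - mean_w) >= abs(w_obs - mean_w) - 1e-12)
        p = compare_paired(d + np.zeros(n), np.zeros(n), "two-sided")
        assert p == pytest.approx(p_oracle, abs=1e-9)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            compare_paired([1.0, 2.0], [0.0, 1.0])
        with pytest.raises(ValueError):
            compare_paired(np.arange(6.0), np.zeros(6), "bogus")


class TestPointwiseFdr:
    def test_null_false_positive_fraction_controlled(self):
        rng = np.random.default_rng(1)
        fractions = []
        for _ in range(100):
            err = rng.normal(size=(15, 40))
            cor = rng.normal(size=(25, 40))
            mask = pointwise_fdr_mask(err, cor, alpha=0.05)
            fractions.append(mask.mean())
        assert np.mean(fractions) <= 0.05

    def test_injected_offset_window_detected(self):
        rng = np.random.default_rng(2)
        err = rng.normal(size=(300, 100))
        cor = rng.normal(size=(300, 100))
        err[:, 40:60] += 5.0
        mask = pointwise_fdr_mask(err, cor, alpha=0.05)
        assert mask[40:60].all()
        assert mask[:30].mean() < 0.2

    def test_alpha_zero_flags_nothing(self, rng):
        mask = pointwise_fdr_mask(rng.normal(size=(5, 20)),
                                  rng.normal(size=(5, 20)), alpha=0.0)
        assert not mask.any()


def _epochs_from(data, labels, srate=250.0):
    times = np.arange(data.shape[2]) / srate * 1000.0 - 200.0
    return EpochsData(data=data, times=times, labels=np.asarray(labels),
                      srate=srate, channel_labels=["Cz"], subject_id="s")


class TestGrandAverage:
    def test_single_trial_difference(self):
        data = np.zeros((2, 1, 100))
        data[0, 0, 60] = 4.0  # error trial
        data[1, 0, 60] = 1.0  # correct trial
        ep = _epochs_from(data, ["error", "correct"])
        ga = grand_average([ep], "Cz", baseline=None)
        assert ga.difference[60] == pytest.approx(3.0)
        assert np.allclose(ga.difference, ga.error_avg - ga.correct_avg)

    def test_zero_correct_class_means_difference_is_error_average(self, rng):
        data = np.zeros((4, 1, 50))
        data[:2] = rng.normal(size=(2, 1, 50))
        ep = _epochs_from(data, ["error", "error", "correct", "correct"])
        ga = grand_average([ep], "Cz", baseline=None)
        assert np.allclose(ga.difference, ga.error_avg)

    def test_subject_order_irrelevant(self, rng):
        subs = []
        for k in range(3):
            data = rng.normal(size=(6, 1, 50))
            subs.append(_epochs_from(data, ["error"] * 3 + ["correct"] * 3))
        a = grand_average(subs, "Cz")
        b = grand_average(subs[::-1], "Cz")
        assert np.allclose(a.difference, b.difference)

    def test_mismatched_time_axes_rejected(self, rng):
        a = _epochs_from(rng.normal(size=(2, 1, 50)), ["error", "correct"])
        b = _epochs_from(rng.normal(size=(2, 1, 60)), ["error", "correct"])
        with pytest.raises(ValueError, match="time axes"):
            grand_average([a, b], "Cz")


class TestFindPeaks:
    times = np.arange(-200.0, 800.0, 4.0)

    def test_gaussian_bump_located(self):
        erp = 3.0 * np.exp(-0.5 * ((self.times - 320) / 30) ** 2)
        peaks = find_peaks(erp, self.times, intervals=((200, 400, "positive"),))
        assert peaks.latency_ms[0] == 320.0
        assert peaks.amplitude[0] == pytest.approx(3.0)

    def test_monotone_ramp_returns_endpoint(self):
        erp = self.times / 100.0
        peaks = find_peaks(erp, self.times, intervals=((200, 400, "positive"),))
        assert peaks.latency_ms[0] == 400.0

    def test_negative_search_on_positive_bump_returns_least_positive(self):
        erp = 3.0 * np.exp(-0.5 * ((self.times - 300) / 30) ** 2)
        peaks = find_peaks(erp, self.times, intervals=((200, 400, "negative"),))
        assert peaks.latency_ms[0] in (200.0, 400.0)

    def test_out_of_axis_interval_rejected(self):
        with pytest.raises(ValueError):
            find_peaks(np.zeros_like(self.times), self.times,
                       intervals=((900, 1000, "positive"),))


class TestQc:
    def test_constant_baseline_rms_is_absolute_value(self):
        data = np.full((10, 1, 100), -3.0)
        ep = _epochs_from(data, ["correct"] * 10)
        out = baseline_rms_distribution([ep], n_perm=50, n_trials_per_perm=5,
                                        rng=np.random.default_rng(0))
        assert out["mean_rms"] == pytest.approx(3.0)
        assert out["std_rms"] == pytest.approx(0.0, abs=1e-12)

    def test_white_noise_rms_approaches_sigma(self):
        rng = np.random.default_rng(3)
        sigma = 2.5
        data = rng.normal(0, sigma, size=(400, 1, 100))
        ep = _epochs_from(data, ["correct"] * 400)
        out = baseline_rms_distribution([ep], n_perm=200, n_trials_per_perm=100,
                                        rng=rng)
        assert out["mean_rms"] == pytest.approx(sigma, rel=0.05)

    def test_zero_data_rms_zero(self):
        ep = _epochs_from(np.zeros((5, 1, 100)), ["correct"] * 5)
        out = baseline_rms_distribution([ep], n_perm=30, n_trials_per_perm=3,
                                        rng=np.random.default_rng(0))
        assert out["mean_rms"] == 0.0

    def test_spectrum_peak_at_tone_frequency(self):
        srate = 250.0
        t = np.arange(250) / srate
        data = np.sin(2 * np.pi * 10 * t)[None, None, :].repeat(20, axis=0)
        ep = _epochs_from(data, ["correct"] * 20)
        freqs, spec = single_trial_spectra(ep, "Cz", n_trials=30,
                                           rng=np.random.default_rng(0))
        assert spec.size == 250 // 2 + 1
        assert freqs[np.argmax(spec[1:]) + 1] == pytest.approx(10.0)

    def test_brown_noise_spectrum_slope(self):
        from errpsim.noise_model import brown_noise

        rng = np.random.default_rng(4)
        data = brown_noise(375, rng, size=(300, 1))
        ep = _epochs_from(data, ["correct"] * 300)
        freqs, spec = single_trial_spectra(ep, "Cz", n_trials=300, rng=rng)
        band = (freqs >= 1) & (freqs <= 40)
        slope = np.polyfit(np.log10(freqs[band]), np.log10(spec[band] ** 2), 1)[0]
        assert slope == pytest.approx(-2.0, abs=0.4)


def test_figure_exports_write_files(tmp_path, rng):
    data = rng.normal(size=(6, 1, 50))
    ep = _epochs_from(data, ["error"] * 3 + ["correct"] * 3)
    ga = grand_average([ep], "Cz")
    p1 = tmp_path / "ga.png"
    evaluate.plot_grand_average(ga, p1)
    img, mean = erp_image(ep.get_channel("Cz")[:3], ga.correct_avg)
    p2 = tmp_path / "erp.png"
    evaluate.plot_erp_image(img, ep.times, p2, mean_erp=mean)
    assert p1.stat().st_size > 0 and p2.stat().st_size > 0


class TestErpImage:
    def test_identical_trials_identical_rows(self):
        trial = np.sin(np.linspace(0, 3, 50))
        err = np.tile(trial, (8, 1))
        img, mean = erp_image(err, np.zeros(50), smooth=5)
        assert np.allclose(img, img[0])
        assert np.allclose(mean, trial)

    def test_smooth_one_is_identity(self, rng):
        err = rng.normal(size=(6, 30))
        cor = rng.normal(size=30)
        img, _ = erp_image(err, cor, smooth=1)
        assert np.allclose(img, err - cor)

    def test_alternating_trials_average_to_one_fifth(self):
        # +1/-1 alternation smoothed over 5 trials -> +-0.2 in the interior
        err = np.array([[1.0], [-1.0]] * 5).reshape(10, 1)
        img, _ = erp_image(err, np.zeros(1), smooth=5)
        interior = img[2:-2, 0]
        assert np.allclose(np.abs(interior), 0.2)
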