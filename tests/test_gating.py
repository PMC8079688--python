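"""Sensory-gating pipeline: ERP scoring, gating metrics, evoked gamma."""

import numpy as np
import pytest

from eegbattery.core import EpochSet, extract_epochs
from eegbattery.gating import (
    average_erp,
    evoked_power_gating,
    gating_metrics,
    score_erp_components,
    stimulus_psd_profile,
)
from eegbattery.spectral import band_power, morlet_tfr
from eegbattery.synth import BackgroundParams, ErpKernelParams, erp_kernel, simulate_gating_session

RATE = 2000.0


def _epochs_from_kernel(kernel_values, n_trials=1, offsets=None, noise=None, rng=None):
    """Epochs of 2 s with the kernel at the 1.0 s mark."""
    n = int(2.0 * RATE)
    data = np.zeros((n_trials, n))
    i0 = int(1.0 * RATE)
    data[:, i0:i0 + kernel_values.size] = kernel_values
    if offsets is not None:
        data += np.asarray(offsets)[:, None]
    if noise is not None:
        data += rng.normal(0.0, noise, size=data.shape)
    return EpochSet(data, rate=RATE, event_time=1.0)


class TestAverageErp:
    def test_dc_offsets_removed_exactly(self):
        kern = erp_kernel(ErpKernelParams(), RATE)
        ep = _epochs_from_kernel(kern, n_trials=5, offsets=[0.0, 10.0, -3.0, 50.0, 7.0])
        erp = average_erp(ep)
        i0 = int(1.0 * RATE)
        assert np.allclose(erp.values[i0:i0 + kern.size], kern, atol=1e-10)
        assert np.allclose(erp.values[:int(0.9 * RATE)], 0.0, atol=1e-10)

    def test_single_trial_equals_baseline_corrected_trial(self, rng):
        kern = erp_kernel(ErpKernelParams(), RATE)
        ep = _epochs_from_kernel(kern, offsets=[42.0])
        erp = average_erp(ep)
        assert erp.n_trials == 1
        assert np.allclose(erp.values, ep.data[0] - 42.0, atol=1e-10)

    def test_noise_suppression_scales_with_trials(self, rng):
        """With n trials of SD-20 noise the ERP error is ~ 2 uV pointwise."""
        kern = erp_kernel(ErpKernelParams(), RATE)
        ep = _epochs_from_kernel(kern, n_trials=100, noise=20.0, rng=rng)
        erp = average_erp(ep)
        i0 = int(1.0 * RATE)
        resid = erp.values[i0:i0 + kern.size] - kern
        # baseline subtraction adds a small common term; allow 4 x SE
        assert np.max(np.abs(resid)) < 4 * 20.0 / np.sqrt(100)

    def test_baseline_outside_epoch_rejected(self):
        ep = _epochs_from_kernel(np.zeros(100))
        with pytest.raises(ValueError, match="baseline"):
            average_erp(ep, baseline=(-1.0, -0.5))


class TestScoreComponents:
    def test_constructed_extrema(self):
        # clean bumps: +6 uV at 22 ms, -9 uV at 40 ms post-onset
        n = int(2.0 * RATE)
        v = np.zeros(n)
        t = np.arange(n) / RATE - 1.0
        v += 6.0 * np.exp(-0.5 * ((t - 0.022) / 0.003) ** 2)
        v -= 9.0 * np.exp(-0.5 * ((t - 0.040) / 0.004) ** 2)
        from eegbattery.gating import ErpWaveform
        erp = ErpWaveform(v, RATE, 1, (0.9, 1.0))
        c = score_erp_components(erp, tone_onset=1.0)
        assert c.p20 == pytest.approx(6.0, abs=0.1)
        assert c.n40 == pytest.approx(-9.0, abs=0.1)
        assert c.p20_n40 == pytest.approx(15.0, abs=0.2)
        assert 0.015 <= c.p20_latency <= 0.030
        assert 0.025 <= c.n40_latency <= 0.055

    def test_constant_shift_removed_by_baseline_correction(self):
        kern = erp_kernel(ErpKernelParams(), RATE)
        ep0 = _epochs_from_kernel(kern, n_trials=3)
        ep1 = _epochs_from_kernel(kern, n_trials=3, offsets=[50.0, 50.0, 50.0])
        c0 = score_erp_components(average_erp(ep0), 1.0)
        c1 = score_erp_components(average_erp(ep1), 1.0)
        assert c0.p20 == pytest.approx(c1.p20, abs=1e-9)
        assert c0.n40 == pytest.approx(c1.n40, abs=1e-9)

    def test_window_past_epoch_end_rejected(self):
        from eegbattery.gating import ErpWaveform
        erp = ErpWaveform(np.zeros(100), RATE, 1, (0.0, 0.01))
        with pytest.raises(ValueError, match="window"):
            score_erp_components(erp, tone_onset=0.04)

    def test_recovery_under_session_noise(self, gating_session, gating_epochs):
        """Programmed kernel extrema recovered from the 100-trial average.

        Peak picking on a noisy average carries a small outward bias (the
        extremum of signal + noise), so the tolerance is a few times the
        ERP standard error (3 uV here) rather than the SE itself.
        """
        _, _, truth = gating_session
        erp = average_erp(gating_epochs)
        c1 = score_erp_components(erp, 1.0)
        tc = truth.params["true_components"]
        assert c1.p20 == pytest.approx(tc["p20"], abs=5.0)
        assert c1.n40 == pytest.approx(tc["n40"], abs=5.0)

    def test_mean_recovery_bias_small_at_sd20(self):
        """Across seeds at noise SD 20 uV the mean scoring error stays
        within ~1 SE of the programmed amplitudes."""
        errs = []
        for seed in range(4):
            rec, ev, tr = simulate_gating_session(
                100, ErpKernelParams(gating_factor=0.25),
                BackgroundParams(rms=20.0), seed=seed)
            ep = extract_epochs(rec, ev, "tone_S1", (1.0, 4.0), "frontal")
            c = score_erp_components(average_erp(ep), 1.0)
            tc = tr.params["true_components"]
            errs.append([c.p20 - tc["p20"], c.n40 - tc["n40"]])
        mean_err = np.abs(np.mean(errs, axis=0))
        assert np.all(mean_err < 2.5)


class TestGatingMetrics:
    def test_hand_examples(self):
        from eegbattery.gating import ErpComponents
        c1 = ErpComponents(p20=16.0, n40=0.0, p20_latency=0.02, n40_latency=0.04)
        c2 = ErpComponents(p20=4.0, n40=0.0, p20_latency=0.02, n40_latency=0.04)
        m = gating_metrics(c1, c2, "P20")
        assert m.s2_over_s1 == pytest.approx(0.25)
        assert m.s1_minus_s2 == pytest.approx(12.0)
        m_eq = gating_metrics(c1, c1, "P20")
        assert m_eq.s2_over_s1 == 1.0 and m_eq.s1_minus_s2 == 0.0

    def test_zero_s1_rejected(self):
        from eegbattery.gating import ErpComponents
        c0 = ErpComponents(0.0, 0.0, 0.02, 0.04)
        with pytest.raises(ZeroDivisionError):
            gating_metrics(c0, c0, "P20")

    def test_n40_uses_magnitude(self):
        from eegbattery.gating import ErpComponents
        c1 = ErpComponents(p20=5.0, n40=-10.0, p20_latency=0.02, n40_latency=0.04)
        c2 = ErpComponents(p20=5.0, n40=-4.0, p20_latency=0.02, n40_latency=0.04)
        m = gating_metrics(c1, c2, "N40")
        assert m.s2_over_s1 == pytest.approx(0.4)
        assert m.s1_minus_s2 == pytest.approx(6.0)

    def test_gating_factor_recovered(self, gating_session, gating_epochs):
        _, _, truth = gating_session
        erp = average_erp(gating_epochs)
        c1 = score_erp_components(erp, 1.0)
        c2 = score_erp_components(erp, 1.5)
        m = gating_metrics(c1, c2, "P20_N40")
        assert m.s2_over_s1 == pytest.approx(truth.params["gating_factor"], abs=0.08)

    def test_noise_free_recovery_is_exact(self):
        kern = ErpKernelParams(gating_factor=0.25)
        rec, events, truth = simulate_gating_session(
            5, kern, BackgroundParams(rms=0.0), seed=0)
        ep = extract_epochs(rec, events, "tone_S1", (1.0, 4.0), "frontal")
        erp = average_erp(ep)
        m = gating_metrics(score_erp_components(erp, 1.0),
                           score_erp_components(erp, 1.5), "P20_N40")
        assert abs(m.s2_over_s1 - 0.25) < 0.02


class TestEvokedGamma:
    def test_identical_responses_zero_reduction(self):
        kern = ErpKernelParams(gating_factor=1.0)
        rec, events, _ = simulate_gating_session(5, kern, BackgroundParams(rms=0.0), seed=0)
        ep = extract_epochs(rec, events, "tone_S1", (1.0, 4.0), "frontal")
        gg = evoked_power_gating(ep)
        assert gg.percent_reduction == pytest.approx(0.0, abs=2.0)

    def test_half_amplitude_quarter_power(self):
        """S2 = 0.5 x S1 amplitude -> ~75 % power reduction (quadratic)."""
        kern = ErpKernelParams(gating_factor=0.5)
        rec, events, _ = simulate_gating_session(5, kern, BackgroundParams(rms=0.0), seed=0)
        ep = extract_epochs(rec, events, "tone_S1", (1.0, 4.0), "frontal")
        gg = evoked_power_gating(ep)
        assert gg.percent_reduction == pytest.approx(75.0, abs=5.0)

    def test_stronger_gating_larger_reduction(self):
        noise = BackgroundParams(rms=30.0)
        for seed in range(3):
            reductions = {}
            for g in (1.0, 0.25):
                rec, events, _ = simulate_gating_session(
                    60, ErpKernelParams(gating_factor=g), noise, seed=seed)
                ep = extract_epochs(rec, events, "tone_S1", (1.0, 4.0), "frontal")
                reductions[g] = evoked_power_gating(ep).percent_reduction
            assert reductions[0.25] > reductions[1.0]

    def test_averaging_order_jensen_inequality(self, gating_epochs):
        """Evoked (transform-of-average) band power never exceeds total
        (average-of-transforms) band power."""
        freqs = np.arange(30.0, 81.0, 2.0)
        window = (1.0, 1.05)
        tf_trials = morlet_tfr(gating_epochs, freqs=freqs, cycles=7.0,
                               keep_phase=False, decim=4)
        total = band_power(tf_trials, (30, 80), window).value
        erp = average_erp(gating_epochs)
        tf_ev = morlet_tfr(erp.values[None, :], rate=RATE, freqs=freqs,
                           cycles=7.0, keep_phase=False, decim=4)
        evoked = band_power(tf_ev, (30, 80), window).value
        assert evoked <= total * (1 + 1e-9)


class TestPsdProfile:
    def test_no_evoked_response_bins_near_zero(self):
        rec, events, _ = simulate_gating_session(
            60, ErpKernelParams(p20=(0.020, 0.008, 0.0), n40=(0.040, 0.015, 0.0)),
            BackgroundParams(rms=30.0), seed=1)
        ep = extract_epochs(rec, events, "tone_S1", (1.0, 4.0), "frontal")
        bins = stimulus_psd_profile(ep)
        assert bins.values.shape == (100,)
        assert np.abs(np.median(bins.values)) < 0.3

    def test_evoked_kernel_elevates_low_gamma_bins(self, gating_epochs):
        bins = stimulus_psd_profile(gating_epochs)
        low = bins.values[(bins.centers >= 20) & (bins.centers <= 50)].mean()
        high = bins.values[(bins.centers >= 80) & (bins.centers <= 100)].mean()
        assert low > high + 0.3
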