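import numpy as np
import pytest

from pftm import (ObserverModel, QuickParams, SessionConfig, analysis_window,
                  average_trials, default_t1, fft_component, perceived_drive,
                  simulate_2afc, simulate_session, simulate_trial)


@pytest.fixture
def config():
    return SessionConfig("red", 21.04, "green", tuple(np.linspace(5, 37, 9)),
                         repeats=2)


def tag_readout(trial, config):
    window = analysis_window(default_t1(config), config.period_s, 4)
    return fft_component(trial.trace, window, config.tag_frequency_hz)


class TestPerceivedDrive:
    def test_first_half_period_shows_fixed(self, config):
        model = ObserverModel(gain=0.9)
        t = np.array([0.0, 0.1, 0.28])
        np.testing.assert_allclose(
            perceived_drive(config, 30.0, model, t), config.fixed_luminance)

    def test_second_half_period_shows_scaled_variable(self, config):
        model = ObserverModel(gain=0.9)
        assert perceived_drive(config, 30.0, model, 0.3) == pytest.approx(27.0)

    def test_prestim_is_background(self, config):
        model = ObserverModel()
        assert perceived_drive(config, 30.0, model, -0.2) == pytest.approx(
            config.fixed_luminance)

    def test_square_wave_mean_over_period(self, config):
        model = ObserverModel(gain=0.8)
        t = np.arange(0, config.period_s, 1e-4)
        mean = np.mean(perceived_drive(config, 30.0, model, t))
        assert mean == pytest.approx((21.04 + 0.8 * 30.0) / 2, rel=1e-3)


class TestSimulateTrial:
    def test_equiluminant_condition_has_no_tag_power(self, config):
        model = ObserverModel(gain=0.85, noise_sd=0.0)
        lv = config.fixed_luminance / 0.85
        cfg = SessionConfig("red", 21.04, "green", (lv,), repeats=1)
        trial = simulate_trial(cfg, lv, model, seed=0)
        amp, _ = tag_readout(trial, cfg)
        assert amp < 1e-6

    def test_symmetric_conditions_equal_amplitude_opposite_phase(self):
        model = ObserverModel(gain=1.0, noise_sd=0.0)
        cfg = SessionConfig("red", 20.0, "green", (10.0, 30.0), repeats=1)
        lo = simulate_trial(cfg, 10.0, model, seed=0)
        hi = simulate_trial(cfg, 30.0, model, seed=0)
        amp_lo, ph_lo = tag_readout(lo, cfg)
        amp_hi, ph_hi = tag_readout(hi, cfg)
        assert amp_lo == pytest.approx(amp_hi, rel=1e-9)
        delta = (ph_lo - ph_hi) % 360.0
        assert min(delta, 360 - delta) == pytest.approx(180.0, abs=1.0)

    def test_same_seed_reproducible(self, config):
        a = simulate_trial(config, 30.0, ObserverModel(), seed=7)
        b = simulate_trial(config, 30.0, ObserverModel(), seed=7)
        np.testing.assert_array_equal(a.trace.values, b.trace.values)

    def test_amplitude_monotone_in_perceived_difference(self):
        model = ObserverModel(gain=1.0, noise_sd=0.0)
        levels = tuple(np.linspace(5.0, 35.0, 7))
        cfg = SessionConfig("red", 20.0, "green", levels, repeats=1)
        amps = {}
        for lv in levels:
            trial = simulate_trial(cfg, lv, model, seed=0)
            amps[lv] = tag_readout(trial, cfg)[0]
        diffs = sorted(levels, key=lambda lv: abs(lv - 20.0))
        ordered = [amps[lv] for lv in diffs]
        assert all(a <= b + 1e-12 for a, b in zip(ordered, ordered[1:]))

    def test_onset_latency_in_expected_band(self):
        """The noise-free response leaves baseline ~0.5-0.7 s after onset."""
        model = ObserverModel(gain=1.0, noise_sd=0.0)
        cfg = SessionConfig("red", 20.0, "green", (35.0,), repeats=1)
        trial = simulate_trial(cfg, 35.0, model, seed=0)
        trace = trial.trace
        dev = np.abs(trace.values - model.baseline_mm)
        threshold = 0.1 * dev.max()
        onset = trace.times[np.argmax(dev > threshold)]
        assert 0.2 < onset < 0.8


class TestSimulateSession:
    def test_counts_and_randomised_order(self, config):
        trials = simulate_session(config, ObserverModel(), seed=1)
        assert len(trials) == 9 * 2
        conditions = [t.condition for t in trials]
        assert sorted(set(conditions)) == list(config.variable_levels)
        # ids are presentation order; conditions must not be block-sorted
        assert conditions != sorted(conditions)

    def test_master_seed_determinism(self, config):
        a = simulate_session(config, ObserverModel(), seed=3)
        b = simulate_session(config, ObserverModel(), seed=3)
        for ta, tb in zip(a, b):
            assert ta.condition == tb.condition
            np.testing.assert_array_equal(ta.trace.values, tb.trace.values)

    def test_noise_leaves_expected_tag_amplitude_unbiased(self):
        """AR(1) noise averages out: across 200 noisy trials of one
        condition the mean-trace amplitude approaches the noiseless one."""
        cfg = SessionConfig("red", 20.0, "green", (30.0,), repeats=200)
        noiseless = simulate_trial(cfg, 30.0, ObserverModel(gain=1.0, noise_sd=0.0),
                                   seed=0)
        amp_clean, _ = tag_readout(noiseless, cfg)
        trials = simulate_session(cfg, ObserverModel(gain=1.0), seed=11)
        avg = average_trials(trials)
        amp_noisy, _ = fft_component(
            avg.mean_trace, analysis_window(default_t1(cfg), cfg.period_s, 4),
            cfg.tag_frequency_hz)
        # Monte-Carlo tolerance: noise SD at the bin shrinks ~ 1/sqrt(200)
        assert amp_noisy == pytest.approx(amp_clean, rel=0.15)


class TestSimulate2AFC:
    def test_zero_probability_level(self):
        params = QuickParams(alpha=20.0, beta=6.0)
        table = simulate_2afc([0.1], params, n_per_level=50, seed=0)
        assert table.n_chose[0] == 0

    def test_proportion_near_half_at_alpha(self):
        params = QuickParams(alpha=20.0, beta=4.0)
        table = simulate_2afc([20.0], params, n_per_level=1000, seed=1)
        prop = table.n_chose[0] / 1000
        assert abs(prop - 0.5) < 3 * 0.5 / np.sqrt(1000)

    def test_seed_reproducible(self):
        params = QuickParams(alpha=20.0, beta=4.0)
        a = simulate_2afc(np.linspace(10, 30, 5), params, 20, seed=9)
        b = simulate_2afc(np.linspace(10, 30, 5), params, 20, seed=9)
        np.testing.assert_array_equal(a.n_chose, b.n_chose)
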