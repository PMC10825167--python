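import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pftm import (SessionConfig, TaggingResult, analysis_window, default_t1,
                  fft_component, normalise_amplitudes, spectrum)

from conftest import cosine_trace, make_trace


def direct_dft_component(values, k):
    """O(N^2)-style direct DFT sum at bin k (independent oracle)."""
    n = values.size
    return np.sum(values * np.exp(-2j * np.pi * k * np.arange(n) / n))


class TestAnalysisWindow:
    def test_worked_example(self):
        w = analysis_window(0.3, 0.567, 4)
        assert w.t2 == 2.568
        assert w.cycles == 4

    def test_single_period(self):
        assert analysis_window(1.0, 0.567, 1).t2 == pytest.approx(1.567)

    @pytest.mark.parametrize("cycles", [0, -3])
    def test_nonpositive_cycles_rejected(self, cycles):
        with pytest.raises(ValueError):
            analysis_window(0.3, 0.567, cycles)

    def test_default_t1_first_boundary_after_one_second(self):
        cfg = SessionConfig("red", 21.04, "green", (10.0, 20.0, 30.0))
        t1 = default_t1(cfg)
        assert t1 == pytest.approx(4 * 0.283)
        assert t1 >= 1.0

    @given(t1=st.floats(0.0, 2.0), cycles=st.integers(1, 10))
    @settings(max_examples=50, deadline=None)
    def test_on_bin_guarantee(self, t1, cycles):
        """With an integer-cycle window the tag frequency bin index is rho."""
        period = 0.566
        w = analysis_window(t1, period, cycles)
        k = w.duration / period
        assert k == pytest.approx(cycles, abs=1e-9)


class TestFFTComponent:
    def test_on_bin_cosine_amplitude_and_phase(self):
        freq = 1.0 / 0.566
        trace = cosine_trace(freq, amplitude=0.5, t0=0.3, duration=3.0)
        window = analysis_window(0.3, 0.566, 4)
        amp, phase = fft_component(trace, window, freq)
        assert amp == pytest.approx(0.5, abs=1e-3)
        assert phase == pytest.approx(0.0, abs=1e-3)

    def test_negated_cosine_flips_phase(self):
        freq = 1.0 / 0.566
        trace = cosine_trace(freq, amplitude=-0.5, t0=0.3, duration=3.0)
        window = analysis_window(0.3, 0.566, 4)
        amp, phase = fft_component(trace, window, freq)
        assert amp == pytest.approx(0.5, abs=1e-3)
        assert abs(phase) == pytest.approx(180.0, abs=1e-3)

    def test_constant_trace_has_no_tag_component(self):
        trace = make_trace(np.full(4000, 5.0))
        window = analysis_window(0.0, 0.566, 4)
        amp, _ = fft_component(trace, window, 1.0 / 0.566)
        assert amp == pytest.approx(0.0, abs=1e-12)
        dc, _ = fft_component(trace, window, 0.0)
        assert dc == pytest.approx(5.0, abs=1e-12)

    def test_off_bin_frequency_rejected(self):
        trace = make_trace(np.zeros(4000))
        window = analysis_window(0.0, 0.566, 4)
        with pytest.raises(ValueError, match="off-bin"):
            fft_component(trace, window, 1.9)

    def test_window_beyond_trace_rejected(self):
        trace = make_trace(np.zeros(1000))
        with pytest.raises(ValueError, match="exceeds"):
            fft_component(trace, analysis_window(0.0, 0.566, 4), 0.0)

    def test_amplitude_invariant_to_dc_offset(self):
        freq = 1.0 / 0.566
        window = analysis_window(0.0, 0.566, 4)
        a = cosine_trace(freq, amplitude=0.4, duration=3.0)
        b = a.with_values(a.values + 17.3)
        amp_a, ph_a = fft_component(a, window, freq)
        amp_b, ph_b = fft_component(b, window, freq)
        assert amp_b == pytest.approx(amp_a, rel=1e-12)
        assert ph_b == pytest.approx(ph_a, abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_direct_dft_oracle_agreement(self, seed):
        rng = np.random.default_rng(seed)
        trace = make_trace(rng.normal(5, 1, 3000))
        window = analysis_window(0.1, 0.566, 4)
        n = int(round(window.duration * 1000))
        i1 = int(np.searchsorted(trace.times, window.t1 - 0.0005))
        segment = trace.values[i1:i1 + n]
        for k in (0, 1, 4, 11):
            freq = k / window.duration
            amp, phase = fft_component(trace, window, freq)
            coef = direct_dft_component(segment, k)
            expected = abs(coef) / n if k == 0 else 2 * abs(coef) / n
            assert amp == pytest.approx(expected, rel=1e-9, abs=1e-12)
            if k > 0:
                assert np.isclose(np.radians(phase),
                                  np.angle(coef), atol=1e-9)


class TestSpectrum:
    def test_zero_trace_all_zero(self):
        trace = make_trace(np.zeros(4000))
        spec = spectrum(trace, analysis_window(0.0, 0.566, 4), 7.0)
        np.testing.assert_allclose(spec.amplitudes, 0.0)
        assert spec.freqs[0] == 0.0

    def test_bin_spacing_is_reciprocal_window(self):
        trace = make_trace(np.zeros(4000))
        window = analysis_window(0.0, 0.566, 4)
        spec = spectrum(trace, window, 7.0)
        np.testing.assert_allclose(np.diff(spec.freqs), 1.0 / window.duration,
                                   atol=1e-9)

    def test_two_sinusoid_linearity(self):
        window = analysis_window(0.0, 0.566, 4)
        f1, f2 = 1.0 / 0.566, 3.0 / 0.566
        t = np.arange(3000) / 1000.0
        values = 0.3 * np.cos(2 * np.pi * f1 * t) + 0.7 * np.cos(2 * np.pi * f2 * t)
        spec = spectrum(make_trace(values), window, 7.0)
        i1 = int(np.argmin(np.abs(spec.freqs - f1)))
        i2 = int(np.argmin(np.abs(spec.freqs - f2)))
        assert spec.amplitudes[i1] == pytest.approx(0.3, abs=1e-6)
        assert spec.amplitudes[i2] == pytest.approx(0.7, abs=1e-6)
        others = np.delete(spec.amplitudes, [i1, i2])
        assert np.max(others) < 1e-6

    def test_parseval_energy_identity(self):
        """Sum of single-sided amplitude^2 terms equals twice the variance
        plus the squared mean (real signal, full band)."""
        rng = np.random.default_rng(7)
        n = 2264  # 4 cycles of 0.566 s at 1 kHz
        values = rng.normal(2.0, 0.5, 4000)
        trace = make_trace(values)
        window = analysis_window(0.0, 0.566, 4)
        spec = spectrum(trace, window, 500.0)
        x = values[:n]
        # DC term + half of each sinusoidal amplitude^2 recompose the power
        power = spec.amplitudes[0] ** 2 + 0.5 * np.sum(spec.amplitudes[1:] ** 2)
        if n % 2 == 0:  # Nyquist bin is not doubled in a single-sided scale
            power -= 0.25 * spec.amplitudes[-1] ** 2
        assert power == pytest.approx(np.mean(x ** 2), rel=1e-6)


class TestNormalise:
    def _result(self, cond, amp):
        return TaggingResult(condition=cond, mean_amplitude=0.0,
                             tag_amplitude=amp, tag_phase_deg=0.0, n_trials=5)

    def test_halves_and_unity(self):
        out = normalise_amplitudes([self._result(1, 3.0), self._result(2, 6.0)])
        np.testing.assert_allclose(out, [0.5, 1.0])

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            normalise_amplitudes([self._result(1, 0.0), self._result(2, 0.0)])

    def test_argmax_preserved(self):
        amps = [0.2, 0.9, 0.4, 0.9001]
        out = normalise_amplitudes([self._result(i, a) for i, a in enumerate(amps)])
        assert int(np.argmax(out)) == int(np.argmax(amps))
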