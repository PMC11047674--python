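"""Filtering, normalisation, windowing and quality screening."""

import numpy as np
import pytest
from scipy import signal as sps

from mwppg import (
    QualityRule,
    bandpass_filter,
    make_window_set,
    normalize,
    reject_abnormal,
    segment_windows,
)
from mwppg.errors import (
    ConfigError,
    DegenerateInputError,
    LengthError,
    SamplingError,
)
from mwppg.preprocess import preprocess_record

FS = 200.0


def _steady_amplitude(y, fs, freq, skip=4.0):
    """Steady-state amplitude at the tone frequency (quadrature projection).

    Projecting the central section onto e^{i 2 pi f t} isolates the tone
    from the slowly decaying low-frequency edge transient of the 0.5 Hz
    corner.
    """
    n0 = int(skip * fs)
    mid = y[n0:-n0]
    t = np.arange(mid.size) / fs
    return 2.0 * np.abs(np.mean(mid * np.exp(-2j * np.pi * freq * t)))


class TestBandpassFilter:
    def test_dc_is_removed(self):
        y = bandpass_filter(np.full(2000, 7.3), FS)
        assert np.max(np.abs(y)) < 1e-6 * 7.3

    @pytest.mark.parametrize("freq,lo,hi", [(4.0, 0.9, 1.1), (50.0, 0.0, 0.1)])
    def test_tone_amplitude_matches_analytic_response(self, freq, lo, hi):
        # oracle: zero-phase filtering applies the squared Butterworth
        # magnitude response, read off the analytic transfer function
        t = np.arange(int(20 * FS)) / FS
        x = np.sin(2 * np.pi * freq * t)
        y = bandpass_filter(x, FS)
        amp = _steady_amplitude(y, FS, freq)
        sos = sps.butter(2, [0.5, 8.0], btype="bandpass", fs=FS, output="sos")
        _, h = sps.sosfreqz(sos, worN=[freq], fs=FS)
        expected = np.abs(h[0]) ** 2  # forward-backward pass squares |H|
        assert lo <= amp <= hi
        # deep in the stop band, edge transients set the floor, hence abs tol
        assert amp == pytest.approx(expected, rel=0.02, abs=1e-3)

    def test_linearity(self, rng):
        x = rng.normal(size=3000)
        y = rng.normal(size=3000)
        lhs = bandpass_filter(2.5 * x - 1.5 * y, FS)
        rhs = 2.5 * bandpass_filter(x, FS) - 1.5 * bandpass_filter(y, FS)
        np.testing.assert_allclose(lhs, rhs, atol=1e-8)

    def test_preserves_length(self, rng):
        x = rng.normal(size=1234)
        assert bandpass_filter(x, FS).shape == x.shape

    def test_insufficient_sampling_rate_rejected(self):
        with pytest.raises(SamplingError):
            bandpass_filter(np.zeros(100), fs=10.0)


class TestNormalize:
    def test_zero_mean_unit_sd(self, rng):
        z = normalize(rng.normal(3.0, 5.0, size=1000))
        assert abs(z.mean()) < 1e-9
        assert abs(z.std() - 1.0) < 1e-9

    def test_affine_invariance(self, rng):
        x = rng.normal(size=500)
        np.testing.assert_allclose(normalize(4.2 * x + 17.0), normalize(x), atol=1e-10)

    def test_constant_input_rejected(self):
        with pytest.raises(DegenerateInputError):
            normalize(np.full(100, 2.0))


class TestSegmentWindows:
    def test_60s_at_200hz_gives_56_windows_of_1000(self, rng):
        w = segment_windows(rng.normal(size=12000), FS)
        assert w.shape == (56, 1000)

    def test_exactly_one_window(self, rng):
        assert segment_windows(rng.normal(size=1000), FS).shape == (1, 1000)

    def test_one_sample_short_raises(self, rng):
        with pytest.raises(LengthError):
            segment_windows(rng.normal(size=999), FS)

    def test_window_contents_match_slices(self, rng):
        x = rng.normal(size=2500)
        w = segment_windows(x, FS)
        assert w.shape == (8, 1000)
        np.testing.assert_array_equal(w[3], x[600:1600])


class TestQualityScreening:
    def test_invalid_rule_rejected(self):
        with pytest.raises(ConfigError):
            QualityRule(max_flatline_fraction=1.5)

    def test_clean_simulated_windows_fully_retained(self, small_cohort):
        # derived from the generator: noise-free-enough defaults keep 100%
        _, records, _ = small_cohort
        ws, log = preprocess_record(records[0])
        assert ws.n_windows == 56
        assert log.empty

    def test_flat_window_dropped(self, small_cohort):
        _, records, _ = small_cohort
        ws = make_window_set(records[0])
        ws.windows[2, 7, :] = 0.123  # flatline one channel of window 7
        kept, log = reject_abnormal(ws)
        assert 7 not in kept.window_indices
        assert {"flatline"} <= set(log["reason"])

    def test_any_channel_violation_drops_window_in_all_channels(self, small_cohort):
        # alignment rule: a spike in channel 1 removes window 3 everywhere
        _, records, _ = small_cohort
        ws = make_window_set(records[1])
        ws.windows[0, 3, 500] += 50.0
        kept, _ = reject_abnormal(ws)
        assert 3 not in kept.window_indices
        assert kept.windows.shape[0] == 4
        assert kept.n_windows == 55

    def test_aperiodic_window_dropped(self, rng, small_cohort):
        _, records, _ = small_cohort
        ws = make_window_set(records[2])
        ws.windows[1, 10] = rng.normal(size=ws.win_len)  # white noise: no beat
        kept, log = reject_abnormal(ws)
        assert 10 not in kept.window_indices


class TestWindowSetInvariants:
    def test_four_channel_alignment_and_label_inheritance(self, small_cohort):
        _, records, _ = small_cohort
        rec = records[3]
        ws, _ = preprocess_record(rec)
        assert ws.windows.shape[0] == 4
        assert ws.sbp == rec.sbp and ws.dbp == rec.dbp
        # identical boundaries: windows re-cut from each filtered channel agree
        assert ws.win_len == 1000
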