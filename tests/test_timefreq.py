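"""Time-frequency chain: interpolation, filtering, Morlet power, dB, binning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tmstheta.timefreq import (
    TFMap,
    bandpass,
    bin_time,
    db_normalize,
    induced_tfr,
    interpolate_pulse_window,
    make_freq_grid,
    morlet_tfr,
)

from conftest import make_epochs


# ---------------------------------------------------------------------------
# pulse-window interpolation
# ---------------------------------------------------------------------------

class TestInterpolatePulseWindow:
    def test_linear_signal_unchanged(self):
        # a channel already linear over the window is a fixed point
        t = -1000.0 + np.arange(1000) / 500.0 * 1000.0
        data = (0.5 * t + 3.0)[None, None, :]
        ep = make_epochs(data)
        out = interpolate_pulse_window(ep)
        np.testing.assert_allclose(out.data, ep.data, atol=1e-9)

    def test_closed_form_line(self):
        # boundary values 0 at -1 ms and 16 at 15 ms give value = (t + 1)
        sfreq = 1000.0  # grid hits -1, 7 and 15 ms (to float rounding)
        n_s = 2000
        t = -1000.0 + np.arange(n_s) / sfreq * 1000.0
        i_lo = int(np.argmin(np.abs(t + 1.0)))
        i_hi = int(np.argmin(np.abs(t - 15.0)))
        data = np.zeros((1, 1, n_s))
        data[..., i_hi] = 16.0
        ep = make_epochs(data, sfreq=sfreq)
        out = interpolate_pulse_window(ep, t[i_lo], t[i_hi])
        i7 = int(np.argmin(np.abs(t - 7.0)))
        assert t[i7] == pytest.approx(7.0)
        assert out.data[0, 0, i7] == pytest.approx(8.0)
        inner = slice(i_lo + 1, i_hi)
        np.testing.assert_allclose(out.data[0, 0, inner], t[inner] + 1.0, atol=1e-9)

    def test_step_artifact_removed(self, rng):
        base = rng.standard_normal((3, 2, 1000))
        ep = make_epochs(base.copy())
        t = ep.times
        artifact = np.zeros_like(base)
        artifact[..., (t > -1.0) & (t < 15.0)] = 500.0
        noisy = make_epochs(base + artifact)
        out = interpolate_pulse_window(noisy)
        outside = ~((t > -1.0) & (t < 15.0))
        np.testing.assert_array_equal(out.data[..., outside], base[..., outside])
        inner = (t > -1.0) & (t < 15.0)
        assert np.abs(out.data[..., inner]).max() < 10.0

    def test_window_errors(self, rng):
        ep = make_epochs(rng.standard_normal((1, 1, 1000)))
        with pytest.raises(ValueError):
            interpolate_pulse_window(ep, 15.0, -1.0)
        with pytest.raises(ValueError):
            interpolate_pulse_window(ep, -2000.0, 15.0)


# ---------------------------------------------------------------------------
# band-pass filter contract
# ---------------------------------------------------------------------------

class TestBandpass:
    def test_passband_gain_and_latency(self, sine_epochs):
        ep = sine_epochs(50.0, n_epochs=1, n_s=2000)
        out = bandpass(ep)
        mid = slice(500, 1500)  # avoid filter edges
        amp = np.abs(out.data[0, 0, mid]).max()
        assert 0.95 <= amp <= 1.05
        # peak latency shift of the passband sinusoid <= 1 sample
        x, y = ep.data[0, 0, mid], out.data[0, 0, mid]
        lag = np.argmax(np.correlate(y, x, mode="full")) - (len(x) - 1)
        assert abs(lag) <= 1

    @pytest.mark.parametrize("freq", [1.5, 150.0])
    def test_stopband_attenuation(self, sine_epochs, freq):
        # >= 20 dB at 0.5*lo and 1.5*hi
        ep = sine_epochs(freq, n_epochs=1, n_s=4000)
        out = bandpass(ep)
        amp = np.abs(out.data[0, 0, 1000:3000]).max()
        assert amp <= 0.1

    def test_dc_removed(self):
        ep = make_epochs(np.full((1, 1, 2000), 7.0))
        out = bandpass(ep)
        assert np.abs(out.data).max() <= 0.7

    def test_default_edges_and_nyquist_guard(self, rng):
        ep = make_epochs(rng.standard_normal((1, 1, 1000)), sfreq=500.0)
        with pytest.raises(ValueError):
            bandpass(ep, 3.0, 250.0)
        bandpass(ep)  # defaults (3, 100) are valid at 500 Hz


# ---------------------------------------------------------------------------
# frequency grid
# ---------------------------------------------------------------------------

class TestFreqGrid:
    def test_endpoints_and_length(self):
        g = make_freq_grid()
        assert len(g) == 30
        assert g.freqs[0] == pytest.approx(3.0)
        assert g.freqs[-1] == pytest.approx(80.0)
        assert g.cycles[0] == pytest.approx(3.0)
        assert g.cycles[-1] == pytest.approx(10.0)

    def test_closed_form_midpoint(self):
        # f_k = 3 * (80/3)^((k-1)/29); oracle value for k = 15
        g = make_freq_grid()
        assert g.freqs[14] == pytest.approx(3.0 * (80.0 / 3.0) ** (14.0 / 29.0))
        assert g.cycles[14] == pytest.approx(3.0 * (10.0 / 3.0) ** (14.0 / 29.0))

    def test_geometric_progressions(self):
        g = make_freq_grid()
        for v in (g.freqs, g.cycles):
            ratios = v[1:] / v[:-1]
            np.testing.assert_allclose(ratios, ratios[0], rtol=1e-12)


# ---------------------------------------------------------------------------
# Morlet decomposition
# ---------------------------------------------------------------------------

class TestMorlet:
    def test_zero_input_zero_power(self):
        ep = make_epochs(np.zeros((2, 1, 1200)))
        tf = morlet_tfr(ep, make_freq_grid(n=10))
        assert np.all(tf.power == 0)

    def test_frequency_localization(self, sine_epochs, rng):
        # random-phase 6 Hz sinusoid peaks at the grid frequency nearest 6 Hz
        grid = make_freq_grid()
        ep = sine_epochs(6.0, n_epochs=8, n_s=1200, phase_rng=rng)
        tf = morlet_tfr(ep, grid)
        mid = tf.power[0, :, 500:700].mean(axis=-1)
        nearest = int(np.argmin(np.abs(grid.freqs - 6.0)))
        assert int(np.argmax(mid)) == nearest

    def test_power_averaging_not_amplitude_averaging(self, sine_epochs):
        # opposite-phase epochs: total power equals one epoch's power
        t = np.arange(1000) / 500.0
        x = np.cos(2 * np.pi * 8.0 * t)
        both = make_epochs(np.stack([x, -x])[:, None, :])
        one = make_epochs(x[None, None, :])
        grid = make_freq_grid(n=10)
        tf2 = morlet_tfr(both, grid)
        tf1 = morlet_tfr(one, grid)
        np.testing.assert_allclose(tf2.power, tf1.power, rtol=1e-4)

    def test_doubling_amplitude_quadruples_power(self, sine_epochs):
        grid = make_freq_grid(n=8)
        ep1 = sine_epochs(10.0, n_epochs=1, n_s=1200)
        ep2 = sine_epochs(10.0, n_epochs=1, n_s=1200, amp=2.0)
        p1 = morlet_tfr(ep1, grid).power
        p2 = morlet_tfr(ep2, grid).power
        np.testing.assert_allclose(p2, 4.0 * p1, rtol=1e-4)

    def test_too_short_epoch_names_frequency(self):
        ep = make_epochs(np.zeros((1, 1, 400)), sfreq=500.0, tmin=-400.0)
        with pytest.raises(ValueError, match="3 Hz"):
            morlet_tfr(ep, make_freq_grid())

    def test_matches_mne_after_db_normalization(self, rng):
        # independent route: mne's Morlet TFR on the same data
        mne = pytest.importorskip("mne")
        grid = make_freq_grid(n=8)
        ep = make_epochs(rng.standard_normal((5, 2, 1500)))
        ours = db_normalize(morlet_tfr(ep, grid))
        theirs_pow = mne.time_frequency.tfr_array_morlet(
            ep.data, ep.sfreq, grid.freqs, n_cycles=grid.cycles,
            output="avg_power", zero_mean=True, verbose="error",
        )
        theirs = db_normalize(
            TFMap(power=theirs_pow, freqs=grid.freqs, times=ep.times,
                  channels=ep.channels)
        )
        interior = slice(400, 1100)
        np.testing.assert_allclose(
            ours.power[:, 2:, interior], theirs.power[:, 2:, interior], atol=0.15
        )

    def test_edge_mask_clears_analysis_windows(self, rng):
        # default 2 s epoch: no flagged bin intersects [20, 300] ms
        ep = make_epochs(rng.standard_normal((2, 1, 1000)))
        tf = bin_time(db_normalize(morlet_tfr(ep, make_freq_grid())), 20.0)
        window = (tf.times >= 20.0) & (tf.times <= 300.0)
        assert not tf.edge_mask[:, window].any()


class TestInducedActivity:
    def test_identical_epochs_cancel(self, sine_epochs):
        ep = sine_epochs(8.0, n_epochs=4, n_s=1200)
        total = morlet_tfr(ep, make_freq_grid(n=8))
        ind = induced_tfr(ep, make_freq_grid(n=8))
        assert ind.power.max() < 1e-6 * total.power.max()

    def test_random_phase_keeps_power(self, sine_epochs, rng):
        # with random phases the ERP is ~0 and induced ~ total
        ep = sine_epochs(8.0, n_epochs=40, n_s=1200, phase_rng=rng)
        grid = make_freq_grid(n=8)
        total = morlet_tfr(ep, grid)
        ind = induced_tfr(ep, grid)
        k = int(np.argmin(np.abs(grid.freqs - 8.0)))
        mid = slice(400, 800)
        ratio = ind.power[0, k, mid].mean() / total.power[0, k, mid].mean()
        assert 0.85 < ratio < 1.05

    def test_removes_erp_keeps_burst(self, rng):
        # phase-locked ERP + random-phase burst: induced keeps only the burst
        sfreq, n_s, n_ep = 500.0, 1000, 30
        times = -1000.0 + np.arange(n_s) / sfreq * 1000.0
        erp = 5.0 * np.exp(-((times - 100.0) ** 2) / (2 * 20.0**2))
        env = np.exp(-((times - 400.0) ** 2) / (2 * 40.0**2))
        phases = rng.uniform(0, 2 * np.pi, n_ep)
        burst = 3.0 * env[None, :] * np.cos(
            2 * np.pi * 6.0 * times[None, :] / 1000.0 + phases[:, None]
        )
        ep = make_epochs((erp[None, :] + burst)[:, None, :], sfreq=sfreq)
        grid = make_freq_grid(n=12)
        total = morlet_tfr(ep, grid)
        ind = induced_tfr(ep, grid)
        k = int(np.argmin(np.abs(grid.freqs - 6.0)))
        t_erp = int(np.argmin(np.abs(times - 100.0)))
        t_burst = int(np.argmin(np.abs(times - 400.0)))
        # burst power survives, ERP power collapses
        assert ind.power[0, k, t_burst] > 0.5 * total.power[0, k, t_burst]
        assert ind.power[0, k, t_erp] < 0.2 * total.power[0, k, t_erp]

    def test_single_epoch_rejected(self):
        ep = make_epochs(np.zeros((1, 1, 1000)))
        with pytest.raises(ValueError):
            induced_tfr(ep, make_freq_grid(n=5))


# ---------------------------------------------------------------------------
# dB normalization
# ---------------------------------------------------------------------------

def _linear_map(power, sfreq=500.0, tmin=-1000.0):
    power = np.asarray(power, dtype=float)
    times = tmin + np.arange(power.shape[-1]) / sfreq * 1000.0
    return TFMap(power=power, freqs=np.arange(power.shape[0]) + 1.0, times=times)


class TestDbNormalize:
    def test_constant_map_is_zero(self):
        tf = db_normalize(_linear_map(np.full((3, 1000), 4.2)))
        np.testing.assert_allclose(tf.power, 0.0, atol=1e-12)

    def test_tenfold_is_ten_db(self):
        p = np.ones((1, 1000))
        p[0, 600] = 10.0
        tf = db_normalize(_linear_map(p))
        # baseline window excludes the bumped sample, so baseline mean is 1
        assert tf.power[0, 600] == pytest.approx(10.0, abs=1e-12)

    def test_baseline_ratio_mean_is_one(self, rng):
        # conservation: mean over baseline of linear ratios = 1 per frequency
        tf = db_normalize(_linear_map(rng.uniform(0.5, 2.0, (5, 1000))))
        mask = (tf.times >= -400.0) & (tf.times <= -200.0)
        ratios = 10.0 ** (tf.power[:, mask] / 10.0)
        np.testing.assert_allclose(ratios.mean(axis=1), 1.0, rtol=1e-13)

    def test_errors(self, rng):
        tf = _linear_map(rng.uniform(0.5, 2.0, (2, 1000)))
        with pytest.raises(ValueError):
            db_normalize(tf, (-5000.0, -200.0))
        bad = _linear_map(np.zeros((2, 1000)))
        with pytest.raises(ValueError):
            db_normalize(bad)


# ---------------------------------------------------------------------------
# temporal binning
# ---------------------------------------------------------------------------

class TestBinTime:
    def test_pairwise_means(self):
        tf = _linear_map(np.array([[1.0, 2.0, 3.0, 4.0]]), sfreq=100.0)
        out = bin_time(tf, 20.0)  # 2 samples per bin at 100 Hz
        np.testing.assert_allclose(out.power, [[1.5, 3.5]])

    def test_constant_preserved(self):
        tf = _linear_map(np.full((2, 1000), 3.3))
        out = bin_time(tf, 20.0)
        np.testing.assert_allclose(out.power, 3.3)
        assert out.power.shape[-1] == 100

    @settings(deadline=None, max_examples=40)
    @given(n=st.integers(20, 1500), spb=st.integers(1, 25))
    def test_bin_count_oracle(self, n, spb):
        sfreq = 1000.0
        tf = _linear_map(np.ones((1, n)), sfreq=sfreq)
        out = bin_time(tf, spb * 1000.0 / sfreq)
        assert out.power.shape[-1] == n // spb

    def test_width_error(self):
        tf = _linear_map(np.ones((1, 100)), sfreq=100.0)
        with pytest.raises(ValueError):
            bin_time(tf, 5.0)  # half a sample interval

    def test_normalize_then_bin_order_is_pinned(self, rng):
        # Jensen: dB of bin-mean != bin-mean of dB; the chain uses dB first
        p = rng.uniform(0.5, 4.0, (3, 1000))
        a = bin_time(db_normalize(_linear_map(p)), 20.0).power
        b = db_normalize(bin_time(_linear_map(p), 20.0)).power
        assert not np.allclose(a, b)
        from tmstheta.pipeline import PipelineConfig, preprocess_and_tfr

        ep = make_epochs(rng.standard_normal((3, 1, 1000)))
        cfg = PipelineConfig(n_freqs=6)
        got = preprocess_and_tfr({"s": {"x": ep}}, cfg)["s"]["x"]
        from tmstheta.timefreq import bandpass as _bp, interpolate_pulse_window as _ip
        from tmstheta.timefreq import make_freq_grid as _mg

        manual = bin_time(db_normalize(morlet_tfr(_bp(_ip(ep)), _mg(n=6))), 20.0)
        np.testing.assert_allclose(got.power, manual.power)
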