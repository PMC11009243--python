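"""Waveform analysis pipeline: normalization, peaks, PSTH, statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import signal

from ernakit import analysis, synth
from ernakit.analysis import (
    build_psth,
    detect_p1_p2,
    erna_firing_table,
    fit_mixed_slope,
    peak_dynamics,
    peak_series,
    peak_series_from_trace,
    prestim_rms,
    psth_trough,
    segment_interstim,
    spearman_rho,
    waveform_average,
    within_site_consistency,
)
from ernakit.errors import (
    ConfigurationError,
    InsufficientBaselineError,
    ProtocolError,
    UndefinedDynamicsError,
)
from ernakit.recording import Recording

FS = 10_000.0


def make_recording(voltage, pulse_times=(), spike_times=(), fs=FS, **meta):
    return Recording(fs=fs, voltage=np.asarray(voltage, float),
                     pulse_times=np.asarray(pulse_times, float),
                     spike_times=np.asarray(spike_times, float), metadata=meta)


class TestPrestimRMS:
    def test_sine_closed_form(self):
        """A pure in-band sinusoid has RMS = amplitude / sqrt(2)."""
        t = np.arange(int(5 * FS)) / FS
        rec = make_recording(3.0 * np.sin(2 * np.pi * 100 * t), pulse_times=[4.5])
        assert prestim_rms(rec) == pytest.approx(3.0 / np.sqrt(2), rel=0.02)

    def test_white_noise_filter_gain_oracle(self, rng):
        """Band-limited RMS of white noise matches the zero-phase filter's
        power gain integrated over the spectrum (Parseval)."""
        sigma = 2.0
        rec = make_recording(sigma * rng.standard_normal(int(8 * FS)),
                             pulse_times=[7.5])
        sos = signal.butter(4, (10, 250), btype="bandpass", fs=FS, output="sos")
        w, h = signal.sosfreqz(sos, worN=8192, fs=FS)
        expected = sigma * np.sqrt(np.mean(np.abs(h) ** 4))  # filtfilt: |H|^2
        assert prestim_rms(rec) == pytest.approx(expected, rel=0.05)

    def test_dc_only_trace_is_degenerate(self):
        rec = make_recording(np.full(int(3 * FS), 7.0), pulse_times=[2.5])
        with pytest.raises(InsufficientBaselineError):
            prestim_rms(rec)

    def test_short_baseline_rejected(self):
        rec = make_recording(np.random.default_rng(0).standard_normal(int(FS)),
                             pulse_times=[0.5])
        with pytest.raises(InsufficientBaselineError):
            prestim_rms(rec)


class TestSegmentation:
    @pytest.mark.parametrize("freq,expected", [(100.0, 999), (10.0, 99)])
    def test_segment_counts(self, freq, expected):
        pulses = 0.0 + np.arange(int(10 * freq)) / freq
        rec = make_recording(np.zeros(int(10.5 * FS)), pulse_times=pulses)
        segments, grid = segment_interstim(rec, blanking_ms=1.5)
        assert segments.shape[0] == expected

    def test_blanking_defines_grid_start(self):
        pulses = np.arange(100) / 100.0
        rec = make_recording(np.zeros(int(1.5 * FS)), pulse_times=pulses)
        _, grid = segment_interstim(rec, blanking_ms=2.0)
        assert grid[0] == pytest.approx(2.0)
        assert grid[-1] <= 10.0

    def test_malformed_pulses_rejected(self):
        rec = make_recording(np.zeros(int(FS)))
        rec.pulse_times = np.array([0.1, 0.3, 0.2])
        with pytest.raises(ProtocolError):
            segment_interstim(rec)
        with pytest.raises(ProtocolError):
            segment_interstim(
                make_recording(np.zeros(int(FS)), pulse_times=np.arange(50) / 100.0),
                blanking_ms=20.0,
            )


class TestDetectPeaks:
    def test_flat_segment_reports_missing(self):
        grid = np.arange(15, 100) / 10.0
        p1, p2, l1, l2 = detect_p1_p2(np.zeros(grid.size), grid, baseline=0.0)
        assert np.isnan(p1) and np.isnan(p2)

    def test_damped_cosine_analytic_extrema(self):
        """Peak amplitudes match the closed-form extrema of a damped cosine
        within one sample."""
        tau, omega, t0 = 6.0, 2 * np.pi / 3.1, 3.2
        grid = np.arange(15, 100) / 10.0  # 1.5-10 ms
        v = np.exp(-(grid - t0) / tau) * np.cos(omega * (grid - t0))
        # extrema: tan(omega (t - t0)) = -1/(omega tau)
        phi = np.arctan(-1.0 / (omega * tau))
        t_max = t0 + phi / omega + np.pi / omega  # first max after t0 is k=0 at t0...
        # candidate extremum times within the window
        ts = t0 + (phi + np.pi * np.arange(-2, 6)) / omega
        vals = np.exp(-(ts - t0) / tau) * np.cos(omega * (ts - t0))
        maxima = ts[vals > 0]
        p1_t = maxima[(maxima >= 2.0) & (maxima <= 5.0)][0]
        p2_t = maxima[(maxima >= 5.0) & (maxima <= 9.0)][0]
        minima = ts[vals < 0]
        trough_t = minima[(minima > p1_t) & (minima < p2_t)][0]

        def value(t):
            return np.exp(-(t - t0) / tau) * np.cos(omega * (t - t0))

        p1, p2, l1, l2 = detect_p1_p2(v, grid, baseline=0.0)
        assert l1 == pytest.approx(p1_t, abs=0.1)
        assert l2 == pytest.approx(p2_t, abs=0.1)
        assert p1 == pytest.approx(value(p1_t), abs=0.02)
        assert p2 == pytest.approx(value(p2_t) - value(trough_t), abs=0.02)

    def test_normalization_divides_amplitudes(self):
        grid = np.arange(15, 100) / 10.0
        v = np.exp(-0.5 * ((grid - 3.2) / 0.5) ** 2)
        p1a, *_ = detect_p1_p2(v, grid, baseline=0.0, normalization=1.0)
        p1b, *_ = detect_p1_p2(v, grid, baseline=0.0, normalization=4.0)
        assert p1a == pytest.approx(4.0 * p1b)

    def test_segment_must_cover_windows(self):
        grid = np.arange(15, 40) / 10.0  # ends at 4 ms
        with pytest.raises(ConfigurationError):
            detect_p1_p2(np.zeros(grid.size), grid, baseline=0.0)


class TestPeakDynamics:
    def make_series(self, p1, p2):
        n = len(p1)
        return analysis.PeakSeries(np.asarray(p1, float), np.asarray(p2, float),
                                   np.full(n, 3.0), np.full(n, 6.0))

    def test_constant_amplitudes_give_unity(self):
        s = self.make_series(np.ones(50), 2 * np.ones(50))
        d = peak_dynamics(s)
        assert d.p1_ratio == pytest.approx(1.0)
        assert d.p2_ratio == pytest.approx(1.0)

    def test_linear_decay_arithmetic_oracle(self):
        """Amplitudes falling linearly to 50% by pulse 40: the ratio is the
        plain arithmetic mean of pulses 40-45 over pulse 1."""
        amps = np.concatenate([np.linspace(1.0, 0.5, 40), np.full(10, 0.5)])
        expected = np.mean(amps[39:45]) / amps[0]
        d = peak_dynamics(self.make_series(amps, amps))
        assert d.p1_ratio == pytest.approx(expected)

    def test_missing_first_pulse_is_error(self):
        amps = np.ones(50)
        bad = amps.copy()
        bad[0] = np.nan
        with pytest.raises(UndefinedDynamicsError):
            peak_dynamics(self.make_series(bad, amps))

    def test_too_few_pulses(self):
        with pytest.raises(UndefinedDynamicsError):
            peak_dynamics(self.make_series(np.ones(30), np.ones(30)))

    def test_missing_late_zero_semantics(self):
        amps = np.ones(50)
        gone = amps.copy()
        gone[35:] = np.nan
        with pytest.raises(UndefinedDynamicsError):
            peak_dynamics(self.make_series(amps, gone))
        d = peak_dynamics(self.make_series(amps, gone), missing_late="zero")
        assert d.p2_ratio == 0.0


class TestPSTH:
    def test_no_spikes_all_zero(self):
        psth = build_psth([], np.arange(100) / 100.0)
        assert psth.rate.sum() == 0.0

    def test_homogeneous_poisson_oracle(self, rng):
        """Folding homogeneous Poisson spikes gives a flat PSTH at the
        source rate within sampling error."""
        rate, dur = 40.0, 200.0
        spikes = np.sort(rng.uniform(0, dur, rng.poisson(rate * dur)))
        pulses = np.arange(int(dur * 100)) / 100.0
        psth = build_psth(spikes, pulses, bin_ms=0.5)
        n_per_bin = rate * 0.0005 * (len(pulses) - 1)
        tol = 4 * rate / np.sqrt(n_per_bin)
        assert np.abs(psth.rate - rate).max() < tol
        assert psth.rate.mean() == pytest.approx(rate, rel=0.03)

    def test_constructed_trough_is_found(self, rng):
        """Spikes thinned in 5-7 ms post-pulse leave a local minimum there."""
        pulses = np.arange(500) / 100.0
        spikes = np.sort(rng.uniform(0, 5.0, 8000))
        offset = (spikes * 1000) % 10.0
        keep = ~((offset >= 5.0) & (offset < 7.0)) | (rng.random(spikes.size) < 0.1)
        psth = build_psth(spikes[keep], pulses, bin_ms=0.5)
        centers = psth.bin_centers
        in_window = psth.rate[(centers >= 5.0) & (centers <= 7.0)].min()
        outside = psth.rate[(centers < 5.0) | (centers > 7.0)].mean()
        assert in_window < 0.5 * outside
        assert psth_trough(psth) == pytest.approx(in_window)

    def test_baseline_rate_from_prestim_window(self, rng):
        pulses = 2.0 + np.arange(100) / 100.0
        spikes = np.sort(rng.uniform(0, 2.0, 80))  # 40 Hz before the train
        psth = build_psth(spikes, pulses)
        assert psth.baseline_rate == pytest.approx(40.0)


class TestInvariances:
    def test_scaling_voltage_leaves_normalized_outputs(self, noisy_recording):
        """Amplitude normalization makes every statistic scale-invariant."""
        rec = noisy_recording
        scaled = Recording(fs=rec.fs, voltage=rec.voltage * 37.5,
                           pulse_times=rec.pulse_times, spike_times=rec.spike_times,
                           metadata=rec.metadata)
        a = peak_series(rec)
        b = peak_series(scaled)
        np.testing.assert_allclose(a.p1, b.p1, rtol=1e-9, equal_nan=True)
        np.testing.assert_allclose(a.p2, b.p2, rtol=1e-9, equal_nan=True)
        wa = waveform_average(rec)
        wb = waveform_average(scaled)
        np.testing.assert_allclose(wa.mean_waveform, wb.mean_waveform, rtol=1e-9)

    def test_time_shift_invariance(self, clean_recording):
        """Shifting pulses, spikes and trace by a constant changes nothing."""
        rec = clean_recording
        shift_samples = 5000
        shift = shift_samples / rec.fs
        shifted = Recording(
            fs=rec.fs,
            voltage=np.concatenate([np.zeros(shift_samples), rec.voltage]),
            pulse_times=rec.pulse_times + shift,
            spike_times=rec.spike_times + shift,
            metadata=rec.metadata,
        )
        a = peak_series_from_trace(rec.voltage, rec.fs, rec.pulse_times)
        b = peak_series_from_trace(shifted.voltage, shifted.fs, shifted.pulse_times)
        np.testing.assert_allclose(a.p1, b.p1, atol=1e-12, equal_nan=True)
        np.testing.assert_allclose(a.p2, b.p2, atol=1e-12, equal_nan=True)
        spikes = np.sort(np.random.default_rng(3).uniform(0, 1, 200)) + rec.pulse_times[0]
        pa = build_psth(spikes, rec.pulse_times, baseline_window=(0.0, 1.0))
        pb = build_psth(spikes + shift, rec.pulse_times + shift,
                        baseline_window=(shift, 1.0 + shift))
        np.testing.assert_allclose(pa.rate, pb.rate)


class TestSpearman:
    @staticmethod
    def rho_oracle(x, y):
        """Brute-force rank correlation with average ranks."""
        def ranks(v):
            v = np.asarray(v, float)
            order = np.argsort(v, kind="stable")
            r = np.empty(len(v))
            i = 0
            sorted_v = v[order]
            while i < len(v):
                j = i
                while j < len(v) and sorted_v[j] == sorted_v[i]:
                    j += 1
                r[order[i:j]] = (i + j + 1) / 2.0
                i = j
            return r
        rx, ry = ranks(x), ranks(y)
        rx -= rx.mean()
        ry -= ry.mean()
        return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))

    @pytest.mark.parametrize("n", [3, 4, 5])
    def test_all_permutations_match_oracle(self, n):
        y = np.arange(n, dtype=float)
        for perm in itertools.permutations(range(n)):
            x = np.array(perm, dtype=float)
            assert spearman_rho(x, y) == pytest.approx(self.rho_oracle(x, y))

    def test_ties_use_average_ranks(self):
        x = np.array([1.0, 1.0, 2.0, 3.0])
        y = np.array([4.0, 2.0, 2.0, 1.0])
        assert spearman_rho(x, y) == pytest.approx(self.rho_oracle(x, y))

    def test_constant_input_is_nan(self):
        assert np.isnan(spearman_rho(np.ones(3), np.arange(3.0)))


def _sites_table(values):
    """Table with one site per (x, y) triple."""
    rows = []
    for site, (xs, ys) in enumerate(values):
        for x, y in zip(xs, ys):
            rows.append({"site": site, "x": float(x), "y": float(y)})
    return pd.DataFrame(rows)


class TestWithinSiteConsistency:
    def test_all_decreasing_is_degenerate(self):
        table = _sites_table([((1, 2, 3), (9, 5, 1))] * 6)
        out = within_site_consistency(table, "x", "y")
        assert np.all(out["rho_values"] == -1.0)
        assert out["degenerate"] and out["p"] == 0.0

    def test_hand_computed_t_statistic(self):
        """rho = {-1, -0.5, 0.5}: t = mean / (sd/sqrt(3))."""
        table = _sites_table([
            ((1, 2, 3), (3, 2, 1)),   # rho -1
            ((1, 2, 3), (2, 3, 1)),   # rho -0.5
            ((1, 2, 3), (2, 1, 3)),   # rho +0.5
        ])
        out = within_site_consistency(table, "x", "y")
        rhos = np.array([-1.0, -0.5, 0.5])
        t_expected = rhos.mean() / (rhos.std(ddof=1) / np.sqrt(3))
        assert out["t"] == pytest.approx(t_expected)
        assert out["p_bonferroni"] == pytest.approx(min(1.0, out["p"] * 4))

    def test_tied_sites_excluded(self):
        table = _sites_table([
            ((1, 2, 3), (3, 2, 1)),
            ((1, 2, 3), (5, 5, 5)),   # constant: rho undefined
            ((1, 2, 3), (1, 2, 3)),
        ])
        out = within_site_consistency(table, "x", "y")
        assert out["excluded_sites"] == [1]
        assert out["n"] == 2


class TestMixedSlope:
    def test_perfect_common_slope_recovered_exactly(self):
        """Noise-free data with slope -13 and distinct intercepts."""
        rows = []
        for site, b0 in enumerate((10.0, 30.0, 50.0, 20.0)):
            for x in (0.0, 1.0, 2.0):
                rows.append({"site": site, "x": x, "y": b0 - 13.0 * x})
        out = fit_mixed_slope(pd.DataFrame(rows), "x", "y")
        assert out["slope"] == pytest.approx(-13.0, abs=1e-6)

    def test_zero_group_variance_equals_ols(self, rng):
        """All intercepts equal: the mixed slope collapses to OLS."""
        x = np.tile(np.array([0.0, 1.0, 2.0]), 15)
        sites = np.repeat(np.arange(15), 3)
        y = 4.0 - 2.5 * x + 0.3 * rng.standard_normal(x.size)
        table = pd.DataFrame({"site": sites, "x": x, "y": y})
        out = fit_mixed_slope(table, "x", "y")
        ols = np.polyfit(x, y, 1)[0]
        assert out["slope"] == pytest.approx(ols, abs=1e-3)

    def test_parameter_recovery_coverage(self, rng):
        """Random-intercept simulations: the 95% CI covers the true slope
        in the vast majority of replicates."""
        beta, hits, n_rep = -7.0, 0, 80
        for _ in range(n_rep):
            sites = np.repeat(np.arange(20), 3)
            x = rng.uniform(0, 2, sites.size)
            b0 = rng.normal(0, 3.0, 20)[sites]
            y = b0 + beta * x + rng.standard_normal(sites.size)
            out = fit_mixed_slope(pd.DataFrame({"site": sites, "x": x, "y": y}),
                                  "x", "y")
            if abs(out["slope"] - beta) <= 1.96 * out["se"]:
                hits += 1
        assert hits / n_rep >= 0.85

    def test_needs_two_groups(self):
        table = pd.DataFrame({"site": [0, 0], "x": [0.0, 1.0], "y": [0.0, 1.0]})
        with pytest.raises(ConfigurationError):
            fit_mixed_slope(table, "x", "y")


@pytest.fixture(scope="module")
def cohort_table():
    cfg = synth.CohortConfig.fig2_style(seed=5, duration=4.0)
    recordings, _ = synth.generate_cohort(cfg)
    return erna_firing_table(recordings)


class TestCohortTable:
    def test_sixty_rows_and_completeness(self, cohort_table):
        """20 sites x 3 intensities = 60 rows, all complete."""
        assert len(cohort_table) == 60
        assert cohort_table["complete"].all()

    def test_negative_association_built_in(self, cohort_table):
        """Stronger ERNA <-> suppressed interstimulus firing, by the
        generator's coupling construction."""
        out = fit_mixed_slope(cohort_table, "log_erna_amp_4_9ms",
                              "mean_firing_4_9ms")
        assert out["slope"] < 0 and out["p"] < 0.01
        within = within_site_consistency(cohort_table, "log_erna_amp_4_9ms",
                                         "mean_firing_4_9ms")
        assert within["mean_rho"] < 0
        within_p2 = within_site_consistency(cohort_table, "log_p2_amp",
                                            "trough_firing_5_7ms")
        assert within_p2["mean_rho"] < 0

    def test_zero_amplitude_rows_flagged(self):
        cfg = synth.CohortConfig.fig2_style(seed=5, duration=4.0)
        rec = synth.generate_recording(seed=1, duration=4.0, template=cfg.template)
        zero = Recording(fs=rec.fs, voltage=np.random.default_rng(0)
                         .standard_normal(len(rec.voltage)),
                         pulse_times=rec.pulse_times, spike_times=rec.spike_times,
                         metadata={"site": 99, "intensity_ua": 30,
                                   "frequency_hz": 100.0})
        table = erna_firing_table([zero])
        assert not table["complete"].iloc[0]
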