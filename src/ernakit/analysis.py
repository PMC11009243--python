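"""Empirical ERNA waveform and spiking analysis.

Implements the measurement pipeline applied to microelectrode recordings
during DBS: interstimulus segmentation and averaging, extraction of the
first (P1) and second (P2) evoked peaks and their temporal dynamics,
peristimulus spike histograms, and the site-level statistics linking
ERNA amplitude to time-locked suppression of single-unit firing.

Conventions (all configurable):

* amplitudes are normalized by the pre-stimulation RMS of the 10–250 Hz
  band-passed LFP;
* P1 is measured against the immediate pre-stimulus baseline, P2 against
  the intervening interstimulus trough;
* peak dynamics are summarized as mean amplitude over pulses 40–45
  divided by the first-pulse amplitude;
* windowed statistics use the 4–9 ms window (captures P1+P2) and the
  5–7 ms window (firing trough).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats

from .errors import (
    ConfigurationError,
    InsufficientBaselineError,
    ProtocolError,
    UndefinedDynamicsError,
)
from .recording import Recording

DEFAULT_BAND = (10.0, 250.0)
DEFAULT_BLANKING_MS = 1.5
DEFAULT_P1_WINDOW = (2.0, 5.0)   # ms post-pulse
DEFAULT_P2_WINDOW = (5.0, 9.0)
ERNA_WINDOW = (4.0, 9.0)         # ms; captures P1 and P2
TROUGH_WINDOW = (5.0, 7.0)       # ms; firing local minimum
N_HYPOTHESES = 4                 # Bonferroni family for the module's tests


@dataclass(frozen=True)
class WaveformAverage:
    time_grid: np.ndarray      # ms post-pulse
    mean_waveform: np.ndarray  # units of pre-stim RMS
    n_segments: int


@dataclass(frozen=True)
class PeakSeries:
    """Per-pulse P1/P2 amplitudes and latencies; NaN marks a missing peak."""

    p1: np.ndarray
    p2: np.ndarray
    p1_latency_ms: np.ndarray
    p2_latency_ms: np.ndarray
    normalization: float = 1.0


@dataclass(frozen=True)
class DynamicsSummary:
    p1_ratio: float   # mean(P1 at pulses 40–45) / P1 at pulse 1
    p2_ratio: float


@dataclass(frozen=True)
class PSTH:
    bin_edges: np.ndarray   # ms post-pulse
    rate: np.ndarray        # Hz per bin
    baseline_rate: float    # Hz, pre-stimulation

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


# --------------------------------------------------------------------------
# normalization and segmentation

def bandpass(voltage: np.ndarray, fs: float, band=DEFAULT_BAND, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass (applied forward and backward)."""
    sos = signal.butter(order, band, btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, voltage)


def prestim_rms(recording: Recording, band=DEFAULT_BAND) -> float:
    """RMS of the band-passed LFP over the pre-stimulation window.

    This is the normalization constant for all amplitude measurements.
    Requires >= 1 s of baseline (ten cycles of the 10 Hz low edge).
    """
    min_window = 10.0 / band[0]
    if recording.prestim_window < min_window:
        raise InsufficientBaselineError(
            f"pre-stimulation window {recording.prestim_window:.3f} s < "
            f"{min_window:.1f} s (10 cycles at {band[0]} Hz)"
        )
    n = int(recording.prestim_window * recording.fs)
    filtered = bandpass(recording.voltage[:n], recording.fs, band)
    rms = float(np.sqrt(np.mean(filtered**2)))
    if rms < 1e-12 * max(1.0, float(np.max(np.abs(recording.voltage), initial=0.0))):
        raise InsufficientBaselineError("degenerate baseline: band-passed RMS ~ 0")
    return rms


def segment_interstim(
    recording: Recording, blanking_ms: float = DEFAULT_BLANKING_MS
) -> tuple[np.ndarray, np.ndarray]:
    """Fold the trace into per-pulse segments on a common grid.

    Returns ``(segments, time_grid_ms)`` where row k covers pulse k from
    ``blanking_ms`` after the pulse to the next pulse.  The last pulse has
    no following pulse and is dropped.
    """
    pulses = recording.pulse_times
    if len(pulses) < 2:
        raise ProtocolError("need at least two pulses to segment")
    intervals = np.diff(pulses)
    if np.any(intervals <= 0):
        raise ProtocolError("pulse times must be strictly increasing")
    period = float(np.median(intervals))
    if np.any(np.abs(intervals - period) > 0.01 * period):
        raise ProtocolError("irregular pulse train: intervals vary by > 1%")
    if blanking_ms / 1000.0 >= period:
        raise ProtocolError(
            f"blanking {blanking_ms} ms >= interstimulus interval {period*1000:.1f} ms"
        )
    fs = recording.fs
    n_skip = int(round(blanking_ms / 1000.0 * fs))
    n_samp = int(np.floor(period * fs)) - n_skip
    starts = np.round(pulses[:-1] * fs).astype(int) + n_skip
    idx = starts[:, None] + np.arange(n_samp)[None, :]
    if idx[-1, -1] >= len(recording.voltage):
        keep = idx[:, -1] < len(recording.voltage)
        idx = idx[keep]
        starts = starts[keep]
    segments = recording.voltage[idx]
    time_grid = (np.arange(n_samp) + n_skip) / fs * 1000.0
    return segments, time_grid


def waveform_average(
    recording: Recording,
    blanking_ms: float = DEFAULT_BLANKING_MS,
    normalization: float | None = None,
) -> WaveformAverage:
    """Interstimulus waveform average in units of pre-stimulation RMS."""
    segments, grid = segment_interstim(recording, blanking_ms)
    norm = prestim_rms(recording) if normalization is None else normalization
    return WaveformAverage(
        time_grid=grid,
        mean_waveform=segments.mean(axis=0) / norm,
        n_segments=segments.shape[0],
    )


# --------------------------------------------------------------------------
# peak extraction

def _local_maxima(y: np.ndarray) -> np.ndarray:
    """Indices of strictly interior local maxima (plateau-tolerant)."""
    peaks, _ = signal.find_peaks(y)
    return peaks


def detect_p1_p2(
    values: np.ndarray,
    time_grid_ms: np.ndarray,
    baseline: float,
    p1_window=DEFAULT_P1_WINDOW,
    p2_window=DEFAULT_P2_WINDOW,
    normalization: float = 1.0,
    p1_from_trough: bool = False,
) -> tuple[float, float, float, float]:
    """Extract P1 and P2 from one interstimulus segment (or average).

    P1 is the dominant local maximum in ``p1_window`` minus the
    immediate pre-stimulus ``baseline``; P2 is the dominant local
    maximum in ``p2_window`` minus the intervening trough (the minimum
    between the two peaks).  A window without a local maximum yields
    NaN — the peak is recorded as missing, never as zero.

    ``p1_from_trough`` instead references P1 to the minimum of the
    segment preceding the P1 peak — appropriate for readouts that do
    not return to baseline within the interstimulus interval (the
    simulator's conductance proxy).

    Returns ``(p1, p2, p1_latency_ms, p2_latency_ms)`` with amplitudes
    divided by ``normalization``.
    """
    if time_grid_ms[-1] < p2_window[1]:
        raise ConfigurationError(
            f"segment ends at {time_grid_ms[-1]:.2f} ms, before the P2 window "
            f"{p2_window}"
        )
    peaks = _local_maxima(values)
    t_peaks = time_grid_ms[peaks]
    p1 = p2 = lat1 = lat2 = float("nan")
    in_p1 = peaks[(t_peaks >= p1_window[0]) & (t_peaks <= p1_window[1])]
    if in_p1.size:
        i1 = in_p1[np.argmax(values[in_p1])]
        ref = np.min(values[: i1 + 1]) if p1_from_trough else baseline
        p1 = (values[i1] - ref) / normalization
        lat1 = time_grid_ms[i1]
    in_p2 = peaks[(t_peaks >= p2_window[0]) & (t_peaks <= p2_window[1])]
    if in_p1.size and in_p2.size:
        i2 = in_p2[np.argmax(values[in_p2])]
        trough = np.min(values[i1: i2 + 1])
        p2 = (values[i2] - trough) / normalization
        lat2 = time_grid_ms[i2]
    elif in_p2.size:
        # no P1: measure P2 against the window-start minimum
        i2 = in_p2[np.argmax(values[in_p2])]
        start = np.searchsorted(time_grid_ms, p1_window[0])
        trough = np.min(values[start: i2 + 1])
        p2 = (values[i2] - trough) / normalization
        lat2 = time_grid_ms[i2]
    return float(p1), float(p2), float(lat1), float(lat2)


def peak_series_from_trace(
    voltage: np.ndarray,
    fs: float,
    pulse_times: np.ndarray,
    blanking_ms: float = DEFAULT_BLANKING_MS,
    p1_window=DEFAULT_P1_WINDOW,
    p2_window=DEFAULT_P2_WINDOW,
    normalization: float = 1.0,
    baseline_ms: float = 0.5,
    smooth_pulses: int = 1,
    smooth_ms: float = 0.0,
    p1_from_trough: bool = False,
) -> PeakSeries:
    """Per-pulse P1/P2 series from a raw trace.

    The immediate pre-stimulus baseline of each pulse is the mean of the
    ``baseline_ms`` preceding it.  ``smooth_pulses`` > 1 applies a short
    running average across consecutive segments before detection;
    ``smooth_ms`` > 0 applies a boxcar of that width along time (useful
    for traces with shot-noise granularity, e.g. spike-driven
    conductance readouts).
    """
    voltage = np.asarray(voltage, dtype=float)
    if smooth_ms > 0:
        width = max(1, int(round(smooth_ms / 1000.0 * fs)))
        kernel = np.ones(width) / width
        voltage = np.convolve(voltage, kernel, mode="same")
    rec = Recording(fs=fs, voltage=voltage, pulse_times=pulse_times, spike_times=[])
    segments, grid = segment_interstim(rec, blanking_ms)
    if smooth_pulses > 1:
        kernel = np.ones(smooth_pulses) / smooth_pulses
        segments = np.apply_along_axis(
            lambda c: np.convolve(c, kernel, mode="same"), 0, segments
        )
    n_base = max(1, int(round(baseline_ms / 1000.0 * fs)))
    starts = np.round(pulse_times[: segments.shape[0]] * fs).astype(int)
    p1 = np.empty(segments.shape[0])
    p2 = np.empty(segments.shape[0])
    l1 = np.empty(segments.shape[0])
    l2 = np.empty(segments.shape[0])
    for k in range(segments.shape[0]):
        lo = max(0, starts[k] - n_base)
        baseline = float(np.mean(voltage[lo: starts[k]])) if starts[k] > lo else 0.0
        p1[k], p2[k], l1[k], l2[k] = detect_p1_p2(
            segments[k], grid, baseline, p1_window, p2_window, normalization,
            p1_from_trough=p1_from_trough,
        )
    return PeakSeries(p1=p1, p2=p2, p1_latency_ms=l1, p2_latency_ms=l2,
                      normalization=normalization)


def peak_series(
    recording: Recording,
    blanking_ms: float = DEFAULT_BLANKING_MS,
    p1_window=DEFAULT_P1_WINDOW,
    p2_window=DEFAULT_P2_WINDOW,
    smooth_pulses: int = 1,
) -> PeakSeries:
    """Per-pulse P1/P2 series of a recording, RMS-normalized."""
    norm = prestim_rms(recording)
    return peak_series_from_trace(
        recording.voltage, recording.fs, recording.pulse_times,
        blanking_ms, p1_window, p2_window, normalization=norm,
        smooth_pulses=smooth_pulses,
    )


def peak_dynamics(series: PeakSeries, late=(40, 45),
                  missing_late: str = "error") -> DynamicsSummary:
    """Temporal-dynamics ratios: mean late-train amplitude over the first.

    ``late`` is the inclusive 1-based pulse range averaged in the
    numerator (default pulses 40–45).  ``missing_late`` controls what an
    entirely undetected late-window peak means: ``"error"`` (empirical
    default — the measurement is undefined) or ``"zero"`` (the peak was
    abolished; appropriate for model ablations where the evoked
    component genuinely vanishes).
    """
    lo, hi = late
    if len(series.p1) < hi:
        raise UndefinedDynamicsError(
            f"need >= {hi} pulses with peaks, got {len(series.p1)}"
        )

    def ratio(x: np.ndarray) -> float:
        first = x[0]
        if not math.isfinite(first) or first == 0:
            raise UndefinedDynamicsError("first-pulse peak missing or zero")
        window = x[lo - 1: hi]
        if np.all(np.isnan(window)):
            if missing_late == "zero":
                return 0.0
            raise UndefinedDynamicsError("no detected peaks in the late window")
        return float(np.nanmean(window) / first)

    return DynamicsSummary(p1_ratio=ratio(series.p1), p2_ratio=ratio(series.p2))


# --------------------------------------------------------------------------
# spiking

def build_psth(
    spike_times: np.ndarray,
    pulse_times: np.ndarray,
    bin_ms: float = 0.5,
    baseline_window: tuple[float, float] | None = None,
) -> PSTH:
    """Peristimulus time histogram folded over all interstimulus intervals.

    Spike times are referenced to the preceding pulse; counts are
    converted to Hz by dividing by (number of intervals x bin width).
    ``baseline_window`` (s) defaults to everything before the first pulse.
    """
    pulse_times = np.asarray(pulse_times, dtype=float)
    spike_times = np.asarray(spike_times, dtype=float)
    if len(pulse_times) < 2:
        raise ProtocolError("need at least two pulses for a PSTH")
    period_ms = float(np.median(np.diff(pulse_times))) * 1000.0
    n_bins = int(np.floor(period_ms / bin_ms))
    edges = np.arange(n_bins + 1) * bin_ms
    t0, t1 = pulse_times[0], pulse_times[-1]
    in_train = spike_times[(spike_times >= t0) & (spike_times < t1)]
    idx = np.searchsorted(pulse_times, in_train, side="right") - 1
    offsets_ms = (in_train - pulse_times[idx]) * 1000.0
    counts, _ = np.histogram(offsets_ms, bins=edges)
    n_intervals = len(pulse_times) - 1
    rate = counts / (n_intervals * bin_ms / 1000.0)
    if baseline_window is None:
        baseline_window = (0.0, t0)
    b0, b1 = baseline_window
    base_rate = 0.0
    if b1 > b0:
        base_rate = float(np.sum((spike_times >= b0) & (spike_times < b1)) / (b1 - b0))
    return PSTH(bin_edges=edges, rate=rate, baseline_rate=base_rate)


def psth_trough(psth: PSTH, window=TROUGH_WINDOW) -> float:
    """Local minimum of firing (Hz) within the window (default 5–7 ms)."""
    mask = (psth.bin_centers >= window[0]) & (psth.bin_centers <= window[1])
    return float(np.min(psth.rate[mask]))


def mean_rate_in_window(psth: PSTH, window=ERNA_WINDOW) -> float:
    mask = (psth.bin_centers >= window[0]) & (psth.bin_centers <= window[1])
    return float(np.mean(psth.rate[mask]))


# --------------------------------------------------------------------------
# cohort statistics

#: amplitudes below this fraction of the RMS are excluded from log transform
LOG_AMP_FLOOR = 1e-6


def erna_firing_table(
    cohort: list[Recording],
    blanking_ms: float = DEFAULT_BLANKING_MS,
    p1_window=DEFAULT_P1_WINDOW,
    p2_window=DEFAULT_P2_WINDOW,
) -> pd.DataFrame:
    """One row per (site, intensity): windowed ERNA and firing statistics.

    Columns: ``log_erna_amp_4_9ms`` (log of the rectified mean waveform
    amplitude in 4–9 ms), ``mean_firing_4_9ms`` (Hz),
    ``log_p2_amp`` (log of P2 from the average waveform),
    ``trough_firing_5_7ms`` (Hz, minimum in 5–7 ms), plus a ``complete``
    flag — sites missing one of the three intensities are excluded from
    within-site statistics.
    """
    rows = []
    for rec in cohort:
        norm = prestim_rms(rec)
        avg = waveform_average(rec, blanking_ms, normalization=norm)
        mask = (avg.time_grid >= ERNA_WINDOW[0]) & (avg.time_grid <= ERNA_WINDOW[1])
        amp = float(np.mean(np.abs(avg.mean_waveform[mask])))
        _, p2, _, _ = detect_p1_p2(
            avg.mean_waveform, avg.time_grid, baseline=0.0,
            p1_window=p1_window, p2_window=p2_window,
        )
        psth = build_psth(rec.spike_times, rec.pulse_times)
        rows.append({
            "site": rec.metadata.get("site"),
            "intensity_ua": rec.metadata.get("intensity_ua"),
            "log_erna_amp_4_9ms": np.log(amp) if amp > LOG_AMP_FLOOR else np.nan,
            "mean_firing_4_9ms": mean_rate_in_window(psth),
            "log_p2_amp": np.log(abs(p2)) if abs(p2) > LOG_AMP_FLOOR else np.nan,
            "trough_firing_5_7ms": psth_trough(psth),
        })
    table = pd.DataFrame(rows)
    counts = table.groupby("site")["intensity_ua"].nunique()
    complete = table["site"].map(counts) == 3
    table["complete"] = complete & table[
        ["log_erna_amp_4_9ms", "log_p2_amp"]
    ].notna().all(axis=1)
    return table


def fit_mixed_slope(
    table: pd.DataFrame,
    predictor: str,
    response: str,
    grouping: str = "site",
) -> dict:
    """Linear mixed-effects slope with a random intercept per group.

    Mirrors the across-site regression of interstimulus firing on log
    ERNA amplitude.  Returns the fixed slope, its standard error, t
    statistic, residual degrees of freedom and p-value; a singular or
    non-converged fit is reported through the ``converged`` /
    ``warnings`` entries rather than silently.
    """
    import warnings as _warnings

    import statsmodels.formula.api as smf

    data = table.dropna(subset=[predictor, response, grouping])
    if data[grouping].nunique() < 2:
        raise ConfigurationError("need >= 2 groups for a mixed model")
    caught: list[str] = []
    with _warnings.catch_warnings(record=True) as wlist:
        _warnings.simplefilter("always")
        model = smf.mixedlm(f"{response} ~ {predictor}", data, groups=data[grouping])
        fit = model.fit(reml=True)
        caught = [str(w.message) for w in wlist]
    slope = float(fit.params[predictor])
    se = float(fit.bse[predictor])
    dof = float(len(data) - 2)
    t = slope / se if se > 0 else float("inf") * np.sign(slope)
    p = float(2 * stats.t.sf(abs(t), dof)) if np.isfinite(t) else 0.0
    return {
        "slope": slope, "se": se, "t": float(t), "dof": dof, "p": p,
        "n": int(len(data)), "converged": bool(getattr(fit, "converged", True)),
        "warnings": caught,
    }


def within_site_consistency(
    table: pd.DataFrame,
    predictor: str,
    response: str,
    grouping: str = "site",
    n_hypotheses: int = N_HYPOTHESES,
) -> dict:
    """Per-site Spearman rho, tested against zero across sites.

    Each site contributes one rho between predictor and response over
    its (three) intensity-ordered observations; the rho values are
    compared to 0 with a one-sample two-tailed t test, Bonferroni-scaled
    by the module's hypothesis family (x4 by default).  Sites whose rho
    is undefined (all-tied values) are excluded and listed.
    """
    rhos, excluded = [], []
    for site, sub in table.dropna(subset=[predictor, response]).groupby(grouping):
        if len(sub) < 2:
            excluded.append(site)
            continue
        rho = spearman_rho(sub[predictor].to_numpy(), sub[response].to_numpy())
        if np.isnan(rho):
            excluded.append(site)
            continue
        rhos.append(rho)
    rhos = np.array(rhos)
    if rhos.size < 2:
        raise ConfigurationError("fewer than two sites with defined rho")
    if np.std(rhos, ddof=1) == 0:
        # all sites identical: the t statistic is degenerate
        t, p, degenerate = float("inf") * np.sign(rhos[0] or 1), 0.0, True
    else:
        t, p = stats.ttest_1samp(rhos, 0.0)
        degenerate = False
    return {
        "rho_values": rhos,
        "mean_rho": float(np.mean(rhos)),
        "t": float(t),
        "p": float(p),
        "p_bonferroni": float(min(1.0, p * n_hypotheses)),
        "degenerate": degenerate,
        "excluded_sites": excluded,
        "n": int(rhos.size),
    }


def spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation (average ranks for ties); NaN if either
    input is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)
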