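"""Synthetic microelectrode recordings with ERNA structure.

Generates extracellular-like traces carrying every statistical feature
the analysis pipeline measures, so the whole pipeline is testable
without patient data:

* a stimulus train of biphasic pulses (0.3 ms metadata; a 1 ms biphasic
  artifact transient is painted at each pulse time to exercise blanking);
* an evoked waveform template of two narrow lobes peaking at the P1 and
  P2 latencies, whose per-pulse amplitudes relax exponentially toward
  the configured pulse-40–45 dynamics targets (P1 depressing to 0.765,
  P2 growing to 1.395 of the first pulse) — at 100 Hz only: at 50 Hz and
  below both ratios are pinned at 1 (frequency specificity);
* single-unit spiking as an inhomogeneous Poisson process whose rate is
  multiplicatively suppressed by the instantaneous ERNA amplitude
  (inhibition time-locked to, and proportional to, the evoked peaks);
* band-limited (10–250 Hz) Gaussian background noise with unit RMS, so
  template amplitudes are in units of the pre-stimulation RMS.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

from .errors import ConfigurationError
from .recording import Recording

#: stimulation frequencies (Hz) at which evoked dynamics are present
DYNAMIC_FREQUENCY_MIN = 100.0


@dataclass(frozen=True)
class ERNATemplateParams:
    """Shape and per-pulse dynamics of the evoked waveform template."""

    p1_latency: float = 3.2       # ms post-pulse
    p2_latency: float = 6.3       # ms; spacing implies ~320 Hz ringing
    p1_amp0: float = 24.0         # first-pulse P1 amplitude (units of pre-stim RMS)
    p2_amp0: float = 16.0
    p1_ratio_target: float = 0.765  # mean(P1 at pulses 40–45) / P1 first
    p2_ratio_target: float = 1.395
    dynamics_tau_pulses: float = 8.0  # e-fold of the amplitude relaxation
    lobe_sigma: float = 0.55      # ms, Gaussian half-width of each lobe
    #: depth of the oscillatory trough between P1 and P2, as a fraction of
    #: the instantaneous P2 lobe amplitude (the trough and P2 belong to the
    #: same resonant cycle, so they scale together)
    trough_frac: float = 0.4

    def __post_init__(self):
        if self.p1_ratio_target <= 0 or self.p2_ratio_target <= 0:
            raise ConfigurationError("ratio targets must be > 0")
        if self.lobe_sigma <= 0 or self.dynamics_tau_pulses <= 0:
            raise ConfigurationError("lobe_sigma and dynamics_tau_pulses must be > 0")


@dataclass(frozen=True)
class SpikingParams:
    baseline_rate: float = 40.0   # Hz
    coupling_gain: float = 0.3    # rate -> rate * exp(-gain * erna amplitude)
    refractory: float = 1.0       # ms, enforced by deletion

    def __post_init__(self):
        if self.coupling_gain < 0 or self.baseline_rate < 0:
            raise ConfigurationError("baseline_rate and coupling_gain must be >= 0")


#: normalized amplitude scale per stimulation intensity (µA); monotone
INTENSITY_SCALE = {30: 0.5, 50: 0.75, 100: 1.0}


@dataclass(frozen=True)
class CohortConfig:
    n_sites: int = 20
    intensities: tuple = (30, 50, 100)       # µA
    frequencies: tuple = (100.0,)            # Hz
    duration: float = 10.0                   # s of stimulation per train
    prestim: float = 2.0                     # s of baseline before the train
    between_site_sd: float = 0.3             # lognormal sd on site amplitudes
    seed: int = 0
    template: ERNATemplateParams = field(default_factory=ERNATemplateParams)
    spiking: SpikingParams = field(default_factory=SpikingParams)
    fs: float = 10_000.0

    @classmethod
    def fig2_style(cls, seed: int = 0, **kw) -> "CohortConfig":
        """20 sites x {30, 50, 100} µA at 100 Hz."""
        return cls(n_sites=20, intensities=(30, 50, 100), frequencies=(100.0,),
                   seed=seed, **kw)

    @classmethod
    def fig3_style(cls, seed: int = 0, frequencies=(10.0, 20.0, 30.0, 50.0, 100.0),
                   **kw) -> "CohortConfig":
        """12 sites at 100 µA across stimulation frequencies."""
        return cls(n_sites=12, intensities=(100,), frequencies=frequencies,
                   seed=seed, **kw)


def pulse_amplitudes(params: ERNATemplateParams, n_pulses: int,
                     frequency: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-pulse (P1, P2) template amplitudes.

    Exponential approach from the first-pulse amplitude toward
    ``target * amp0`` with e-fold ``dynamics_tau_pulses``; at stimulation
    frequencies below 100 Hz the synaptic dynamics do not engage and the
    amplitudes are pulse-index invariant.
    """
    k = np.arange(n_pulses, dtype=float)
    if frequency < DYNAMIC_FREQUENCY_MIN:
        return (np.full(n_pulses, params.p1_amp0),
                np.full(n_pulses, params.p2_amp0))
    relax = np.exp(-k / params.dynamics_tau_pulses)

    def track(target):
        return target + (1.0 - target) * relax

    return params.p1_amp0 * track(params.p1_ratio_target), \
        params.p2_amp0 * track(params.p2_ratio_target)


def erna_waveform(t_since_pulse_ms, pulse_index: int,
                  params: ERNATemplateParams, frequency: float = 100.0):
    """Template amplitude at ``t_since_pulse_ms`` for pulse ``pulse_index``
    (1-based).  Two Gaussian lobes peaking at the P1/P2 latencies."""
    if pulse_index < 1:
        raise ConfigurationError("pulse_index is 1-based")
    a1, a2 = pulse_amplitudes(params, pulse_index, frequency)
    return _lobes(np.asarray(t_since_pulse_ms, dtype=float), a1[-1], a2[-1], params)


def _lobes(t_ms: np.ndarray, a1: float, a2: float, params: ERNATemplateParams):
    """Two positive lobes plus the intervening oscillatory trough."""
    s = params.lobe_sigma
    t_mid = 0.5 * (params.p1_latency + params.p2_latency)
    return (a1 * np.exp(-0.5 * ((t_ms - params.p1_latency) / s) ** 2)
            - params.trough_frac * a2 * np.exp(-0.5 * ((t_ms - t_mid) / s) ** 2)
            + a2 * np.exp(-0.5 * ((t_ms - params.p2_latency) / s) ** 2))


def _erna_train(times_s: np.ndarray, pulse_times: np.ndarray,
                params: ERNATemplateParams, frequency: float) -> np.ndarray:
    """Evoked-template component of the trace on the full sample grid."""
    out = np.zeros_like(times_s)
    a1, a2 = pulse_amplitudes(params, len(pulse_times), frequency)
    support_ms = max(params.p2_latency + 5 * params.lobe_sigma, 10.0)
    fs = 1.0 / (times_s[1] - times_s[0])
    n_sup = int(support_ms / 1000.0 * fs)
    for k, tp in enumerate(pulse_times):
        i0 = int(np.round(tp * fs))
        i1 = min(i0 + n_sup, len(out))
        if i0 >= len(out):
            break
        t_ms = (times_s[i0:i1] - tp) * 1000.0
        out[i0:i1] += _lobes(t_ms, a1[k], a2[k], params)
    return out


def band_limited_noise(n: int, fs: float, rng: np.random.Generator,
                       band=(10.0, 250.0), rms: float = 1.0) -> np.ndarray:
    """Gaussian noise shaped to the LFP band, scaled to a target RMS."""
    white = rng.standard_normal(n)
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    shaped = signal.sosfiltfilt(sos, white)
    return shaped * (rms / np.sqrt(np.mean(shaped**2)))


def generate_spikes(
    erna_trace: np.ndarray,
    fs: float,
    duration: float,
    params: SpikingParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Inhomogeneous Poisson spikes suppressed by the evoked waveform.

    Thinning: candidates are homogeneous Poisson at the baseline rate;
    each is accepted with probability ``exp(-gain * erna(t))`` (the
    rectified template amplitude at the candidate time), so suppression
    is time-locked to and monotone in the evoked peaks.  A refractory
    period is enforced afterwards by deletion.
    """
    if params.baseline_rate == 0:
        return np.empty(0)
    n_cand = rng.poisson(params.baseline_rate * duration)
    cand = np.sort(rng.uniform(0.0, duration, size=n_cand))
    idx = np.minimum((cand * fs).astype(int), len(erna_trace) - 1)
    amp = np.maximum(erna_trace[idx], 0.0)
    keep = rng.random(n_cand) < np.exp(-params.coupling_gain * amp)
    spikes = cand[keep]
    if params.refractory > 0 and len(spikes) > 1:
        out = [spikes[0]]
        for t in spikes[1:]:
            if t - out[-1] >= params.refractory / 1000.0:
                out.append(t)
        spikes = np.array(out)
    return spikes


def generate_recording(
    seed: int,
    intensity_ua: int = 100,
    frequency: float = 100.0,
    duration: float = 10.0,
    prestim: float = 2.0,
    fs: float = 10_000.0,
    template: ERNATemplateParams | None = None,
    spiking: SpikingParams | None = None,
    noise_rms: float = 1.0,
    artifact_amp: float = 50.0,
    site: int | str = 0,
    amp_scale: float = 1.0,
) -> Recording:
    """One synthetic microelectrode recording.

    The trace is evoked-template train + band-limited noise + brief
    biphasic artifact transients at the pulse times, preceded by
    ``prestim`` seconds of baseline.  Deterministic under ``seed``.
    """
    template = template or ERNATemplateParams()
    spiking = spiking or SpikingParams()
    scale = INTENSITY_SCALE.get(intensity_ua, intensity_ua / 100.0) * amp_scale
    template = replace(template,
                       p1_amp0=template.p1_amp0 * scale,
                       p2_amp0=template.p2_amp0 * scale)
    total = prestim + duration + 0.5
    n = int(round(total * fs))
    times = np.arange(n) / fs
    n_pulses = int(np.floor(duration * frequency))
    pulse_times = prestim + np.arange(n_pulses) / frequency

    ss = np.random.SeedSequence(seed)
    rng_noise, rng_spk = (np.random.default_rng(s) for s in ss.spawn(2))

    erna = _erna_train(times, pulse_times, template, frequency)
    voltage = erna.copy()
    if noise_rms > 0:
        voltage = voltage + band_limited_noise(n, fs, rng_noise, rms=noise_rms)
    if artifact_amp > 0:
        half = int(round(0.5e-3 * fs))  # 1 ms biphasic transient
        for tp in pulse_times:
            i0 = int(round(tp * fs))
            voltage[i0:i0 + half] += artifact_amp
            voltage[i0 + half:i0 + 2 * half] -= artifact_amp
    spikes = generate_spikes(erna, fs, total, spiking, rng_spk)
    return Recording(
        fs=fs,
        voltage=voltage,
        pulse_times=pulse_times,
        spike_times=spikes,
        metadata={
            "site": site,
            "intensity_ua": intensity_ua,
            "frequency_hz": frequency,
            "seed": seed,
        },
    )


def generate_cohort(config: CohortConfig) -> tuple[list[Recording], pd.DataFrame]:
    """Cohort of recordings with lognormal between-site amplitude variability.

    Returns the recordings and a manifest (site, intensity, frequency,
    seed, amplitude scale).  Child seeds derive from the master seed, so
    the cohort is fully reproducible.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_sites = np.random.default_rng(ss.spawn(1)[0])
    site_scales = np.exp(rng_sites.normal(0.0, config.between_site_sd, config.n_sites))
    recordings, rows = [], []
    n_combo = len(config.intensities) * len(config.frequencies)
    child = ss.spawn(config.n_sites * n_combo)
    i = 0
    for site in range(config.n_sites):
        for freq in config.frequencies:
            for inten in config.intensities:
                seed = int(child[i].generate_state(1)[0] % (2**31 - 1))
                i += 1
                rec = generate_recording(
                    seed=seed,
                    intensity_ua=inten,
                    frequency=freq,
                    duration=config.duration,
                    prestim=config.prestim,
                    fs=config.fs,
                    template=config.template,
                    spiking=config.spiking,
                    site=site,
                    amp_scale=float(site_scales[site]),
                )
                recordings.append(rec)
                rows.append({
                    "site": site, "intensity_ua": inten, "frequency_hz": freq,
                    "seed": seed, "amp_scale": float(site_scales[site]),
                })
    return recordings, pd.DataFrame(rows)
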