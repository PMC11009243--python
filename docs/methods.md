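# Methods

`ernakit` has two computational pillars: a point-neuron model of the
subthalamo-pallidal (STN–GPe) mesocircuit under deep-brain-stimulation
(DBS) pulse trains, and the measurement pipeline used to quantify evoked
resonant neural activity (ERNA) and its relationship to single-unit
spiking.  A synthetic recording generator supplies microelectrode-like
data with known ground truth so the pipeline is testable end to end.

## The mesocircuit model

**Populations.**  100 STN units and 100 GPe units.  STN units are
homogeneous Poisson sources at 39.9 Hz; they drive GPe but are not
themselves integrated (the loop is read out on the synaptic conductance
onto STN, not closed through STN spiking — a Poisson source cannot be
inhibited, so the feedback is observed on the conductance proxy).  GPe
units are conductance-based leaky integrate-and-fire neurons
(IF_cond_exp form):

    C dV/dt = -g_L (V - V_p) + g_e (E_e - V) + g_i (E_i - V) + I_e + I_noise

with C = 200 pF, τ_p = 10 ms (g_L = C/τ_p = 20 nS), V_p = −65 mV,
V_th = −50 mV, V_r = −70 mV, t_ref = 2 ms, E_e = 0 mV, E_i = −85 mV.
Voltage uses forward Euler at dt = 0.1 ms (100 samples per interstimulus
interval at 100 Hz); all conductance, utilization/resource and noise
decays use exact exponential updates, so only the voltage line carries
discretization error.  `I_noise` is an Ornstein–Uhlenbeck process with
τ = 5 ms, exact-transition sampling, stationary mean 0 and stationary
sd α = 150 pA; α√(2/τ) diffusion scaling makes α the stationary sd
exactly.

**Connectivity.**  Each GPe neuron receives 18–22 STN synapses (uniform
in-degree, sources drawn without replacement) and reciprocal GPe–GPe
inhibition with in-degree uniform in [20, 25] (high-connectivity
default; [1, 5] is the low-connectivity configuration).  No
self-connections.  One master seed fans out, via `SeedSequence`
spawning, to independent streams for connectivity, the Poisson source,
OU noise and initial states.

**Short-term plasticity.**  Every DBS-activated projection passes
through a Tsodyks–Markram synapse.  On a presynaptic event,

    u+ = u + U(1 − u),   release = A·u+·r,   r+ = r − u+·r,

and between events u relaxes to 0 (τ_facil) and r to 1 (τ_rec).
Because all synapses of a projection class receive the identical
periodic pulse train, their per-pulse releases follow an exact
recursion (`release_train`); the simulator uses it directly instead of
sub-stepping every synapse, and the continuous-time `tm_step` path is
held to the recursion at 1e-9 relative error in the test suite.

The literature constrains each projection by its steady-state release
*fidelity* under 100 Hz drive — late-train release as a fraction of the
first release — not by TM parameter values: 10% for cortico-STN
(hyperdirect), 65% for the pallidal class (GPe-STN afferents and GPe-GPe
collaterals), 80% for STN-GPe efferents.  `calibrate_synapse` makes the
fidelity the ground truth: it fixes U = 0.5, sets τ_facil = 0 (pure
depression; u is pinned at U on every spike) and bisects τ_rec in log
space, for which fidelity is strictly decreasing and spans (0, 1].  A
target of 1 returns τ_rec = 0, a static synapse.  Calibration is always
done at 100 Hz; the calibrated synapse is then driven at whatever rate
the protocol requests, which is what makes fidelity frequency
dependent (the 65% pallidal synapse recovers to ~98% at 20 Hz).

**DBS pulse application.**  A pulse at time t triggers, simultaneously:

* the 500-synapse afferent bank onto STN — 225 excitatory cortico-STN
  releases (10% fidelity) and 275 inhibitory pallido-STN releases (65%),
  arriving monosynaptically at t + 2.5 ms;
* an efferent STN-GPe conductance jump on every GPe neuron (80%
  fidelity by default; `static` and `depressing` (20%) modes exist),
  at t + 1 ms;
* GPe-GPe collateral inhibition via antidromic invasion, scaled by each
  neuron's GPe-GPe in-degree (65% fidelity), at t + 1 ms.

The 0.3 ms biphasic pulse width is protocol metadata; pulses are points
in the event model.  `release_schedule` exposes the resulting per-pulse
release amplitudes of every projection.

**ERNA proxy and peak extraction.**  The proxy is the population-summed
inhibitory synaptic conductance onto STN: the afferent-bank releases
(monosynaptic → first peak, P1) plus feedback from every GPe spike
(delay 3 ms, 2 ms synaptic rise, τ = 5 ms decay; disynaptic → second
peak, P2).  The proxy is a pure readout computed from the spike record
after integration.  Per-pulse P1/P2 are obtained with the analysis
module's peak extraction, with three adaptations required by the
proxy's physics: the known exponential tail of pre-pulse conductance is
subtracted per segment (the proxy does not return to zero in 10 ms), a
0.4 ms boxcar removes single-spike shot noise, and P1 is referenced to
the preceding within-segment trough instead of the pre-pulse baseline.
Search windows are 2–5 ms (P1) and 5–9 ms (P2) post-pulse.

**Why P2 grows only under HFS.**  At 100 Hz, efferent excitation of GPe
depresses to 80% while collateral inhibition depresses to 65%; net
evoked excitation of GPe therefore *grows* across the train, recruiting
more per-pulse GPe spikes, whose feedback deepens the disynaptic
inhibition of STN (P2).  Peak-minus-trough measurement adds a second,
faithful route: the depressing P1 tail lowers the intervening trough.
Removing collaterals saturates GPe from the first pulse (no growth);
depressing efferents (≤ 30% fidelity) collapse late-train spiking (P2
abolished).  At low frequencies the synapses recover between pulses, so
the model follows the source construction and treats LFS as the regime
in which short-term dynamics are not engaged: `lfs_*` scenarios deliver
the train at the requested frequency with releases pinned at their
first-pulse amplitude.  This is an idealization — a single-exponential
TM synapse deep enough to reach 65% at 100 Hz necessarily retains ~15%
depression at 50 Hz, and natural recovery at 10–30 Hz differs from the
idealization by < 7%.

**Rate calibration.**  GPe membrane parameters are conventional; the
bias current and synaptic weights were calibrated once against the
population rates the model is required to reproduce (~40.5 Hz with
stimulation OFF, ~100 Hz during a sustained 100 Hz train) and frozen as
defaults: I_e = 196.875 pA (from `tune_bias`, a bisection on the OFF
rate), w_stn = 1.2 nS per baseline STN spike, w_gg = 0.1 nS per
baseline GPe spike ("scaled down in weight"), w_eff = 72 nS per
efferent pulse, w_coll = 2.8 nS per collateral synapse per pulse.  The
large DBS conductances put the evoked response in a shunting regime in
which the spike/no-spike decision depends on the excitation/inhibition
balance rather than the pre-pulse membrane state; that balance is what
the differential depression shifts across the train.  `tune_bias` is
exposed for re-tuning modified circuits.

## The analysis pipeline

All amplitudes are normalized by the pre-stimulation RMS of the
10–250 Hz band-passed LFP (zero-phase 4th-order Butterworth; ≥ 1 s of
baseline required — ten cycles of the low edge).  The trace is folded
into per-pulse segments from `blanking_ms` (default 1.5 ms, excluding
the stimulus artifact) to the next pulse.  P1 is the dominant local
maximum in 2–5 ms minus the immediate pre-stimulus baseline (mean of
the 0.5 ms before the pulse); P2 is the dominant local maximum in
5–9 ms minus the intervening trough.  A window without a local maximum
yields NaN — missing, never zero.  Temporal dynamics are summarized as
mean amplitude over pulses 40–45 divided by the first-pulse amplitude;
an optional 3-pulse running average exists but per-pulse measurement is
the default.  Peristimulus time histograms fold spikes over all
interstimulus intervals (0.5 ms bins, rates in Hz, baseline from the
pre-stimulation window).

Site-level statistics constrain the ERNA/firing relationship to the
windows that capture it: log rectified mean waveform amplitude and mean
PSTH rate in 4–9 ms; log P2 amplitude and the PSTH minimum in 5–7 ms.
Amplitudes below 1e-6 of the RMS are excluded from the log rather than
producing log(~0).  Across sites, a linear mixed-effects model
(statsmodels `MixedLM`, random intercept per site — the random-effects
structure is not uniquely determined by the source description, and
intercept-only is the documented default) estimates the fixed slope of
firing on log amplitude; degrees of freedom are reported as n − 2
rather than forcing any particular small-sample convention.  Within
sites, Spearman's rho across the three intensities (exact rank
correlation, average ranks for ties; undefined-rho sites are excluded
and listed) is tested against zero with a one-sample two-tailed t test;
p-values carry a Bonferroni factor of 4, the module's hypothesis
family.  A zero-variance rho vector is reported as degenerate with
p → 0 rather than failing.

## The synthetic generator

Each recording is: evoked template train + band-limited noise + artifact
transients, preceded by 2 s of clean baseline, at 10 kHz.

* **Template** — two Gaussian lobes (σ = 0.55 ms) peaking at 3.2 ms
  (P1) and 6.3 ms (P2), plus a negative trough lobe midway whose depth
  is 0.4 of the instantaneous P2 amplitude (the trough and P2 belong to
  the same resonant cycle, so peak-minus-trough scales exactly with the
  P2 amplitude).  Latencies place both peaks inside the 4–9 ms analysis
  window and the trough inside 5–7 ms.  Per-pulse amplitudes relax
  exponentially (e-fold 8 pulses) from the first-pulse value toward the
  dynamics targets — P1 to 0.765, P2 to 1.395 of the first pulse — at
  100 Hz only; at ≤ 50 Hz both amplitudes are pulse-index invariant.
  First-pulse amplitudes default to 24 (P1) and 16 (P2) RMS units,
  a strong-ERNA signal-to-noise regime in which single-sweep peak
  measurements are reliable.
* **Spiking** — inhomogeneous Poisson by thinning: candidates at the
  baseline rate (40 Hz), each accepted with probability
  exp(−gain · max(template, 0)); refractory (1 ms) enforced by
  deletion.  The default gain 0.3 suppresses interstimulus firing by
  roughly half at 100 µA.  Suppression is therefore time-locked to and
  monotone in the evoked peaks by construction.
* **Noise and artifact** — white Gaussian noise shaped by the same
  10–250 Hz filter, scaled to unit RMS (so template amplitudes are in
  normalized units up front); a 1 ms biphasic transient at each pulse
  exercises the blanking logic without modeling electrode physics.
* **Cohorts** — 20 sites × {30, 50, 100} µA at 100 Hz, or 12 sites
  across {10, 20, 30, 50, 100} Hz.  Intensity scales amplitudes
  monotonically (0.5 / 0.75 / 1.0); between-site variability is
  lognormal (sd 0.3 on amplitude) — a free parameter, not a claim about
  real inter-site distributions.  All child seeds derive from the
  master seed.

What the generator does **not** emulate: biophysical extracellular
waveforms, spike shapes (spikes are timestamps), electrode impedance,
nonstationary baselines, or any spatial structure.  Passing tests
demonstrate that the pipeline measures what it claims to measure on
data with this statistical structure, not that it is robust to every
pathology of intraoperative recordings.

## Problem sizes and numerical checks

Rate measurements use 10 seeded 5 s simulations (OFF and ON); scenario
dynamics average 10 model iterations of 50-pulse trains; cohort
recovery uses the default 12-site, 10 s, 100 Hz cohort.  The TM
recursion/stepping agreement is held to 1e-9; OU moments to Monte-Carlo
error; the mixed-model routine to ≥ 85% CI coverage over simulated
random-intercept datasets; Spearman to a brute-force rank oracle over
all permutations of n ≤ 5.  Degenerate inputs (zero-release synapses,
DC-only baselines, tied ranks, missing peaks, divergent membranes) are
reported through typed exceptions or NaN flags rather than silently.

## Known limitations

* The STN population is a rate-fixed Poisson source; feedback
  inhibition is read out on conductance, not on STN spiking.
* No long-term plasticity, chronic adaptation, multi-compartment
  morphology or extracellular forward model; GPi/SNr are absent.
* The LFS condition idealizes synapses as fully recovered (see above).
* Synaptic weights are abstract population-level conductances tuned to
  population rates, not measurements of unitary synapses.
* The generator's site variability and SNR are plausible defaults, not
  fitted distributions.
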