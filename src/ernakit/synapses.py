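"""Tsodyks–Markram short-term synaptic plasticity.

Every projection activated by a DBS pulse in the mesocircuit passes through
this model.  Two state variables evolve per synapse: the utilization ``u``
(release probability, facilitates on spikes, decays with ``tau_facil``) and
the resource fraction ``r`` (depletes on release, recovers with ``tau_rec``).
On a presynaptic spike at time ``t_sp``::

    u+       = u + U * (1 - u)          (facilitation jump, applied first)
    release  = A * u+ * r               (synaptic drive delivered)
    r+       = r - u+ * r               (resource depletion)

and between spikes ``u`` relaxes to 0 and ``r`` to 1 exponentially.  The
postsynaptic drive ``i_syn`` decays with ``tau_s`` (3 ms excitatory, 5 ms
inhibitory) and jumps by the release amount.

The limit ``tau_facil -> 0`` pins ``u`` at ``U`` on every spike (a pure
depression synapse); ``tau_rec -> 0`` recovers resources instantaneously
(a static synapse).  Both limits are handled exactly.

Because DBS delivers an identical periodic spike train to every synapse of a
projection class, per-pulse release amplitudes admit an exact recursion
(:func:`release_train`); the simulator uses it instead of sub-stepping each
synapse, and :func:`tm_step` provides the continuous-time path for arbitrary
spike trains.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

from .errors import CalibrationError, ConfigurationError, DegenerateSynapseError, StateError

Polarity = Literal["excitatory", "inhibitory"]

#: Postsynaptic decay constants by polarity (ms).
TAU_S_BY_POLARITY = {"excitatory": 3.0, "inhibitory": 5.0}


@dataclass(frozen=True)
class TMSynapseParams:
    """Parameters of one Tsodyks–Markram synapse.

    Parameters
    ----------
    U : float
        Utilization increment per spike, in (0, 1].
    tau_facil : float
        Facilitation time constant (ms); 0 disables facilitation
        (``u`` is pinned at ``U`` on every spike).
    tau_rec : float
        Resource recovery time constant (ms); 0 means instantaneous
        recovery (a static synapse).
    A : float
        Synaptic efficacy — the conductance delivered by a spike at full
        utilization and full resources (arbitrary nS-equivalent units).
    polarity : {"excitatory", "inhibitory"}
    tau_s : float, optional
        Postsynaptic conductance decay (ms).  Defaults to 3 ms for
        excitatory and 5 ms for inhibitory synapses.
    """

    U: float
    tau_facil: float
    tau_rec: float
    A: float = 1.0
    polarity: Polarity = "excitatory"
    tau_s: float | None = None

    def __post_init__(self):
        if not 0.0 < self.U <= 1.0:
            raise ConfigurationError(f"U must be in (0, 1], got {self.U}")
        if self.tau_rec < 0 or self.tau_facil < 0:
            raise ConfigurationError("time constants must be >= 0")
        if self.A <= 0:
            raise ConfigurationError(f"A must be > 0, got {self.A}")
        if self.polarity not in TAU_S_BY_POLARITY:
            raise ConfigurationError(f"unknown polarity {self.polarity!r}")
        if self.tau_s is None:
            object.__setattr__(self, "tau_s", TAU_S_BY_POLARITY[self.polarity])
        elif self.tau_s <= 0:
            raise ConfigurationError("tau_s must be > 0")


@dataclass(frozen=True)
class TMSynapseState:
    """Instantaneous synapse state: utilization, resources, drive."""

    u: float = 0.0
    r: float = 1.0
    i_syn: float = 0.0

    def __post_init__(self):
        if not (0.0 <= self.u <= 1.0) or not (0.0 <= self.r <= 1.0):
            raise StateError(f"u={self.u}, r={self.r} outside [0, 1]")
        if not math.isfinite(self.i_syn):
            raise StateError("i_syn is not finite")


def _decay(value: float, target: float, tau: float, dt: float) -> float:
    """Exact exponential relaxation of ``value`` toward ``target``."""
    if tau == 0.0:
        return target
    return target + (value - target) * math.exp(-dt / tau)


def tm_step(
    state: TMSynapseState,
    params: TMSynapseParams,
    dt: float,
    spike_arrived: bool = False,
) -> TMSynapseState:
    """Advance one synapse by ``dt`` ms, optionally processing a spike.

    The spike (if any) is applied at the start of the step: the
    facilitation jump precedes release, release magnitude is
    ``A * u+ * r``, and depletion follows.  Decays use exact exponential
    updates, so the step is accurate for any ``dt``.

    Returns the new state; ``state.i_syn`` carries the synaptic drive.
    """
    if dt <= 0:
        raise ConfigurationError(f"dt must be > 0, got {dt}")
    u, r, i = state.u, state.r, state.i_syn
    if not (math.isfinite(u) and math.isfinite(r) and math.isfinite(i)):
        raise StateError("non-finite synapse state")

    release = 0.0
    if spike_arrived:
        u = u + params.U * (1.0 - u)
        release = params.A * u * r
        r = r - u * r

    u = _decay(u, 0.0, params.tau_facil, dt)
    r = _decay(r, 1.0, params.tau_rec, dt)
    i = i * math.exp(-dt / params.tau_s) + release
    return TMSynapseState(u=u, r=r, i_syn=i)


def release_train(params: TMSynapseParams, n_pulses: int, period_ms: float) -> np.ndarray:
    """Exact per-pulse release amplitudes under a periodic spike train.

    Iterates the discrete per-spike map with exact inter-spike relaxation
    over ``period_ms``; no time discretization error.  The first spike
    arrives with the resting state (u=0, r=1).
    """
    if n_pulses < 1:
        raise ConfigurationError("n_pulses must be >= 1")
    if period_ms <= 0:
        raise ConfigurationError("period_ms must be > 0")
    fu = 0.0 if params.tau_facil == 0 else math.exp(-period_ms / params.tau_facil)
    fr = 0.0 if params.tau_rec == 0 else math.exp(-period_ms / params.tau_rec)
    u, r = 0.0, 1.0
    out = np.empty(n_pulses)
    for k in range(n_pulses):
        u = u + params.U * (1.0 - u)
        out[k] = params.A * u * r
        r = r - u * r
        # relax to the next pulse
        u = u * fu
        r = 1.0 - (1.0 - r) * fr
    return out


def depression_fixed_point(U: float, period_ms: float, tau_rec: float) -> float:
    """Steady-state resource fraction of a depression-only synapse.

    For ``u`` pinned at ``U`` and periodic spiking with period ``T``, the
    per-pulse resource map ``r -> 1 - (1 - (1-U) r) e^{-T/tau_rec}``
    has the fixed point returned here; the steady-state release ratio
    relative to the first pulse equals this value.
    """
    if tau_rec == 0:
        return 1.0
    e = math.exp(-period_ms / tau_rec)
    return (1.0 - e) / (1.0 - (1.0 - U) * e)


def steady_state_fidelity(
    params: TMSynapseParams, frequency: float, n_pulses: int = 100
) -> float:
    """Late-train release amplitude as a fraction of the first release.

    Drives the synapse with ``n_pulses`` at ``frequency`` Hz and returns
    mean release over the final 10% of pulses divided by the first-pulse
    release — the "fidelity" of the projection under repetitive DBS.
    """
    if frequency <= 0:
        raise ConfigurationError("frequency must be > 0")
    if n_pulses < 30:
        raise ConfigurationError("n_pulses must be >= 30 for a steady-state estimate")
    rel = release_train(params, n_pulses, 1000.0 / frequency)
    if rel[0] <= 0:
        raise DegenerateSynapseError("first-pulse release is zero")
    tail = max(1, n_pulses // 10)
    return float(np.mean(rel[-tail:]) / rel[0])


# Calibration search bounds for tau_rec (ms).
_TAU_REC_LO = 1e-3
_TAU_REC_HI = 1e6


def calibrate_synapse(
    target_fidelity: float,
    frequency: float,
    polarity: Polarity = "excitatory",
    U: float = 0.5,
    A: float = 1.0,
    n_pulses: int = 100,
    tol: float = 1e-4,
) -> TMSynapseParams:
    """Find depression parameters realizing a steady-state fidelity.

    The paper-facing constraint on each projection is its fidelity under
    100 Hz drive (e.g. 10% cortico-STN, 65% pallidal, 80% STN efferent),
    not its TM parameters.  This routine makes that constraint the ground
    truth: it fixes ``U`` and bisects deterministically over ``tau_rec``
    of a pure-depression synapse (``tau_facil = 0``), for which fidelity
    is strictly decreasing in ``tau_rec`` and spans (0, 1].

    Raises :class:`CalibrationError` with the bracket if the target is
    unreachable within the search bounds.
    """
    if not 0.0 < target_fidelity <= 1.0:
        raise ConfigurationError("target_fidelity must be in (0, 1]")

    def make(tau_rec: float) -> TMSynapseParams:
        return TMSynapseParams(U=U, tau_facil=0.0, tau_rec=tau_rec, A=A, polarity=polarity)

    def fid(tau_rec: float) -> float:
        return steady_state_fidelity(make(tau_rec), frequency, n_pulses)

    if target_fidelity >= 1.0 - tol:
        return make(0.0)  # static synapse: instantaneous recovery

    lo, hi = _TAU_REC_LO, _TAU_REC_HI
    f_lo, f_hi = fid(lo), fid(hi)
    if not (f_hi <= target_fidelity <= f_lo):
        raise CalibrationError(
            f"target {target_fidelity} outside reachable fidelities "
            f"[{f_hi:.4g}, {f_lo:.4g}] for U={U} at {frequency} Hz",
            bracket=(lo, hi),
        )
    for _ in range(200):
        mid = math.sqrt(lo * hi)  # bisect in log space: tau_rec spans decades
        f_mid = fid(mid)
        if abs(f_mid - target_fidelity) <= tol:
            return make(mid)
        if f_mid > target_fidelity:
            lo = mid
        else:
            hi = mid
    return make(math.sqrt(lo * hi))


def scaled(params: TMSynapseParams, A: float) -> TMSynapseParams:
    """Copy of ``params`` with efficacy ``A`` (plasticity unchanged)."""
    return replace(params, A=A)
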