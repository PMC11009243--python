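"""Conductance-based leaky integrate-and-fire GPe neurons.

Each GPe unit follows the IF_cond_exp form: a passive leak with time
constant ``tau_p`` toward the resting potential ``V_p``, exponential
conductance-based excitatory/inhibitory synapses, a constant bias current
and additive noise current::

    C dV/dt = -g_L (V - V_p) + g_exc (E_exc - V) + g_inh (E_inh - V) + I_e + I_noise

with ``g_L = C / tau_p``.  Crossing ``V_th`` emits a spike, resets V to
``V_r`` and clamps it there for the refractory period.

Units: C in pF, conductances in nS, voltages in mV, currents in pA,
time in ms (so pF*mV/ms = nS*mV = pA and the equation is homogeneous).

The GPe membrane parameters are not uniquely constrained by population
firing rates, so conventional LIF values are used; the bias current and
synaptic weights are set by the simulator's calibration to the target
OFF/ON rates (see :mod:`ernakit.simulate`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, NumericalInstabilityError


@dataclass(frozen=True)
class GPeNeuronParams:
    C: float = 200.0        # membrane capacitance (pF)
    tau_p: float = 10.0     # passive membrane time constant (ms)
    V_p: float = -65.0      # resting potential (mV)
    V_th: float = -50.0     # spike threshold (mV)
    V_r: float = -70.0      # reset potential (mV)
    t_ref: float = 2.0      # absolute refractory period (ms)
    E_exc: float = 0.0      # excitatory reversal (mV)
    E_inh: float = -85.0    # inhibitory reversal (mV)
    I_e: float = 0.0        # constant bias current (pA)

    def __post_init__(self):
        if self.tau_p <= 0 or self.C <= 0:
            raise ConfigurationError("C and tau_p must be > 0")
        if not self.V_r < self.V_th:
            raise ConfigurationError("require V_r < V_th")
        if not self.E_inh < self.V_th < self.E_exc:
            raise ConfigurationError("require E_inh < V_th < E_exc")
        if self.t_ref < 0:
            raise ConfigurationError("t_ref must be >= 0")

    @property
    def g_L(self) -> float:
        """Leak conductance (nS)."""
        return self.C / self.tau_p


@dataclass
class LIFState:
    """Vector state of a LIF population: voltages and refractory clocks."""

    v: np.ndarray            # membrane potential (mV)
    refrac_left: np.ndarray  # remaining refractory time (ms)

    @classmethod
    def resting(cls, n: int, params: GPeNeuronParams) -> "LIFState":
        return cls(v=np.full(n, params.V_p), refrac_left=np.zeros(n))


def lif_step(
    state: LIFState,
    params: GPeNeuronParams,
    dt: float,
    g_exc: np.ndarray | float = 0.0,
    g_inh: np.ndarray | float = 0.0,
    i_noise: np.ndarray | float = 0.0,
) -> tuple[LIFState, np.ndarray]:
    """Advance the population one forward-Euler step of ``dt`` ms.

    Returns ``(state, spiked)`` where ``spiked`` is a boolean array.
    Modifies ``state`` in place (and returns it) for speed; conductances
    are instantaneous values supplied by the caller, which owns their
    exponential decay.
    """
    if dt <= 0:
        raise ConfigurationError(f"dt must be > 0, got {dt}")
    v = state.v
    active = state.refrac_left <= 0.0
    i_total = (
        -params.g_L * (v - params.V_p)
        + g_exc * (params.E_exc - v)
        + g_inh * (params.E_inh - v)
        + params.I_e
        + i_noise
    )
    v += np.where(active, dt * i_total / params.C, 0.0)
    if not np.all(np.isfinite(v)):
        raise NumericalInstabilityError(
            f"membrane potential diverged (dt={dt} ms too coarse?)"
        )
    spiked = active & (v >= params.V_th)
    v[spiked] = params.V_r
    state.refrac_left[spiked] = params.t_ref
    state.refrac_left[~spiked] = np.maximum(state.refrac_left[~spiked] - dt, 0.0)
    state.v[~active] = params.V_r  # hold at reset during refractory
    return state, spiked


def constant_current_isi(params: GPeNeuronParams, i_const: float) -> float:
    """Closed-form interspike interval under constant suprathreshold current.

    ``inf`` if the current cannot reach threshold.  Used as an analytic
    oracle for the integrator.
    """
    v_inf = params.V_p + i_const / params.g_L
    if v_inf <= params.V_th:
        return float("inf")
    return params.t_ref + params.tau_p * np.log(
        (v_inf - params.V_r) / (v_inf - params.V_th)
    )
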