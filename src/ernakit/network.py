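"""Mesocircuit architecture: populations, connectivity, DBS protocol.

The model abstracts the subthalamic nucleus (STN) and external globus
pallidus (GPe) as two populations of 100 units.  STN units are Poisson
sources at 39.9 Hz; GPe units are conductance-based LIF neurons.  Each GPe
neuron receives 18–22 synapses from the STN population (uniform) and
reciprocal GPe–GPe inhibition with in-degree drawn from a configurable
range ([1–5] low to [20–25] high connectivity).

A DBS pulse train activates, on every pulse:

* a bank of 500 afferent synapses onto STN — 45% excitatory cortico-STN
  (rapidly depressing, 10% fidelity) and 55% inhibitory pallido-STN
  (resilient, 65% fidelity);
* STN-GPe efferents onto every GPe neuron connected to STN (resilient,
  80% fidelity by default, with static and depressing alternatives);
* GPe-GPe axon collaterals via antidromic invasion of pallido-STN
  projections (65% fidelity), scaled by each neuron's GPe-GPe in-degree.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError

#: Steady-state release fidelities at 100 Hz, per projection class.
DEFAULT_FIDELITY_TARGETS = {
    "cortico_stn": 0.10,
    "gpe_stn": 0.65,
    "gpe_gpe": 0.65,
    "stn_efferent": 0.80,
}


@dataclass(frozen=True)
class NetworkConfig:
    n_stn: int = 100
    n_gpe: int = 100
    stn_rate: float = 39.9                       # Hz, Poisson source rate
    stn_to_gpe_indegree: tuple[int, int] = (18, 22)
    gpe_to_gpe_indegree: tuple[int, int] = (20, 25)  # high-connectivity default
    seed: int = 0

    def __post_init__(self):
        for name, (lo, hi), pop in (
            ("stn_to_gpe_indegree", self.stn_to_gpe_indegree, self.n_stn),
            ("gpe_to_gpe_indegree", self.gpe_to_gpe_indegree, self.n_gpe - 1),
        ):
            if lo < 0 or hi < lo:
                raise ConfigurationError(f"{name} range must be 0 <= lo <= hi")
            if hi > pop:
                raise ConfigurationError(
                    f"{name} upper bound {hi} exceeds available sources ({pop})"
                )
        if self.stn_rate < 0:
            raise ConfigurationError("stn_rate must be >= 0")


@dataclass(frozen=True)
class DBSProtocol:
    """Stimulation pulse train and which projections it activates."""

    frequency: float = 100.0          # Hz
    duration: float = 5.0             # s of stimulation
    train_start: float = 0.0          # s, onset of first pulse
    pulse_width_ms: float = 0.3       # biphasic width; metadata for the point-process model
    n_afferent: int = 500
    frac_excitatory: float = 0.45
    fidelity_targets: dict = field(default_factory=lambda: dict(DEFAULT_FIDELITY_TARGETS))
    efferent_mode: str = "resilient"  # resilient (80%) | static | depressing
    depressing_efferent_fidelity: float = 0.2
    gpe_gpe_collaterals_enabled: bool = True
    hyperdirect_enabled: bool = True
    #: False = release amplitudes pinned at their first-pulse values.  The
    #: low-frequency regime is idealized this way: at long inter-pulse
    #: intervals synaptic resources recover (nearly) fully, so short-term
    #: dynamics are not engaged.
    plasticity_enabled: bool = True

    def __post_init__(self):
        if self.frequency < 0:
            raise ConfigurationError("frequency must be >= 0")
        if not 0.0 <= self.frac_excitatory <= 1.0:
            raise ConfigurationError("frac_excitatory must be in [0, 1]")
        if self.efferent_mode not in ("resilient", "static", "depressing"):
            raise ConfigurationError(
                f"efferent_mode must be resilient|static|depressing, got {self.efferent_mode!r}"
            )

    @property
    def n_excitatory_afferent(self) -> int:
        return round(self.n_afferent * self.frac_excitatory)

    @property
    def n_inhibitory_afferent(self) -> int:
        return self.n_afferent - self.n_excitatory_afferent

    def pulse_times(self) -> np.ndarray:
        """Pulse onset times in seconds, strictly increasing at 1/frequency."""
        if self.frequency == 0 or self.duration <= 0:
            return np.empty(0)
        n = int(np.floor(self.duration * self.frequency))
        return self.train_start + np.arange(n) / self.frequency

    def with_(self, **kwargs) -> "DBSProtocol":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class Network:
    """Realized connectivity: boolean adjacency, row = target GPe neuron."""

    config: NetworkConfig
    stn_to_gpe: np.ndarray   # (n_gpe, n_stn) bool
    gpe_to_gpe: np.ndarray   # (n_gpe, n_gpe) bool, no self-connections

    @property
    def gpe_gpe_indegree(self) -> np.ndarray:
        return self.gpe_to_gpe.sum(axis=1)


def build_network(config: NetworkConfig) -> Network:
    """Sample the adjacency. Deterministic for a given config seed."""
    rng = np.random.default_rng(config.seed)
    stn_to_gpe = _sample_indegree(
        rng, config.n_gpe, config.n_stn, config.stn_to_gpe_indegree, exclude_self=False
    )
    gpe_to_gpe = _sample_indegree(
        rng, config.n_gpe, config.n_gpe, config.gpe_to_gpe_indegree, exclude_self=True
    )
    return Network(config=config, stn_to_gpe=stn_to_gpe, gpe_to_gpe=gpe_to_gpe)


def _sample_indegree(rng, n_targets, n_sources, indegree, exclude_self) -> np.ndarray:
    lo, hi = indegree
    adj = np.zeros((n_targets, n_sources), dtype=bool)
    for i in range(n_targets):
        k = int(rng.integers(lo, hi + 1))
        pool = np.delete(np.arange(n_sources), i) if exclude_self else np.arange(n_sources)
        if k > 0:
            src = rng.choice(pool, size=k, replace=False)
            adj[i, src] = True
    return adj
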