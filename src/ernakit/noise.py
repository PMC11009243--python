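"""Ornstein–Uhlenbeck synaptic background noise.

The GPe population receives mean-reverting Gaussian noise

    dx = -(x - mu)/tau dt + alpha * sqrt(2/tau) * xi(t) dt^(1/2)

with stationary mean ``mu`` and stationary standard deviation ``alpha``
(the sqrt(2/tau) diffusion scaling makes alpha the stationary sd exactly).
Updates use the exact discretization of the OU transition density rather
than Euler–Maruyama, so they are unbiased for any step size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError


@dataclass(frozen=True)
class OUProcessParams:
    """Stationary mean, stationary sd, and time constant (ms) of the process."""

    mu: float = 0.0
    alpha: float = 1.0
    tau: float = 5.0

    def __post_init__(self):
        if self.tau <= 0:
            raise ConfigurationError("tau must be > 0")
        if self.alpha < 0:
            raise ConfigurationError("alpha must be >= 0")


def ou_step(x, params: OUProcessParams, dt: float, rng: np.random.Generator):
    """Advance the process by ``dt`` ms (exact transition sampling).

    ``x`` may be a scalar or an array (one independent process per element).
    """
    if dt <= 0:
        raise ConfigurationError(f"dt must be > 0, got {dt}")
    decay = np.exp(-dt / params.tau)
    sd = params.alpha * np.sqrt(1.0 - decay * decay)
    mean = params.mu + (np.asarray(x) - params.mu) * decay
    if params.alpha == 0:
        return mean
    return mean + sd * rng.standard_normal(np.shape(x))


def ou_path(
    params: OUProcessParams,
    n_steps: int,
    dt: float,
    rng: np.random.Generator,
    x0: float | None = None,
) -> np.ndarray:
    """Sample a full trajectory; starts at ``x0`` (default: the mean)."""
    x = params.mu if x0 is None else x0
    out = np.empty(n_steps)
    for i in range(n_steps):
        x = ou_step(x, params, dt, rng)
        out[i] = x
    return out
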