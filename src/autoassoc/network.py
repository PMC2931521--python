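"""Network architecture: 100 excitatory neurons + one feedback interneuron.

Recurrent excitatory connectivity is a random digraph with a fixed
out-degree per presynaptic neuron.  Every excitatory neuron drives the
single interneuron (at 90% of the maximal AMPA conductance) and the
interneuron inhibits every excitatory neuron plus itself via an autapse.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["NetworkConfig", "build_connectivity", "feedback_inhibition_strength"]


@dataclass(frozen=True)
class NetworkConfig:
    """Parameters of one network realization.

    ``relative_inhibition`` scales feedback GABA conductance relative to the
    maximal excitation a neuron can receive from one stimulus pattern:
    gGABA = g_max_ampa * pattern_size * connectivity_level * relative_inhibition.
    """

    connectivity_level: float
    g_max_ampa: float          # nS, fully potentiated synapse
    gamma_ltd: float           # dimensionless LTD strength
    relative_inhibition: float
    n_exc: int = 100
    pattern_size: int = 10
    e_to_i_scale: float = 0.9
    connectivity_seed: int = 0
    pattern_seed: int = 0
    fixed_outdegree: bool = True

    def __post_init__(self):
        if not (0 < self.connectivity_level <= 1):
            raise ValueError("connectivity_level must be in (0, 1]")
        if self.pattern_size > self.n_exc:
            raise ValueError("pattern_size cannot exceed n_exc")
        if self.gamma_ltd <= 0:
            raise ValueError("gamma_ltd must be positive")
        if self.g_max_ampa < 0 or self.relative_inhibition < 0:
            raise ValueError("conductance parameters must be non-negative")

    @property
    def out_degree(self) -> int:
        # round-half-up so 50% of 99 -> 50
        return int(math.floor(self.connectivity_level * (self.n_exc - 1) + 0.5))

    def with_(self, **kwargs) -> "NetworkConfig":
        return replace(self, **kwargs)


def build_connectivity(config: NetworkConfig, seed: int | None = None) -> np.ndarray:
    """Random boolean adjacency (presynaptic row -> postsynaptic column).

    Each presynaptic neuron projects to exactly ``out_degree`` distinct
    postsynaptic targets chosen uniformly among the other excitatory
    neurons (no autapses).  With ``fixed_outdegree=False`` each ordered
    pair is an independent Bernoulli draw at the connectivity level.
    """
    if seed is None:
        seed = config.connectivity_seed
    n = config.n_exc
    rng = np.random.default_rng(seed)
    adj = np.zeros((n, n), dtype=bool)
    if config.fixed_outdegree:
        k = config.out_degree
        if k == 0:
            raise ValueError("connectivity level too low: out-degree rounds to 0")
        for i in range(n):
            others = np.concatenate([np.arange(i), np.arange(i + 1, n)])
            targets = rng.choice(others, size=k, replace=False)
            adj[i, targets] = True
    else:
        adj = rng.random((n, n)) < config.connectivity_level
        np.fill_diagonal(adj, False)
    return adj


def feedback_inhibition_strength(config: NetworkConfig) -> float:
    """Peak GABA conductance (nS) the interneuron delivers to each neuron."""
    return (
        config.g_max_ampa
        * config.pattern_size
        * config.connectivity_level
        * config.relative_inhibition
    )
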