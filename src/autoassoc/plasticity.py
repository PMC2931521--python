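"""Hebbian LTP/LTD rule converting coactivation counts into synaptic weights.

A synapse is potentiated toward g_max_ampa by joint activations (n11) and
dragged down by independent activations (n10 + n01) scaled by gamma_ltd:

    W = g_max_ampa * n11 / (n11 + (n10 + n01) * gamma_ltd)

Synapses never co-activated (n11 = 0) stay silent with zero conductance.
"""

from __future__ import annotations

import numpy as np

from .network import NetworkConfig
from .patterns import PairCounts

__all__ = ["compute_weight", "build_weight_matrix"]


def compute_weight(n11, n10, n01, g_max_ampa: float, gamma_ltd: float):
    """Synaptic weight (nS) for coactivation counts; vectorized over arrays."""
    if gamma_ltd <= 0:
        raise ValueError("gamma_ltd must be positive")
    n11 = np.asarray(n11, dtype=float)
    n10 = np.asarray(n10, dtype=float)
    n01 = np.asarray(n01, dtype=float)
    if np.any(n11 < 0) or np.any(n10 < 0) or np.any(n01 < 0):
        raise ValueError("counts must be non-negative")
    denom = n11 + (n10 + n01) * gamma_ltd
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(n11 > 0, g_max_ampa * n11 / np.where(denom > 0, denom, 1.0), 0.0)
    if np.ndim(w) == 0:
        return float(w)
    return w


def build_weight_matrix(counts: PairCounts, config: NetworkConfig) -> np.ndarray:
    """Dense (n_exc, n_exc) weight matrix over the anatomical synapses.

    ``counts`` must have been computed on the same adjacency; entries
    without a synapse carry n11 = 0 and therefore weight 0.
    """
    return compute_weight(
        counts.n11, counts.n10, counts.n01, config.g_max_ampa, config.gamma_ltd
    )
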