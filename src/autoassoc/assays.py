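"""Pattern-separation and pattern-completion assays.

Two evaluation routes are provided:

* explicit conductance-based simulation of the full network over one gamma
  cycle (:func:`assay_separation`, :func:`assay_completion`);
* the fast path (:func:`fast_assay`), which decides each neuron's firing by
  comparing its summed excitatory/inhibitory conductances against a
  precomputed spike-threshold table, with a single synchronous recruitment
  round per cycle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .biophysics import (
    AMPA,
    DEFAULT_DT,
    GABA,
    NeuronParams,
    TableCoverageError,
    ThresholdTable,
    _resting_cache,
)
from .network import NetworkConfig, build_connectivity, feedback_inhibition_strength
from .patterns import PatternSet, count_pair_activity, generate_pattern_set
from .plasticity import build_weight_matrix

__all__ = [
    "NetworkRealization",
    "AssayResult",
    "simulate_cycle",
    "assay_separation",
    "assay_completion",
    "explicit_assay",
    "fast_assay",
    "aggregate_errors",
]

GAMMA_WINDOW = 25.0  # ms, default single-gamma-cycle evaluation window
STIM_CURRENT = 200.0  # pA suprathreshold pulse forcing stimulated neurons to spike
STIM_DURATION = 1.0  # ms


@dataclass(frozen=True)
class NetworkRealization:
    """One concrete network: adjacency + plastic weights + inhibition level."""

    config: NetworkConfig
    adjacency: np.ndarray
    weights: np.ndarray  # nS; zero off-adjacency and at silent synapses
    g_gaba: float        # nS, I->E (and autaptic) peak conductance
    neuron_params: NeuronParams = field(default_factory=NeuronParams)

    @property
    def g_e_to_i(self) -> float:
        """Peak conductance of each excitatory synapse onto the interneuron."""
        return self.config.e_to_i_scale * self.config.g_max_ampa

    @classmethod
    def build(
        cls,
        config: NetworkConfig,
        patterns: PatternSet,
        adjacency: np.ndarray | None = None,
        neuron_params: NeuronParams | None = None,
    ) -> "NetworkRealization":
        """Realize connectivity (from the config seed) and store the patterns."""
        if adjacency is None:
            adjacency = build_connectivity(config)
        counts = count_pair_activity(patterns, adjacency)
        weights = build_weight_matrix(counts, config)
        return cls(
            config,
            adjacency,
            weights,
            feedback_inhibition_strength(config),
            neuron_params or NeuronParams(),
        )


# ---------------------------------------------------------------------------
# Explicit network simulation
# ---------------------------------------------------------------------------

def simulate_cycle(
    network: NetworkRealization,
    stimulated,
    window: float = GAMMA_WINDOW,
    dt: float = DEFAULT_DT,
    stim_current: float = STIM_CURRENT,
    stim_duration: float = STIM_DURATION,
):
    """Simulate one gamma cycle; return (exc_spiked, inh_spiked, first_spike_times).

    ``stimulated`` neurons receive a suprathreshold current pulse at cycle
    onset.  Spikes propagate through the stored weight matrix, the
    excitatory->interneuron synapses, and feedback inhibition, all with a
    1 ms synaptic delay.  Vectorized exponential-Euler over all neurons.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    cfg = network.config
    n = cfg.n_exc
    n_tot = n + 1  # interneuron last
    prm = network.neuron_params
    rest = _resting_cache(prm)

    v = np.full(n_tot, rest.v)
    m = np.full(n_tot, rest.m)
    h = np.full(n_tot, rest.h)
    gate_n = np.full(n_tot, rest.n)

    # double-exponential synapse states per neuron (AMPA and GABA channels)
    a1 = np.zeros(n_tot)
    a2 = np.zeros(n_tot)
    b1 = np.zeros(n_tot)
    b2 = np.zeros(n_tot)
    da1, da2 = math.exp(-dt / AMPA.tau1), math.exp(-dt / AMPA.tau2)
    db1, db2 = math.exp(-dt / GABA.tau1), math.exp(-dt / GABA.tau2)

    stim_mask = np.zeros(n_tot, dtype=bool)
    stim_mask[np.asarray(list(stimulated), dtype=int)] = True

    n_steps = int(round(window / dt))
    delay_steps = int(round(AMPA.delay / dt))
    pending_ampa: dict[int, np.ndarray] = {}
    pending_gaba: dict[int, np.ndarray] = {}

    g_leak, g_na_max, g_k_max = prm.g_leak_nS, prm.g_na_nS, prm.g_k_nS
    e_leak, e_na, e_k, cm = prm.e_leak, prm.e_na, prm.e_k, prm.capacitance_pF

    first_spike = np.full(n_tot, np.nan)
    spiked = np.zeros(n_tot, dtype=bool)
    w_scaled = network.weights / AMPA.peak_factor  # add directly to synapse states

    for i in range(n_steps):
        t = i * dt
        inc = pending_ampa.pop(i, None)
        if inc is not None:
            a1 += inc
            a2 += inc
        inc = pending_gaba.pop(i, None)
        if inc is not None:
            b1 += inc
            b2 += inc
        a1 *= da1
        a2 *= da2
        b1 *= db1
        b2 *= db2
        g_ampa = np.maximum(a2 - a1, 0.0)
        g_gaba = np.maximum(b2 - b1, 0.0)

        am = 0.32 * _vtrap_vec(v + 54.0, 4.0)
        bm = 0.28 * _vtrap_vec(-(v + 27.0), 5.0)
        ah = 0.128 * np.exp(-(v + 50.0) / 18.0)
        bh = 4.0 / (1.0 + np.exp(-(v + 27.0) / 5.0))
        an = 0.032 * _vtrap_vec(v + 52.0, 5.0)
        bn = 0.5 * np.exp(-(v + 57.0) / 40.0)
        m = _relax_vec(m, am, bm, dt)
        h = _relax_vec(h, ah, bh, dt)
        gate_n = _relax_vec(gate_n, an, bn, dt)

        i_stim = np.where(stim_mask & (t < stim_duration), stim_current, 0.0)
        g_na = g_na_max * m ** 3 * h
        g_k = g_k_max * gate_n ** 4
        g_tot = g_leak + g_na + g_k + g_ampa + g_gaba
        e_eff = (
            g_leak * e_leak
            + g_na * e_na
            + g_k * e_k
            + g_ampa * AMPA.e_rev
            + g_gaba * GABA.e_rev
            + i_stim
        ) / g_tot
        v_new = e_eff + (v - e_eff) * np.exp(-g_tot * dt / cm)

        crossing = (v < 0.0) & (v_new >= 0.0)
        if crossing.any():
            t_spk = t + dt
            newly = crossing & ~spiked
            first_spike[newly] = t_spk
            spiked |= crossing
            arrival = i + delay_steps
            exc_spk = np.flatnonzero(crossing[:n])
            if exc_spk.size:
                add = w_scaled[exc_spk].sum(axis=0)
                buf = pending_ampa.setdefault(arrival, np.zeros(n_tot))
                buf[:n] += add
                buf[n] += exc_spk.size * network.g_e_to_i / AMPA.peak_factor
            if crossing[n]:
                buf = pending_gaba.setdefault(arrival, np.zeros(n_tot))
                buf += network.g_gaba / GABA.peak_factor  # I->E fan-out + autapse
        v = v_new

    return spiked[: n], bool(spiked[n]), first_spike


def _vtrap_vec(x, y):
    small = np.abs(x / y) < 1e-6
    safe = np.where(small, 1.0, x)
    return np.where(small, y * (1.0 + x / (2.0 * y)), safe / (1.0 - np.exp(-safe / y)))


def _relax_vec(x, a, b, dt):
    x_inf = a / (a + b)
    return x_inf + (x - x_inf) * np.exp(-(a + b) * dt)


# ---------------------------------------------------------------------------
# Assays
# ---------------------------------------------------------------------------

def assay_separation(
    network: NetworkRealization,
    patterns: PatternSet,
    window: float = GAMMA_WINDOW,
    **sim_kwargs,
) -> np.ndarray:
    """Explicit-simulation separation outcomes: True marks a failed pattern.

    Each stored pattern's members are stimulated at cycle onset; the
    pattern fails if one or more non-member excitatory neurons spike
    within the window.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    failures = np.zeros(len(patterns), dtype=bool)
    for p, members in enumerate(patterns.patterns):
        spiked, _, _ = simulate_cycle(network, members, window, **sim_kwargs)
        mask = np.ones(network.config.n_exc, dtype=bool)
        mask[list(members)] = False
        failures[p] = bool(spiked[mask].any())
    return failures


def assay_completion(
    network: NetworkRealization,
    patterns: PatternSet,
    window: float = GAMMA_WINDOW,
    holdouts: str = "all",
    rng: np.random.Generator | None = None,
    **sim_kwargs,
) -> np.ndarray:
    """Explicit-simulation completion error fraction per pattern.

    For each pattern and each leave-one-out holdout, the remaining members
    are stimulated and the holdout must spike within the window.  With
    ``holdouts="all"`` every member is held out in turn and the per-pattern
    error is the failed fraction; ``holdouts="single"`` tests one random
    holdout per pattern (requires ``rng``).
    """
    if window <= 0:
        raise ValueError("window must be positive")
    errors = np.zeros(len(patterns))
    for p, members in enumerate(patterns.patterns):
        members = list(members)
        if holdouts == "single":
            if rng is None:
                raise ValueError("holdouts='single' requires an rng")
            test_set = [members[int(rng.integers(len(members)))]]
        else:
            test_set = members
        failed = 0
        for held_out in test_set:
            cue = [idx for idx in members if idx != held_out]
            spiked, _, _ = simulate_cycle(network, cue, window, **sim_kwargs)
            if not spiked[held_out]:
                failed += 1
        errors[p] = failed / len(test_set)
    return errors


@dataclass(frozen=True)
class AssayResult:
    """Separation/completion outcomes for one network + pattern-set run."""

    separation_failures: np.ndarray  # bool per pattern
    completion_errors: np.ndarray    # fraction per pattern
    metadata: dict = field(default_factory=dict)

    @property
    def separation_error_rate(self) -> float:
        return float(np.mean(self.separation_failures))

    @property
    def completion_error_rate(self) -> float:
        return float(np.mean(self.completion_errors))

    @property
    def max_error(self) -> float:
        return max(self.separation_error_rate, self.completion_error_rate)


def explicit_assay(
    network: NetworkRealization,
    patterns: PatternSet,
    window: float = GAMMA_WINDOW,
    **sim_kwargs,
) -> AssayResult:
    """Both assays via full conductance-based simulation."""
    return AssayResult(
        assay_separation(network, patterns, window, **sim_kwargs),
        assay_completion(network, patterns, window, **sim_kwargs),
        metadata={"route": "explicit", "window": window},
    )


def fast_assay(
    network: NetworkRealization,
    patterns: PatternSet,
    table: ThresholdTable,
) -> AssayResult:
    """Threshold-table assay: one synchronous recruitment round per cycle.

    Per tested neuron, total excitatory conductance is the sum of stored
    weights from the firing (stimulated) presynaptic neurons; the
    interneuron's drive is 0.9*g_max_ampa per firing excitatory cell, and
    it is resolved first at zero inhibition (its autaptic GABA arrives only
    after its own spike).  If it fires, every excitatory decision sees
    gGABA of inhibition.
    """
    cfg = network.config
    w = network.weights
    n_pat = len(patterns)
    member = patterns.membership_matrix()
    k = cfg.pattern_size

    # interneuron decisions depend only on how many cue neurons fire
    g_i_full = network.g_gaba if table.predicts_spike(k * network.g_e_to_i, 0.0) else 0.0
    g_i_cue = (
        network.g_gaba if table.predicts_spike((k - 1) * network.g_e_to_i, 0.0) else 0.0
    )
    thr_full = table.threshold_at(g_i_full)
    thr_cue = table.threshold_at(g_i_cue)
    drive = member.astype(float) @ w  # (n_pat, n_exc) summed conductance
    max_drive = float(drive.max(initial=0.0))
    if max_drive > table.g_exc_max:
        raise TableCoverageError(
            f"summed excitatory drive {max_drive:g} nS exceeds table search bound "
            f"{table.g_exc_max:g} nS"
        )
    sep_fail = np.zeros(n_pat, dtype=bool)
    comp_err = np.zeros(n_pat)
    for p in range(n_pat):
        non = ~member[p]
        sep_fail[p] = bool(np.any(drive[p][non] >= thr_full))
        # diagonal of w is zero, so a member's drive excludes itself
        comp_err[p] = float(np.mean(drive[p][member[p]] < thr_cue))

    return AssayResult(
        sep_fail,
        comp_err,
        metadata={"route": "table", "offset": table.offset},
    )


def aggregate_errors(results: dict[int, dict[int, AssayResult]]) -> dict:
    """Aggregate per-run results over pattern-set seeds, then profiles.

    ``results[profile][pattern_seed]`` must form a complete grid.  Rates
    are averaged over pattern seeds within each connectivity profile, then
    reported as mean +/- SEM over the profiles.
    """
    profiles = sorted(results)
    seed_sets = [sorted(results[p]) for p in profiles]
    expected = seed_sets[0]
    missing = [
        (p, s)
        for p, seeds in zip(profiles, seed_sets)
        for s in set(expected) ^ set(seeds)
    ]
    if missing:
        raise ValueError(f"incomplete run grid; missing (profile, seed) pairs: {missing}")

    sep_by_profile = np.array(
        [np.mean([results[p][s].separation_error_rate for s in expected]) for p in profiles]
    )
    comp_by_profile = np.array(
        [np.mean([results[p][s].completion_error_rate for s in expected]) for p in profiles]
    )
    n_prof = len(profiles)

    def sem(x):
        if len(x) < 2:
            return 0.0
        return float(np.std(x, ddof=1) / np.sqrt(len(x)))

    sep = float(np.mean(sep_by_profile))
    comp = float(np.mean(comp_by_profile))
    return {
        "separation_error_rate": sep,
        "completion_error_rate": comp,
        "max_error": max(sep, comp),
        "separation_sem": sem(sep_by_profile),
        "completion_sem": sem(comp_by_profile),
        "n_profiles": n_prof,
        "n_pattern_seeds": len(expected),
    }


_ADJ_CACHE: dict[tuple, np.ndarray] = {}
_COUNT_CACHE: dict[tuple, tuple] = {}


def evaluate_config(
    config: NetworkConfig,
    n_patterns: int,
    table: ThresholdTable,
    n_profiles: int = 3,
    n_pattern_seeds: int = 10,
    base_connectivity_seed: int = 0,
    base_pattern_seed: int = 1000,
) -> dict:
    """Fast-assay a parameter combination over the full profile x seed grid.

    Connectivity matrices and pattern coactivation counts depend only on
    (connectivity level, seeds, load), not on the synaptic strength
    parameters, so they are memoized; pathology/therapy line searches that
    rescan g_max_ampa, gamma_ltd or inhibition reuse them for free.
    """
    from .patterns import PatternSet
    from .plasticity import compute_weight

    results: dict[int, dict[int, AssayResult]] = {}
    for prof in range(n_profiles):
        adj_key = (
            config.n_exc,
            round(config.connectivity_level, 12),
            config.fixed_outdegree,
            base_connectivity_seed + prof,
        )
        adjacency = _ADJ_CACHE.get(adj_key)
        if adjacency is None:
            adjacency = build_connectivity(config, seed=base_connectivity_seed + prof)
            _ADJ_CACHE[adj_key] = adjacency
            if len(_ADJ_CACHE) > 256:
                _ADJ_CACHE.pop(next(iter(_ADJ_CACHE)))
        results[prof] = {}
        for ps in range(n_pattern_seeds):
            cnt_key = adj_key + (config.pattern_size, n_patterns, base_pattern_seed + ps)
            cached = _COUNT_CACHE.get(cnt_key)
            if cached is None:
                pats = generate_pattern_set(
                    n_patterns, config, seed=base_pattern_seed + ps
                )
                counts = count_pair_activity(pats, adjacency)
                cached = (pats, counts)
                _COUNT_CACHE[cnt_key] = cached
                if len(_COUNT_CACHE) > 2048:
                    _COUNT_CACHE.pop(next(iter(_COUNT_CACHE)))
            pats, counts = cached
            weights = compute_weight(
                counts.n11, counts.n10, counts.n01, config.g_max_ampa, config.gamma_ltd
            )
            net = NetworkRealization(
                config, adjacency, weights, feedback_inhibition_strength(config)
            )
            results[prof][ps] = fast_assay(net, pats, table)
    return aggregate_errors(results)
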