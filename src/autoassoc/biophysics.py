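"""Single-neuron conductance-based dynamics, synaptic waveforms and spike-threshold tables.

The model neuron is an isopotential sphere (radius 10 um) carrying leak,
fast Na+ and delayed-rectifier K+ conductances with reduced Traub--Miles
gating kinetics.  Internal units: mV, ms, nS, pF, pA.

.. note::
    Conductance densities are interpreted in mS/cm^2.  Some sources print
    the same numerical values with uS/cm^2 units, which would yield a
    membrane time constant of ~10^4 s and a cell unable to spike; with
    mS/cm^2 the leak gives tau_m = C_m/G_leak = 10 ms and normal spiking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "NeuronParams",
    "SynapseKinetics",
    "NeuronState",
    "SynapticEvent",
    "AMPA",
    "GABA",
    "DEFAULT_DT",
    "conductance_waveform",
    "step_neuron",
    "simulate_single_neuron",
    "find_spike_threshold",
    "ThresholdTable",
    "TableCoverageError",
]

DEFAULT_DT = 0.025  # ms

UM2_TO_CM2 = 1e-8


class NumericalDivergenceError(RuntimeError):
    """Raised when an integrated state variable becomes non-finite."""


class TableCoverageError(ValueError):
    """Requested conductance lies outside the range a threshold table covers."""


# ---------------------------------------------------------------------------
# Gating kinetics (reduced Traub-Miles rate functions; V in mV, rates in 1/ms)
# ---------------------------------------------------------------------------

def _vtrap(x, y):
    """x / (1 - exp(-x/y)) with the removable singularity at x = 0 handled."""
    x = np.asarray(x, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(
            np.abs(x / y) < 1e-6, y * (1.0 + x / (2.0 * y)), x / (1.0 - np.exp(-x / y))
        )
    return out


def alpha_m(v):
    return 0.32 * _vtrap(v + 54.0, 4.0)


def beta_m(v):
    return 0.28 * _vtrap(-(v + 27.0), 5.0)


def alpha_h(v):
    return 0.128 * np.exp(-(np.asarray(v, dtype=float) + 50.0) / 18.0)


def beta_h(v):
    return 4.0 / (1.0 + np.exp(-(np.asarray(v, dtype=float) + 27.0) / 5.0))


def alpha_n(v):
    return 0.032 * _vtrap(v + 52.0, 5.0)


def beta_n(v):
    return 0.5 * np.exp(-(np.asarray(v, dtype=float) + 57.0) / 40.0)


def gate_steady_state(v):
    """Return (m_inf, h_inf, n_inf) at membrane potential ``v`` (mV)."""
    am, bm = alpha_m(v), beta_m(v)
    ah, bh = alpha_h(v), beta_h(v)
    an, bn = alpha_n(v), beta_n(v)
    return am / (am + bm), ah / (ah + bh), an / (an + bn)


def gate_time_constants(v):
    """Return (tau_m, tau_h, tau_n) in ms at membrane potential ``v``."""
    return (
        1.0 / (alpha_m(v) + beta_m(v)),
        1.0 / (alpha_h(v) + beta_h(v)),
        1.0 / (alpha_n(v) + beta_n(v)),
    )


# ---------------------------------------------------------------------------
# Parameters and kinetics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NeuronParams:
    """Biophysical constants of the isopotential model neuron.

    Densities are per-area values (capacitance in uF/cm^2, conductances in
    mS/cm^2); whole-cell values are derived through the sphere surface area.
    """

    radius_um: float = 10.0
    capacitance_density: float = 1.0   # uF/cm^2
    leak_density: float = 0.1          # mS/cm^2
    na_density: float = 100.0          # mS/cm^2
    k_density: float = 80.0            # mS/cm^2
    e_leak: float = -67.0              # mV
    e_na: float = 90.0                 # mV
    e_k: float = -100.0                # mV
    gating_kinetics: str = "reduced-traub-miles"

    def __post_init__(self):
        if self.radius_um <= 0:
            raise ValueError("radius must be positive")
        if not (self.e_k < self.e_leak < 0 < self.e_na):
            raise ValueError("reversal potentials must satisfy E_K < E_leak < 0 < E_Na")

    @property
    def area_cm2(self) -> float:
        r_cm = self.radius_um * 1e-4
        return 4.0 * math.pi * r_cm * r_cm

    @property
    def capacitance_pF(self) -> float:
        return self.capacitance_density * self.area_cm2 * 1e6  # uF -> pF

    @property
    def g_leak_nS(self) -> float:
        return self.leak_density * self.area_cm2 * 1e6  # mS -> nS

    @property
    def g_na_nS(self) -> float:
        return self.na_density * self.area_cm2 * 1e6

    @property
    def g_k_nS(self) -> float:
        return self.k_density * self.area_cm2 * 1e6

    def resting_state(self) -> "NeuronState":
        """Steady state found by relaxing the full dynamics from E_leak."""
        v = self.e_leak
        m, h, n = gate_steady_state(v)
        state = NeuronState(v=float(v), m=float(m), h=float(h), n=float(n))
        # Relax for 200 ms; the fixed point is reached well within tau_m*20.
        for _ in range(int(200.0 / DEFAULT_DT)):
            state = step_neuron(state, self, DEFAULT_DT)
        return replace(state, spike_times=(), t=0.0)


@dataclass(frozen=True)
class SynapseKinetics:
    """Difference-of-exponentials conductance time course, peak-normalized."""

    tau1: float  # ms, rise
    tau2: float  # ms, decay
    e_rev: float  # mV
    delay: float = 1.0  # ms

    def __post_init__(self):
        if not (self.tau2 > self.tau1 > 0):
            raise ValueError("require tau2 > tau1 > 0")

    @property
    def peak_time(self) -> float:
        """Time of the waveform maximum after onset (ms)."""
        return self.tau1 * self.tau2 / (self.tau2 - self.tau1) * math.log(self.tau2 / self.tau1)

    @property
    def peak_factor(self) -> float:
        """Value of exp(-t/tau2) - exp(-t/tau1) at the peak (the normalizer)."""
        t = self.peak_time
        return math.exp(-t / self.tau2) - math.exp(-t / self.tau1)


AMPA = SynapseKinetics(tau1=1.0, tau2=4.0, e_rev=0.0)
GABA = SynapseKinetics(tau1=2.0, tau2=8.0, e_rev=-80.0)


@dataclass(frozen=True)
class SynapticEvent:
    onset: float  # ms
    kinetics: SynapseKinetics
    amplitude: float  # nS, peak conductance

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValueError("synaptic amplitude must be non-negative")


@dataclass(frozen=True)
class NeuronState:
    """Dynamical state of one neuron plus its pending synaptic events."""

    v: float
    m: float
    h: float
    n: float
    t: float = 0.0
    events: tuple[SynapticEvent, ...] = ()
    stim_current: float = 0.0  # pA, tonic injected current
    spike_times: tuple[float, ...] = ()


def conductance_waveform(t_since_onset, kinetics: SynapseKinetics, amplitude: float):
    """Peak-normalized double-exponential conductance at ``t_since_onset`` ms.

    The waveform is scaled so that its maximum equals ``amplitude`` (nS),
    making event amplitudes directly interpretable as peak conductances.
    Returns 0 for negative times.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    t = np.asarray(t_since_onset, dtype=float)
    raw = np.where(t >= 0, np.exp(-t / kinetics.tau2) - np.exp(-t / kinetics.tau1), 0.0)
    out = amplitude * raw / kinetics.peak_factor
    if np.isscalar(t_since_onset):
        return float(out)
    return out


def _synaptic_conductance(state: NeuronState, t: float):
    """Summed (g_exc*E, g_exc, g_inh*E, g_inh) pairs -> (sum g*E, sum g)."""
    g_sum = 0.0
    ge_sum = 0.0
    for ev in state.events:
        g = conductance_waveform(t - ev.onset, ev.kinetics, ev.amplitude)
        g_sum += g
        ge_sum += g * ev.kinetics.e_rev
    return ge_sum, g_sum


def step_neuron(state: NeuronState, params: NeuronParams, dt: float) -> NeuronState:
    """Advance one exponential-Euler step of dt ms; spike on upward 0-mV crossing."""
    if not (0 < dt <= 0.1):
        raise ValueError("dt must be in (0, 0.1] ms")
    for name in ("v", "m", "h", "n"):
        if not math.isfinite(getattr(state, name)):
            raise NumericalDivergenceError(f"state variable {name!r} is non-finite")

    v = state.v
    # Gates: exact update of the linear relaxation at frozen V.
    am, bm = float(alpha_m(v)), float(beta_m(v))
    ah, bh = float(alpha_h(v)), float(beta_h(v))
    an, bn = float(alpha_n(v)), float(beta_n(v))
    m = _relax(state.m, am / (am + bm), (am + bm), dt)
    h = _relax(state.h, ah / (ah + bh), (ah + bh), dt)
    n = _relax(state.n, an / (an + bn), (an + bn), dt)

    ge_syn, g_syn = _synaptic_conductance(state, state.t)
    g_na = params.g_na_nS * m ** 3 * h
    g_k = params.g_k_nS * n ** 4
    g_tot = params.g_leak_nS + g_na + g_k + g_syn
    e_eff = (
        params.g_leak_nS * params.e_leak
        + g_na * params.e_na
        + g_k * params.e_k
        + ge_syn
        + state.stim_current
    ) / g_tot
    v_new = e_eff + (v - e_eff) * math.exp(-g_tot * dt / params.capacitance_pF)

    t_new = state.t + dt
    spikes = state.spike_times
    if v < 0.0 <= v_new:
        spikes = spikes + (t_new,)
    return replace(state, v=v_new, m=m, h=h, n=n, t=t_new, spike_times=spikes)


def _relax(x, x_inf, rate, dt):
    return x_inf + (x - x_inf) * math.exp(-rate * dt)


# ---------------------------------------------------------------------------
# Fast scalar single-neuron simulation (used heavily by threshold search)
# ---------------------------------------------------------------------------

def simulate_single_neuron(
    params: NeuronParams,
    events: list[SynapticEvent] | tuple[SynapticEvent, ...],
    duration: float,
    dt: float = DEFAULT_DT,
    initial: NeuronState | None = None,
    stim_current: float = 0.0,
    stim_window: tuple[float, float] | None = None,
) -> list[float]:
    """Integrate one neuron for ``duration`` ms; return spike times (ms).

    Synaptic drive is tracked with per-kinetics exponential state pairs
    (jump on event onset, pure decay otherwise), which is exact for the
    difference-of-exponentials waveform and avoids re-evaluating every
    event at every step.
    """
    if initial is None:
        initial = _resting_cache(params)
    v, m, h, n = initial.v, initial.m, initial.h, initial.n

    groups: dict[SynapseKinetics, list[float]] = {}
    pending: dict[SynapseKinetics, list[tuple[int, float]]] = {}
    n_steps = int(round(duration / dt))
    for ev in events:
        step_idx = int(math.ceil(ev.onset / dt - 1e-9))
        pending.setdefault(ev.kinetics, []).append((step_idx, ev.amplitude / ev.kinetics.peak_factor))
        groups.setdefault(ev.kinetics, [0.0, 0.0])
    for k in pending:
        pending[k].sort()

    decay = {k: (math.exp(-dt / k.tau1), math.exp(-dt / k.tau2)) for k in groups}
    g_leak, g_na_max, g_k_max = params.g_leak_nS, params.g_na_nS, params.g_k_nS
    e_leak, e_na, e_k, cm = params.e_leak, params.e_na, params.e_k, params.capacitance_pF
    exp = math.exp
    spikes: list[float] = []

    for i in range(n_steps):
        t = i * dt
        # apply due events, then decay the synapse states
        ge_syn = 0.0
        g_syn = 0.0
        for k, st in groups.items():
            due = pending.get(k)
            while due and due[0][0] <= i:
                _, amp = due.pop(0)
                st[0] += amp
                st[1] += amp
            d1, d2 = decay[k]
            st[0] *= d1
            st[1] *= d2
            g = st[1] - st[0]
            if g < 0:
                g = 0.0
            g_syn += g
            ge_syn += g * k.e_rev

        am = 0.32 * _vtrap_s(v + 54.0, 4.0)
        bm = 0.28 * _vtrap_s(-(v + 27.0), 5.0)
        ah = 0.128 * exp(-(v + 50.0) / 18.0)
        bh = 4.0 / (1.0 + exp(-(v + 27.0) / 5.0))
        an = 0.032 * _vtrap_s(v + 52.0, 5.0)
        bn = 0.5 * exp(-(v + 57.0) / 40.0)
        m = am / (am + bm) + (m - am / (am + bm)) * exp(-(am + bm) * dt)
        h = ah / (ah + bh) + (h - ah / (ah + bh)) * exp(-(ah + bh) * dt)
        n = an / (an + bn) + (n - an / (an + bn)) * exp(-(an + bn) * dt)

        i_stim = stim_current if (stim_window is not None and stim_window[0] <= t < stim_window[1]) else 0.0
        g_na = g_na_max * m * m * m * h
        g_k = g_k_max * n * n * n * n
        g_tot = g_leak + g_na + g_k + g_syn
        e_eff = (g_leak * e_leak + g_na * e_na + g_k * e_k + ge_syn + i_stim) / g_tot
        v_new = e_eff + (v - e_eff) * exp(-g_tot * dt / cm)
        if v < 0.0 <= v_new:
            spikes.append(t + dt)
        v = v_new
    return spikes


def _vtrap_s(x: float, y: float) -> float:
    if abs(x / y) < 1e-6:
        return y * (1.0 + x / (2.0 * y))
    return x / (1.0 - math.exp(-x / y))


_REST_CACHE: dict[NeuronParams, NeuronState] = {}


def _resting_cache(params: NeuronParams) -> NeuronState:
    st = _REST_CACHE.get(params)
    if st is None:
        st = params.resting_state()
        _REST_CACHE[params] = st
    return st


# ---------------------------------------------------------------------------
# Spike thresholds and the lookup table
# ---------------------------------------------------------------------------

UNREACHABLE = math.inf


#: Default lag of the GABA event behind the AMPA event in threshold-table
#: simulations.  The nominal disynaptic latency is 2 ms (1 ms E->I plus
#: 1 ms I->E delay), but the measured emergent lag in full network
#: simulations is ~1.3 ms because the strongly driven interneuron spikes
#: with sub-millisecond latency while stimulated cells take ~1 ms to fire.
#: The matched value maximizes table/explicit agreement; it remains a
#: configurable table parameter.
DEFAULT_EI_OFFSET = 1.3


def find_spike_threshold(
    params: NeuronParams,
    g_inhibition: float,
    timing_offset: float = DEFAULT_EI_OFFSET,
    *,
    excitatory: SynapseKinetics = AMPA,
    inhibitory: SynapseKinetics = GABA,
    upper_bound: float = 5000.0,
    rtol: float = 1e-3,
    onset: float = 1.0,
    duration: float = 25.0,
    dt: float = DEFAULT_DT,
) -> float:
    """Minimal AMPA peak conductance (nS) that makes the neuron spike.

    A single excitatory event arrives at ``onset``; a GABA event with peak
    conductance ``g_inhibition`` follows after ``timing_offset`` ms (the
    disynaptic feedback latency).  The threshold is located by bisection to
    relative tolerance ``rtol``; if even ``upper_bound`` fails to evoke a
    spike the sentinel ``math.inf`` ("unreachable") is returned.
    """
    if g_inhibition < 0:
        raise ValueError("g_inhibition must be non-negative")

    def spikes(g_exc: float) -> bool:
        events = [SynapticEvent(onset, excitatory, g_exc)]
        if g_inhibition > 0:
            events.append(SynapticEvent(onset + timing_offset, inhibitory, g_inhibition))
        return len(simulate_single_neuron(params, events, duration, dt)) > 0

    if not spikes(upper_bound):
        return UNREACHABLE
    lo, hi = 0.0, upper_bound
    while hi - lo > rtol * hi:
        mid = 0.5 * (lo + hi)
        if spikes(mid):
            hi = mid
        else:
            lo = mid
    return hi


@dataclass
class ThresholdTable:
    """Lookup table: minimal excitatory conductance to spike vs. inhibition.

    ``thresholds[i]`` is the spiking threshold (nS of AMPA peak conductance)
    at inhibitory peak conductance ``g_inh_grid[i]``; ``math.inf`` marks
    inhibition levels where no spike is reachable below ``g_exc_max``.
    """

    g_inh_grid: np.ndarray
    thresholds: np.ndarray
    offset: float
    g_exc_max: float
    params: NeuronParams = field(default_factory=NeuronParams)

    @classmethod
    def build(
        cls,
        params: NeuronParams | None = None,
        *,
        g_inh_max: float = 1e6,
        n_points: int = 28,
        offset: float = DEFAULT_EI_OFFSET,
        g_exc_max: float = 5000.0,
        dt: float = DEFAULT_DT,
    ) -> "ThresholdTable":
        """Generate the table from systematic single-neuron simulations.

        The inhibition grid is 0 plus log-spaced points up to ``g_inh_max``,
        dense at low conductances where the threshold curve bends.
        """
        params = params or NeuronParams()
        grid = np.concatenate([[0.0], np.geomspace(0.5, g_inh_max, n_points - 1)])
        thresholds = np.array(
            [
                find_spike_threshold(
                    params, gi, offset, upper_bound=g_exc_max, dt=dt
                )
                for gi in grid
            ]
        )
        return cls(grid, thresholds, offset, g_exc_max, params)

    def threshold_at(self, g_inh):
        """Interpolated spiking threshold at inhibitory conductance ``g_inh``.

        Linear interpolation between grid points; any segment touching an
        unreachable entry is itself unreachable (conservative).  Raises
        :class:`TableCoverageError` outside the grid.
        """
        gi = np.atleast_1d(np.asarray(g_inh, dtype=float))
        if np.any(gi < 0) or np.any(gi > self.g_inh_grid[-1]):
            raise TableCoverageError(
                f"inhibitory conductance outside table range [0, {self.g_inh_grid[-1]:g}] nS"
            )
        idx = np.searchsorted(self.g_inh_grid, gi, side="right") - 1
        idx = np.clip(idx, 0, len(self.g_inh_grid) - 2)
        x0 = self.g_inh_grid[idx]
        x1 = self.g_inh_grid[idx + 1]
        y0 = self.thresholds[idx]
        y1 = self.thresholds[idx + 1]
        with np.errstate(invalid="ignore"):
            frac = (gi - x0) / (x1 - x0)
            out = y0 + frac * (y1 - y0)
        # exact hits on a grid point take the tabulated value even if a
        # neighbor is unreachable
        exact = gi == x0
        out = np.where(exact, y0, out)
        out = np.where((gi == x1), y1, out)
        out = np.where(np.isinf(y0) & ~ (gi == x1), np.inf, out)
        out = np.where(np.isinf(y1) & ~exact, np.inf, out)
        if np.isscalar(g_inh) or np.ndim(g_inh) == 0:
            return float(out[0])
        return out

    def predicts_spike(self, g_exc, g_inh):
        """Table prediction: does excitation ``g_exc`` fire against ``g_inh``?"""
        thr = self.threshold_at(g_inh)
        ge = np.asarray(g_exc, dtype=float)
        if np.any(ge > self.g_exc_max * (1 + 1e-9)):
            raise TableCoverageError(
                f"excitatory conductance exceeds table search bound {self.g_exc_max:g} nS"
            )
        out = ge >= thr
        if np.ndim(g_exc) == 0 and np.ndim(g_inh) == 0:
            return bool(out)
        return out

    # -- persistence --------------------------------------------------------

    def to_csv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame(
            {
                "gI": self.g_inh_grid,
                "offset": self.offset,
                "threshold_gE": self.thresholds,
            }
        )
        with open(path, "w") as fh:
            fh.write(f"# g_exc_max={self.g_exc_max}\n")
            df.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path, params: NeuronParams | None = None) -> "ThresholdTable":
        import pandas as pd

        with open(path) as fh:
            header = fh.readline()
            g_exc_max = float(header.strip().split("=", 1)[1]) if "=" in header else 5000.0
            df = pd.read_csv(fh)
        return cls(
            df["gI"].to_numpy(float),
            df["threshold_gE"].to_numpy(float),
            float(df["offset"].iloc[0]),
            g_exc_max,
            params or NeuronParams(),
        )
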