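"""Parameter-grid database: build, run (threshold-table fast path), select optima.

The full design crosses 20 values of each of four synaptic parameters
(160,000 combinations) with 6 pattern-set sizes, each evaluated over
3 connectivity profiles x 10 random memory sets (180 runs per combination,
960,000 database conditions).  A ``values_per_axis`` override provides the
desk-scale mode used by tests and examples.
"""

from __future__ import annotations

import itertools
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .biophysics import ThresholdTable
from .network import NetworkConfig, build_connectivity, feedback_inhibition_strength
from .patterns import count_pair_activity, generate_pattern_set

__all__ = ["GridSpec", "build_grid", "run_sweep", "select_optimal"]

DB_COLUMNS = [
    "connectivity",
    "g_max_ampa",
    "gamma_ltd",
    "relative_inhibition",
    "n_patterns",
    "sep_err",
    "comp_err",
    "max_err",
    "sep_sem",
    "comp_sem",
]


@dataclass(frozen=True)
class GridSpec:
    """Factorial grid over the four synaptic parameters plus storage loads."""

    values_per_axis: int = 20
    connectivity_range: tuple[float, float] = (0.05, 1.0)      # linear
    g_max_range: tuple[float, float] = (2.78, 55.56)           # nS, linear
    inhibition_range: tuple[float, float] = (0.01, 100.0)      # log-spaced
    gamma_ltd_range: tuple[float, float] = (0.1, 10.0)         # log-spaced
    set_sizes: tuple[int, ...] = (5, 10, 15, 20, 25, 30)
    n_profiles: int = 3
    n_pattern_seeds: int = 10

    def connectivity_values(self) -> np.ndarray:
        return np.linspace(*self.connectivity_range, self.values_per_axis)

    def g_max_values(self) -> np.ndarray:
        return np.linspace(*self.g_max_range, self.values_per_axis)

    def inhibition_values(self) -> np.ndarray:
        return np.geomspace(*self.inhibition_range, self.values_per_axis)

    def gamma_ltd_values(self) -> np.ndarray:
        return np.geomspace(*self.gamma_ltd_range, self.values_per_axis)

    @property
    def n_combinations(self) -> int:
        return self.values_per_axis ** 4

    @property
    def runs_per_combination(self) -> int:
        return len(self.set_sizes) * self.n_profiles * self.n_pattern_seeds

    @property
    def n_conditions(self) -> int:
        return self.n_combinations * len(self.set_sizes)

    def scaled(self, values_per_axis: int, set_sizes: tuple[int, ...] | None = None) -> "GridSpec":
        """Subsampled grid with the same endpoints (desk-scale mode)."""
        out = replace(self, values_per_axis=values_per_axis)
        if set_sizes is not None:
            out = replace(out, set_sizes=tuple(set_sizes))
        return out


def build_grid(spec: GridSpec) -> list[tuple[float, float, float, float]]:
    """Enumerate (connectivity, g_max_ampa, gamma_ltd, relative_inhibition)."""
    return list(
        itertools.product(
            spec.connectivity_values(),
            spec.g_max_values(),
            spec.gamma_ltd_values(),
            spec.inhibition_values(),
        )
    )


def _sem(x: np.ndarray) -> float:
    if len(x) < 2:
        return 0.0
    return float(np.std(x, ddof=1) / np.sqrt(len(x)))


def run_sweep(
    spec: GridSpec,
    table: ThresholdTable,
    seed: int = 0,
    connectivity_values: np.ndarray | None = None,
    checkpoint_dir: str | None = None,
    resume: bool = True,
    n_exc: int = 100,
    pattern_size: int = 10,
    e_to_i_scale: float = 0.9,
    progress: bool = False,
) -> pd.DataFrame:
    """Evaluate every grid condition with the threshold-table fast path.

    Seeds for connectivity profiles and memory sets are derived from
    ``seed`` deterministically per (profile, set) index, so a rerun with
    the same arguments reproduces the database exactly.  When a
    ``checkpoint_dir`` is given, one CSV per connectivity level is written
    and finished levels are skipped on resume.

    The inner loops are ordered so that pattern coactivation counts are
    computed once per (connectivity level, profile, load, memory set) and
    reused across all (g_max, gamma_ltd, inhibition) combinations.
    """
    if connectivity_values is None:
        connectivity_values = spec.connectivity_values()
    g_max_values = spec.g_max_values()
    gamma_values = spec.gamma_ltd_values()
    inh_values = spec.inhibition_values()

    # verify table coverage up front: worst-case conductances in any decision
    max_ge = max(
        pattern_size * g_max_values.max(),
        pattern_size * e_to_i_scale * g_max_values.max(),
    )
    max_gi = g_max_values.max() * pattern_size * max(connectivity_values) * inh_values.max()
    if max_ge > table.g_exc_max or max_gi > table.g_inh_grid[-1]:
        raise ValueError(
            "threshold table does not cover the grid: needs "
            f"gE<={max_ge:g} nS (table {table.g_exc_max:g}) and "
            f"gI<={max_gi:g} nS (table {table.g_inh_grid[-1]:g})"
        )

    if checkpoint_dir is not None:
        os.makedirs(checkpoint_dir, exist_ok=True)

    frames = []
    iterator = enumerate(connectivity_values)
    if progress:
        try:
            from tqdm import tqdm

            iterator = tqdm(list(iterator), desc="connectivity levels")
        except ImportError:
            pass

    for level_idx, level in iterator:
        ckpt = (
            os.path.join(checkpoint_dir, f"level_{level_idx:03d}.csv")
            if checkpoint_dir
            else None
        )
        if ckpt and resume and os.path.exists(ckpt):
            frames.append(pd.read_csv(ckpt))
            continue
        df = _sweep_level(
            float(level),
            spec,
            table,
            g_max_values,
            gamma_values,
            inh_values,
            seed,
            n_exc,
            pattern_size,
            e_to_i_scale,
        )
        if ckpt:
            df.to_csv(ckpt, index=False)
        frames.append(df)

    return pd.concat(frames, ignore_index=True)


def _sweep_level(
    level, spec, table, g_max_values, gamma_values, inh_values, seed,
    n_exc, pattern_size, e_to_i_scale,
):
    probe = NetworkConfig(
        connectivity_level=level,
        g_max_ampa=1.0,
        gamma_ltd=1.0,
        relative_inhibition=0.0,
        n_exc=n_exc,
        pattern_size=pattern_size,
        e_to_i_scale=e_to_i_scale,
    )
    n_prof, n_seeds = spec.n_profiles, spec.n_pattern_seeds
    n_g, n_gam, n_inh = len(g_max_values), len(gamma_values), len(inh_values)
    n_combo = n_g * n_gam * n_inh
    n_loads = len(spec.set_sizes)
    sep_acc = np.zeros((n_combo, n_loads, n_prof))
    comp_acc = np.zeros((n_combo, n_loads, n_prof))

    # thresholds per (g_max, rel_inh): the interneuron is resolved first at
    # zero inhibition, then every excitatory decision sees gGABA (or 0)
    k = pattern_size
    thr_full = np.empty((n_g, n_inh))   # all k members firing (separation)
    thr_cue = np.empty((n_g, n_inh))    # k-1 members firing (completion)
    for gi, g_max in enumerate(g_max_values):
        for ii, rel_inh in enumerate(inh_values):
            g_gaba = g_max * k * level * rel_inh
            inh_fires = table.predicts_spike(k * e_to_i_scale * g_max, 0.0)
            thr_full[gi, ii] = table.threshold_at(g_gaba if inh_fires else 0.0)
            inh_fires9 = table.predicts_spike((k - 1) * e_to_i_scale * g_max, 0.0)
            thr_cue[gi, ii] = table.threshold_at(g_gaba if inh_fires9 else 0.0)

    for prof in range(n_prof):
        adjacency = build_connectivity(probe, seed=seed * 10007 + prof)
        for load_idx, n_patterns in enumerate(spec.set_sizes):
            for ps in range(n_seeds):
                pats = generate_pattern_set(
                    n_patterns, probe, seed=seed * 7919 + 1000 * n_patterns + ps
                )
                counts = count_pair_activity(pats, adjacency)
                n11 = counts.n11.astype(float)
                s = (counts.n10 + counts.n01).astype(float)
                members = pats.membership_matrix()
                memf = members.astype(float)
                for gamma_idx, gamma in enumerate(gamma_values):
                    denom = n11 + s * gamma
                    ratio = np.where(n11 > 0, n11 / np.where(denom > 0, denom, 1.0), 0.0)
                    drive = memf @ ratio  # (n_pat, n_exc), per unit g_max
                    # separation: only the largest non-member drive matters
                    sep_max = np.where(members, -np.inf, drive).max(axis=1)
                    # completion: drive onto each held-out member (diag of
                    # the weight matrix is zero, so self-drive is absent)
                    hold = np.array([drive[p][members[p]] for p in range(n_patterns)])
                    for g_idx, g_max in enumerate(g_max_values):
                        flat0 = g_idx * n_gam * n_inh + gamma_idx * n_inh
                        sep_err = np.mean(
                            g_max * sep_max[:, None] >= thr_full[g_idx][None, :], axis=0
                        )
                        comp_err = np.mean(
                            (g_max * hold[:, :, None] < thr_cue[g_idx][None, None, :]),
                            axis=(0, 1),
                        )
                        sep_acc[flat0 : flat0 + n_inh, load_idx, prof] += sep_err
                        comp_acc[flat0 : flat0 + n_inh, load_idx, prof] += comp_err

    sep_mean = sep_acc / n_seeds
    comp_mean = comp_acc / n_seeds
    rows = []
    for flat, (g_max, gamma, rel_inh) in enumerate(
        itertools.product(g_max_values, gamma_values, inh_values)
    ):
        for load_idx, n_patterns in enumerate(spec.set_sizes):
            sep_p = sep_mean[flat, load_idx]
            comp_p = comp_mean[flat, load_idx]
            sep, comp = float(sep_p.mean()), float(comp_p.mean())
            rows.append(
                (
                    level, g_max, gamma, rel_inh, n_patterns,
                    sep, comp, max(sep, comp), _sem(sep_p), _sem(comp_p),
                )
            )
    return pd.DataFrame(rows, columns=DB_COLUMNS)


def select_optimal(
    db: pd.DataFrame,
    connectivity: float,
    n_patterns: int,
    top_k: int = 100,
) -> pd.DataFrame:
    """Lowest-max-error parameter combinations at a fixed connectivity and load.

    Ties break by smaller |sep_err - comp_err| (more balanced), then by
    lexicographic parameter order, for reproducibility.
    """
    sl = db[
        np.isclose(db["connectivity"], connectivity) & (db["n_patterns"] == n_patterns)
    ].copy()
    if len(sl) < top_k:
        raise ValueError(
            f"slice has {len(sl)} records, fewer than top_k={top_k}"
        )
    sl["_balance"] = (sl["sep_err"] - sl["comp_err"]).abs()
    sl = sl.sort_values(
        ["max_err", "_balance", "connectivity", "g_max_ampa", "gamma_ltd", "relative_inhibition"],
        kind="mergesort",
    ).head(top_k)
    return sl.drop(columns="_balance").reset_index(drop=True)


def optimal_configs(
    selected: pd.DataFrame,
    n_exc: int = 100,
    pattern_size: int = 10,
    e_to_i_scale: float = 0.9,
) -> list[NetworkConfig]:
    """Turn selected database rows into NetworkConfig objects."""
    return [
        NetworkConfig(
            connectivity_level=float(r["connectivity"]),
            g_max_ampa=float(r["g_max_ampa"]),
            gamma_ltd=float(r["gamma_ltd"]),
            relative_inhibition=float(r["relative_inhibition"]),
            n_exc=n_exc,
            pattern_size=pattern_size,
            e_to_i_scale=e_to_i_scale,
        )
        for _, r in selected.iterrows()
    ]
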