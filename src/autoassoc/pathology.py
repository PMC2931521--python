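"""Simulated synaptic pathologies, bias classification, and in-silico therapy.

Optimal ("wild-type") parameter combinations are perturbed multiplicatively
in LTP (g_max_ampa), LTD (gamma_ltd) and relative inhibition, and
additively in connectivity, then re-assayed.  Error imbalances are
classified against tolerable limits derived from the optimal ensemble, and
each imbalance maps to signed therapeutic directions per synaptic property.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .assays import evaluate_config
from .biophysics import ThresholdTable
from .network import NetworkConfig

__all__ = [
    "PathologySpec",
    "BiasClassification",
    "apply_pathology",
    "single_pathology_curves",
    "interaction_surface",
    "tolerable_limits",
    "classify_bias",
    "prescribe",
    "generate_cohort",
    "treat_cohort",
    "DEFAULT_FACTOR_GRID",
    "DEFAULT_CONNECTIVITY_DELTAS",
]

PROPERTIES = ("ltp", "ltd", "inhibition", "connectivity")

# symmetric log grid around 1 for multiplicative perturbations
DEFAULT_FACTOR_GRID = (0.25, 0.5, 2 ** -0.5, 1.0, 2 ** 0.5, 2.0, 4.0)
# percentage-point shifts for connectivity
DEFAULT_CONNECTIVITY_DELTAS = (-0.3, -0.2, -0.1, 0.0, 0.1, 0.2, 0.3)


@dataclass(frozen=True)
class PathologySpec:
    """Multiplicative factors per synaptic property + connectivity shift.

    ``connectivity_delta`` is an absolute change of the connectivity level
    (e.g. +0.1 = ten percentage points); the result is clipped to at most
    100% and must remain positive.
    """

    ltp_factor: float = 1.0
    ltd_factor: float = 1.0
    inhibition_factor: float = 1.0
    connectivity_delta: float = 0.0

    def __post_init__(self):
        if min(self.ltp_factor, self.ltd_factor, self.inhibition_factor) <= 0:
            raise ValueError("pathology factors must be positive")


def apply_pathology(config: NetworkConfig, spec: PathologySpec) -> NetworkConfig:
    """Perturbed copy of ``config``.

    gGABA is not stored in the config; it is always recomputed from
    g_max_ampa, connectivity and relative inhibition, so it inherits the
    perturbations automatically.
    """
    level = min(config.connectivity_level + spec.connectivity_delta, 1.0)
    if level <= 0:
        raise ValueError("perturbed connectivity is not positive")
    return config.with_(
        g_max_ampa=config.g_max_ampa * spec.ltp_factor,
        gamma_ltd=config.gamma_ltd * spec.ltd_factor,
        relative_inhibition=config.relative_inhibition * spec.inhibition_factor,
        connectivity_level=level,
    )


def _spec_for(prop: str, value: float) -> PathologySpec:
    if prop == "ltp":
        return PathologySpec(ltp_factor=value)
    if prop == "ltd":
        return PathologySpec(ltd_factor=value)
    if prop == "inhibition":
        return PathologySpec(inhibition_factor=value)
    if prop == "connectivity":
        return PathologySpec(connectivity_delta=value)
    raise ValueError(f"unknown property {prop!r}; expected one of {PROPERTIES}")


def _combine(a: PathologySpec, b: PathologySpec) -> PathologySpec:
    return PathologySpec(
        ltp_factor=a.ltp_factor * b.ltp_factor,
        ltd_factor=a.ltd_factor * b.ltd_factor,
        inhibition_factor=a.inhibition_factor * b.inhibition_factor,
        connectivity_delta=a.connectivity_delta + b.connectivity_delta,
    )


def _mean_errors(
    configs, spec: PathologySpec, table: ThresholdTable, n_patterns: int, **eval_kwargs
):
    sep, comp = [], []
    for cfg in configs:
        try:
            perturbed = apply_pathology(cfg, spec)
        except ValueError:
            continue  # connectivity driven non-positive; skip this network
        res = evaluate_config(perturbed, n_patterns, table, **eval_kwargs)
        sep.append(res["separation_error_rate"])
        comp.append(res["completion_error_rate"])
    return float(np.mean(sep)), float(np.mean(comp))


def single_pathology_curves(
    configs: list[NetworkConfig],
    prop: str,
    factor_grid=None,
    table: ThresholdTable | None = None,
    n_patterns: int = 30,
    **eval_kwargs,
) -> pd.DataFrame:
    """Mean completion/separation error vs. perturbation magnitude.

    For multiplicative properties the grid entries are factors (1 = the
    unperturbed optimum); for connectivity they are absolute level shifts
    (0 = unperturbed).
    """
    if not configs:
        raise ValueError("need at least one optimal network")
    if table is None:
        raise ValueError("a threshold table is required")
    if factor_grid is None:
        factor_grid = (
            DEFAULT_CONNECTIVITY_DELTAS if prop == "connectivity" else DEFAULT_FACTOR_GRID
        )
    rows = []
    for value in factor_grid:
        sep, comp = _mean_errors(configs, _spec_for(prop, value), table, n_patterns, **eval_kwargs)
        rows.append((prop, value, comp, sep, max(comp, sep)))
    return pd.DataFrame(
        rows, columns=["property", "factor", "comp_err", "sep_err", "max_err"]
    )


def interaction_surface(
    configs: list[NetworkConfig],
    property_pair: tuple[str, str],
    grid_a=None,
    grid_b=None,
    table: ThresholdTable | None = None,
    n_patterns: int = 30,
    **eval_kwargs,
) -> pd.DataFrame:
    """Mean max-error over the ensemble for joint perturbations of two properties."""
    prop_a, prop_b = property_pair
    if prop_a == prop_b:
        raise ValueError("properties must be distinct")
    if table is None:
        raise ValueError("a threshold table is required")
    if grid_a is None:
        grid_a = DEFAULT_CONNECTIVITY_DELTAS if prop_a == "connectivity" else DEFAULT_FACTOR_GRID
    if grid_b is None:
        grid_b = DEFAULT_CONNECTIVITY_DELTAS if prop_b == "connectivity" else DEFAULT_FACTOR_GRID
    rows = []
    for va in grid_a:
        for vb in grid_b:
            spec = _combine(_spec_for(prop_a, va), _spec_for(prop_b, vb))
            sep, comp = _mean_errors(configs, spec, table, n_patterns, **eval_kwargs)
            rows.append((prop_a, va, prop_b, vb, comp, sep, max(comp, sep)))
    return pd.DataFrame(
        rows,
        columns=["property_a", "factor_a", "property_b", "factor_b", "comp_err", "sep_err", "max_err"],
    )


# ---------------------------------------------------------------------------
# Bias classification and prescriptions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BiasClassification:
    label: str  # "separation_bias" | "completion_bias" | "balanced"
    limits: dict = field(default_factory=dict)


def tolerable_limits(
    optimal_errors: pd.DataFrame | list[dict], mode: str = "mean"
) -> dict:
    """Per-error-type tolerable limits from the optimal ensemble.

    ``mode="mean"`` uses the ensemble means; ``mode="mean+sd"`` adds one
    standard deviation per error type.
    """
    if isinstance(optimal_errors, pd.DataFrame):
        comp = optimal_errors["comp_err"].to_numpy(float)
        sep = optimal_errors["sep_err"].to_numpy(float)
    else:
        comp = np.array([r["completion_error_rate"] for r in optimal_errors])
        sep = np.array([r["separation_error_rate"] for r in optimal_errors])
    if mode == "mean":
        return {"completion": float(comp.mean()), "separation": float(sep.mean())}
    if mode == "mean+sd":
        return {
            "completion": float(comp.mean() + comp.std(ddof=1)),
            "separation": float(sep.mean() + sep.std(ddof=1)),
        }
    raise ValueError("mode must be 'mean' or 'mean+sd'")


def classify_bias(result: dict, limits: dict) -> BiasClassification:
    """Label a network's error profile against tolerable limits.

    A *separation bias* keeps separation errors low while completion
    errors exceed their limit (and vice versa for *completion bias*).
    When both exceed, the larger relative exceedance decides.
    """
    comp = result["completion_error_rate"]
    sep = result["separation_error_rate"]
    comp_exceed = comp > limits["completion"]
    sep_exceed = sep > limits["separation"]
    if not comp_exceed and not sep_exceed:
        label = "balanced"
    elif comp_exceed and not sep_exceed:
        label = "separation_bias"
    elif sep_exceed and not comp_exceed:
        label = "completion_bias"
    else:
        rel_comp = (comp - limits["completion"]) / max(limits["completion"], 1e-12)
        rel_sep = (sep - limits["separation"]) / max(limits["separation"], 1e-12)
        label = "separation_bias" if rel_comp >= rel_sep else "completion_bias"
    return BiasClassification(label, dict(limits))


_SEPARATION_BIAS_RX = {
    "ltp": "increase",
    "ltd": "decrease",
    "inhibition": "decrease",
    "connectivity": "increase",
}


def prescribe(bias: BiasClassification) -> dict:
    """Signed therapeutic direction per synaptic property for an imbalance.

    A separation-biased network (intolerable completion error) calls for
    more excitatory drive: stronger LTP, weaker LTD, less inhibition, more
    connectivity.  A completion bias prescribes the opposites.  Balanced
    networks get an empty prescription.
    """
    if bias.label == "balanced":
        return {}
    if bias.label == "separation_bias":
        return dict(_SEPARATION_BIAS_RX)
    if bias.label == "completion_bias":
        flip = {"increase": "decrease", "decrease": "increase"}
        return {k: flip[v] for k, v in _SEPARATION_BIAS_RX.items()}
    raise ValueError(f"unknown bias label {bias.label!r}")


# ---------------------------------------------------------------------------
# Heterogeneous cohort and personalized treatment
# ---------------------------------------------------------------------------

DEFAULT_COHORT_RANGES = {
    "ltp": (0.85, 1.0),
    "ltd": (0.5, 1.0),
    "inhibition": (0.5, 1.0),
    "connectivity": (0.85, 1.0),
}
"""Uniform decrease ranges per property for the synthetic cohort.

Calibration choice: all four properties are decreased, but the LTP and
connectivity decreases are kept milder so the population's mean imbalance
is a completion bias (excess separation error) while a minority of
individuals still land on the separation-bias side.
"""


@dataclass(frozen=True)
class Individual:
    base: NetworkConfig
    spec: PathologySpec
    config: NetworkConfig


def generate_cohort(
    configs: list[NetworkConfig],
    ranges: dict | None = None,
    seed: int = 0,
) -> list[Individual]:
    """Independently perturbed copy of each optimal network.

    Each property gets an independent uniform multiplicative decrease drawn
    from its range; connectivity is scaled multiplicatively (then expressed
    as a level shift and clipped to (0, 1]).
    """
    ranges = {**DEFAULT_COHORT_RANGES, **(ranges or {})}
    for k, (lo, hi) in ranges.items():
        if not (0 < lo <= hi <= 1):
            raise ValueError(f"range for {k!r} must lie within (0, 1]")
    rng = np.random.default_rng(seed)
    cohort = []
    for cfg in configs:
        f = {k: float(rng.uniform(*ranges[k])) for k in PROPERTIES}
        delta = cfg.connectivity_level * (f["connectivity"] - 1.0)
        spec = PathologySpec(
            ltp_factor=f["ltp"],
            ltd_factor=f["ltd"],
            inhibition_factor=f["inhibition"],
            connectivity_delta=delta,
        )
        cohort.append(Individual(cfg, spec, apply_pathology(cfg, spec)))
    return cohort


def treat_cohort(
    cohort: list[Individual],
    table: ThresholdTable,
    limits: dict,
    target_property: str = "inhibition",
    factor_grid: np.ndarray | None = None,
    n_patterns: int = 30,
    **eval_kwargs,
) -> pd.DataFrame:
    """Personalized single-target therapy for each individual.

    Each individual is classified; non-balanced individuals get the
    prescribed direction of ``target_property`` and a log-grid line search
    (always including factor 1) picks the factor minimizing max-error.
    Returns one row per individual with untreated and treated errors.
    """
    if factor_grid is None:
        factor_grid = np.geomspace(1.0, 8.0, 10)
    factor_grid = np.asarray(factor_grid, dtype=float)
    if not np.any(np.isclose(factor_grid, 1.0)):
        factor_grid = np.concatenate([[1.0], factor_grid])

    rows = []
    for idx, ind in enumerate(cohort):
        untreated = evaluate_config(ind.config, n_patterns, table, **eval_kwargs)
        bias = classify_bias(untreated, limits)
        rx = prescribe(bias)
        if target_property in rx:
            direction = rx[target_property]
            grid = factor_grid if direction == "increase" else 1.0 / factor_grid
            best_factor, best = 1.0, untreated
            for f in grid:
                value = (
                    ind.config.connectivity_level * (f - 1.0)
                    if target_property == "connectivity"
                    else f
                )
                treated_cfg = apply_pathology(ind.config, _spec_for(target_property, value))
                res = evaluate_config(treated_cfg, n_patterns, table, **eval_kwargs)
                if res["max_error"] < best["max_error"]:
                    best_factor, best = float(f), res
        else:
            best_factor, best = 1.0, untreated
        rows.append(
            {
                "individual": idx,
                "bias": bias.label,
                "treatment_factor": best_factor,
                "untreated_sep": untreated["separation_error_rate"],
                "untreated_comp": untreated["completion_error_rate"],
                "untreated_max": untreated["max_error"],
                "treated_sep": best["separation_error_rate"],
                "treated_comp": best["completion_error_rate"],
                "treated_max": best["max_error"],
            }
        )
    return pd.DataFrame(rows)


def uniform_treatment(
    cohort: list[Individual],
    table: ThresholdTable,
    target_property: str = "inhibition",
    factor_grid: np.ndarray | None = None,
    n_patterns: int = 30,
    **eval_kwargs,
) -> pd.DataFrame:
    """Best single common factor of ``target_property`` applied to everyone.

    The factor minimizing the cohort's mean max-error is chosen from a
    two-sided log grid (the same drug and dose for all individuals).
    Returns per-individual rows for the winning factor.
    """
    if factor_grid is None:
        up = np.geomspace(1.0, 8.0, 10)
        factor_grid = np.unique(np.concatenate([1.0 / up, up]))
    evaluations = {}
    for f in factor_grid:
        per_ind = []
        for ind in cohort:
            value = (
                ind.config.connectivity_level * (f - 1.0)
                if target_property == "connectivity"
                else f
            )
            cfg = apply_pathology(ind.config, _spec_for(target_property, value))
            per_ind.append(evaluate_config(cfg, n_patterns, table, **eval_kwargs))
        evaluations[float(f)] = per_ind
    best_f = min(evaluations, key=lambda f: np.mean([r["max_error"] for r in evaluations[f]]))
    rows = [
        {
            "individual": i,
            "treatment_factor": best_f,
            "treated_sep": r["separation_error_rate"],
            "treated_comp": r["completion_error_rate"],
            "treated_max": r["max_error"],
        }
        for i, r in enumerate(evaluations[best_f])
    ]
    return pd.DataFrame(rows)
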