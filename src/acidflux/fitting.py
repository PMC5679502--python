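"""Least-squares parameter fitting and AIC model selection.

Trajectories are compared with observed time-series through a weighted
residual sum of squares (per-variable inverse-range-squared weights by
default, so mixed units are commensurable), minimised with seeded multi-start
Nelder-Mead over bounded parameters, and model variants are ranked by
``AIC = 2k + n ln(RSS/n)``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize

from .engine import SimulationConfig, Trajectory, run
from .kinetics import KineticParameters
from .network import BiomassAdjustment, MetabolicNetwork, apply_biomass_adjustment

__all__ = [
    "Observation",
    "FitResult",
    "ModelVariant",
    "rss",
    "aic",
    "fit",
    "select_model",
    "generate_synthetic_observations",
    "OBSERVABLE_VARIABLES",
]

#: observation variable name -> trajectory variable name
_VARIABLE_MAP = {
    "biomass": "biomass",
    "glucose": "glucose",
    "xylose": "xylose",
    "phosphate": "phosphate",
    "citrate": "citric",
    "oxalate": "oxalic",
    "gluconate": "gluconic",
}
OBSERVABLE_VARIABLES = tuple(_VARIABLE_MAP)

_ADJUSTMENT_PARAMS = ("nucleic_acid_scale", "phospholipid_scale")
_KINETIC_PARAMS = tuple(
    f.name for f in KineticParameters.__dataclass_fields__.values()
)


@dataclass(frozen=True)
class Observation:
    """One measured data-point on the inoculation clock."""

    time_h: float
    variable: str
    value: float  # g/L
    sd: float | None = None

    def __post_init__(self) -> None:
        if self.time_h < 0:
            raise ValueError("observation time must be non-negative")
        if self.value < 0:
            raise ValueError("observation value must be non-negative")
        if self.variable not in _VARIABLE_MAP:
            raise ValueError(
                f"unknown variable {self.variable!r}; "
                f"expected one of {sorted(_VARIABLE_MAP)}"
            )


@dataclass
class FitResult:
    parameters: dict[str, float]
    k: int
    n: int
    rss: float
    aic: float
    variant: str = ""
    n_evaluations: int = 0
    budget_exhausted: bool = False


@dataclass(frozen=True)
class ModelVariant:
    """A candidate model: free parameters (with bounds) plus fixed overrides."""

    name: str
    free_params: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    overrides: Mapping[str, float] = field(default_factory=dict)


def default_weights(observations: Sequence[Observation]) -> dict[str, float]:
    """Inverse squared observed range per variable (1 for degenerate ranges)."""
    by_var: dict[str, list[float]] = {}
    for obs in observations:
        by_var.setdefault(obs.variable, []).append(obs.value)
    weights = {}
    for var, values in by_var.items():
        spread = max(values) - min(values)
        weights[var] = 1.0 / spread**2 if spread > 0 else 1.0
    return weights


def rss(
    traj: Trajectory,
    observations: Sequence[Observation],
    weights: Mapping[str, float] | None = None,
) -> float:
    """Weighted residual sum of squares of observations against a trajectory.

    Simulated values are linearly interpolated between trajectory points;
    every observation time must fall inside the simulated range.
    """
    if weights is None:
        weights = default_weights(observations)
    times = traj.times
    cache: dict[str, np.ndarray] = {}
    total = 0.0
    for obs in observations:
        if not times[0] - 1e-9 <= obs.time_h <= times[-1] + 1e-9:
            raise ValueError(
                f"observation at t={obs.time_h} h outside simulated range "
                f"[{times[0]}, {times[-1]}]"
            )
        if obs.variable not in cache:
            cache[obs.variable] = traj.variable(_VARIABLE_MAP[obs.variable])
        sim = float(np.interp(obs.time_h, times, cache[obs.variable]))
        total += weights.get(obs.variable, 1.0) * (sim - obs.value) ** 2
    return total


def aic(k: int, n: int, rss_value: float) -> float:
    """Akaike information criterion, ``2k + n ln(RSS/n)`` (no small-sample
    correction)."""
    if n <= 0:
        raise ValueError("n must be positive")
    if rss_value <= 0:
        raise ValueError("rss must be positive")
    return 2.0 * k + n * math.log(rss_value / n)


def _safe_aic(k: int, n: int, rss_value: float) -> float:
    """AIC with the perfect-fit limit mapped to -inf (RSS can be exactly
    zero on noiseless synthetic data)."""
    return aic(k, n, rss_value) if rss_value > 0 else float("-inf")


def _split_free(names: Iterable[str]) -> tuple[list[str], list[str]]:
    kinetic, adjustment = [], []
    for name in names:
        if name in _ADJUSTMENT_PARAMS:
            adjustment.append(name)
        elif name in _KINETIC_PARAMS:
            kinetic.append(name)
        else:
            raise ValueError(f"unknown fittable parameter {name!r}")
    return kinetic, adjustment


def _normalize_experiments(
    observations, config
) -> list[tuple[SimulationConfig, list[Observation]]]:
    """Accept one experiment (obs, config) or parallel sequences of both."""
    if isinstance(config, SimulationConfig):
        return [(config, list(observations))]
    configs = list(config)
    if len(configs) != len(observations):
        raise ValueError("need one observation set per configuration")
    return [(cfg, list(obs)) for cfg, obs in zip(configs, observations)]


def _evaluate(
    net: MetabolicNetwork,
    params: KineticParameters,
    values: Mapping[str, float],
    experiments: Sequence[tuple[SimulationConfig, Sequence[Observation]]],
    weights: Mapping[str, float],
) -> float:
    kin = {k: v for k, v in values.items() if k in _KINETIC_PARAMS}
    adj = {k: v for k, v in values.items() if k in _ADJUSTMENT_PARAMS}
    if kin:
        params = params.with_overrides(**kin)
    if adj:
        net = apply_biomass_adjustment(net, BiomassAdjustment(**adj))
    return sum(
        rss(run(net, params, cfg), obs, weights) for cfg, obs in experiments
    )


def fit(
    net: MetabolicNetwork,
    base_params: KineticParameters,
    free_params: Mapping[str, tuple[float, float]],
    observations: Sequence[Observation],
    config: SimulationConfig,
    seed: int = 0,
    n_starts: int = 3,
    max_evaluations: int | None = None,
    weights: Mapping[str, float] | None = None,
    variant_name: str = "",
) -> FitResult:
    """Fit the named parameters to observations by bounded Nelder-Mead.

    Deterministic for a fixed ``seed`` (which drives the multi-start
    points).  If the evaluation budget runs out, the best point so far is
    returned with ``budget_exhausted`` set and a warning, never silently.
    """
    experiments = _normalize_experiments(observations, config)
    all_obs = [obs for _, obs_list in experiments for obs in obs_list]
    if not all_obs:
        raise ValueError("no observations supplied")
    names = list(free_params)
    _split_free(names)  # validates
    if weights is None:
        weights = default_weights(all_obs)
    n = len(all_obs)

    if not names:
        value = _evaluate(net, base_params, {}, experiments, weights)
        return FitResult(
            parameters={},
            k=0,
            n=n,
            rss=value,
            aic=_safe_aic(0, n, value),
            variant=variant_name,
            n_evaluations=1,
        )

    lo = np.array([free_params[name][0] for name in names], dtype=float)
    hi = np.array([free_params[name][1] for name in names], dtype=float)
    if np.any(lo >= hi):
        raise ValueError("each free parameter needs lower < upper bound")
    budget = max_evaluations or 80 * len(names)
    evaluations = 0

    def objective(x: np.ndarray) -> float:
        nonlocal evaluations
        evaluations += 1
        values = dict(zip(names, np.clip(x, lo, hi)))
        try:
            return _evaluate(net, base_params, values, experiments, weights)
        except ValueError:
            return 1e12  # inadmissible region (e.g. glycerol fraction < 0)

    rng = np.random.default_rng(seed)
    # coarse pre-search: objective plateaus (a cap that stops binding, a
    # threshold that never triggers) would strand Nelder-Mead at a flat
    # start point, so local searches launch from the best coarse points
    candidates = [0.5 * (lo + hi), lo + 0.1 * (hi - lo), lo + 0.9 * (hi - lo)]
    for _ in range(max(4, 2 * n_starts)):
        candidates.append(lo + (hi - lo) * rng.uniform(0.05, 0.95, size=len(names)))
    scored = sorted(candidates, key=objective)
    starts = scored[: max(1, n_starts)]

    best_x, best_f = None, np.inf
    per_start = max(budget // max(1, len(starts)), 10 * len(names))
    exhausted = False
    for x0 in starts:
        res = minimize(
            objective,
            x0,
            method="Nelder-Mead",
            bounds=list(zip(lo, hi)),
            options={
                "maxfev": per_start,
                "xatol": 1e-6 * float(np.max(hi - lo)),
                "fatol": 1e-12,
            },
        )
        if not res.success:
            exhausted = True
        if res.fun < best_f:
            best_f, best_x = float(res.fun), np.clip(res.x, lo, hi)
    if exhausted:
        warnings.warn(
            "fit evaluation budget exhausted before convergence; "
            "returning best point found",
            RuntimeWarning,
            stacklevel=2,
        )
    return FitResult(
        parameters=dict(zip(names, map(float, best_x))),
        k=len(names),
        n=n,
        rss=best_f,
        aic=_safe_aic(len(names), n, best_f),
        variant=variant_name,
        n_evaluations=evaluations,
        budget_exhausted=exhausted,
    )


def select_model(
    candidates: Sequence[ModelVariant],
    net: MetabolicNetwork,
    base_params: KineticParameters,
    observations: Sequence[Observation],
    config: SimulationConfig,
    seed: int = 0,
    **fit_kwargs,
) -> list[FitResult]:
    """Fit every candidate variant and rank them by ascending AIC.

    Ties preserve input order (stable sort).
    """
    if len(candidates) < 2:
        raise ValueError("model selection needs at least two candidates")
    results = []
    for variant in candidates:
        params = (
            base_params.with_overrides(**variant.overrides)
            if variant.overrides
            else base_params
        )
        results.append(
            fit(
                net,
                params,
                variant.free_params,
                observations,
                config,
                seed=seed,
                variant_name=variant.name,
                **fit_kwargs,
            )
        )
    return sorted(results, key=lambda r: r.aic)


def relative_noise_sd(
    net: MetabolicNetwork,
    params: KineticParameters,
    config: SimulationConfig,
    variables: Sequence[str],
    fraction: float,
    sample_every_h: float = 24.0,
) -> dict[str, float]:
    """Absolute noise SDs equal to ``fraction`` of each variable's sampled
    range on a clean run (so "2% noise" is comparable across variables)."""
    clean = generate_synthetic_observations(
        net, params, config, {v: 0.0 for v in variables},
        seed=0, sample_every_h=sample_every_h,
    )
    spans: dict[str, tuple[float, float]] = {}
    for obs in clean:
        lo, hi = spans.get(obs.variable, (obs.value, obs.value))
        spans[obs.variable] = (min(lo, obs.value), max(hi, obs.value))
    return {v: fraction * (spans[v][1] - spans[v][0]) for v in variables}


def generate_synthetic_observations(
    net: MetabolicNetwork,
    params: KineticParameters,
    config: SimulationConfig,
    noise_sd: Mapping[str, float],
    seed: int,
    sample_every_h: float = 24.0,
    variables: Sequence[str] | None = None,
) -> list[Observation]:
    """Sample a simulated run at regular inoculation-clock times with seeded
    additive Gaussian noise (floored at zero).

    ``noise_sd`` maps variable names to absolute standard deviations in g/L;
    variables defaults to the keys of ``noise_sd``.
    """
    for name, sd in noise_sd.items():
        if sd < 0:
            raise ValueError(f"negative noise SD for {name}")
    variables = list(noise_sd) if variables is None else list(variables)
    traj = run(net, params, config)
    times = traj.times
    rng = np.random.default_rng(seed)
    sample_times = np.arange(
        math.ceil(times[0] / sample_every_h) * sample_every_h,
        times[-1] + 1e-9,
        sample_every_h,
    )
    observations = []
    for var in variables:
        series = traj.variable(_VARIABLE_MAP[var])
        sd = noise_sd.get(var, 0.0)
        for t in sample_times:
            clean = float(np.interp(t, times, series))
            noisy = clean + (rng.normal(0.0, sd) if sd > 0 else 0.0)
            observations.append(
                Observation(time_h=float(t), variable=var, value=max(0.0, noisy))
            )
    return observations
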