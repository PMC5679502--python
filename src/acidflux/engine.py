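"""Batch-fermentation simulation loop.

Every step: rebuild the kinetic flux constraints from the current external
pools, rewrite the per-acid proton release coefficients at the ambient pH,
force the extracellular glucose-oxidase flux, run the two-stage optimisation,
then explicit-Euler-update every tracked pool from the returned fluxes
(``C[n+1] = C[n] + dt * f[n] * B[n]``, pools per litre of culture so the
biomass concentration in gDW/L closes the units).

The reported time axis is offset by the spore-germination lag (default 18 h)
so trajectories line up with the inoculation clock used for sampling.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import kinetics
from .acids import H_E_FLOOR, acid_table, protons_released
from .fba import DEFAULT_BACKEND, GlpkProblem, SecondaryObjective, double_optimize
from .kinetics import KineticParameters, to_gL, to_mM
from .network import MetabolicNetwork, Tag, apply_knockout

logger = logging.getLogger(__name__)

__all__ = [
    "EnvironmentState",
    "SimulationConfig",
    "Trajectory",
    "step",
    "run",
    "diauxic_switch_time",
]

#: Growth/objective level treated as "nothing is happening" for early stop.
STALL_TOL = 1e-9


@dataclass
class EnvironmentState:
    """Tracked pools at one time-point (concentrations per litre of culture)."""

    t: float  # h since simulation start (germination clock)
    biomass: float  # gDW/L
    glucose: float  # mM
    xylose: float  # mM
    phosphate_ext: float  # mM
    phosphate_stored: float  # mM (per litre of culture)
    acids: dict[str, float]  # mM per acid
    h_e: float  # M
    co2: float = 0.0  # mM, cumulative

    def __post_init__(self) -> None:
        pools = {
            "biomass": self.biomass,
            "glucose": self.glucose,
            "xylose": self.xylose,
            "phosphate_ext": self.phosphate_ext,
            "phosphate_stored": self.phosphate_stored,
            **self.acids,
        }
        for name, value in pools.items():
            if value < 0:
                raise ValueError(f"negative pool {name}: {value}")
        if self.h_e <= 0:
            raise ValueError("proton concentration must be positive")

    @property
    def ph(self) -> float:
        return -math.log10(self.h_e)


@dataclass
class SimulationConfig:
    duration: float = 192.0  # h of simulated fermentation after start
    dt: float = 1.0 / 60.0  # h
    start_offset: float = 18.0  # germination lag; added to reported times
    initial_biomass: float = 0.3125  # gDW/L
    initial_ph: float = 2.0
    glucose_gL: float = 160.0
    xylose_gL: float = 0.0
    phosphate_gL: float = 0.17
    stored_phosphate_mM: float = 0.0
    initial_acids_gL: dict[str, float] = field(default_factory=dict)
    knockouts: frozenset[str] = frozenset()
    solver_backend: str | None = None
    growth_slack: float = 1e-6
    secondary_epsilon: float = 1e-7
    stall_hours: float = 24.0  # early stop after this long with zero activity
    seed: int | None = None  # used by fitting/synthetic-data callers only

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.duration < 0:
            raise ValueError("duration must be non-negative")
        steps = self.duration / self.dt
        if abs(steps - round(steps)) > 1e-9 * max(1.0, steps):
            raise ValueError("duration must be a whole number of time-steps")
        if not 0.0 < self.initial_ph < 14.0:
            raise ValueError("initial pH must lie in (0, 14)")
        if self.initial_biomass <= 0:
            raise ValueError("initial biomass must be positive")
        unknown = set(self.knockouts) - {"oah", "gox"}
        if unknown:
            raise ValueError(f"unknown knockouts {sorted(unknown)}")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))

    def initial_state(self) -> EnvironmentState:
        acids = {name: 0.0 for name in acid_table()}
        for name, g_per_l in self.initial_acids_gL.items():
            if name not in acids:
                raise ValueError(f"unknown acid {name}")
            acids[name] = to_mM(g_per_l, name)
        return EnvironmentState(
            t=0.0,
            biomass=self.initial_biomass,
            glucose=to_mM(self.glucose_gL, "glucose"),
            xylose=to_mM(self.xylose_gL, "xylose"),
            phosphate_ext=to_mM(self.phosphate_gL, "phosphate"),
            phosphate_stored=self.stored_phosphate_mM,
            acids=acids,
            h_e=10.0 ** (-self.initial_ph),
        )


@dataclass
class StepDiagnostics:
    secondary: str
    growth_rate: float
    secondary_value: float
    pie_constraint: float
    pie_flux_step1: float
    citrate_cap: float
    oxalate_cap: float
    gox_flux: float


class Trajectory:
    """Ordered states plus per-step diagnostics and full flux vectors."""

    def __init__(
        self,
        config: SimulationConfig,
        reaction_ids: list[str],
        acid_names: list[str],
    ):
        self.config = config
        self.reaction_ids = reaction_ids
        self.acid_names = acid_names
        self.states: list[EnvironmentState] = []
        self.diagnostics: list[StepDiagnostics] = []
        self._fluxes: list[np.ndarray] = []
        self.stop_reason: str | None = None

    def append_state(self, state: EnvironmentState) -> None:
        self.states.append(state)

    def append_step(self, diag: StepDiagnostics, fluxes: np.ndarray) -> None:
        self.diagnostics.append(diag)
        self._fluxes.append(fluxes)

    def __len__(self) -> int:
        return len(self.states)

    @property
    def times(self) -> np.ndarray:
        """Reported times on the inoculation clock."""
        return np.array([s.t for s in self.states]) + self.config.start_offset

    @property
    def flux_matrix(self) -> np.ndarray:
        """(n_steps x n_reactions) fluxes applied at each step start."""
        if not self._fluxes:
            return np.zeros((0, len(self.reaction_ids)))
        return np.vstack(self._fluxes)

    def flux_series(self, reaction_id: str) -> np.ndarray:
        j = self.reaction_ids.index(reaction_id)
        return self.flux_matrix[:, j]

    def variable(self, name: str) -> np.ndarray:
        """Time series of a tracked variable, in g/L for mass variables."""
        if name == "biomass":
            return np.array([s.biomass for s in self.states])
        if name == "glucose":
            return np.array([to_gL(s.glucose, "glucose") for s in self.states])
        if name == "xylose":
            return np.array([to_gL(s.xylose, "xylose") for s in self.states])
        if name == "phosphate":
            return np.array(
                [to_gL(s.phosphate_ext, "phosphate") for s in self.states]
            )
        if name == "stored_phosphate_mM":
            return np.array([s.phosphate_stored for s in self.states])
        if name == "ph":
            return np.array([s.ph for s in self.states])
        if name in self.acid_names:
            return np.array([to_gL(s.acids[name], name) for s in self.states])
        raise KeyError(f"unknown trajectory variable {name!r}")

    def to_dataframe(self) -> pd.DataFrame:
        rows = {
            "time_h": self.times,
            "biomass_gL": self.variable("biomass"),
            "glucose_gL": self.variable("glucose"),
            "xylose_gL": self.variable("xylose"),
            "phosphate_gL": self.variable("phosphate"),
            "stored_P_mM": self.variable("stored_phosphate_mM"),
        }
        for name in self.acid_names:
            rows[f"{_ACID_COLUMN[name]}_gL"] = self.variable(name)
        rows["pH"] = self.variable("ph")
        pad = lambda vals, fill: np.concatenate([[fill], vals]) if len(vals) else [fill]
        rows["objective"] = pad(
            np.array([d.secondary for d in self.diagnostics], dtype=object), ""
        )
        rows["growth_rate"] = pad(
            np.array([d.growth_rate for d in self.diagnostics]), 0.0
        )
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        switch = diauxic_switch_time(self)
        final = self.states[-1]
        return {
            "n_steps": len(self.diagnostics),
            "diauxic_switch_time_h": switch,
            "stop_reason": self.stop_reason,
            "final": {
                "time_h": float(self.times[-1]),
                "biomass_gL": final.biomass,
                "glucose_gL": to_gL(final.glucose, "glucose"),
                "xylose_gL": to_gL(final.xylose, "xylose"),
                "phosphate_gL": to_gL(final.phosphate_ext, "phosphate"),
                "stored_P_mM": final.phosphate_stored,
                "pH": final.ph,
                **{
                    f"{_ACID_COLUMN[name]}_gL": to_gL(final.acids[name], name)
                    for name in self.acid_names
                },
            },
        }


_ACID_COLUMN = {
    "citric": "citrate",
    "oxalic": "oxalate",
    "gluconic": "gluconate",
    "acetic": "acetate",
    "malic": "malate",
    "succinic": "succinate",
    "lactic": "lactate",
}


class _Runner:
    """Pre-resolved ids, boundary accounting and a persistent LP."""

    def __init__(
        self,
        net: MetabolicNetwork,
        params: KineticParameters,
        backend: str | None = None,
    ):
        self.net = net
        self.params = params
        backend = backend or DEFAULT_BACKEND
        self.problem = GlpkProblem(net) if backend == "glpk" else None
        self.acids = acid_table()
        self.rxn_ids = [r.id for r in net.reactions]
        self.biomass_id = net.tagged(Tag.BIOMASS).id
        self.glc_id = net.tagged(Tag.GLUCOSE_EX).id
        self.xyl_id = net.tagged(Tag.XYLOSE_EX).id
        self.pie_id = net.tagged(Tag.EXTERNAL_P_IN).id
        self.pi_id = net.tagged(Tag.STORED_P_IN).id
        self.hpe_id = net.tagged(Tag.PROTON_OUT).id
        self.gox_id = net.tagged(Tag.GOX).id
        self.sec_ids = {
            r.acid: r.id for r in net.reactions_by_tag(Tag.ACID_SECRETION)
        }
        self.diss = {r.acid: r for r in net.reactions_by_tag(Tag.ACID_DISSOCIATION)}
        hpe = net.tagged(Tag.PROTON_OUT)
        self.proton_met = next(iter(hpe.stoichiometry))
        # boundary production rows for pool bookkeeping
        S_full = net.stoichiometric_matrix(include_boundary=True)
        met_ids = [m.id for m in net.metabolites]
        self._row = {mid: S_full[i] for i, mid in enumerate(met_ids)}
        self.ext_acid_met = {
            acid: self._external_pool_metabolite(acid) for acid in self.diss
        }

    def _external_pool_metabolite(self, acid: str) -> str:
        rxn = self.diss[acid]
        produced = [
            m
            for m, coeff in rxn.stoichiometry.items()
            if coeff > 0 and m != self.proton_met
        ]
        if len(produced) != 1:
            raise ValueError(f"{rxn.id}: cannot identify external acid pool")
        return produced[0]

    def production(self, met_id: str, v: np.ndarray) -> float:
        return float(self._row[met_id] @ v)


def step(
    state: EnvironmentState,
    net: MetabolicNetwork,
    params: KineticParameters,
    config: SimulationConfig,
    _runner: _Runner | None = None,
) -> tuple[EnvironmentState, StepDiagnostics, np.ndarray]:
    """Advance the environment by one Euler step.

    Returns the new state, the step diagnostics and the applied flux vector.
    Mutates the dissociation proton coefficients of ``net`` in place (the
    caller owns the working copy).
    """
    r = _Runner(net, params) if _runner is None else _runner
    dt, B = config.dt, state.biomass
    ph = state.ph

    cit_cap, oxal_cap = kinetics.secretion_caps(config.initial_ph, ph, params)
    v_pe = kinetics.phosphate_uptake(
        state.phosphate_ext, params, t=state.t, initial_ph=config.initial_ph
    )
    v_p = kinetics.stored_phosphate_release(state.phosphate_stored, params)
    v_g = kinetics.glucose_uptake(state.glucose, state.acids["citric"], params)
    v_x = kinetics.xylose_uptake(state.xylose, params)
    gox = (
        0.0
        if net.gox_forcing_disabled
        else kinetics.gox_rate(state.glucose, ph, params)
    )

    # a pool may not be overdrawn within the step: cap each uptake bound by
    # what the pool can supply (mass-consistent form of negative-pool clamping)
    avail = lambda pool: max(0.0, pool) / (dt * B)
    avail_g = avail(state.glucose)
    gox_f = min(gox, avail_g)
    bounds = {
        r.gox_id: (gox_f, gox_f),
        r.glc_id: (0.0, max(0.0, min(v_g, avail_g - gox_f))),
        r.xyl_id: (0.0, min(v_x, avail(state.xylose))),
        r.pie_id: (0.0, min(v_pe, avail(state.phosphate_ext))),
        r.pi_id: (-1000.0, min(v_p, avail(state.phosphate_stored))),
        r.sec_ids["citric"]: (0.0, cit_cap),
        r.sec_ids["oxalic"]: (0.0, oxal_cap),
    }
    if net.gox_forcing_disabled:
        bounds[r.gox_id] = (0.0, 0.0)
    if net.has_reaction("SEC_BUDGET"):
        # shared citrate/oxalate secretion capacity, sized by the citrate cap
        bounds["SEC_BUDGET"] = (0.0, cit_cap)

    for acid, rxn in r.diss.items():
        rxn.stoichiometry[r.proton_met] = protons_released(r.acids[acid], state.h_e)
    if r.problem is not None:
        r.problem.sync_metabolite_row(r.proton_met)

    sol = double_optimize(
        net,
        bounds,
        pie_constraint=bounds[r.pie_id][1],
        backend=config.solver_backend,
        delta=config.growth_slack,
        epsilon=config.secondary_epsilon,
        problem=r.problem,
    )
    v = np.array([sol.fluxes[rid] for rid in r.rxn_ids])

    scale = dt * B
    clamp = lambda x: max(0.0, x)
    new_acids = {
        acid: clamp(state.acids[acid] + scale * r.production(met, v))
        for acid, met in r.ext_acid_met.items()
    }
    mu = sol.fluxes[r.biomass_id]
    new_state = EnvironmentState(
        t=state.t + dt,
        biomass=B + scale * mu,
        glucose=clamp(state.glucose + scale * r.production("glc_e", v)),
        xylose=clamp(state.xylose + scale * r.production("xyl_e", v)),
        phosphate_ext=clamp(state.phosphate_ext + scale * r.production("pi_e", v)),
        phosphate_stored=clamp(
            state.phosphate_stored + scale * r.production("polyp", v)
        ),
        acids=new_acids,
        h_e=max(state.h_e + scale * sol.fluxes[r.hpe_id] / 1000.0, H_E_FLOOR),
        co2=state.co2 + scale * r.production("co2_e", v),
    )
    diag = StepDiagnostics(
        secondary=sol.meta["secondary"],
        growth_rate=mu,
        secondary_value=sol.objective_value,
        pie_constraint=sol.meta["pie_constraint"],
        pie_flux_step1=sol.meta["pie_flux_step1"],
        citrate_cap=cit_cap,
        oxalate_cap=oxal_cap,
        gox_flux=gox_f,
    )
    return new_state, diag, v


def run(
    net: MetabolicNetwork,
    params: KineticParameters,
    config: SimulationConfig,
) -> Trajectory:
    """Run the full simulation and return the trajectory.

    Knockouts named in the config are applied to a working copy of the
    network.  The run stops early (with a logged reason) once growth and the
    secondary objective have both been at numerical zero for
    ``config.stall_hours`` of simulated time.
    """
    working = apply_knockout(net, config.knockouts)
    runner = _Runner(working, params, backend=config.solver_backend)
    traj = Trajectory(config, runner.rxn_ids, sorted(runner.diss))
    state = config.initial_state()
    traj.append_state(state)
    stall_steps = 0
    stall_limit = int(round(config.stall_hours / config.dt))
    events = _EventLog(config)
    events.observe(state, None)
    for _ in range(config.n_steps):
        state, diag, v = step(state, working, params, config, runner)
        events.observe(state, diag)
        traj.append_state(state)
        traj.append_step(diag, v)
        if (
            abs(diag.growth_rate) < STALL_TOL
            and abs(diag.secondary_value) < STALL_TOL
        ):
            stall_steps += 1
            if stall_steps >= stall_limit:
                traj.stop_reason = (
                    f"stalled: growth and secondary objective at zero for "
                    f"{config.stall_hours} h"
                )
                break
        else:
            stall_steps = 0
    return traj


class _EventLog:
    """Logs every event-rule transition with its simulation time."""

    def __init__(self, config: SimulationConfig):
        self.config = config
        self.flags: dict[str, bool] = {}

    def _flag(self, name: str, value: bool, t: float, message: str) -> None:
        if self.flags.get(name) != value:
            if name in self.flags or value:
                logger.info("t=%.3f h (+%g h offset): %s", t, self.config.start_offset, message)
            self.flags[name] = value

    def observe(self, state: EnvironmentState, diag: StepDiagnostics | None) -> None:
        t = state.t
        self._flag(
            "glc_low_affinity",
            state.glucose >= kinetics.to_mM(kinetics.LOW_AFFINITY_THRESHOLD_GL, "glucose"),
            t,
            "low-affinity glucose transport active",
        )
        self._flag(
            "pie_switched",
            t >= kinetics.PHOSPHATE_SWITCH_H,
            t,
            "external phosphate input rate switched to post-8h value",
        )
        self._flag("oxalate_off", state.ph < 2.0, t, "oxalate secretion shut off (pH < 2)")
        if diag is not None:
            self._flag(
                "proton_mode",
                diag.secondary == SecondaryObjective.PROTON_PRODUCTION,
                t,
                "secondary objective switched to proton production",
            )


def diauxic_switch_time(traj: Trajectory) -> float | None:
    """First reported time at which the secondary objective is proton
    production, on the inoculation clock; ``None`` if it never switches."""
    for i, diag in enumerate(traj.diagnostics):
        if diag.secondary == SecondaryObjective.PROTON_PRODUCTION:
            return float(traj.times[i])
    return None
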