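"""Configuration loading/validation, tabular writers and run manifests.

The canonical on-disk formats are plain text: YAML configuration, CSV
trajectories and observations, JSON summaries and manifests.  Unknown
configuration keys are rejected with their field path so typos cannot
silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .engine import SimulationConfig, Trajectory
from .fba import DEFAULT_BACKEND
from .fitting import Observation
from .kinetics import KineticParameters
from .network import MetabolicNetwork, Reaction, make_toy_network
from .sbml_io import load_sbml

__all__ = [
    "ConfigError",
    "LoadedConfig",
    "load_config",
    "resolve_network",
    "write_trajectory",
    "read_trajectory",
    "write_observations",
    "read_observations",
    "write_network_tsv",
    "RunManifest",
    "write_manifest",
]


class ConfigError(ValueError):
    pass


_SIM_KEYS = {f.name for f in dataclasses.fields(SimulationConfig)}
_PARAM_KEYS = {f.name for f in dataclasses.fields(KineticParameters)}
_TOP_KEYS = {"network", "simulation", "parameters"}


@dataclass
class LoadedConfig:
    network_spec: str
    simulation: SimulationConfig
    parameters: KineticParameters
    raw: dict

    def network(self) -> MetabolicNetwork:
        return resolve_network(self.network_spec)


def resolve_network(spec: str) -> MetabolicNetwork:
    if spec == "toy":
        return make_toy_network()
    return load_sbml(spec)


def _reject_unknown(mapping: Mapping[str, Any], allowed: set[str], path: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) at {path}: {sorted(unknown)}; allowed: {sorted(allowed)}"
        )


def load_config(path: str | Path | None = None, data: Mapping | None = None) -> LoadedConfig:
    """Load and validate a simulation configuration.

    Omitted fields take the documented defaults (dt = 1/60 h, 18 h start
    offset, 0.3125 g/L initial biomass, the calibrated parameter set and the
    bundled toy network).
    """
    if data is None:
        if path is None:
            data = {}
        else:
            with open(path) as handle:
                data = yaml.safe_load(handle) or {}
    if not isinstance(data, Mapping):
        raise ConfigError("configuration root must be a mapping")
    _reject_unknown(data, _TOP_KEYS, "<root>")

    sim_raw = dict(data.get("simulation") or {})
    _reject_unknown(sim_raw, _SIM_KEYS, "simulation")
    if "knockouts" in sim_raw:
        sim_raw["knockouts"] = frozenset(sim_raw["knockouts"])
    try:
        sim = SimulationConfig(**sim_raw)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"simulation: {exc}") from exc

    param_raw = dict(data.get("parameters") or {})
    _reject_unknown(param_raw, _PARAM_KEYS, "parameters")
    try:
        params = KineticParameters(**param_raw)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"parameters: {exc}") from exc

    network_spec = data.get("network", "toy")
    if not isinstance(network_spec, str):
        raise ConfigError("network must be 'toy' or a path to an SBML file")
    return LoadedConfig(network_spec, sim, params, raw=dict(data))


# ---------------------------------------------------------------------------
# tabular writers
# ---------------------------------------------------------------------------


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write the trajectory as deterministic CSV (fixed column order)."""
    df = traj.to_dataframe()
    df.to_csv(path, index=False, float_format="%.12g")


def read_trajectory(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_observations(observations, path: str | Path) -> None:
    rows = [
        {
            "time_h": obs.time_h,
            "variable": obs.variable,
            "value_gL": obs.value,
            "sd": "" if obs.sd is None else obs.sd,
        }
        for obs in observations
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.12g")


def read_observations(path: str | Path) -> list[Observation]:
    df = pd.read_csv(path)
    required = {"time_h", "variable", "value_gL"}
    if not required <= set(df.columns):
        raise ConfigError(f"observation table needs columns {sorted(required)}")
    out = []
    for row in df.itertuples(index=False):
        sd = getattr(row, "sd", None)
        sd = None if sd is None or pd.isna(sd) else float(sd)
        out.append(
            Observation(
                time_h=float(row.time_h),
                variable=str(row.variable),
                value=float(row.value_gL),
                sd=sd,
            )
        )
    return out


def _equation(rxn: Reaction) -> str:
    def side(sign):
        parts = []
        for met, coeff in rxn.stoichiometry.items():
            if (coeff < 0) == (sign < 0) and coeff != 0:
                mag = abs(coeff)
                parts.append(met if mag == 1 else f"{mag:g} {met}")
        return " + ".join(parts)

    arrow = "<=>" if rxn.reversible else "-->"
    return f"{side(-1)} {arrow} {side(+1)}".strip()


def write_network_tsv(net: MetabolicNetwork, reactions_path, metabolites_path) -> None:
    """Export the network as two plain TSV tables (reactions + metabolites)."""
    rxn_rows = [
        {
            "reaction_id": r.id,
            "equation": _equation(r),
            "lower_bound": r.lower_bound,
            "upper_bound": r.upper_bound,
            "tag": r.tag,
            "acid": r.acid or "",
        }
        for r in net.reactions
    ]
    pd.DataFrame(rxn_rows).to_csv(reactions_path, sep="\t", index=False)
    met_rows = [
        {
            "metabolite_id": m.id,
            "name": m.name,
            "compartment": m.compartment,
            "carbon_count": m.carbon_count,
            "phosphorus_count": m.phosphorus_count,
            "boundary": int(m.boundary),
        }
        for m in net.metabolites
    ]
    pd.DataFrame(met_rows).to_csv(metabolites_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------


@dataclass
class RunManifest:
    config: dict
    software_version: str = __version__
    solver: str = DEFAULT_BACKEND
    seed: int | None = None
    outputs: dict[str, str] = field(default_factory=dict)
    timestamp: str = ""
    config_hash: str = ""

    def finalize(self) -> "RunManifest":
        canonical = json.dumps(self.config, sort_keys=True, default=str)
        self.config_hash = hashlib.sha256(canonical.encode()).hexdigest()
        self.timestamp = time.strftime("%Y-%m-%dT%H:%M:%S%z")
        return self


def write_manifest(manifest: RunManifest, path: str | Path) -> None:
    manifest.finalize()
    with open(path, "w") as handle:
        json.dump(dataclasses.asdict(manifest), handle, indent=2, default=str)
        handle.write("\n")
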