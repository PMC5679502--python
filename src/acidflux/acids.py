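"""Polyprotic organic-acid dissociation chemistry and the dynamic proton pool.

Each secreted acid releases a pH-dependent, generally fractional, number of
protons per mole.  The release count is the equilibrium average over the
dissociation states of the acid at the ambient external proton concentration,
computed from up to three successive dissociation constants.  The external
proton concentration is tracked as a dynamic pool so that ambient pH evolves
as acids are secreted.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping

__all__ = [
    "AcidSpecies",
    "ProtonPool",
    "acid_table",
    "protons_released",
    "update_proton_pool",
    "acidification_efficiency",
]

#: Hard floor on the external proton concentration (M).  Water autoprotolysis
#: is otherwise not modelled; the pool only ever gains protons.
H_E_FLOOR = 1e-14

ACID_NAMES = ("citric", "oxalic", "gluconic", "acetic", "malic", "succinic", "lactic")


@dataclass(frozen=True)
class AcidSpecies:
    """One secreted acid: dissociation constants and carbon count.

    ``K = 0`` encodes "no such dissociation site"; a monoprotic acid has
    ``K2 == K3 == 0``.
    """

    name: str
    K1: float
    K2: float = 0.0
    K3: float = 0.0
    carbon_count: int = 0

    def __post_init__(self) -> None:
        if self.K1 <= 0:
            raise ValueError(f"{self.name}: K1 must be positive")
        for hi, lo in ((self.K1, self.K2), (self.K2, self.K3)):
            if lo and lo > hi:
                raise ValueError(
                    f"{self.name}: dissociation constants must not increase "
                    "with site index"
                )
        if self.carbon_count < 0:
            raise ValueError(f"{self.name}: carbon_count must be non-negative")

    @property
    def n_sites(self) -> int:
        return 1 + int(self.K2 > 0) + int(self.K3 > 0)


def _load_table() -> dict[str, AcidSpecies]:
    species: dict[str, AcidSpecies] = {}
    path = resources.files("acidflux.data").joinpath("acid_constants.tsv")
    with path.open() as handle:
        for row in csv.DictReader(handle, delimiter="\t"):
            ks = [
                10.0 ** (-float(row[col])) if row[col].strip() else 0.0
                for col in ("pka1", "pka2", "pka3")
            ]
            species[row["name"]] = AcidSpecies(
                name=row["name"],
                K1=ks[0],
                K2=ks[1],
                K3=ks[2],
                carbon_count=int(row["carbons"]),
            )
    if tuple(species) != ACID_NAMES:
        raise RuntimeError("bundled acid constant table is corrupt")
    return species


_TABLE: dict[str, AcidSpecies] | None = None


def acid_table() -> dict[str, AcidSpecies]:
    """The seven bundled acid species, keyed by name."""
    global _TABLE
    if _TABLE is None:
        _TABLE = _load_table()
    return dict(_TABLE)


def protons_released(acid: AcidSpecies, h_e: float) -> float:
    """Moles of H+ released per mole of *acid* at external [H+] ``h_e`` (M).

    Equilibrium average number of dissociated sites,

        H = (K1/h + 2 K1 K2/h^2 + 3 K1 K2 K3/h^3)
            / (1 + K1/h + K1 K2/h^2 + K1 K2 K3/h^3),

    evaluated in a form multiplied through by h^3 for numerical stability at
    low pH.  Absent sites (K == 0) contribute zero terms.
    """
    if h_e <= 0:
        raise ValueError("external proton concentration must be positive")
    k1, k2, k3 = acid.K1, acid.K2, acid.K3
    a = k1 * h_e * h_e
    b = k1 * k2 * h_e
    c = k1 * k2 * k3
    num = a + 2.0 * b + 3.0 * c
    den = h_e**3 + a + b + c
    return num / den


def acidification_efficiency(acid: AcidSpecies, ph: float) -> float:
    """Protons released per carbon secreted, at ambient pH.

    Diagnostic for ranking acids as acidification vehicles: a diprotic
    two-carbon acid approaches 1 proton per carbon at high pH whereas a
    triprotic six-carbon acid tops out at 0.5.
    """
    if not 0.0 < ph < 14.0:
        raise ValueError("pH must lie in (0, 14)")
    if acid.carbon_count <= 0:
        raise ValueError(f"{acid.name}: carbon count unknown")
    return protons_released(acid, 10.0 ** (-ph)) / acid.carbon_count


@dataclass(frozen=True)
class ProtonPool:
    """External proton concentration (M) with derived pH."""

    h_e: float

    def __post_init__(self) -> None:
        if self.h_e <= 0:
            raise ValueError("proton pool concentration must be positive")

    @property
    def ph(self) -> float:
        return -math.log10(self.h_e)

    @classmethod
    def from_ph(cls, ph: float) -> "ProtonPool":
        return cls(h_e=10.0 ** (-ph))


def update_proton_pool(
    pool: ProtonPool,
    acid_secretion_fluxes: Mapping[str, float],
    biomass: float,
    dt: float,
    species: Mapping[str, AcidSpecies] | None = None,
) -> ProtonPool:
    """Explicit-Euler update of the proton pool from acid secretion fluxes.

    Fluxes are mmol gDW^-1 h^-1, biomass gDW/L, dt hours.  The per-acid
    release count is evaluated at the *step-start* pH and held constant over
    the step.  The mmol -> mol conversion divides by 1000.
    """
    if dt < 0:
        raise ValueError("dt must be non-negative")
    if biomass < 0:
        raise ValueError("biomass must be non-negative")
    table = acid_table() if species is None else species
    delta = 0.0
    for name, flux in acid_secretion_fluxes.items():
        if flux < 0:
            raise ValueError(f"negative secretion flux for {name}")
        delta += flux * protons_released(table[name], pool.h_e)
    h_new = pool.h_e + dt * biomass * delta / 1000.0
    return replace(pool, h_e=max(h_new, H_E_FLOOR))
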