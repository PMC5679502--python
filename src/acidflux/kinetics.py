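"""Time-dependent flux constraints: substrate uptake kinetics and event rules.

All rates are mmol gDW^-1 h^-1; concentrations are mM unless noted.  The
parameter set mirrors the calibrated model: transport-mediated glucose uptake
and glucose-oxidase kinetics come from literature measurements, everything
else was fitted to batch-fermentation data.  Conditional rules:

* the external phosphate maximum input rate drops 8 h after the simulation
  start, to a value keyed to whether the culture started at pH 2 or pH 7;
* the low-affinity glucose/xylose transport systems are only active at or
  above 150 g/L of the sugar, re-evaluated every step;
* the citrate secretion cap is lower for cultures started above pH 2;
* oxalate secretion shuts off entirely below pH 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

__all__ = [
    "KineticParameters",
    "MOLAR_MASS",
    "to_mM",
    "to_gL",
    "phosphate_uptake",
    "stored_phosphate_release",
    "glucose_uptake",
    "xylose_uptake",
    "gox_rate",
    "p_gox",
    "secretion_caps",
]

#: g/mol used for every g/L <-> mM conversion in the package.
MOLAR_MASS = {
    "glucose": 180.16,
    "xylose": 150.13,
    "phosphate": 94.97,  # as orthophosphate PO4
    "citric": 192.12,
    "oxalic": 90.03,
    "gluconic": 196.16,
    "acetic": 60.05,
    "malic": 134.09,
    "succinic": 118.09,
    "lactic": 90.08,
}

#: Low-affinity sugar transport activates at this external concentration.
LOW_AFFINITY_THRESHOLD_GL = 150.0

#: The phosphate input rate changes this many hours after simulation start.
PHOSPHATE_SWITCH_H = 8.0


def to_mM(value_gL: float, compound: str) -> float:
    return value_gL * 1000.0 / MOLAR_MASS[compound]


def to_gL(value_mM: float, compound: str) -> float:
    return value_mM * MOLAR_MASS[compound] / 1000.0


@dataclass(frozen=True)
class KineticParameters:
    """Kinetic constants and secretion caps.

    ``provenance`` tags each field "literature" or "fitted" for reporting.
    Rates are mmol gDW^-1 h^-1, Michaelis/inhibition constants mM, except
    ``v_G1``/``v_X1`` (rate per mM sugar) and ``GOX_conc`` (mg enzyme per
    gDW, multiplied by ``v_GOX_per_mg`` to give the GOX Vmax).
    """

    # phosphate (fitted)
    v_Pe_max: float = 0.08
    K_Pe: float = 0.0333
    v_P_max: float = 0.0008
    K_P: float = 0.0833
    # glucose: passive fitted, transport-mediated from literature
    v_G1: float = 0.00031419
    v_G2_max: float = 0.186
    K_G2: float = 0.26
    K_i2: float = 933.0
    v_G3_max: float = 2.706
    K_G3: float = 3.67
    K_i3: float = 233.21
    # xylose (fitted)
    v_X1: float = 0.00033
    v_X2_max: float = 0.2
    K_X2: float = 3.33
    v_X3_max: float = 2.5
    K_X3: float = 3.33
    # glucose oxidase
    GOX_conc: float = 0.1
    v_GOX_per_mg: float = 27.48
    K_GOX: float = 33.0
    # secretion caps (fitted)
    v_CIT: float = 0.12
    v_OXAL: float = 0.01
    # conditional variants
    pie_after_8h_pH2: float = 0.015
    pie_after_8h_pH7: float = 0.004
    v_CIT_high_pH: float = 0.016

    def __post_init__(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            if value < 0:
                raise ValueError(f"{f.name} must be non-negative")
        for name in ("K_Pe", "K_P", "K_G2", "K_G3", "K_X2", "K_X3", "K_GOX"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def v_GOX_max(self) -> float:
        return self.v_GOX_per_mg * self.GOX_conc

    def with_overrides(self, **overrides: float) -> "KineticParameters":
        return replace(self, **overrides)

    provenance = {
        "v_G2_max": "literature",
        "K_G2": "literature",
        "K_i2": "literature",
        "v_G3_max": "literature",
        "K_G3": "literature",
        "K_i3": "literature",
        "v_GOX_per_mg": "literature",
        "K_GOX": "literature",
    }


def _check_nonneg(**values: float) -> None:
    for name, value in values.items():
        if value < 0:
            raise ValueError(f"{name} must be non-negative, got {value}")


def phosphate_uptake(
    p_e: float,
    params: KineticParameters,
    t: float = 0.0,
    initial_ph: float = 2.0,
) -> float:
    """Michaelis-Menten external phosphate uptake bound.

    From ``t >= 8`` h the maximum rate switches to the post-germination
    value: 0.015 for cultures started at pH <= 2, 0.004 otherwise.
    """
    _check_nonneg(p_e=p_e)
    if t >= PHOSPHATE_SWITCH_H:
        v_max = (
            params.pie_after_8h_pH2 if initial_ph <= 2.0 else params.pie_after_8h_pH7
        )
    else:
        v_max = params.v_Pe_max
    return v_max * p_e / (params.K_Pe + p_e)


def stored_phosphate_release(p: float, params: KineticParameters) -> float:
    """Michaelis-Menten cap on release from the stored phosphate pool."""
    _check_nonneg(p=p)
    return params.v_P_max * p / (params.K_P + p)


def _inhibited_mm(v_max: float, k_m: float, k_i: float, s: float, c: float) -> float:
    # The (1 + C/K_i) factor multiplies both the K and S terms, written
    # exactly as in the source kinetics even though it factors out.
    inh = 1.0 + c / k_i
    return v_max * s / (k_m * inh + s * inh)


def glucose_uptake(g: float, c_citrate: float, params: KineticParameters) -> float:
    """Glucose uptake bound: passive + citrate-inhibited facilitated terms.

    The low-affinity system contributes only at >= 150 g/L glucose,
    re-evaluated from the instantaneous concentration.
    """
    _check_nonneg(g=g, c_citrate=c_citrate)
    v = params.v_G1 * g
    v += _inhibited_mm(params.v_G2_max, params.K_G2, params.K_i2, g, c_citrate)
    if g >= to_mM(LOW_AFFINITY_THRESHOLD_GL, "glucose"):
        v += _inhibited_mm(params.v_G3_max, params.K_G3, params.K_i3, g, c_citrate)
    return v


def xylose_uptake(x: float, params: KineticParameters) -> float:
    """Xylose uptake bound: passive + facilitated, low-affinity >= 150 g/L."""
    _check_nonneg(x=x)
    v = params.v_X1 * x + params.v_X2_max * x / (params.K_X2 + x)
    if x >= to_mM(LOW_AFFINITY_THRESHOLD_GL, "xylose"):
        v += params.v_X3_max * x / (params.K_X3 + x)
    return v


def p_gox(ph: float) -> float:
    """Proportion of active glucose oxidase at ambient pH, clamped to [0, 1].

    The underlying quadratic (-0.102 pH^2 + 1.082 pH - 1.95) is negative
    below pH ~2.2 and must not yield negative rates.
    """
    raw = -0.102 * ph * ph + 1.082 * ph - 1.95
    return min(1.0, max(0.0, raw))


def gox_rate(
    g: float,
    ph: float,
    params: KineticParameters,
    gox_knocked_out: bool = False,
) -> float:
    """Forced extracellular glucose-oxidase flux (glucose -> gluconate)."""
    _check_nonneg(g=g)
    if gox_knocked_out:
        return 0.0
    return p_gox(ph) * params.v_GOX_max * g / (params.K_GOX + g)


def secretion_caps(
    initial_ph: float,
    current_ph: float,
    params: KineticParameters,
) -> tuple[float, float]:
    """(citrate cap, oxalate cap) for the current step.

    The citrate cap is keyed to the *initial* culture pH (strictly above 2
    selects the low cap); oxalate secretion is forced to zero whenever the
    *current* pH is strictly below 2.
    """
    for name, ph in (("initial_ph", initial_ph), ("current_ph", current_ph)):
        if not 0.0 < ph < 14.0:
            raise ValueError(f"{name} must lie in (0, 14)")
    v_cit = params.v_CIT if initial_ph <= 2.0 else params.v_CIT_high_pH
    v_oxal = 0.0 if current_ph < 2.0 else params.v_OXAL
    return v_cit, v_oxal
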