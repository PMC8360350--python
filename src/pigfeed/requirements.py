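"""Daily nutrient requirements: effective energy, digestible protein, digestible P.

Requirements are the sum of a maintenance term, scaled on current body protein
relative to mature protein (coefficient * Np * Npm**-0.27), and a growth term
derived from the Gompertz-form potential retentions of protein and lipid.
Growth requirements are expressed on a digestible basis by dividing the
potential retentions by marginal efficiencies (protein 0.763, phosphorus
0.940); energy for growth costs 50.0 MJ per kg protein and 56.0 MJ per kg
lipid retained, on the effective-energy scale.  Maximum P retention is tied to
protein retention by the fixed body composition ratio 0.0337 kg P per kg
protein.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

from .growth import DEFAULT_CONSTANTS, GrowthTraits, ModelConstants, composition_at

__all__ = [
    "EfficiencyConstants",
    "DailyRequirement",
    "DEFAULT_EFFICIENCIES",
    "maintenance",
    "max_retentions",
    "growth_requirements",
    "daily_requirement",
    "requirement_from_state",
]


@dataclass(frozen=True)
class EfficiencyConstants:
    """Maintenance coefficients and marginal efficiencies of nutrient use.

    Maintenance efficiencies are 1.00 (no inefficiency assumed for
    maintenance).  ``e_EgNp``/``e_EgL`` are MJ effective energy per kg protein
    / lipid retained; ``e_Npg``/``e_Pg`` convert potential retention to
    digestible requirement; ``p_to_protein_ratio`` couples maximum P retention
    to maximum protein retention.
    """

    e_Em: float = 1.00
    e_Npm: float = 1.00
    e_Pm: float = 1.00
    e_EgNp: float = 50.0
    e_EgL: float = 56.0
    e_Npg: float = 0.763
    e_Pg: float = 0.940
    p_to_protein_ratio: float = 0.0337
    maint_E_coef: float = 1.63
    maint_Np_coef: float = 0.004
    maint_P_coef: float = 0.0001293
    maint_exp: float = 0.27

    def __post_init__(self) -> None:
        for name in ("e_Em", "e_Npm", "e_Pm", "e_Npg", "e_Pg"):
            if not 0 < getattr(self, name) <= 1:
                raise ValueError(f"efficiency {name} must lie in (0, 1]")
        for name in (
            "e_EgNp", "e_EgL", "p_to_protein_ratio",
            "maint_E_coef", "maint_Np_coef", "maint_P_coef", "maint_exp",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"coefficient {name} must be > 0")


DEFAULT_EFFICIENCIES = EfficiencyConstants()


class Maintenance(NamedTuple):
    E_maint: float  # MJ/d
    Np_maint: float  # kg/d digestible protein
    P_maint: float  # kg/d digestible P


class Retentions(NamedTuple):
    Np_max: float  # kg/d
    P_max: float  # kg/d
    L_desired: float  # kg/d


class GrowthReq(NamedTuple):
    E_growth: float  # MJ/d
    Np_growth: float  # kg/d digestible protein
    P_growth: float  # kg/d digestible P


@dataclass(frozen=True)
class DailyRequirement:
    """All requirement components for one day, kept separate for reporting."""

    t: float
    E_maint: float
    E_growth: float
    Np_maint: float
    Np_growth: float
    P_maint: float
    P_growth: float
    Np_max: float
    P_max: float
    L_desired: float

    @property
    def E_total(self) -> float:
        return self.E_maint + self.E_growth

    @property
    def Np_total(self) -> float:
        return self.Np_maint + self.Np_growth

    @property
    def P_total(self) -> float:
        return self.P_maint + self.P_growth


def maintenance(
    Np: float, Npm: float, k: EfficiencyConstants = DEFAULT_EFFICIENCIES
) -> Maintenance:
    """Maintenance requirements at body protein ``Np`` given mature protein ``Npm``.

    Each component is coefficient * Np * Npm**-0.27 divided by its (unit)
    maintenance efficiency.
    """
    if not 0 < Np <= Npm:
        raise ValueError("require 0 < Np <= Npm")
    scale = Np * Npm ** (-k.maint_exp)
    return Maintenance(
        E_maint=k.maint_E_coef * scale / k.e_Em,
        Np_maint=k.maint_Np_coef * scale / k.e_Npm,
        P_maint=k.maint_P_coef * scale / k.e_Pm,
    )


def max_retentions(
    traits: GrowthTraits, Np: float, L: float,
    k: EfficiencyConstants = DEFAULT_EFFICIENCIES,
) -> Retentions:
    """Potential daily retentions (kg/d) at body state (Np, L).

    Np_max = (1/B) * Np * ln(Npm/Np); P_max = 0.0337 * Np_max;
    L_desired = (1/B) * L * ln(L_m/L).  All vanish as the state approaches
    maturity.
    """
    if not 0 < Np <= traits.Npm:
        raise ValueError("require 0 < Np <= Npm")
    if not 0 < L <= traits.L_m:
        raise ValueError("require 0 < L <= L_m")
    np_max = (1.0 / traits.B) * Np * math.log(traits.Npm / Np)
    l_des = (1.0 / traits.B) * L * math.log(traits.L_m / L)
    return Retentions(Np_max=np_max, P_max=k.p_to_protein_ratio * np_max, L_desired=l_des)


def growth_requirements(
    retentions: Retentions, k: EfficiencyConstants = DEFAULT_EFFICIENCIES
) -> GrowthReq:
    """Digestible growth requirements from potential retentions."""
    if min(retentions) < 0:
        raise ValueError("retentions must be >= 0")
    return GrowthReq(
        E_growth=k.e_EgNp * retentions.Np_max + k.e_EgL * retentions.L_desired,
        Np_growth=retentions.Np_max / k.e_Npg,
        P_growth=retentions.P_max / k.e_Pg,
    )


def _assemble(t, maint, rets, grow) -> DailyRequirement:
    return DailyRequirement(
        t=t,
        E_maint=maint.E_maint, E_growth=grow.E_growth,
        Np_maint=maint.Np_maint, Np_growth=grow.Np_growth,
        P_maint=maint.P_maint, P_growth=grow.P_growth,
        Np_max=rets.Np_max, P_max=rets.P_max, L_desired=rets.L_desired,
    )


def daily_requirement(
    traits: GrowthTraits, t: float,
    k: EfficiencyConstants = DEFAULT_EFFICIENCIES,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> DailyRequirement:
    """Requirements at age ``t`` on the pig's potential growth trajectory."""
    state = composition_at(traits, t, constants)
    maint = maintenance(state.Np, traits.Npm, k)
    rets = max_retentions(traits, state.Np, state.L, k)
    grow = growth_requirements(rets, k)
    return _assemble(float(t), maint, rets, grow)


def requirement_from_state(
    traits: GrowthTraits, Np: float, L: float, t: float = math.nan,
    k: EfficiencyConstants = DEFAULT_EFFICIENCIES,
) -> DailyRequirement:
    """Requirements at an arbitrary body state (Np, L), which may deviate from
    the potential trajectory — used by the feeding simulation, where actual
    growth can fall behind or exceed the Gompertz clock."""
    maint = maintenance(Np, traits.Npm, k)
    rets = max_retentions(traits, Np, L, k)
    grow = growth_requirements(rets, k)
    return _assemble(t, maint, rets, grow)
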