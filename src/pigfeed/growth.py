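"""Deterministic growth and body-composition model for growing-finishing pigs.

Bodyweight follows a Gompertz trajectory parameterised by the mature weight
``BW_m`` (kg) and the inverse growth-rate ``B`` (d); whole-body protein and
lipid scale allometrically with bodyweight, anchored so the power laws pass
exactly through the initial and mature component weights; water and ash are
tied to protein by classical allometric rules.  Empty bodyweight is a fixed
fraction ``alpha`` of bodyweight, and the discrepancy between ``alpha*BW`` and
the sum of the four chemical components (the *closure residual*) is reported
rather than forced to zero — downstream Bayesian inference uses it as a soft
constraint that identifies the composition traits from bodyweight data alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "ModelConstants",
    "GrowthTraits",
    "CompositionState",
    "DEFAULT_CONSTANTS",
    "AVERAGE_PIG",
    "bw_at",
    "inverse_bw",
    "protein_at",
    "lipid_at",
    "water_of_protein",
    "ash_of_protein",
    "composition_at",
]


@dataclass(frozen=True)
class ModelConstants:
    """Global constants of the composition model.

    alpha
        Empty-bodyweight fraction of bodyweight (gut fill removed).
    n_to_protein
        Protein = 6.25 x nitrogen.
    water_coef, water_exp
        Water allometry on protein: W = 3.04 * Np**0.855 (kg).
    ash_coef
        Ash proportional to protein: Ash = 0.190 * Np (kg).
    composition_form
        "absolute" (default) evaluates the water/ash rules on the protein
        weight itself; "ratio" evaluates them on Np/Npm as literally printed
        in some sources, which bounds water by 3.04 kg and ash by 0.19 kg and
        is retained only for auditability.
    """

    alpha: float = 0.95
    n_to_protein: float = 6.25
    water_coef: float = 3.04
    water_exp: float = 0.855
    ash_coef: float = 0.190
    composition_form: str = "absolute"

    def __post_init__(self) -> None:
        for name in ("alpha", "n_to_protein", "water_coef", "water_exp", "ash_coef"):
            if getattr(self, name) <= 0:
                raise ValueError(f"ModelConstants.{name} must be > 0")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")
        if self.composition_form not in ("absolute", "ratio"):
            raise ValueError("composition_form must be 'absolute' or 'ratio'")


DEFAULT_CONSTANTS = ModelConstants()


@dataclass(frozen=True)
class GrowthTraits:
    """The six unknown per-pig traits plus fixed initial conditions.

    BW_m : mature bodyweight (kg); B : inverse growth rate (d);
    Npm / Npin : mature / initial protein weight (kg);
    L_m / L_in : mature / initial lipid weight (kg);
    BW_in, t0 : observed initial bodyweight (kg) and age (d), fixed from data.
    """

    BW_m: float
    B: float
    Npm: float
    L_m: float
    Npin: float
    L_in: float
    BW_in: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self, alpha: float = 0.95) -> None:
        if not (self.BW_m > self.BW_in > 0):
            raise ValueError("require BW_m > BW_in > 0")
        if self.B <= 0:
            raise ValueError("require B > 0")
        if not (self.Npm > self.Npin > 0):
            raise ValueError("require Npm > Npin > 0")
        if not (self.L_m > self.L_in > 0):
            raise ValueError("require L_m > L_in > 0")
        if self.Npm + self.L_m >= alpha * self.BW_m:
            raise ValueError(
                "protein plus lipid at maturity must not exceed mature empty bodyweight"
            )

    def with_initial(self, BW_in: float, t0: float) -> "GrowthTraits":
        return replace(self, BW_in=BW_in, t0=t0)


#: Traits of the average pig of the reference population (posterior medians of
#: the individual minimising the summed relative trait deviation); initial
#: conditions set to the 35 kg start of the growing-finishing period.
AVERAGE_PIG = GrowthTraits(
    BW_m=205.0, B=65.0, Npm=31.0, L_m=71.6, Npin=7.33, L_in=3.34, BW_in=35.0, t0=0.0
)


@dataclass(frozen=True)
class CompositionState:
    """Bodyweight and chemical composition at one age.

    ``residual`` is the closure gap eBW - (Np + L + W + Ash) in kg; it is
    reported, not forced to zero.
    """

    t: float
    BW: float
    eBW: float
    Np: float
    L: float
    W: float
    Ash: float
    residual: float


def _check_t(traits: GrowthTraits, t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < traits.t0):
        raise ValueError(f"age t must be >= t0 = {traits.t0}")
    return t


def bw_at(traits: GrowthTraits, t):
    """Gompertz bodyweight (kg) at age ``t`` (d; scalar or array).

    BW(t) = BW_m * exp(-ln(BW_m/BW_in) * exp(-(t - t0)/B)).
    """
    t = _check_t(traits, t)
    decay = np.exp(-(t - traits.t0) / traits.B)
    out = traits.BW_m * np.exp(-math.log(traits.BW_m / traits.BW_in) * decay)
    return out if out.ndim else float(out)


def inverse_bw(traits: GrowthTraits, BW_target: float) -> float:
    """Age (d) at which the Gompertz trajectory reaches ``BW_target`` kg.

    Closed-form inverse; requires BW_in <= BW_target < BW_m.
    """
    if not traits.BW_in <= BW_target < traits.BW_m:
        raise ValueError(
            f"BW_target must lie in [BW_in, BW_m) = [{traits.BW_in}, {traits.BW_m})"
        )
    if BW_target == traits.BW_in:
        return traits.t0
    num = math.log(traits.BW_m / traits.BW_in)
    den = math.log(traits.BW_m / BW_target)
    return traits.t0 + traits.B * math.log(num / den)


def _allometric_exponent(y_m: float, y_in: float, traits: GrowthTraits) -> float:
    return math.log(y_m / y_in) / math.log(traits.BW_m / traits.BW_in)


def protein_at(traits: GrowthTraits, BW):
    """Whole-body protein weight (kg) at bodyweight ``BW`` via anchored allometry.

    Np = Npm * (BW/BW_m)**b with b = log(Npm/Npin)/log(BW_m/BW_in); the power
    law passes exactly through (BW_in, Npin) and (BW_m, Npm).
    """
    BW = np.asarray(BW, dtype=float)
    if np.any(BW <= 0) or np.any(BW > traits.BW_m):
        raise ValueError("require 0 < BW <= BW_m")
    b = _allometric_exponent(traits.Npm, traits.Npin, traits)
    out = traits.Npm * (BW / traits.BW_m) ** b
    return out if out.ndim else float(out)


def lipid_at(traits: GrowthTraits, BW):
    """Whole-body lipid weight (kg) at bodyweight ``BW`` (anchored allometry)."""
    BW = np.asarray(BW, dtype=float)
    if np.any(BW <= 0) or np.any(BW > traits.BW_m):
        raise ValueError("require 0 < BW <= BW_m")
    b = _allometric_exponent(traits.L_m, traits.L_in, traits)
    out = traits.L_m * (BW / traits.BW_m) ** b
    return out if out.ndim else float(out)


def water_of_protein(Np, constants: ModelConstants = DEFAULT_CONSTANTS, Npm: float | None = None):
    """Body water (kg) from protein weight ``Np`` (kg).

    Default absolute form W = 3.04 * Np**0.855; with
    ``constants.composition_form == "ratio"`` the literal ratio form
    3.04 * (Np/Npm)**0.855 is used and ``Npm`` must be given.
    """
    Np = np.asarray(Np, dtype=float)
    if np.any(Np <= 0):
        raise ValueError("require Np > 0")
    if constants.composition_form == "ratio":
        if Npm is None:
            raise ValueError("ratio composition form requires Npm")
        base = Np / Npm
    else:
        base = Np
    out = constants.water_coef * base**constants.water_exp
    return out if out.ndim else float(out)


def ash_of_protein(Np, constants: ModelConstants = DEFAULT_CONSTANTS, Npm: float | None = None):
    """Body ash (kg) from protein weight ``Np`` (kg); Ash = 0.190 * Np by default."""
    Np = np.asarray(Np, dtype=float)
    if np.any(Np <= 0):
        raise ValueError("require Np > 0")
    if constants.composition_form == "ratio":
        if Npm is None:
            raise ValueError("ratio composition form requires Npm")
        base = Np / Npm
    else:
        base = Np
    out = constants.ash_coef * base
    return out if out.ndim else float(out)


def composition_at(
    traits: GrowthTraits, t: float, constants: ModelConstants = DEFAULT_CONSTANTS
) -> CompositionState:
    """Full composition state at age ``t`` on the potential trajectory.

    Assembles BW, eBW = alpha*BW, protein, lipid, water and ash, and reports
    the closure residual eBW - (Np + L + W + Ash).
    """
    BW = bw_at(traits, float(t))
    eBW = constants.alpha * BW
    Np = protein_at(traits, BW)
    L = lipid_at(traits, BW)
    W = water_of_protein(Np, constants, Npm=traits.Npm)
    Ash = ash_of_protein(Np, constants, Npm=traits.Npm)
    return CompositionState(
        t=float(t), BW=BW, eBW=eBW, Np=Np, L=L, W=W, Ash=Ash,
        residual=eBW - (Np + L + W + Ash),
    )
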