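"""Feed formulation, intake regulation, growth and N/P excretion scenarios.

Four feeding strategies are compared over the growing-finishing window
(nominally 35 -> 120 kg bodyweight):

S1  two-phase feeding of the average pig: two fixed feeds formulated for the
    average pig at reference bodyweights (50.0 and 92.5 kg), switching at
    65 kg;
S2  daily precision feeding of the average pig, for the same number of days
    as S1;
S3  the S1 feeds offered to every pig of a heterogeneous population, with the
    phase switch and stopping rule driven by the running population-mean
    bodyweight;
S4  per-pig daily precision feeding of the population, for the S3 duration.

Feed intake follows the first-limiting-resource rule: pigs eat to meet their
effective-energy requirement, over-consume when digestible protein is the
most deficient nutrient, but never over-consume for phosphorus.  Actual
protein and P retention are capped at the potential (Gompertz-form) maxima;
surplus energy is retained as extra lipid and surplus protein/P is excreted.
Daily nitrogen and phosphorus balances close exactly: intake = retention +
excretion, with maintenance losses routed to excretion.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .growth import (
    DEFAULT_CONSTANTS,
    GrowthTraits,
    ModelConstants,
    bw_at,
    inverse_bw,
    lipid_at,
    protein_at,
)
from .inference import PigObservations
from .population import select_average_pig
from .requirements import (
    DEFAULT_EFFICIENCIES,
    DailyRequirement,
    EfficiencyConstants,
    requirement_from_state,
)

__all__ = [
    "FeedSpec",
    "TargetDFIModel",
    "ScenarioConfig",
    "ScenarioResult",
    "SCENARIOS",
    "to_crude_protein",
    "to_total_p",
    "reference_dfi",
    "formulate_phase_feed",
    "fit_target_dfi",
    "target_dfi",
    "formulate_precision_feed",
    "predict_dfi",
    "actual_retention",
    "excretion",
    "step_day",
    "run_scenario",
    "performance_table",
    "balance_table",
]

SCENARIOS = ("S1", "S2", "S3", "S4")


# ---------------------------------------------------------------------------
# feed specification and content conversions
# ---------------------------------------------------------------------------

def to_crude_protein(
    dig_Np: float, digestibility: float = 0.800, biological_value: float = 0.750
) -> float:
    """Crude protein content (g/kg) from digestible protein content (g/kg):
    crude = digestible / (digestibility * biological_value)."""
    if dig_Np <= 0 or digestibility <= 0 or biological_value <= 0:
        raise ValueError("inputs must be > 0")
    return dig_Np / (digestibility * biological_value)


def to_total_p(dig_P: float, p_digestibility: float = 0.500) -> float:
    """Total P content (g/kg) from digestible P content (g/kg)."""
    if dig_P <= 0 or p_digestibility <= 0:
        raise ValueError("inputs must be > 0")
    return dig_P / p_digestibility


@dataclass(frozen=True)
class FeedSpec:
    """Nutrient contents of one feed: crude/digestible protein (g/kg),
    total/digestible P (g/kg) and effective energy (MJ/kg)."""

    crude_Np: float
    dig_Np: float
    total_P: float
    dig_P: float
    EE: float

    def __post_init__(self) -> None:
        for name in ("crude_Np", "dig_Np", "total_P", "dig_P", "EE"):
            if getattr(self, name) <= 0:
                raise ValueError(f"FeedSpec.{name} must be > 0")
        if not math.isclose(self.dig_Np, self.crude_Np * 0.800 * 0.750, rel_tol=5e-3):
            raise ValueError("dig_Np must equal crude_Np * 0.800 * 0.750 (to rounding)")
        if not math.isclose(self.dig_P, self.total_P * 0.500, rel_tol=5e-3):
            raise ValueError("dig_P must equal total_P * 0.500 (to rounding)")

    @classmethod
    def from_digestible(
        cls,
        dig_Np: float,
        dig_P: float,
        EE: float,
        digestibility: float = 0.800,
        biological_value: float = 0.750,
        p_digestibility: float = 0.500,
    ) -> "FeedSpec":
        return cls(
            crude_Np=to_crude_protein(dig_Np, digestibility, biological_value),
            dig_Np=dig_Np,
            total_P=to_total_p(dig_P, p_digestibility),
            dig_P=dig_P,
            EE=EE,
        )


# ---------------------------------------------------------------------------
# phase-feed formulation (S1/S3)
# ---------------------------------------------------------------------------

def reference_dfi(observations: dict[str, PigObservations], BW_ref: float) -> float:
    """Across-pig median DFI at the (fractional) day the across-pig median BW
    crosses ``BW_ref``, with linear interpolation between days."""
    frames = []
    for pid, obs in observations.items():
        if obs.DFI is None:
            raise ValueError(f"pig {pid} has no DFI record")
        frames.append(pd.DataFrame({"day": obs.t, "bw": obs.BW, "dfi": obs.DFI}))
    daily = pd.concat(frames).groupby("day").median().sort_index()
    med_bw = daily["bw"].to_numpy()
    med_dfi = daily["dfi"].to_numpy()
    above = np.nonzero(med_bw >= BW_ref)[0]
    if len(above) == 0 or above[0] == 0:
        raise ValueError(
            f"median bodyweight never crosses {BW_ref} kg inside the record"
        )
    i = above[0]
    f = (BW_ref - med_bw[i - 1]) / (med_bw[i] - med_bw[i - 1])
    return float(med_dfi[i - 1] + f * (med_dfi[i] - med_dfi[i - 1]))


def formulate_phase_feed(
    avg_traits: GrowthTraits,
    dfi_reference: float,
    BW_ref: float,
    k: EfficiencyConstants = DEFAULT_EFFICIENCIES,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> FeedSpec:
    """Fixed feed meeting the average pig's requirements at ``BW_ref`` exactly
    when eaten at ``dfi_reference`` kg/d: each per-kg content is the daily
    requirement divided by the reference intake."""
    if dfi_reference <= 0:
        raise ValueError("dfi_reference must be > 0")
    if not avg_traits.BW_in <= BW_ref < avg_traits.BW_m:
        raise ValueError("BW_ref outside the pig's growth range")
    t_ref = inverse_bw(avg_traits, BW_ref)
    np_ref = protein_at(avg_traits, BW_ref)
    l_ref = lipid_at(avg_traits, BW_ref)
    req = requirement_from_state(avg_traits, np_ref, l_ref, t=t_ref, k=k)
    return FeedSpec.from_digestible(
        dig_Np=req.Np_total * 1000.0 / dfi_reference,
        dig_P=req.P_total * 1000.0 / dfi_reference,
        EE=req.E_total / dfi_reference,
    )


# ---------------------------------------------------------------------------
# target feed intake model (S2/S4)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TargetDFIModel:
    """Power-law intake model: cumulative feed intake = theta1 * CG**theta2,
    with CG the cumulative bodyweight gain (kg).  Daily target intake is the
    day-over-day difference of this curve."""

    theta1: float
    theta2: float
    rss: float = math.nan
    n: int = 0

    def __post_init__(self) -> None:
        if self.theta1 <= 0 or self.theta2 <= 0:
            raise ValueError("theta1 and theta2 must be > 0")


def fit_target_dfi(history: PigObservations) -> TargetDFIModel:
    """Estimate (theta1, theta2) from a pig's past bodyweight and intake.

    Cumulative intake CFI(t) is regressed on cumulative gain
    CG(t) = BW(t) - BW_in: log-log least squares provides the start, refined
    by nonlinear least squares on the original scale.
    """
    if history.DFI is None:
        raise ValueError("history must include DFI")
    cg = history.BW - history.BW_in
    cfi = np.cumsum(history.DFI)
    mask = (cg > 0) & (cfi > 0)
    cg, cfi = cg[mask], cfi[mask]
    if len(cg) < 5:
        raise ValueError("need at least 5 history points with positive gain")
    if cg[-1] <= cg[0]:
        raise ValueError("cumulative gain is non-monotone: cannot fit intake model")
    slope, intercept = np.polyfit(np.log(cg), np.log(cfi), 1)
    try:
        theta, _ = curve_fit(
            lambda g, a, b: a * g**b, cg, cfi,
            p0=[math.exp(intercept), slope], maxfev=10_000,
        )
    except RuntimeError as err:  # pragma: no cover - singular fits
        raise ValueError(f"intake-model fit failed to converge: {err}") from err
    theta1, theta2 = float(theta[0]), float(theta[1])
    if theta1 <= 0 or theta2 <= 0:
        raise ValueError("intake-model fit produced non-positive parameters")
    rss = float(np.sum((cfi - theta1 * cg**theta2) ** 2))
    return TargetDFIModel(theta1=theta1, theta2=theta2, rss=rss, n=len(cg))


def target_dfi(model: TargetDFIModel, traits: GrowthTraits, t: float) -> float:
    """Target intake (kg) over day [t, t+1) from the potential trajectory:
    theta1 * (CG(t+1)**theta2 - CG(t)**theta2)."""
    cg0 = max(bw_at(traits, max(t, traits.t0)) - traits.BW_in, 0.0)
    cg1 = max(bw_at(traits, max(t, traits.t0) + 1.0) - traits.BW_in, 0.0)
    return model.theta1 * (cg1**model.theta2 - cg0**model.theta2)


def formulate_precision_feed(
    traits: GrowthTraits,
    t: float,
    dfi_model: TargetDFIModel,
    state: tuple[float, float] | None = None,
    k: EfficiencyConstants = DEFAULT_EFFICIENCIES,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> FeedSpec:
    """Daily feed for one pig: per-kg contents are the day's requirements
    divided by the target intake.

    By default requirements are read off the potential trajectory at age
    ``t``; the simulation engine passes the pig's current body state
    ``(Np, L)`` instead so the feed tracks real-time performance.
    """
    dfi = target_dfi(dfi_model, traits, t)
    if dfi <= 0:
        raise ValueError("target DFI must be > 0")
    if state is None:
        bw = bw_at(traits, max(t, traits.t0))
        np_t, l_t = protein_at(traits, bw), lipid_at(traits, bw)
    else:
        np_t, l_t = state
    req = requirement_from_state(traits, np_t, min(l_t, traits.L_m), t=t, k=k)
    return FeedSpec.from_digestible(
        dig_Np=req.Np_total * 1000.0 / dfi,
        dig_P=req.P_total * 1000.0 / dfi,
        EE=req.E_total / dfi,
    )


# ---------------------------------------------------------------------------
# intake regulation, retention, excretion
# ---------------------------------------------------------------------------

class PredictedIntake(NamedTuple):
    DFI: float  # kg/d
    limiting: str  # "energy" | "protein" | "phosphorus"


class ActualRetention(NamedTuple):
    Np_ret: float  # kg/d
    P_ret: float  # kg/d
    L_ret: float  # kg/d (may be negative under energy deficit)


class Excretion(NamedTuple):
    N_out: float  # kg/d nitrogen
    P_out: float  # kg/d phosphorus


def predict_dfi(feed: FeedSpec, req: DailyRequirement) -> PredictedIntake:
    """First-limiting-resource intake rule.

    The pig eats to its energy requirement, ``I_E = E_total/EE``.  If, at
    that intake, digestible protein is the most deficient nutrient, intake
    rises to cover the protein requirement; a phosphorus deficit never drives
    extra intake (intake stays energy-controlled).
    """
    i_e = req.E_total / feed.EE
    r_n = req.Np_total / (i_e * feed.dig_Np / 1000.0)
    r_p = req.P_total / (i_e * feed.dig_P / 1000.0)
    if max(r_n, r_p) <= 1.0 + 1e-12:
        return PredictedIntake(DFI=i_e, limiting="energy")
    if r_n >= r_p:
        return PredictedIntake(DFI=req.Np_total / (feed.dig_Np / 1000.0), limiting="protein")
    return PredictedIntake(DFI=i_e, limiting="phosphorus")


def actual_retention(
    feed: FeedSpec,
    DFI: float,
    req: DailyRequirement,
    k: EfficiencyConstants = DEFAULT_EFFICIENCIES,
) -> ActualRetention:
    """Realised daily retentions given the feed actually eaten.

    Protein and P retention use marginal efficiencies on supply above
    maintenance and are capped at the potential maxima (and floored at 0);
    lipid retention absorbs the remaining energy and may exceed the desired
    rate (surplus energy) or go negative (deficit).
    """
    if DFI < 0:
        raise ValueError("DFI must be >= 0")
    np_ret = (DFI * feed.dig_Np / 1000.0 - req.Np_maint) * k.e_Npg
    np_ret = min(max(np_ret, 0.0), req.Np_max)
    p_ret = (DFI * feed.dig_P / 1000.0 - req.P_maint) * k.e_Pg
    p_ret = min(max(p_ret, 0.0), req.P_max)
    l_ret = (DFI * feed.EE - req.E_maint - k.e_EgNp * np_ret) / k.e_EgL
    return ActualRetention(Np_ret=np_ret, P_ret=p_ret, L_ret=l_ret)


def excretion(
    feed: FeedSpec,
    DFI: float,
    retentions: ActualRetention,
    req: DailyRequirement | None = None,
    n_to_protein: float = 6.25,
    eq_literal_maintenance: bool = False,
) -> Excretion:
    """Daily N and P excretion by mass balance.

    Default accounting routes maintenance losses to excretion, so that
    intake = retention + excretion holds exactly every day:
    N_out = (crude protein intake - body protein retained) / 6.25 and
    P_out = total P intake - body P retained.  With
    ``eq_literal_maintenance=True`` the maintenance flows are additionally
    subtracted (the literal printed form, which does not close the balance).
    """
    prot_in = DFI * feed.crude_Np / 1000.0
    p_in = DFI * feed.total_P / 1000.0
    if eq_literal_maintenance:
        if req is None:
            raise ValueError("literal maintenance accounting needs the requirement")
        n_out = (prot_in - req.Np_maint - retentions.Np_ret) / n_to_protein
        p_out = p_in - req.P_maint - retentions.P_ret
    else:
        n_out = (prot_in - retentions.Np_ret) / n_to_protein
        p_out = p_in - retentions.P_ret
    if n_out < 0 or p_out < 0:
        raise ValueError("retention exceeds intake: inconsistent inputs")
    return Excretion(N_out=n_out, P_out=p_out)


# ---------------------------------------------------------------------------
# daily state update and scenario engine
# ---------------------------------------------------------------------------

@dataclass
class _PigState:
    """Mutable simulation state: body protein and lipid (kg).

    The composition state, not the Gompertz clock, carries the simulation.
    Bodyweight is derived from the state: protein maps to bodyweight through
    the inverse of the pig's own anchored protein allometry (the potential
    protein retention rule is exactly the time-derivative of protein along
    the Gompertz bodyweight curve, so a pig fed to potential follows its
    Gompertz trajectory), and lipid above or below its allometric expectation
    adds or removes bodyweight on top (scaled by the gut-fill fraction).
    """

    traits: GrowthTraits
    Np: float
    L: float
    t_start: float
    declining_days: int = 0

    def bw(self, constants: ModelConstants) -> float:
        tr = self.traits
        b_n = math.log(tr.Npm / tr.Npin) / math.log(tr.BW_m / tr.BW_in)
        np_capped = min(self.Np, tr.Npm)
        bw_base = tr.BW_m * (np_capped / tr.Npm) ** (1.0 / b_n)
        l_expected = lipid_at(tr, bw_base)
        return bw_base + (self.L - l_expected) / constants.alpha


def _initial_state(
    traits: GrowthTraits, bw_start: float, constants: ModelConstants
) -> _PigState:
    bw0 = max(bw_start, traits.BW_in)
    return _PigState(
        traits=traits,
        Np=protein_at(traits, bw0),
        L=lipid_at(traits, bw0),
        t_start=inverse_bw(traits, bw0),
    )


def step_day(
    state: _PigState,
    feed: FeedSpec,
    day: int,
    k: EfficiencyConstants = DEFAULT_EFFICIENCIES,
    constants: ModelConstants = DEFAULT_CONSTANTS,
    eq_literal_maintenance: bool = False,
) -> dict:
    """Advance one pig by one day on the given feed (explicit daily update).

    Computes requirement -> intake -> retention -> excretion, then updates
    protein and lipid; water and ash are recomputed from protein and
    bodyweight from the composition.  Returns the day's record; mutates
    ``state``.
    """
    bw_before = state.bw(constants)
    np_before, l_before = state.Np, state.L
    l_capped = min(state.L, state.traits.L_m)
    req = requirement_from_state(
        state.traits, state.Np, l_capped, t=state.t_start + day, k=k
    )
    intake = predict_dfi(feed, req)
    rets = actual_retention(feed, intake.DFI, req, k)
    out = excretion(
        feed, intake.DFI, rets, req=req,
        eq_literal_maintenance=eq_literal_maintenance,
    )
    state.Np += rets.Np_ret
    state.L = max(state.L + rets.L_ret, 1e-3)
    bw_after = state.bw(constants)
    if bw_after < bw_before:
        state.declining_days += 1
        if state.declining_days >= 2:
            warnings.warn(
                "bodyweight decreasing on consecutive days under ad-libitum feeding",
                RuntimeWarning,
            )
    else:
        state.declining_days = 0
    return {
        "day": day,
        "BW": bw_before,
        "eBW": constants.alpha * bw_before,
        "Np": np_before,
        "L": l_before,
        "DFI": intake.DFI,
        "limiting": intake.limiting,
        "Np_ret": rets.Np_ret,
        "L_ret": rets.L_ret,
        "P_ret": rets.P_ret,
        "N_out": out.N_out,
        "P_out": out.P_out,
        "N_in": intake.DFI * feed.crude_Np / 1000.0 / 6.25,
        "P_in": intake.DFI * feed.total_P / 1000.0,
        "dig_Np_content": feed.dig_Np,
        "dig_P_content": feed.dig_P,
        "EE_content": feed.EE,
        "crude_Np_content": feed.crude_Np,
        "total_P_content": feed.total_P,
    }


@dataclass(frozen=True)
class ScenarioConfig:
    """Scenario parameters: bodyweight window, phase-switch point, feed
    reference bodyweights, digestibility constants and the accounting switch
    for the literal maintenance-subtracting excretion form."""

    bw_start: float = 35.0
    bw_stop: float = 120.0
    bw_switch: float = 65.0
    bw_ref_feed1: float = 50.0
    bw_ref_feed2: float = 92.5
    max_days: int = 400
    digestibility: float = 0.800
    biological_value: float = 0.750
    p_digestibility: float = 0.500
    eq_literal_maintenance: bool = False


@dataclass
class ScenarioResult:
    """One pig's outcome under one scenario: daily trajectory, performance
    summary and cumulative N/P balances (kg/pig)."""

    scenario: str
    pig_id: str
    trajectory: pd.DataFrame
    summary: dict[str, float]
    balances: dict[str, float]
    n_days: int
    truncated: bool = False


def _finalise(
    scenario: str, pig_id: str, records: list[dict], state: _PigState,
    constants: ModelConstants, truncated: bool,
) -> ScenarioResult:
    traj = pd.DataFrame(records)
    n_days = len(traj)
    bw_first = traj["BW"].iloc[0]
    bw_final = state.bw(constants)
    adfi = traj["DFI"].mean()
    adg = (bw_final - bw_first) / n_days
    summary = {
        "ADFI_kg_d": adfi,
        "ADG_kg_d": adg,
        "FCR_kg_kg": adfi / adg,
        "Np_ret_g_d": traj["Np_ret"].mean() * 1000.0,
        "L_ret_g_d": traj["L_ret"].mean() * 1000.0,
        "final_Np_kg": state.Np,
        "final_L_kg": state.L,
        "final_BW_kg": bw_final,
    }
    balances = {
        "N_intake_kg": traj["N_in"].sum(),
        "N_retention_kg": traj["Np_ret"].sum() / 6.25,
        "N_excretion_kg": traj["N_out"].sum(),
        "P_intake_kg": traj["P_in"].sum(),
        "P_retention_kg": traj["P_ret"].sum(),
        "P_excretion_kg": traj["P_out"].sum(),
    }
    return ScenarioResult(
        scenario=scenario, pig_id=pig_id, trajectory=traj,
        summary=summary, balances=balances, n_days=n_days, truncated=truncated,
    )


def _run_two_phase(
    scenario: str,
    pigs: list[tuple[str, GrowthTraits]],
    feed1: FeedSpec,
    feed2: FeedSpec,
    cfg: ScenarioConfig,
    k: EfficiencyConstants,
    constants: ModelConstants,
) -> list[ScenarioResult]:
    """Lockstep simulation of all pigs on the two fixed feeds; the phase
    switch and the stop are driven by the running population-mean bodyweight
    (for a single pig this reduces to its own bodyweight)."""
    states = [_initial_state(tr, cfg.bw_start, constants) for _, tr in pigs]
    records: list[list[dict]] = [[] for _ in pigs]
    switched = False
    day = 0
    while day < cfg.max_days:
        mean_bw = float(np.mean([s.bw(constants) for s in states]))
        if mean_bw >= cfg.bw_stop:
            break
        if not switched and mean_bw >= cfg.bw_switch:
            switched = True
        feed = feed2 if switched else feed1
        for s, rec in zip(states, records):
            rec.append(
                step_day(s, feed, day, k, constants, cfg.eq_literal_maintenance)
            )
        day += 1
    truncated = day >= cfg.max_days
    if truncated:
        warnings.warn(
            f"{scenario}: population mean BW did not reach {cfg.bw_stop} kg "
            f"within {cfg.max_days} d",
            RuntimeWarning,
        )
    return [
        _finalise(scenario, pid, rec, s, constants, truncated)
        for (pid, _), s, rec in zip(pigs, states, records)
    ]


def _run_precision(
    scenario: str,
    pigs: list[tuple[str, GrowthTraits, TargetDFIModel]],
    n_days: int,
    cfg: ScenarioConfig,
    k: EfficiencyConstants,
    constants: ModelConstants,
) -> list[ScenarioResult]:
    results = []
    for pid, traits, model in pigs:
        state = _initial_state(traits, cfg.bw_start, constants)
        rec = []
        for day in range(n_days):
            feed = formulate_precision_feed(
                traits, state.t_start + day, model,
                state=(state.Np, state.L), k=k, constants=constants,
            )
            rec.append(
                step_day(state, feed, day, k, constants, cfg.eq_literal_maintenance)
            )
        results.append(_finalise(scenario, pid, rec, state, constants, False))
    return results


def _traits_from_row(row: pd.Series) -> GrowthTraits:
    return GrowthTraits(
        BW_m=float(row["BW_m"]), B=float(row["B"]), Npm=float(row["Npm"]),
        L_m=float(row["L_m"]), Npin=float(row["Npin"]), L_in=float(row["L_in"]),
        BW_in=float(row["BW_in"]), t0=float(row["t0"]),
    )


def _phase_feeds(
    avg_traits: GrowthTraits,
    observations: dict[str, PigObservations],
    cfg: ScenarioConfig,
    k: EfficiencyConstants,
    constants: ModelConstants,
) -> tuple[FeedSpec, FeedSpec]:
    feed1 = formulate_phase_feed(
        avg_traits, reference_dfi(observations, cfg.bw_ref_feed1),
        cfg.bw_ref_feed1, k, constants,
    )
    feed2 = formulate_phase_feed(
        avg_traits, reference_dfi(observations, cfg.bw_ref_feed2),
        cfg.bw_ref_feed2, k, constants,
    )
    return feed1, feed2


def run_scenario(
    scenario_id: str,
    traits_table: pd.DataFrame,
    observations: dict[str, PigObservations],
    config: ScenarioConfig = ScenarioConfig(),
    k: EfficiencyConstants = DEFAULT_EFFICIENCIES,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> list[ScenarioResult]:
    """Run one feeding scenario; returns one :class:`ScenarioResult` per pig
    (a single result for the average-pig scenarios S1/S2).

    The trait table must carry columns pig_id, BW_m, B, Npm, L_m, Npin, L_in,
    BW_in, t0; ``observations`` provides the population feed-intake records
    used for the phase-feed reference intakes and the per-pig intake-model
    fits.  S2 runs S1 internally to inherit its duration, S4 likewise runs S3.
    """
    if scenario_id not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario_id!r}; expected one of {SCENARIOS}")
    table = traits_table.copy()
    if "pig_id" not in table.columns:
        raise ValueError("traits_table must have a pig_id column")
    table["pig_id"] = table["pig_id"].astype(str)
    table = table.set_index("pig_id", drop=False)

    selection = select_average_pig(
        table[["pig_id", "BW_m", "B", "Npm", "L_m", "Npin", "L_in"]]
    )
    avg_id = str(selection.pig_id)
    avg_traits = _traits_from_row(table.loc[avg_id])

    if scenario_id in ("S1", "S3"):
        feed1, feed2 = _phase_feeds(avg_traits, observations, config, k, constants)
        if scenario_id == "S1":
            pigs = [(avg_id, avg_traits)]
        else:
            pigs = [(pid, _traits_from_row(row)) for pid, row in table.iterrows()]
        return _run_two_phase("S" + scenario_id[1], pigs, feed1, feed2, config, k, constants)

    # precision scenarios inherit the paired two-phase duration
    paired = "S1" if scenario_id == "S2" else "S3"
    paired_results = run_scenario(paired, traits_table, observations, config, k, constants)
    n_days = paired_results[0].n_days
    if scenario_id == "S2":
        rows = [(avg_id, avg_traits)]
    else:
        rows = [(pid, _traits_from_row(row)) for pid, row in table.iterrows()]
    pigs = []
    for pid, traits in rows:
        if pid not in observations:
            raise ValueError(f"no observation record for pig {pid}")
        pigs.append((pid, traits, fit_target_dfi(observations[pid])))
    return _run_precision(scenario_id, pigs, n_days, config, k, constants)


def performance_table(results: list[ScenarioResult]) -> pd.DataFrame:
    """Across-pig mean (SD) of the performance summaries of one scenario."""
    df = pd.DataFrame([r.summary for r in results], index=[r.pig_id for r in results])
    return pd.DataFrame({"mean": df.mean(), "sd": df.std(ddof=1) if len(df) > 1 else 0.0})


def balance_table(results: list[ScenarioResult]) -> pd.DataFrame:
    """Across-pig mean (SD) of the cumulative N and P balances of one scenario."""
    df = pd.DataFrame([r.balances for r in results], index=[r.pig_id for r in results])
    return pd.DataFrame({"mean": df.mean(), "sd": df.std(ddof=1) if len(df) > 1 else 0.0})
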