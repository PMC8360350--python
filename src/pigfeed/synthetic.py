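"""Synthetic pig populations with the statistical structure of the reference trial.

Emulates a growing-finishing trial of ~32 barrows/gilts recorded daily for
~81 d, starting at a mean bodyweight of 35.2 (SD 4.70) kg and finishing
around 118 kg.  Trait heterogeneity is generated by a shared multiplicative
construction — mature bodyweight, inverse growth rate and the lipid:protein
ratio at maturity are lognormal, mature protein is a (noisy) fixed share of
mature empty bodyweight, mature lipid is ratio x protein — which induces the
between-trait correlations without specifying any covariance matrix.  Draws
are rejection-sampled into the observed population envelopes, whose heavy
right tail also produces the occasional outlier-like animal.  Ground-truth
traits are recorded so inference can be validated by parameter recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .growth import DEFAULT_CONSTANTS, GrowthTraits, ModelConstants, bw_at, inverse_bw, lipid_at, protein_at
from .inference import PigObservations
from .requirements import DEFAULT_EFFICIENCIES, EfficiencyConstants, requirement_from_state

__all__ = ["PopulationSpec", "TRAIT_ENVELOPES", "sample_traits", "simulate_observations"]

#: observed population [min, max] envelopes for each trait
TRAIT_ENVELOPES: dict[str, tuple[float, float]] = {
    "BW_m": (124.0, 580.0),
    "B": (50.1, 127.0),
    "Lm_Npm_ratio": (0.683, 4.41),
    "Npm": (16.6, 93.5),
    "L_m": (35.7, 184.0),
    "Npin": (3.86, 8.24),
    "L_in": (2.17, 5.72),
}


@dataclass(frozen=True)
class PopulationSpec:
    """Generator settings.

    Medians and log-sds of the lognormal trait distributions are chosen so
    the sample medians and IQRs match the reference population statistics
    (e.g. BW_m median 203 kg, IQR ~48 kg); the protein share of mature empty
    bodyweight is centred at 0.16 with 10% CV.  Observation noise: additive
    Normal on bodyweight (SD 0.5 kg), multiplicative Normal on intake
    (CV 8%).
    """

    n_pigs: int = 32
    n_days: int = 81
    bw_in_mean: float = 35.2
    bw_in_sd: float = 4.70
    bwm_median: float = 203.0
    bwm_log_sd: float = 0.175
    b_median: float = 67.0
    b_log_sd: float = 0.231
    ratio_median: float = 2.23
    ratio_log_sd: float = 0.269
    npm_share: float = 0.16
    npm_share_log_sd: float = 0.10
    npin_share: float = 0.16
    npin_share_log_sd: float = 0.13
    lin_share: float = 0.11
    lin_share_log_sd: float = 0.25
    bw_noise_sd: float = 0.5
    dfi_noise_cv: float = 0.08
    ee_reference: float = 11.8  # MJ/kg, typical effective-energy feed content
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pigs < 1:
            raise ValueError("n_pigs must be >= 1")
        for name in (
            "bw_in_sd", "bwm_log_sd", "b_log_sd", "ratio_log_sd",
            "npm_share_log_sd", "npin_share_log_sd", "lin_share_log_sd",
            "dfi_noise_cv", "ee_reference",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def _draw_one(spec: PopulationSpec, rng: np.random.Generator, alpha: float) -> dict:
    """One rejection-sampled trait vector inside all envelopes."""
    for _ in range(10_000):
        bw_in = rng.normal(spec.bw_in_mean, spec.bw_in_sd)
        if bw_in < 20.0:
            continue
        bw_m = spec.bwm_median * math.exp(rng.normal(0.0, spec.bwm_log_sd))
        b = spec.b_median * math.exp(rng.normal(0.0, spec.b_log_sd))
        ratio = spec.ratio_median * math.exp(rng.normal(0.0, spec.ratio_log_sd))
        npm = spec.npm_share * math.exp(rng.normal(0.0, spec.npm_share_log_sd)) * alpha * bw_m
        l_m = ratio * npm
        npin = spec.npin_share * math.exp(rng.normal(0.0, spec.npin_share_log_sd)) * alpha * bw_in
        l_in = spec.lin_share * math.exp(rng.normal(0.0, spec.lin_share_log_sd)) * alpha * bw_in
        values = {
            "BW_m": bw_m, "B": b, "Lm_Npm_ratio": ratio, "Npm": npm,
            "L_m": l_m, "Npin": npin, "L_in": l_in,
        }
        if any(
            not TRAIT_ENVELOPES[k][0] <= v <= TRAIT_ENVELOPES[k][1]
            for k, v in values.items()
        ):
            continue
        try:
            GrowthTraits(
                BW_m=bw_m, B=b, Npm=npm, L_m=l_m, Npin=npin, L_in=l_in,
                BW_in=bw_in, t0=0.0,
            ).validate(alpha)
        except ValueError:
            continue
        return {
            "BW_m": bw_m, "B": b, "Npm": npm, "L_m": l_m,
            "Npin": npin, "L_in": l_in, "BW_in": bw_in, "t0": 0.0,
        }
    raise ValueError(
        "rejection sampling failed: population spec is incompatible with the "
        "trait envelopes"
    )


def sample_traits(spec: PopulationSpec = PopulationSpec(), seed: int | None = None) -> pd.DataFrame:
    """Draw a ground-truth trait table (one row per pig).

    Deterministic under a fixed seed (``seed`` overrides ``spec.seed``).
    Every row satisfies the growth-trait invariants and lies inside the
    population envelopes.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    alpha = DEFAULT_CONSTANTS.alpha
    rows = []
    for i in range(spec.n_pigs):
        row = {"pig_id": f"pig{i + 1:03d}"}
        row.update(_draw_one(spec, rng, alpha))
        rows.append(row)
    return pd.DataFrame(rows)


def simulate_observations(
    truth: pd.DataFrame,
    spec: PopulationSpec = PopulationSpec(),
    seed: int | None = None,
    k: EfficiencyConstants = DEFAULT_EFFICIENCIES,
) -> dict[str, PigObservations]:
    """Generate daily observation records for each pig of a truth table.

    Bodyweight is the pig's Gompertz trajectory plus Normal noise; daily feed
    intake is the energy requirement on the potential trajectory divided by a
    typical feed energy content, with multiplicative noise.  Non-positive
    draws are redrawn.
    """
    rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)
    out: dict[str, PigObservations] = {}
    for _, row in truth.iterrows():
        traits = GrowthTraits(
            BW_m=row["BW_m"], B=row["B"], Npm=row["Npm"], L_m=row["L_m"],
            Npin=row["Npin"], L_in=row["L_in"], BW_in=row["BW_in"], t0=row["t0"],
        )
        days = np.arange(spec.n_days, dtype=float)
        bw_true = bw_at(traits, traits.t0 + days)
        bw_obs = bw_true + rng.normal(0.0, spec.bw_noise_sd, size=spec.n_days)
        for i in np.nonzero(bw_obs <= 0)[0]:  # pragma: no cover - vanishing rate
            while bw_obs[i] <= 0:
                bw_obs[i] = bw_true[i] + rng.normal(0.0, spec.bw_noise_sd)
        dfi = np.empty(spec.n_days)
        for i, bw in enumerate(bw_true):
            np_t = protein_at(traits, bw)
            l_t = lipid_at(traits, bw)
            req = requirement_from_state(traits, np_t, l_t, k=k)
            base = req.E_total / spec.ee_reference
            draw = base * (1.0 + rng.normal(0.0, spec.dfi_noise_cv))
            while draw <= 0:  # pragma: no cover - vanishing rate
                draw = base * (1.0 + rng.normal(0.0, spec.dfi_noise_cv))
            dfi[i] = draw
        pid = str(row["pig_id"])
        out[pid] = PigObservations(pig_id=pid, t=traits.t0 + days, BW=bw_obs, DFI=dfi)
    return out
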