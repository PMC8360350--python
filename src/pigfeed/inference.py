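"""Per-pig Bayesian estimation of growth traits from bodyweight time series.

Each pig is fitted independently (no hierarchical pooling): a random-walk
Metropolis–Hastings sampler explores the joint posterior of the Gompertz
parameters (BW_m, B), the composition anchors (Npm, L_m, Npin, L_in,
reparameterised as the mature protein share of empty bodyweight and the
lipid-to-protein ratio at maturity) and the bodyweight observation noise
sigma_BW.  The likelihood has two parts:

* a Normal observation model on bodyweight around the Gompertz curve, and
* a *closure pseudo-likelihood*: the empty-bodyweight identity
  alpha*BW = Np + L + W + Ash is treated as observed with zero residual and a
  standard deviation proportional to empty bodyweight.  This soft constraint
  is what identifies the composition traits from bodyweight-only data.

All positive parameters are sampled on the log scale.  Proposal scales and a
joint proposal covariance are adapted during burn-in only and frozen
afterwards, so retained samples form a valid Markov chain.  Convergence is
assessed with the rank-normalised split R-hat; chains whose mean drifts far
from the pooled mean are dropped before pooling, replacing visual trace-plot
inspection with a quantitative rule.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import rankdata

from .growth import DEFAULT_CONSTANTS, GrowthTraits, ModelConstants

__all__ = [
    "PigObservations",
    "LognormalPrior",
    "PriorSpec",
    "MCMCConfig",
    "MCMCChains",
    "PosteriorResult",
    "ConvergenceError",
    "StuckChainError",
    "PARAM_NAMES",
    "TRAIT_NAMES",
    "default_priors",
    "log_likelihood",
    "random_walk_metropolis",
    "mh_sample",
    "split_rhat",
    "fit_pig",
    "save_trace_plots",
]

#: sampled parameters, in log space, in this order
PARAM_NAMES = ("BW_m", "B", "npm_share", "lm_ratio", "Npin", "L_in", "sigma_BW")
#: natural-scale traits reported in summaries
TRAIT_NAMES = ("BW_m", "B", "Npm", "L_m", "Npin", "L_in", "sigma_BW")

MIN_OBSERVATIONS = 8


class ConvergenceError(RuntimeError):
    """Raised when fewer than two chains survive the convergence screen."""


class StuckChainError(RuntimeError):
    """Raised when every chain's acceptance rate collapses below 1%."""


@dataclass(frozen=True)
class PigObservations:
    """One pig's longitudinal record: ages (d), bodyweights (kg) and daily
    feed intake (kg/d).  DFI is optional for fitting but required downstream
    for feed formulation."""

    pig_id: str
    t: np.ndarray
    BW: np.ndarray
    DFI: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        bw = np.asarray(self.BW, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "BW", bw)
        if self.DFI is not None:
            dfi = np.asarray(self.DFI, dtype=float)
            object.__setattr__(self, "DFI", dfi)
            if dfi.shape != t.shape:
                raise ValueError("DFI must have the same length as t")
        if t.shape != bw.shape or t.ndim != 1:
            raise ValueError("t and BW must be equal-length 1-D vectors")
        if len(t) < MIN_OBSERVATIONS:
            raise ValueError(f"at least {MIN_OBSERVATIONS} observations required")
        if np.any(np.diff(t) <= 0):
            raise ValueError("ages must be strictly increasing")
        if np.any(bw <= 0):
            raise ValueError("bodyweights must be positive")

    @property
    def t0(self) -> float:
        return float(self.t[0])

    @property
    def BW_in(self) -> float:
        return float(self.BW[0])


@dataclass(frozen=True)
class LognormalPrior:
    """Lognormal prior given by its natural-scale median, log-sd and hard bounds."""

    median: float
    log_sd: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (0 < self.lower < self.median < self.upper):
            raise ValueError("require 0 < lower < median < upper")
        if self.log_sd <= 0:
            raise ValueError("log_sd must be > 0")


@dataclass(frozen=True)
class PriorSpec:
    """Priors for the sampled parameters.

    ``npm_share`` is Npm/(alpha*BW_m); ``lm_ratio`` is L_m/Npm.  ``sigma_BW``
    has a half-Normal prior with scale ``sigma_scale`` (kg).  ``closure_sd``
    is the closure pseudo-likelihood standard deviation as a fraction of
    empty bodyweight.
    """

    BW_m: LognormalPrior
    B: LognormalPrior
    npm_share: LognormalPrior
    lm_ratio: LognormalPrior
    Npin: LognormalPrior
    L_in: LognormalPrior
    sigma_scale: float = 2.0
    sigma_bounds: tuple[float, float] = (1e-3, 20.0)
    closure_sd: float = 0.03


def default_priors(
    obs: PigObservations, constants: ModelConstants = DEFAULT_CONSTANTS
) -> PriorSpec:
    """Default weakly-informative priors, anchored on the observed record.

    BW_m is bounded below by max(observed BW) + 5 kg so the asymptote cannot
    fall inside the data.  Initial protein and lipid are centred on typical
    shares of initial empty bodyweight (16% protein, 11% lipid).
    """
    bw_floor = max(120.0, float(np.max(obs.BW)) + 5.0)
    a_bw_in = constants.alpha * obs.BW_in
    return PriorSpec(
        BW_m=LognormalPrior(230.0, 0.35, bw_floor, 700.0),
        B=LognormalPrior(70.0, 0.25, 30.0, 200.0),
        npm_share=LognormalPrior(0.16, 0.20, 0.05, 0.40),
        lm_ratio=LognormalPrior(2.2, 0.30, 0.30, 8.0),
        Npin=LognormalPrior(0.16 * a_bw_in, 0.15, 0.05 * a_bw_in, 0.45 * a_bw_in),
        L_in=LognormalPrior(0.11 * a_bw_in, 0.25, 0.02 * a_bw_in, 0.40 * a_bw_in),
    )


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler configuration.

    ``n_samples`` counts total iterations per chain; the first
    ``burn_in`` fraction is discarded (and is the only period during which
    proposal scales adapt).  ``sweep_every``: after burn-in, a full
    component-wise refresh sweep is interleaved every that many joint
    proposals (a fixed kernel composition, hence still valid MCMC).
    """

    n_chains: int = 4
    n_samples: int = 100_000
    burn_in: float = 0.10
    rhat_threshold: float = 1.01
    seed: int = 0
    init_scale: float = 0.05
    sweep_every: int = 2
    target_accept_low: float = 0.20
    target_accept_high: float = 0.40
    adapt_window: int = 50

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("n_chains must be >= 2")
        if not 0 < self.burn_in < 1:
            raise ValueError("burn_in fraction must lie in (0, 1)")

    @property
    def n_burn(self) -> int:
        return int(round(self.burn_in * self.n_samples))


@dataclass
class MCMCChains:
    """Raw sampler output: log-scale chains including burn-in."""

    chains: np.ndarray  # (n_chains, n_samples, n_params)
    param_names: tuple[str, ...]
    n_burn: int
    acceptance: np.ndarray  # post-burn-in accepted-move fraction per chain
    param_acceptance: np.ndarray  # (n_chains, n_params) component-wise rates


@dataclass
class PosteriorResult:
    """Pooled posterior for one pig.

    ``samples`` maps trait name -> (n_converged_chains, n_retained) array on
    the natural scale; summaries and the point ``traits`` (posterior medians)
    are computed over converged chains only.
    """

    pig_id: str
    samples: dict[str, np.ndarray]
    rhat: dict[str, float]
    acceptance: np.ndarray
    converged_chains: np.ndarray  # boolean mask over the original chains
    summary: pd.DataFrame
    traits: GrowthTraits
    n_retained_total: int


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

_LOG_2PI = math.log(2.0 * math.pi)


def log_likelihood(
    traits: GrowthTraits,
    sigma_BW: float,
    obs: PigObservations,
    closure_sd: float | None = None,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> float:
    """Observation-model log-density of one pig's bodyweight record.

    Sum over observations of the Normal log-density of BW around the Gompertz
    curve (sd ``sigma_BW``), plus, when ``closure_sd`` is given, the Normal
    log-density of the empty-bodyweight closure residual with sd
    ``closure_sd * eBW(t)``.  Returns -inf instead of raising for non-finite
    evaluations, so it can be used directly inside a sampler.
    """
    if sigma_BW <= 0:
        raise ValueError("sigma_BW must be > 0")
    x = np.array(
        [
            math.log(traits.BW_m),
            math.log(traits.B),
            math.log(traits.Npm / (constants.alpha * traits.BW_m)),
            math.log(traits.L_m / traits.Npm),
            math.log(traits.Npin),
            math.log(traits.L_in),
            math.log(sigma_BW),
        ]
    )
    fn = _make_loglik(obs, constants, closure_sd)
    return fn(x)


def _make_loglik(obs: PigObservations, constants: ModelConstants, closure_sd):
    """Build a fast log-likelihood over the log-parameter vector."""
    dt = obs.t - obs.t[0]
    bw_obs = obs.BW
    n = len(bw_obs)
    bw_in = obs.BW_in
    alpha = constants.alpha
    w_coef, w_exp, a_coef = constants.water_coef, constants.water_exp, constants.ash_coef
    ratio_form = constants.composition_form == "ratio"
    log_bw_in = math.log(bw_in)

    def loglik(x: np.ndarray) -> float:
        l_bwm, l_b, l_share, l_ratio, l_npin, l_lin, l_sig = x
        bw_m = math.exp(l_bwm)
        if bw_m <= bw_in:
            return -math.inf
        lnr = l_bwm - log_bw_in  # ln(BW_m / BW_in) > 0
        decay = np.exp(-dt * math.exp(-l_b))
        u = lnr * decay  # -log(BW_hat / BW_m)
        bw_hat = bw_m * np.exp(-u)
        sig = math.exp(l_sig)
        resid = bw_obs - bw_hat
        ll = -n * (l_sig + 0.5 * _LOG_2PI) - 0.5 * float(resid @ resid) / (sig * sig)
        if closure_sd is not None:
            npm = math.exp(l_share) * alpha * bw_m
            lm = math.exp(l_ratio) * npm
            npin, lin = math.exp(l_npin), math.exp(l_lin)
            if npin >= npm or lin >= lm:
                return -math.inf
            b_n = math.log(npm / npin) / lnr
            b_l = math.log(lm / lin) / lnr
            np_t = npm * np.exp(-b_n * u)
            l_t = lm * np.exp(-b_l * u)
            base = np_t / npm if ratio_form else np_t
            w_t = w_coef * base**w_exp
            ash_t = a_coef * base
            ebw = alpha * bw_hat
            r = ebw - (np_t + l_t + w_t + ash_t)
            sd = closure_sd * ebw
            ll += float(np.sum(-np.log(sd) - 0.5 * (r / sd) ** 2)) - n * 0.5 * _LOG_2PI
        if not math.isfinite(ll):
            return -math.inf
        return ll

    return loglik


def _make_log_posterior(
    obs: PigObservations, priors: PriorSpec, constants: ModelConstants
):
    loglik = _make_loglik(obs, constants, priors.closure_sd)
    alpha = constants.alpha
    ln_priors = [priors.BW_m, priors.B, priors.npm_share, priors.lm_ratio,
                 priors.Npin, priors.L_in]
    mu = np.array([math.log(p.median) for p in ln_priors])
    sd = np.array([p.log_sd for p in ln_priors])
    lo = np.array([math.log(p.lower) for p in ln_priors] + [math.log(priors.sigma_bounds[0])])
    hi = np.array([math.log(p.upper) for p in ln_priors] + [math.log(priors.sigma_bounds[1])])
    s_sigma = priors.sigma_scale

    def logpost(x: np.ndarray) -> float:
        if np.any(x < lo) or np.any(x > hi):
            return -math.inf
        l_bwm, l_b, l_share, l_ratio, l_npin, l_lin, l_sig = x
        bw_m = math.exp(l_bwm)
        npm = math.exp(l_share) * alpha * bw_m
        lm = math.exp(l_ratio) * npm
        if math.exp(l_npin) >= npm or math.exp(l_lin) >= lm:
            return -math.inf
        if npm + lm >= alpha * bw_m:
            return -math.inf
        z = (x[:6] - mu) / sd
        lp = -0.5 * float(z @ z)
        sig = math.exp(l_sig)
        lp += -0.5 * (sig / s_sigma) ** 2 + l_sig  # half-Normal on sigma + Jacobian
        return lp + loglik(x)

    return logpost


# ---------------------------------------------------------------------------
# sampler
# ---------------------------------------------------------------------------

def random_walk_metropolis(
    log_density,
    x0: np.ndarray,
    n_samples: int,
    n_burn: int,
    seed: int,
    init_scales: np.ndarray | None = None,
    sweep_every: int = 5,
    accept_band: tuple[float, float] = (0.20, 0.40),
    adapt_window: int = 50,
):
    """Adaptive random-walk Metropolis on an arbitrary log-density.

    Burn-in runs in stages, all adaptation confined to it: an initial
    component-wise stage tunes per-parameter scales toward the target
    acceptance band; the remaining stages mix joint Gaussian proposals (with
    an empirical covariance re-estimated at each stage boundary and a global
    scale tuned around 2.38/sqrt(d)) with component-wise sweeps.  After
    burn-in every quantity is frozen, so the retained draws form a valid
    Markov chain: each iteration is one joint proposal plus, every
    ``sweep_every`` iterations, one full component-wise sweep.  Returns the
    chain of all ``n_samples`` states plus diagnostics.
    """
    x = np.array(x0, dtype=float)
    d = len(x)
    rng = np.random.default_rng(seed)
    scales = (
        np.full(d, 0.05) if init_scales is None else np.array(init_scales, dtype=float)
    )
    lp = log_density(x)
    if not math.isfinite(lp):
        raise ValueError("log-density is not finite at the initial point")
    samples = np.empty((n_samples, d))
    acc_win = np.zeros(d)
    acc_comp_post = np.zeros(d)
    try_comp_post = np.zeros(d)
    n_acc_post = 0
    n_try_post = 0
    buf: list[np.ndarray] = []
    chol = None
    block_scale = 2.38 / math.sqrt(d)
    acc_block_win = tries_block_win = 0
    # stage boundaries within burn-in: component-wise only, then two
    # covariance-refinement stages
    s1 = int(0.4 * n_burn)
    s2 = int(0.7 * n_burn)

    def _refresh_chol() -> np.ndarray:
        arr = np.asarray(buf)
        if len(arr) > 3 * d:
            cov = np.atleast_2d(np.cov(arr.T))
        else:
            cov = np.diag(scales**2)
        return np.linalg.cholesky(cov + 1e-10 * np.eye(d))

    def _sweep(adapt: bool) -> None:
        nonlocal x, lp
        for j in range(d):
            prop = x.copy()
            prop[j] += rng.normal() * scales[j]
            lpp = log_density(prop)
            accepted = math.log(rng.random()) < lpp - lp
            if accepted:
                x, lp = prop, lpp
            if adapt:
                acc_win[j] += accepted
            else:
                try_comp_post[j] += 1
                acc_comp_post[j] += accepted

    for i in range(n_samples):
        in_burn = i < n_burn
        if in_burn and i < s1:
            _sweep(adapt=True)
            if (i + 1) % adapt_window == 0:
                rate = acc_win / adapt_window
                scales[rate > accept_band[1]] *= 1.4
                scales[rate < accept_band[0]] /= 1.4
                acc_win[:] = 0
            if i >= s1 // 2:
                buf.append(x.copy())
            if i == s1 - 1 or (s1 == 0 and n_burn == 0):
                chol = _refresh_chol()
                buf = []
        else:
            if chol is None:  # degenerate tiny burn-in
                chol = _refresh_chol()
            prop = x + block_scale * (chol @ rng.normal(size=d))
            lpp = log_density(prop)
            if math.log(rng.random()) < lpp - lp:
                x, lp = prop, lpp
                if in_burn:
                    acc_block_win += 1
                else:
                    n_acc_post += 1
            if in_burn:
                tries_block_win += 1
                if tries_block_win == adapt_window:
                    rate = acc_block_win / tries_block_win
                    if rate > accept_band[1]:
                        block_scale *= 1.3
                    elif rate < accept_band[0] / 2:
                        block_scale /= 1.3
                    acc_block_win = tries_block_win = 0
            else:
                n_try_post += 1
            if sweep_every and (i - (n_burn if not in_burn else 0)) % sweep_every == 0:
                _sweep(adapt=in_burn)
                if in_burn:
                    acc_win[:] = 0  # sweeps inside covariance stages do not retune
            if in_burn:
                buf.append(x.copy())
                if i == s2 - 1 or i == n_burn - 1:
                    chol = _refresh_chol()
                    if i == s2 - 1:
                        buf = []
        samples[i] = x

    n_try = n_try_post + try_comp_post.sum()
    n_acc = n_acc_post + acc_comp_post.sum()
    diagnostics = {
        "acceptance": n_acc / max(n_try, 1),
        "param_acceptance": acc_comp_post / np.maximum(try_comp_post, 1),
        "scales": scales,
    }
    return samples, diagnostics


def _draw_start(priors: PriorSpec, logpost, rng) -> np.ndarray:
    ln_priors = [priors.BW_m, priors.B, priors.npm_share, priors.lm_ratio,
                 priors.Npin, priors.L_in]
    for _ in range(500):
        x = np.empty(7)
        for j, p in enumerate(ln_priors):
            v = rng.normal(math.log(p.median), p.log_sd)
            x[j] = min(max(v, math.log(p.lower) + 1e-9), math.log(p.upper) - 1e-9)
        sig = abs(rng.normal(0.0, priors.sigma_scale)) + 0.05
        x[6] = math.log(min(max(sig, priors.sigma_bounds[0] * 1.01),
                            priors.sigma_bounds[1] * 0.99))
        if math.isfinite(logpost(x)):
            return x
    raise RuntimeError("could not find a finite-posterior starting point")


def mh_sample(
    obs: PigObservations,
    priors: PriorSpec | None = None,
    config: MCMCConfig = MCMCConfig(),
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> MCMCChains:
    """Run independent Metropolis–Hastings chains for one pig.

    Chain ``c`` is seeded with ``config.seed + c`` (starting point and
    proposal stream), so output is reproducible and chains are overdispersed
    via independent prior draws.
    """
    if priors is None:
        priors = default_priors(obs, constants)
    logpost = _make_log_posterior(obs, priors, constants)
    n_burn = config.n_burn
    all_chains = np.empty((config.n_chains, config.n_samples, len(PARAM_NAMES)))
    acceptance = np.empty(config.n_chains)
    param_acc = np.empty((config.n_chains, len(PARAM_NAMES)))
    for c in range(config.n_chains):
        rng = np.random.default_rng(config.seed + c)
        x0 = _draw_start(priors, logpost, rng)
        samples, diag = random_walk_metropolis(
            logpost, x0, config.n_samples, n_burn, seed=config.seed + c,
            init_scales=np.full(len(PARAM_NAMES), config.init_scale),
            sweep_every=config.sweep_every,
            accept_band=(config.target_accept_low, config.target_accept_high),
            adapt_window=config.adapt_window,
        )
        all_chains[c] = samples
        acceptance[c] = diag["acceptance"]
        param_acc[c] = diag["param_acceptance"]
    if np.all(acceptance < 0.01):
        worst = PARAM_NAMES[int(np.argmin(param_acc.mean(axis=0)))]
        raise StuckChainError(
            f"all chains stuck (acceptance < 1%); lowest component-wise "
            f"acceptance on parameter '{worst}'"
        )
    return MCMCChains(
        chains=all_chains, param_names=PARAM_NAMES, n_burn=n_burn,
        acceptance=acceptance, param_acceptance=param_acc,
    )


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def split_rhat(chains: np.ndarray) -> float:
    """Rank-normalised split R-hat of one parameter.

    ``chains`` has shape (n_chains, n_draws).  Each chain is halved, pooled
    draws are rank-normalised through the Normal quantile function (with the
    Blom offset 3/8), and the classic between/within variance ratio is taken
    on the resulting z-scores.  Degenerate zero-variance chains yield +inf
    with a warning.
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2-D array with at least 2 chains")
    n = x.shape[1]
    if n < 4:
        raise ValueError("need at least 4 draws per chain")
    if np.any(x.var(axis=1) == 0):
        warnings.warn("zero-variance chain: R-hat is +inf", RuntimeWarning)
        return math.inf
    half = n // 2
    split = np.vstack([x[:, :half], x[:, n - half:]])
    ranks = rankdata(split, method="average").reshape(split.shape)
    z = ndtri((ranks - 0.375) / (split.size + 0.25))
    m, nn = z.shape
    within = z.var(axis=1, ddof=1).mean()
    between = nn * z.mean(axis=1).var(ddof=1)
    var_hat = (nn - 1) / nn * within + between / nn
    return float(np.sqrt(var_hat / within))


def _natural_samples(chains: MCMCChains, alpha: float) -> dict[str, np.ndarray]:
    """Map retained log-scale chains to natural-scale trait arrays."""
    retained = chains.chains[:, chains.n_burn:, :]
    e = np.exp(retained)
    bw_m, b = e[..., 0], e[..., 1]
    npm = e[..., 2] * alpha * bw_m
    lm = e[..., 3] * npm
    return {
        "BW_m": bw_m, "B": b, "Npm": npm, "L_m": lm,
        "Npin": e[..., 4], "L_in": e[..., 5], "sigma_BW": e[..., 6],
    }


def fit_pig(
    obs: PigObservations,
    priors: PriorSpec | None = None,
    config: MCMCConfig = MCMCConfig(),
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> PosteriorResult:
    """Full per-pig posterior: sample, screen chains, pool, summarise.

    Chains whose mean on any trait lies more than 5 pooled standard
    deviations from the pooled mean are dropped (outlier-chain screen);
    split R-hat is then recomputed over the surviving chains.  Raises
    :class:`ConvergenceError` if fewer than two chains survive.
    """
    chains = mh_sample(obs, priors, config, constants)
    alpha = constants.alpha
    nat = _natural_samples(chains, alpha)

    n_chains = config.n_chains
    keep = np.ones(n_chains, dtype=bool)
    for name in TRAIT_NAMES:
        arr = nat[name]
        pooled_mean, pooled_sd = arr.mean(), arr.std()
        if pooled_sd == 0:
            continue
        keep &= np.abs(arr.mean(axis=1) - pooled_mean) <= 5.0 * pooled_sd
    if keep.sum() < 2:
        raise ConvergenceError(
            f"pig {obs.pig_id}: only {int(keep.sum())} chain(s) passed the "
            f"outlier screen; acceptance rates {np.round(chains.acceptance, 3)}"
        )

    rhat = {name: split_rhat(nat[name][keep]) for name in TRAIT_NAMES}
    bad = {k: v for k, v in rhat.items() if v > config.rhat_threshold}
    if bad:
        warnings.warn(
            f"pig {obs.pig_id}: R-hat above {config.rhat_threshold} for "
            f"{ {k: round(v, 4) for k, v in bad.items()} }",
            RuntimeWarning,
        )

    kept = {name: nat[name][keep] for name in TRAIT_NAMES}
    rows = []
    medians = {}
    for name in TRAIT_NAMES:
        pooled = kept[name].ravel()
        q25, q50, q75 = np.percentile(pooled, [25, 50, 75])
        medians[name] = q50
        rows.append(
            {
                "trait": name, "median": q50, "iqr": q75 - q25,
                "mean": pooled.mean(), "sd": pooled.std(ddof=1),
                "rhat": rhat[name],
            }
        )
    summary = pd.DataFrame(rows).set_index("trait")

    trait_kwargs = dict(
        BW_m=medians["BW_m"], B=medians["B"], Npm=medians["Npm"],
        L_m=medians["L_m"], Npin=medians["Npin"], L_in=medians["L_in"],
        BW_in=obs.BW_in, t0=obs.t0,
    )
    try:
        point = GrowthTraits(**trait_kwargs)
    except ValueError:
        # componentwise medians can (rarely) violate a joint constraint that
        # every individual sample satisfies; fall back to the sample closest
        # to the medians in log distance
        stacked = np.column_stack([kept[n].ravel() for n in TRAIT_NAMES[:6]])
        med = np.array([medians[n] for n in TRAIT_NAMES[:6]])
        idx = int(np.argmin(np.abs(np.log(stacked / med)).sum(axis=1)))
        vals = stacked[idx]
        point = GrowthTraits(
            BW_m=vals[0], B=vals[1], Npm=vals[2], L_m=vals[3],
            Npin=vals[4], L_in=vals[5], BW_in=obs.BW_in, t0=obs.t0,
        )

    return PosteriorResult(
        pig_id=obs.pig_id,
        samples=kept,
        rhat=rhat,
        acceptance=chains.acceptance,
        converged_chains=keep,
        summary=summary,
        traits=point,
        n_retained_total=int(keep.sum()) * (config.n_samples - config.n_burn),
    )


def save_trace_plots(result: PosteriorResult, path) -> None:
    """Write per-trait trace plots (one panel per trait) for audit."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = list(result.samples)
    fig, axes = plt.subplots(len(names), 1, figsize=(8, 2 * len(names)), sharex=True)
    for ax, name in zip(np.atleast_1d(axes), names):
        for c in range(result.samples[name].shape[0]):
            ax.plot(result.samples[name][c], lw=0.3)
        ax.set_ylabel(name)
    axes[-1].set_xlabel("retained iteration")
    fig.suptitle(f"pig {result.pig_id}")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
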