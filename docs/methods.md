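# Methods

This note records the modelling choices behind `pigfeed`: the equations and
their assumptions, the defaults that matter, what the synthetic data do and
do not emulate, and the places where the design was genuinely open.

## Growth and body composition

Bodyweight of each pig follows a Gompertz function parameterised by the
mature weight `BW_m` (kg) and the inverse growth rate `B` (d), anchored at
the observed initial weight `BW_in` at age `t0`. Body protein and lipid are
anchored allometries of bodyweight: `N*(BW) = N*_m (BW/BW_m)^b` with
`b = ln(N*_m/N*_in)/ln(BW_m/BW_in)` (likewise lipid), so both curves pass
through the initial and mature component weights exactly. The exponent is a
ratio of logarithms and therefore base-invariant.

Water and ash are functions of protein. Two forms are implemented:

* **absolute** (default): `W = 3.04 · N*^0.855`, `Ash = 0.190 · N*` — the
  classical allometric rules for growing pigs;
* **ratio** (`composition_form="ratio"`): the same expressions evaluated on
  `N*/N*_m`, which bounds water by 3.04 kg and ash by 0.19 kg over the whole
  trajectory. This is physically impossible for a growing pig and is kept
  only for auditability; the package default is the absolute form.

Empty bodyweight is a fixed fraction `eBW = α·BW` with `α = 0.95`, identical
across pigs and time. The closure identity `eBW = N* + L + W + Ash` does not
hold exactly for an arbitrary trait vector under either composition form;
the *closure residual* is therefore computed and reported, never forced to
zero. It plays two roles: a diagnostic, and the soft constraint that
identifies composition traits during inference (below).

## Per-pig Bayesian inference

Each pig is fitted independently — no hierarchical pooling and no explicit
between-trait covariance model; population-level statements are made by
summarising the per-pig posteriors afterwards.

**Observation model.** Bodyweight observations are Normal around the
Gompertz curve with unknown noise `σ_BW` (half-Normal prior, scale 2 kg).
Feed intake is not used for fitting (it is needed later, for feed
formulation). Because bodyweight alone cannot identify the composition
traits, the closure residual at every observation time enters as a
pseudo-likelihood: Normal with mean zero and standard deviation
`closure_sd · eBW(t)`, default `closure_sd = 0.03`.

**Priors** (user-overridable; chosen to cover the plausible ranges of
commercial growing-finishing genotypes): lognormal `BW_m` (median 230 kg,
log-sd 0.35, bounds [120, 700] and additionally `> max(observed BW) + 5`, so
the asymptote cannot fall inside the data); lognormal `B` (median 70 d,
log-sd 0.25, bounds [30, 200]); lognormal mature protein share
`N*_m/(α·BW_m)` centred at 0.16 (log-sd 0.20); lognormal lipid:protein ratio
`L_m/N*_m` centred at 2.2 (log-sd 0.30); lognormal initial weights centred
at 16% (protein) and 11% (lipid) of initial empty bodyweight, log-sds 0.15
and 0.25 (the initial-weight spreads are our own choice; they bracket the
observed initial-trait ranges).

**Sampler.** Random-walk Metropolis–Hastings on the log-transformed
parameter vector, default 4 chains × 100,000 samples with the first 10%
discarded as burn-in and no thinning. All adaptation is confined to
burn-in: a component-wise stage tunes per-parameter proposal scales toward
20–40% acceptance, then two stages re-estimate a joint proposal covariance
and tune a global block scale around 2.38/√d. After burn-in the kernel is
frozen — one joint proposal per iteration plus a full component-wise sweep
every second iteration (a fixed composition of valid kernels). Chain `c`
uses seed `base_seed + c`; all output is reproducible from the
configuration.

**Convergence.** Rank-normalised split R̂ per trait, threshold 1.01.
Trace-plot inspection is replaced by a quantitative rule: a chain whose mean
on any trait lies more than 5 pooled standard deviations from the pooled
mean is dropped before pooling; fewer than two surviving chains is an error.
Trace plots can still be written for audit (`pigfeed fit --plots`).
Summaries (median, IQR, mean, SD) and the point traits (posterior medians)
are computed over surviving chains only. Posterior medians are used as point
estimates throughout, including in the average-pig metric, for robustness
and consistency with the median-based population summaries.

**Known limitation — composition-trait bias on closure-violating pigs.**
When the true trait vector carries a large closure residual (as draws from
independent marginal distributions typically do), the closure
pseudo-likelihood pulls the posterior of `N*_m` toward closure-consistent
values: a systematic error that longer chains do not remove. In recovery
experiments on the default synthetic populations the median absolute
relative error is ~4% for `BW_m` and `B` but ~30% for `N*_m`. Tests assert
the bounds actually achievable under this mechanism (20% and 35%
respectively, as medians over ten pigs).

## Average pig

The average pig of a population is the individual minimising
`D_i = Σ_j |Ŷ_ij − med_j| / med_j` over the four traits
(`BW_m`, `B`, `N*_m`, `L_m`), with `med_j` the across-pig medians of the
posterior-median estimates; initial weights are excluded. Ties break to the
lowest pig id. The mode reported in trait summaries of continuous traits is
defined as the argmax of a Gaussian kernel density estimate (Silverman
bandwidth) on a 2048-point grid.

## Nutrient requirements

Maintenance scales on current body protein relative to mature protein:
`1.63 · N* · N*_m^−0.27` MJ/d effective energy, `0.004 · N* · N*_m^−0.27`
kg/d digestible protein, `0.0001293 · N* · N*_m^−0.27` kg/d digestible P,
with unit maintenance efficiencies. (The scaled-maintenance expression is
typeset ambiguously in some sources; the `N*_m^−0.27` reading is adopted —
it yields ~13 MJ/d for a mid-growth pig, the plausible magnitude. Energy for
growth is likewise reported in MJ/d, the dimensionally necessary unit.)

Growth requirements derive from the potential retentions
`N*'_max = (1/B)·N*·ln(N*_m/N*)` — which is exactly the time-derivative of
protein along the Gompertz bodyweight trajectory — `P'_max = 0.0337·N*'_max`
(a single multiplication, so the coupling is exact to machine precision) and
`L'_des = (1/B)·L·ln(L_m/L)`. Digestible requirements divide by the
marginal efficiencies 0.763 (protein) and 0.940 (P); effective energy for
growth is `50.0·N*'_max + 56.0·L'_des` MJ/d.

## Feeding simulation

**Feeds.** A feed is its per-kg contents: crude/digestible protein, total/
digestible P, effective energy. Digestible protein converts to crude by
dividing by 0.800 (digestibility) × 0.750 (biological value); digestible P
to total P by dividing by 0.500.

**Two-phase feeds** are formulated for the average pig at reference
bodyweights 50.0 kg (Feed 1) and 92.5 kg (Feed 2): each content is the
daily requirement at the reference point divided by a reference intake — the
across-pig median observed intake on the (linearly interpolated) day the
across-pig median bodyweight crosses the reference weight.

**Precision feeds** are recomputed daily per pig as requirement divided by
the target intake `DFI_t = θ1(CG_{t+1}^{θ2} − CG_t^{θ2})`, the day-over-day
difference of the fitted power law `CFI = θ1·CG^{θ2}` linking cumulative
intake to cumulative gain (log-log least squares refined by nonlinear least
squares on the pig's own record; hindcast setting — fitted once on the full
record, with a rolling refit available). The difference is taken across the
coming day, which is well-defined on the first simulated day where the
backward difference would be zero. The engine evaluates the requirement at
the pig's *current simulated state*, so the daily feed adapts to real-time
performance; the same function evaluated on the potential trajectory is
available for formulating feeds offline.

**Intake rule.** The pig eats `I_E = E_req/E_feed`. If digestible protein is
the most deficient nutrient at that intake it eats up to the protein
requirement instead; a P deficit never drives extra intake. No bulk or
climatic constraints; thermoneutral housing is assumed.

**Retention and excretion.** Protein and P retention apply the marginal
efficiencies to supply above maintenance, are capped at their potential
maxima and floored at zero; lipid retention absorbs the remaining energy
(surplus energy becomes extra lipid; deficits make it negative — flagged,
since no catabolism model is provided). Excretion closes the balance
daily: `N_out = (crude protein intake − body protein retained)/6.25`,
`P_out = total P intake − body P retained`; maintenance losses are thereby
routed to excretion, which is the accounting that makes cumulative
intake = retention + excretion hold exactly. A literal variant that also
subtracts maintenance from excretion (and breaks the balance) is available
behind `eq_literal_maintenance=True` for comparison.

**State update.** Explicit daily stepping (Δt = 1 d) on the composition
state (N*, L); water and ash are recomputed from protein. Bodyweight is
derived from the state, not from the clock: protein maps to bodyweight
through the inverse of the pig's own anchored protein allometry, and lipid
above/below its allometric expectation adds/removes weight scaled by 1/α.
Because the potential protein retention is the exact derivative of protein
along the Gompertz curve, a pig fed to its potential follows its Gompertz
bodyweight trajectory (to one-step Euler error, <0.1%/day), while
under-feeding slows the simulated pig down and excess energy shows up as
extra weight. Deriving bodyweight purely from the component sum was
rejected: it would inherit the closure residual of the trait vector and
shift the whole weight scale for perfectly ordinary pigs. Lipid is floored
at 1 g to keep the state admissible under extreme deficit, and the lipid
entering the requirement is capped at `L_m`.

**Scenarios.** S1: the average pig on Feed 1 until 65 kg then Feed 2,
stopping the first day bodyweight ≥ 120 kg (cap 400 d, truncation warning).
S2: the same pig on daily precision feeds for exactly S1's number of days.
S3: every pig on the S1 feeds, with the switch and the stop driven by the
*running simulated population-mean* bodyweight (65 and 120 kg). S4: per-pig
daily precision feeds for S3's duration. For a homogeneous population these
definitions collapse exactly: S3 = S1 and S4 = S2 per pig, which the tests
assert bitwise. Performance summaries report ADFI, ADG (from first-day to
final bodyweight), FCR = ADFI/ADG, mean daily protein and lipid retention
(g/d), final protein and lipid weights; balances report cumulative N and P
intake, retention and excretion in kg/pig.

## Synthetic populations

The generator emulates a growing-finishing trial of 32 pigs recorded daily
for 81 d from a mean initial bodyweight of 35.2 (SD 4.70) kg to a ~118 kg
finish. Traits come from a shared multiplicative construction — lognormal
`BW_m` (median 203 kg), `B` (median 67 d) and `L_m/N*_m` (median 2.23);
mature protein a 0.16 share (CV 10%) of mature empty bodyweight; initial
protein/lipid 16%/11% shares of initial empty bodyweight — rejection-sampled
into the observed population envelopes (e.g. `BW_m` ∈ [124, 580] kg). The
log-sds (0.175, 0.231, 0.269) are set so the lognormal IQRs match the
reported population IQRs. Correlations between traits arise only from the
shared factors (`BW_m` in protein, protein in lipid); no covariance matrix
is specified, and outlier-like animals arise from the lognormal right tail
rather than being injected.

Observations are the pig's Gompertz trajectory plus Normal noise (SD 0.5 kg)
for bodyweight, and the potential energy requirement divided by a typical
feed energy content (11.8 MJ/kg) with 8% multiplicative noise for intake.

What the generator does *not* emulate: closure-consistent trait vectors
(see the inference limitation above), day-to-day autocorrelated intake,
health or environmental perturbations, and sex differences. Passing tests
therefore demonstrate correctness of the machinery and directional
conclusions on heterogeneous herds, not calibration to any real herd.

## Problem sizes and numerics

Default analysis settings are 4 × 100,000 MCMC samples per pig. The test
suite and the acceptance script run the same code at reduced sizes chosen as
standard practice for continuous verification: 4 × 20,000 samples for
recovery checks (where all R̂ ≤ 1.01 is still required and achieved),
4 × 2,000 for the end-to-end pipeline smoke run, and 32-pig populations for
all scenario work. Quantile summaries use linear interpolation; the
average-pig tie-break and all seeds are deterministic; scenario trajectories
are bit-reproducible under a fixed configuration.
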