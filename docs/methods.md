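# Methods

## The model

Cumulative live births `y` for woman `i` of population `j`, interviewed at
age `a_i`, are modelled as a one-inflated Poisson count:

    y_i ~ OIP(λ_i, θ)
    P(y) = θ·[y = 1] + (1 − θ)·Poisson(y; λ)

The inflation mass θ captures the excess of women at parity one relative to
a Poisson parity distribution (a robust feature of reproductive-history
data: many women are interviewed shortly after a first birth, and some stop
at one). θ is a single global parameter by default; a per-population θ is
available behind `ModelSpec(theta_scope="population")`.

The rate is a saturating growth curve in age,

    λ(a) = M_i · (1 − exp(−k·(a − a0)))^b ,

with `M_i` the asymptotic expected parity, `k` (per year) the rate of
approach, `b` a dimensionless shape parameter (`b = 1` gives the
monomolecular curve), and `a0` an age anchor below which expected parity is
zero. The exact parameterization of the growth curve used in the life-history
literature varies; this form is the common genus (asymptote × saturating
kernel raised to an elasticity). `GrowthParams` defaults to `a0 = 0`; the
fitted models default to `a0 = 10` so that the curve turns on at a
pre-reproductive age rather than at birth — with `a0 = 0` the model must
push `b` up to suppress implied births in childhood, which distorts the
(k, b) posterior without changing CF at 60 materially. `a0` is configurable
in `ModelSpec` and must lie below the youngest woman in the data (enforced).

Heterogeneity and predictors enter through the log asymptote:

    log M_i = α + α_pop[j] + (μ_β + β_pop[j])·z_i + u_i
    α_pop[j] ~ Normal(0, σ_pop)
    β_pop[j] ~ Normal(0, σ_β)        (partial pooling of slopes)
    u_i      ~ Normal(0, σ_u)        (woman-level deviation, optional)

`z_i` is the focal predictor standardized within population (sample SD,
denominator n−1; count/amount predictors are log(x+1)-transformed first
because zeros are legitimate). Each fitted model carries exactly one focal
predictor — predictors are deliberately modelled independently, since they
are observed at different subsets of sites and capture different dimensions
of subsistence. Group-level models replace the predictor term with a fixed
shift `δ_g` of log M per subsistence type or market-integration level.
Effects on `log k` (population-varying tempo) exist behind
`k_pop_effects=True` but are off by default: the reported quantity is the
asymptotic CF, which M governs.

Woman-level deviations `u_i` are on by default. On real or realistic data
they absorb genuine woman-level heterogeneity *and* every unmodelled
predictor of family size, so the recovered σ_u is an upper bound on the
generating woman-level scale (the synthetic study-condition scenario
generates σ_u = 0.15 but eleven predictor effects are active; a group-level
fit recovers σ_u ≈ 0.4, which is the correct marginal heterogeneity).

## Priors

Weakly informative, chosen so the prior-predictive parity at age 60 spans
roughly 1–15 births:

| parameter | prior | note |
|---|---|---|
| α | Normal(log 5, 1) | baseline log asymptote |
| μ_β | Normal(0, 0.5) | ±1 SD moves M by ×/÷ e^0.5 at 1 prior SD |
| log k | Normal(log 0.05, 0.5) | half-life of saturation ~14 y at center |
| log b | Normal(0, 0.5) | shape ~1 |
| σ_pop, σ_β, σ_u, σ_k | Half-Normal(0.5) | all group scales |
| θ | Beta(2, 18) | inflation mass, prior mean 0.1 |
| δ_g | Normal(0, 1) | group shifts of log M |

All priors are overridable per fit via `ModelSpec(priors={...})`.

## Computation

Models are fitted by the No-U-Turn sampler over the unconstrained
parameterization (log scales, logit θ), with analytic gradients of the
joint log posterior (verified against finite differences in the test
suite). Step size adapts by dual averaging to a target acceptance of 0.85;
the mass matrix is re-estimated twice during warmup — dense (full
covariance) for fits up to 80 parameters, where the (α, log k, log b)
posterior correlation otherwise forces deep trajectories, and diagonal
above that (fits with per-woman effects). Population-level effects use the
*centered* parameterization: every site contributes tens to hundreds of
women, so the effects are data-identified and centering removes the funnel
between the group scales and their effects; the weakly identified per-woman
deviations stay non-centered. Divergences are counted at a 1000-nat energy
error; fits warn (never silently pass) on any R-hat > 1.01 (computed by
arviz, along with bulk/tail ESS) or any post-warmup divergence. Defaults
are 2 chains × (400 warmup + 400 draws); every entry point takes an
explicit seed and is bit-reproducible given (seed, chains, data).

## Posterior summaries

Predicted cumulative fertility is the expectation at age 60 under the full
outcome model, `CF = θ + (1 − θ)·λ(60)`, evaluated per posterior draw and
then summarized — never a summary of summaries. CF~ denotes the posterior
median. Contrasts ΔCF~ are per-draw differences: `CF(z=1) − CF(z=0)` for a
+1-SD contrast (for binary predictors this is exactly category 1 minus
category 0), `CF(group b) − CF(group a)` for group contrasts. The pooled
contrast sets β_pop = 0 and α_pop = 0 (the population-mean woman);
per-population contrasts use the conditional draws μ_β + β_pop[j].

Intervals are 90% highest-posterior-density intervals: the shortest
contiguous window over the sorted draws containing ⌈0.9·n⌉ of them, ties
broken toward the lowest lower bound — a deterministic, oracle-checkable
algorithm (no kernel density estimate). Equal-tailed intervals are also
available (`eti`). The posterior probability (PP) of an effect is the share
of draws on the median's side of zero (zeros split evenly); evidence is
labelled strong (PP ≥ 0.9), moderate (0.8 ≤ PP < 0.9) or weak (PP < 0.8).

## The synthetic-data generator

`synthetic.simulate` draws from exactly the generative structure above:
ages Uniform(14, 85) (the age pyramid of the source populations is not
published; a stationary-pyramid option would sharpen realism but not change
any inferential property being tested), predictors on their raw scales
(log-normal counts/amounts, proportions around site-specific centers,
Bernoulli binaries), and outcomes one-inflated Poisson around the growth
curve. The value that enters the outcome is the *within-population sample
z-score* of the transformed raw column — i.e. the quantity the analysis
model sees — so a correctly specified refit is exactly calibrated, which is
what the recovery tests check.

`default_paperlike_truth` encodes the study conditions: 27 populations
(10,250 women at full scale, evenly split; analyses here run a 2,700-woman
scaling for tractability on one CPU — stated as the package's problem-size
choice), a fixed subsistence × market-integration grid in which types span
MI levels (12 low / 9 medium / 6 high sites), group-level CF targets of
4.6 / 5.61 / 4.09 / 4.8 / 4.4 for hunter-gatherers / horticulturalists /
agriculturalists / pastoralists / fishers and 5.5 / 4.5 / 3.53 for
low / medium / high market integration, per-predictor pooled slopes
inverted from published 1-SD contrasts via ΔCF = (1−θ)·λ(60)·(e^μβ − 1)
with σ_β = 0.1 of cross-site slope spread, θ = 0.1, σ_u = 0.15, and
site-varying predictor availability (e.g. foraging time-budgets at the 8
low-MI sites only). The two sets of group targets cannot be satisfied by
arbitrary assignment: they are reconciled into per-population CF values by
iterative proportional fitting on log λ(60) (the scale on which the
hierarchical group model recovers group levels), clipped to a plausible
CF range of 2–9; on this grid all eight margins reconcile to < 0.01
births. Pastoralist/fisher targets are package choices (the published
group summaries cover the three major types).

What the generator does *not* emulate: marriage, birth-spacing and
mortality processes (parities are drawn directly from the count model, not
from event histories), selective survival of respondents, recall error,
correlated predictors (each predictor's latent score is independent), or
the real joint distribution of the deposited data. Passing recovery tests
therefore demonstrates that the *estimator* is correct and calibrated under
the model's own assumptions — not that those assumptions hold in any real
population.

## Scaled-down study sizes

The recovery calibration runs 20 replicates of 5 populations × 400 women
(true pooled slope 0.3, θ = 0.1) and checks 90% HPDI coverage of the pooled
ΔCF at a binomial-tolerant ≥ 14/20 with sign agreement ≥ 18/20; the group
recovery uses 6 populations × 250 women with true CF 5.5 vs 3.5. These
sizes give each fit a posterior informative enough that coverage is a real
test while keeping a full calibration run in minutes on one CPU.

## Degenerate inputs and numerical choices

* Ages ≤ a0 make λ = 0; the likelihood rejects such datasets up front.
* Populations with < 2 observed predictor values or zero within-population
  variance are dropped from that model's subset with a logged warning.
* Missing predictor cells are preserved as missing and handled by listwise
  deletion per model — never imputed.
* The one-inflated log-pmf mixes in log space (`logaddexp`), so large
  parities far from λ do not underflow.
* HPDI on constant draws returns the degenerate interval [c, c]; PP splits
  exact zeros evenly between signs.
* θ = 1 is allowed in the generator (every woman at parity one — useful as
  a degenerate check) but excluded from the likelihood's domain.

## Known limitations

* The sampler is single-threaded pure numpy; fits with thousands of
  per-woman parameters take a few minutes. For the full 10,250-woman
  scenario budget accordingly or set `woman_effect=False`.
* Group-level CF estimates are log-scale (geometric) population means by
  construction of the hierarchy; arithmetic group means of a skewed
  population mix will differ.
* Per-population contrasts are conditional estimates (draws of
  μ_β + β_pop[j] from the joint fit), not separate per-site fits.
* The selection process acknowledged in the source literature (women must
  survive to interview) is not modelled; estimates are conditional on
  observation.
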