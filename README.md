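# fertgrowth

Multilevel Bayesian growth models of cumulative fertility across
small-scale societies.

A long-standing question in evolutionary demography is whether subsistence
strategy predicts fertility — do farmers out-reproduce foragers, and does
market integration depress fertility? Population-level typologies
("hunter-gatherer", "agriculturalist") turn out to be blunt instruments:
individual women within the same society mix foraging, cultivation and wage
labor in very different proportions. This package implements the
individual-level analysis: it models each woman's cumulative live births as
a function of her age and her own subsistence and market-integration
measures, pooled hierarchically across populations, and reports predicted
cumulative fertility at age 60 and the change in it per standard deviation
of each predictor.

## The model

A woman's cumulative live births `y` at interview age `a` follow a
one-inflated Poisson distribution — a Poisson with extra probability mass
θ at parity one —

    P(y) = θ·[y = 1] + (1 − θ)·Poisson(y; λ(a)),

with the rate given by a saturating growth curve rising from zero toward an
asymptotic parity M:

    λ(a) = M·(1 − e^{−k(a − a0)})^b .

Predictors and hierarchy enter on the log asymptote,

    log M_ij = α + α_pop[j] + (μ_β + β_pop[j])·z_ij + u_i ,

where `z` is the focal predictor standardized *within* population (so
effects compare relative variation inside each site), `α_pop` and `β_pop`
are partially pooled population intercepts and slopes, and `u_i` is an
optional woman-level deviation. Group-level variants replace the predictor
with a fixed shift per subsistence type or market-integration level.
Fitting is by a No-U-Turn HMC sampler with analytic gradients (pure numpy;
see `docs/methods.md` for priors, parameterization and diagnostics).

Headline quantities: predicted cumulative fertility
`CF = E[y | age 60] = θ + (1 − θ)·λ(60)` per posterior draw; `CF~` is its
posterior median; `ΔCF~` the posterior-median contrast for +1 SD of a
predictor (or between two groups). Intervals are 90% highest-posterior-
density intervals; evidence is labelled by the posterior probability of the
sign (strong ≥ 0.9, moderate ≥ 0.8, weak below).

A synthetic-data generator with full known ground truth (27 populations,
group-level CF structure and per-predictor effects calibrated to published
cross-cultural summaries, site-varying predictor availability) makes every
stage testable without any data download.

## Worked example

The analysis is a sequence of numbered drivers over the library:

```
python analysis/01_simulate.py             # synthetic study data -> results/synthetic/
python analysis/02_group_contrasts.py      # CF~ by subsistence type and MI level
python analysis/03_predictor_contrasts.py  # 1-SD contrasts per predictor
python analysis/04_recovery_calibration.py # coverage of the pooled contrast
```

`02_group_contrasts.py` prints, for the default 2,700-woman scenario
(generating group truths 5.5 / 4.5 / 3.53 for low/medium/high market
integration):

```
== CF~ at age 60 by market_integration ==
  low                CF~  5.45  90% HPDI [ 5.07,  5.83]
  medium             CF~  4.34  90% HPDI [ 3.99,  4.67]
  high               CF~  3.55  90% HPDI [ 3.21,  3.90]
  dCF~ medium - low            -1.10  [-1.61, -0.64]  PP=0.999 (strong)
  dCF~ high - low              -1.91  [-2.39, -1.46]  PP=1.000 (strong)
  dCF~ high - medium           -0.79  [-1.19, -0.23]  PP=0.999 (strong)
```

i.e. women in the most market-integrated populations are predicted ~1.9
births short of those in the least integrated ones, a strong effect whose
interval excludes zero comfortably. `03_predictor_contrasts.py` gives the
individual-level counterpart:

```
foraging_activities      ( 8 sites, n=  800): pooled dCF~ +0.05 [-0.43, +0.55] PP=0.569 (weak); generating truth -0.34
farming_activities       (13 sites, n= 1300): pooled dCF~ +0.27 [+0.06, +0.47] PP=0.976 (strong); generating truth +0.32
education_years          (24 sites, n= 2400): pooled dCF~ -0.42 [-0.55, -0.27] PP=1.000 (strong); generating truth -0.46
```

A +1 SD shift toward farming activity adds ~0.27 births to predicted
cumulative fertility (truth +0.32); a +1 SD of education removes ~0.42
(truth −0.46). The foraging measure — observed at only 8 sites of 100
women each in this scaled scenario — is too noisy for its small true
effect: the interval covers the truth but the point estimate is unsigned,
which is exactly the behaviour the calibration study quantifies.

An optional workflow (`analysis/05_replicate_deposited.py`) refits all
eleven predictor models on the study's deposited anonymized CSV if you
download it; it is not part of the tested, self-contained pipeline.

The package also installs a small CLI: `fertgrowth simulate --out dir/`
and `fertgrowth fit --data ... --meta ... --predictor livestock ...`.

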