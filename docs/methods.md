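# Methods

`morphoclock` implements the full model stack used to date a fossil-rich
radiation from discrete morphology and to map its geographic history: an
Mk(v) morphological likelihood, relaxed morphological clocks, a
fossilized birth–death (FBD) tip-dating prior, Metropolis–Hastings
sampling with the field's convergence gates, stepping-stone model
selection, posterior tree summarization, stochastic character mapping,
and DEC/DECX ancestral-range inference. This note records the models, the
defaults and why, what the synthetic-data generator does and does not
emulate, and the numerical and design choices a maintainer would want
spelled out.

## Character evolution: Mk(v) with discrete-gamma rates

Characters are k-state symmetric Markov chains (Lewis's Mk) under the
unit-mean-rate convention, so the probability of observing the same state
after `t` expected substitutions is `1/k + (k-1)/k * exp(-k t/(k-1))`.
Among-character rate variation uses a discrete gamma with four categories
(shape `alpha`, Exp(1) prior), built as mean-of-quantile-bin rates with
mean exactly 1. Polymorphic cells (`{01}`) and missing cells (`?`, and
the inapplicable `-`, treated the same way) enter as indicator partials
over the listed states.

Matrices assembled from variable characters only are ascertainment-biased;
the "v" correction divides each character's likelihood by
`1 - P(constant pattern)`, with the constant-pattern probability computed
by the same pruning engine. Because that probability depends on the state
count, the correction is applied per state-count class; the k constant
pseudo-patterns are appended to each class's tip data so one pruning pass
serves both the data and the correction. Note the direction: conditioning
on variability *raises* each character's log-likelihood (the denominator
is below 1). Root frequencies are fixed uniform (Mk stationarity). The
pruning kernel is compiled with numba, scales partials per character, and
agrees with brute-force enumeration over internal-state assignments to
1e-12 on trees of up to 6 taxa (the acceptance suite runs 200 random
cases). One shared `alpha` spans all state-count classes by default; the
class container accepts per-class shapes.

## Clock models

Effective branch lengths are `duration x base rate x branch multiplier`.
Five multiplier models are implemented:

* **strict** — all multipliers 1;
* **ILN** — independent lognormal multipliers with real-space mean 1
  (`mean_log = -nu/2`, `var_log = nu`; "independent lognormal" admits two
  conventions and this is the real-space-mean one);
* **IGR** — independent gamma, mean 1, variance `nu`;
* **WN** (white noise) — gamma, mean 1, variance `nu / duration`, so long
  branches average out their rate noise;
* **TK02** — autocorrelated lognormal *node* rates: the child's rate is
  lognormal around the parent's with log-variance `nu x duration` (with
  the -var/2 mean correction so rates are prior-unbiased), and a branch's
  multiplier is the arithmetic mean of its endpoint rates. The root node
  rate is pinned at 1: it is confounded with the base rate and carries no
  prior term.

Sampled-ancestor attachment branches have zero duration: they contribute
no substitutions and no rate-prior term; under TK02 the rate passes
through unchanged.

The base-rate prior is the informative construction standard for
morphological clocks: `mean_log = ln(median non-clock tree height in
substitutions / median root-prior age)` with a broad `sd_log` (default
1.5). With the study-scale inputs 16.6429 substitutions and 37.6 Ma this
gives a ratio of 0.4426 and `mean_log = -0.8150`. Clock variance
parameters `nu` take exponential hyperpriors (mean 1 by default,
configurable); the source analyses do not print their hyperpriors, so
these defaults are explicit package choices.

## Tree prior: fossilized birth–death with sampled ancestors

The FBD process has speciation `lambda`, extinction `mu`, fossil-sampling
`psi` and extant-sampling `rho`, parameterized as net diversification
`d = lambda - mu` (Exp(1) prior), turnover `r = mu/lambda` (U[0,1)) and
fossil-sampling probability `s = psi/(mu + psi)` (U[0,1]); `rho` defaults
to 1. The density is conditioned on the root (crown) age — which carries
its own calibration — with a `q(x_root)` factor per crown lineage,
`lambda q(x)` per birth, `psi p0(y)/q(y)` per extinct fossil tip, a bare
`psi` per sampled ancestor (a degree-2 sampling event, not a birth) and
`rho` per extant tip, optionally conditioned on both crown lineages
leaving samples (default on). The density was validated three ways: it
collapses to the closed-form Yule product at `mu = psi = 0`; a hand-derived
two-tip density matches term by term; and the *shape over ages* matches
forward simulation — internal ages of conditioned 3-tip birth–death trees
follow `q(x)` (KS p = 0.51) and fossil-tip ages follow `p0(y)/q(y)`
(KS p = 0.59) against an independent forward simulator.

The root calibration is an offset exponential: hard minimum at the oldest
assignable fossil (34 Ma in the study system), mode at the minimum, and
the tail rate set so the soft maximum (41.2 Ma) is the 95th percentile by
default (the sources state the bound but not the tail mass; the quantile
is configurable). Fossil tip ages are free parameters with uniform priors
over their stratigraphic windows.

One property worth knowing: like the tip-dating implementations in field
use, the density is *not* renormalized by the probability of observing
the given number of taxa. Sampling (d, r, s) at a fixed taxon set
therefore tilts the implied node-age prior; the calibration study below
holds (d, r, s) fixed for exactly this reason.

## MCMC

A single-temperature Metropolis–Hastings sampler over node ages, fossil
tip ages, sampled-ancestor flags, topology (dated narrow exchange), branch
rates and all scalar parameters. Moves are weighted in proportion to the
number of parameters they update. Beyond the standard scale/slide moves
there are: a whole-tree scale move that multiplies every internal age by
`f` and divides the base rate by `f` (Jacobian `(n-1) ln f`), a
subtree-scale move, independence proposals from the prior for d, r, s (a
multiplier walk crawls through the Exp tail), prior/conditional-prior
independence proposals for branch rates, and a reversible-jump toggle
between fossil tip and sampled ancestor. The cached log-posterior is kept
as a component dictionary (likelihood, FBD, calibrations, rate priors,
scalar priors); each move refreshes only the components it can change,
and a periodic audit recomputes everything from scratch and raises if the
cache has drifted by more than 1e-8. All randomness flows through one
seeded generator; a fixed seed reproduces the trace bit for bit.

Convergence gates mirror tip-dating practice: average standard deviation
of split frequencies across independent runs (ASDSF, n-1 convention,
min_freq 0.10, gate <= 0.01), Gelman–Rubin PSRF (~1), and
autocorrelation-time ESS (Geyer initial-positive-sequence; gate > 200).
Zero-variance series report PSRF 1 / ESS n with a warning flag.

Prior-only sampling (likelihood off) with the FBD density detached targets
exactly the stated parameter priors and is used to validate the proposal
machinery by KS tests: Exp(1) for net diversification, U(0,1) for turnover
and fossil sampling, uniform windows for tip ages. The validation fixture
pins the focal fossil's parent above its whole window via a sibling, since
otherwise the tip's *marginal* is truncated by its parent and is not the
stated uniform.

## Calibration of the dating machinery

The simulation-based calibration draws, per replicate: a root age from the
offset-exponential calibration, base rate from its lognormal prior
(sd_log 0.5), gamma shape from Exp(1), clock variance from Exp(0.1), an
FBD tree of 16–26 tips at fixed (d, r, s) = (0.12, 0.5, 0.5) shared by
generator and sampler, ILN branch rates, and 100 variable-only characters.
Inference runs 25k generations with the topology held at the truth (node
ages are defined per clade). Over 20 replicates, 91% of the 397 true node
ages fall inside their 95% HPDs — consistent with nominal given the
residual tip-count conditioning noted above. The same experiment under
TK02 measures 86–91% at desk-scale chain lengths: the autocorrelated
node rates ride a rate–age ridge that needs longer chains than a desk run
affords, so the shipped calibration check uses ILN.

## Stepping-stone model selection

Marginal likelihoods are estimated with power posteriors along a
descending beta schedule drawn from quantiles of Beta(0.4, 1) (denser near
the prior), accumulating `ln mean exp[(b_k - b_{k+1}) lnL]` per step with
log-sum-exp; the beta = 0 endpoint is run a hair above zero so likelihoods
are still recorded. Desk-scale defaults are 8–10 steps of a few thousand
generations; the study-scale profile (30 steps + 5 burn-in, 250M
generations) is retained as the named "paper" profile for long-run use.
The estimator is validated against the closed-form marginal of a conjugate
normal–normal model (within 3 Monte Carlo SEs). Bayes factors are
reported on the `2 x delta-mLnL` scale — the convention that reproduces
the published four-clock comparison exactly (190.34, 190.92, 324.68;
TK02 best) — with BF > 5 labelled strong.

## Tree summarization

Majority-rule consensus keeps clades above frequency 0.5 (pairwise
compatible by construction); the maximum-compatible ("allcompat") variant
greedily adds remaining clades in descending frequency, breaking ties by
lexicographic clade encoding. Node ages on the consensus are medians over
the samples containing the clade (not common-ancestor heights), with
shortest-interval HPDs; where medians over different sample subsets cross,
parents are bumped up to restore monotonicity. MRCA age summaries locate
the MRCA per sampled tree whether or not the clade is monophyletic there.

## Stochastic character mapping

Per character, ER/SYM/ARD rate matrices are fitted by maximum likelihood
(L-BFGS-B on log rates, two starts, rates per Ma on the dated tree); the
AIC-best model drives the mapping, with ties resolved to the simpler model
and misbehaving SYM/ARD fits falling back to ER with a warning (for binary
characters SYM *is* ER — same single free rate). Ancestral marginals come
from an up-down pruning pass with the fitted matrix's stationary
distribution at the root (configurable to uniform); states are called only
when their posterior strictly exceeds 0.5, so an exact half is
"uncertain". Full histories are drawn by backward-sampling node states and
then endpoint-conditioned paths per branch by uniformization (jump count
from the conditioned Poisson series, bridge states from cached powers of
the uniformized chain). Characters with fewer than 2 scoreable states
after ambiguity resolution are skipped.

## DEC / DECX biogeography

Ranges are subsets of a named area set capped at `max_range_size`
(default 3–4 in the drivers: inferred ancestral ranges in systems like
this span at most ~3 areas; 13 areas at cap 3 give 378 states). The
anagenetic generator expands range R into area b at rate
`d * sum_{a in R} m[a, b]` under the epoch's 0/1 connectivity matrix m,
contracts at rate `e` per occupied area, and sends singletons to the
absorbing empty range. Branch propagators split at epoch boundaries;
small state spaces use dense matrix exponentials with per-duration
caching, large ones the sparse action of the exponential on partial
vectors. Cladogenesis allows narrow sympatry, subset sympatry and
single-area vicariance with equal weights, plus wide (both-daughters-
multi-area) vicariance behind the DECX flag. Fossil tips enter as
ordinary tips at their own ages; the root prior is uniform over non-empty
ranges. Likelihood fitting is bounded 2-D optimization of (d, e) on the
log scale from three starts; ancestral ranges are up-down marginals,
reporting every range within 2 log units of each node's best.

Validation: pruning matches brute-force enumeration with discretized
propagators to 1e-6 on 3-taxon toys; likelihoods are invariant to area
permutation; epoch splits obey the semigroup property; never-connected
blocks provably exchange no simulated lineages. Parameter recovery on
~100-tip simulations recovers dispersal within ~10% (median), but the ML
extirpation rate collapses toward zero under every honest design tried.
This is a property of the observable data, not the code: the generator and
likelihood agree exactly when fitted to unconditioned single-branch
endpoint draws (d = 0.149, e = 0.080 at truth 0.15/0.08), so the collapse
comes from conditioning on survival (range-extinct lineages are
unobservable and pruned) plus root-state marginalization, which lets
`e = 0` explain narrow tips as "never expanded" — the long-known DEC
extinction-rate pathology. The corresponding acceptance check is left
failing with this explanation rather than loosened.

## Synthetic data

The generator produces everything the pipeline consumes with known truth:
forward birth–death–fossilization trees conditioned on their crown age
(fossils on lineages with sampled descendants become sampled ancestors;
attempts are rejected unless both crown lineages leave samples, matching
the density's conditioning; a lineage-count budget aborts parameter draws
that would explode), characters evolved under the chosen clock with
per-character rates drawn from the same discrete-gamma mixture the
inference integrates over (variable-only coding by rejection, reproducing
the ascertainment the Mk(v) correction undoes), and ranges evolved by
exact Gillespie simulation respecting epoch connectivity, with root
ranges restricted to sets internally connected at the root's epoch.
Fixture calibration windows are true age ± U(0.2, 1.5) Ma. The default
state-count mixture is 60% binary, 25% three-state, 10% four-state, 5%
five-state — chosen to resemble morphological matrices. The 13-area,
3-epoch connectivity fixture is a documented synthetic paleogeography
(oldest epoch isolates sub-Saharan Africa and South-East Asia from the
Palearctic core, the middle epoch opens the Arabian corridor, the
youngest connects all adjacent areas), not a reconstruction.

What passing tests show — and do not show — about real data: the
generator draws independent characters from the exact inference model, so
calibration results certify the estimator and sampler, not robustness to
correlated characters, heterogeneous preservation, or model violation;
real matrices also carry far more missing data than the fixtures.

## Scale and limitations

Desk-scale settings throughout (tens of taxa, 10^4–10^5 generations,
8–10 stepping-stone steps) are the package's working sizes for synthetic
validation; the "paper" profile records the study-scale settings (250M
generations, 30+5 steps) for cluster-scale reruns, and the empirical
quantities that require the real 166 x 108 matrix and such runs (the
printed marginal likelihoods themselves, the full divergence-time table,
the empirical range maps) are documented inputs, not desk-scale outputs.
Known limitations: single-temperature chains (no Metropolis coupling);
TK02 mixing at desk scale as measured above; no molecular partitions or
total-evidence mode; no founder-event (+J) cladogenesis; Bayesian
sampling of DEC rates is out of scope (ML only).
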