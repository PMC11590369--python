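# morphoclock

Bayesian tip dating from discrete morphology, with fossilized birth–death
tree priors, relaxed morphological clocks, stepping-stone model selection,
stochastic character mapping and DEC/DECX ancestral-range inference — the
full model stack used to date fossil-rich radiations (the motivating
system is a muroid-rodent-style radiation: dozens to hundreds of taxa
scored for ~100 discrete dental characters, a near-continuous fossil
record over ~45 Ma, and presence/absence ranges over 13 biogeographic
areas). It is aimed at phylogeneticists and paleobiologists who want the
whole chain — likelihood, priors, sampler, diagnostics, summaries — as
inspectable, tested Python rather than a monolithic binary.

## Models

* **Mk(v) likelihood** — k-state symmetric Markov chains for characters,
  `P(same state | t) = 1/k + (k-1)/k e^{-kt/(k-1)}`, discrete-gamma rate
  variation (4 categories, shape α), and the ascertainment correction for
  variable-only matrices: each character's likelihood is divided by
  `1 − P(constant)` for its state-count class. Pruning is numba-compiled
  and matches brute-force enumeration to 1e-12.
* **Clock models** — strict, independent lognormal (ILN), independent
  gamma (IGR), white noise (WN, variance ∝ 1/duration) and autocorrelated
  lognormal node rates (TK02). Effective branch length = duration × base
  rate c × branch multiplier. The base-rate prior is lognormal with
  `mean_log = ln(tree height in substitutions / root age)` — with the
  study-scale inputs, `ln(16.6429/37.6) = ln(0.4426) = −0.8150`, σ = 1.5.
* **FBD tip dating** — fossilized birth–death prior over dated trees with
  extinct tips and sampled ancestors, parameterized by net
  diversification d = λ−μ ~ Exp(1), turnover r = μ/λ ~ U(0,1), fossil
  sampling s = ψ/(μ+ψ) ~ U(0,1); offset-exponential root calibration
  (hard minimum, soft maximum) and uniform stratigraphic windows on
  fossil tip ages.
* **MCMC** — Metropolis–Hastings over ages, tip ages, sampled-ancestor
  toggles, topology, rates and scalars, with ASDSF / PSRF / ESS
  convergence gates (≤0.01 / ≈1 / >200).
* **Model selection** — stepping-stone marginal likelihoods (power
  posteriors on a Beta(0.4, 1)-quantile schedule) and Bayes factors on
  the 2·Δln scale (>5 strong).
* **Summaries** — majority-rule and maximum-compatible consensus, median
  node ages, shortest-interval 95% HPDs, MRCA age summaries.
* **Character mapping** — ER/SYM/ARD fits, AIC choice, marginal ancestral
  states with a strict 50% call threshold, endpoint-conditioned history
  sampling by uniformization.
* **Biogeography** — DEC over bounded area subsets with epoch-wise 0/1
  connectivity matrices, cladogenetic scenarios (DECX wide vicariance
  optional), ML fitting of (d, e), per-node ancestral ranges on
  non-ultrametric fossil-bearing trees.

`docs/methods.md` documents every model, default and numerical choice.

## Worked example

The `analysis/` scripts run the study workflow end to end on synthetic
data with known truth:

```
python analysis/01_simulate_dataset.py
python analysis/02_derive_clock_prior.py
python analysis/03_clock_model_selection.py
python analysis/04_tip_dating_run.py
python analysis/05_character_mapping.py
python analysis/06_biogeography.py
python analysis/07_validation_summary.py
```

Step 01 prints, for example:

```
tree: 22 tips (4 fossil tips, of which 4 sampled ancestors), root 37.6 Ma
matrix: 22 x 80, coding=variable
ranges: 22 taxa over 13 areas
```

Step 02 reproduces the informative clock-prior chain —
`ratio 0.4426, mean_log -0.8150, sd 1.5` — and repeats it for the
synthetic non-clock stand-in. Step 03 prints the published four-clock
comparison (TK02 best; BFs 190.34, 190.92, 324.68 against IGR/ILN/WN)
and a desk-scale strict-vs-ILN stepping stone. Step 04 runs two dating
chains and summarizes:

```
diagnostics: ASDSF 0.0948 (gate <= 0.01), PSRF(root) 1.021 (~1), ESS(root) 64 (gate > 200)
root age: median 36.45 Ma (95% HPD 35.77-37.66); truth 37.60 Ma
```

(the truth sits inside the HPD; at this deliberately short desk run the
ASDSF/ESS gates are honestly reported as not yet met — they are the
stopping criteria for real runs). Step 06 fits DEC on the 13-area ranges:

```
ML estimates: d = 0.0309 /Ma, e = 0.00000 /Ma, lnL = -50.82
root range: AC+ECA+NA (p = 0.1672) at 37.6 Ma
```

— dispersal is informative; the ML extirpation rate collapsing to zero is
the documented DEC pathology, not a convergence failure.

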