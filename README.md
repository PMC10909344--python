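# capturebias

Individual-based simulation and estimation suite for quantifying how
**infection-driven capture bias** and sampling error distort the disease
metrics that field studies of host–parasite selection rely on.

Parasites change host behaviour: a lethargic infected lizard hides (it is
under-sampled), a malnourished one forages in the open (over-sampled).
When the proportion of infected animals in a sample no longer reflects the
population, three standard ecoimmunological quantities go wrong in
different ways:

1. **Fitness cost of infection** — difference in mean offspring number
   between uninfected and infected parents, raw and *corrected* (divided
   by the mean offspring count of uninfected parents);
2. **Relative risk (RR)** — proportion infected in the susceptible
   genotype class over the proportion infected in the resistant class;
3. **Allele-frequency change** — focal (resistance) allele frequency of
   the offspring generation minus the parents'.

`capturebias` simulates a closed diploid host population with a single
biallelic resistance locus, infects it, breeds it, samples it with
robust-design mark–recapture under a controllable infected/uninfected
capture-rate ratio *c*, and fits a from-scratch
**Cormack–Jolly–Seber (CJS)** model whose group detection-probability
difference `Δp = p̂_infected − p̂_uninfected` serves as a field-usable
bias diagnostic.

## Model

- **Founders**: *N* = 5,000 diploids; each allele an independent fair
  Bernoulli draw (genotype proportions 1/4, 1/2, 1/4).
- **Infection**: individual risk `clamp(w·g + (1−w)·r, 0, 1)` with
  genotype risk *g* ∈ {0.8, 0.2} (susceptible/resistant class; either
  heterozygote-advantage or resistance-allele scheme), prediction weight
  *w* ∈ [0, 1], and per-individual noise `r ~ N(0.5, 0.2)`; infection is
  a Bernoulli trial at that risk.
- **Reproduction**: random perfect matching into 2,500 pairs; offspring
  per pair `Poisson(λ)` with base λ = 10, an infected parent's half of λ
  multiplied by the retained-share penalty ρ ∈ [0, 1]
  (one infected parent: `λ/2 + round(ρ·λ/2)`; two: `ρ·λ`); Mendelian
  gamete transmission; offspring then infected by the same risk model.
- **Sampling**: 5 bouts of 500 captures from the pooled (parents +
  offspring) population. Infected hosts are captured at *c* times the
  per-capita rate of uninfected hosts: the expected infected share of a
  bout is `prev·c / (prev·c + 1 − prev)`. Control *c* = 1; decreased
  *c* ~ U(0.1, 0.9); increased *c* ~ U(1.1, 1.9).
- **CJS**: conditional-on-first-capture likelihood, constant survival φ,
  detection *p* by infection group on the logit scale, maximised with an
  analytic-gradient quasi-Newton iteration.

Experiments repeat the full cycle 200 times, perturbing the penalty
(fitness experiments) or the prediction weight (RR / allele-change
experiments) uniformly per run, and compare each sampled metric against
the truth with a standardized-major-axis (SMA) regression and its
one-sample slope test against 1, Fligner–Killeen variance tests, Welch
t-tests of Δp between capture conditions, and an OLS diagnostic of
metric residuals against |Δp|.

## Worked example

One complete run under strong genotype-predicted infection (w = 0.8),
full fecundity loss for infected parents, resistance-allele scheme:

```python
from capturebias import ScenarioConfig, run_single

cfg = ScenarioConfig(scheme="resistance_allele", genotype_prediction_value=0.8,
                     infection_penalty=0.0, seed=42)
r = run_single(cfg, run_index=0)
```

prints (via the fields of `r.metric_sets` and `r.fits`):

```
decreased-capture bias draw: 0.622
full population:   RR = 2.898  d_allele_freq = 0.0527  corrected_repro_diff = 0.617
decreased sample:  RR = 3.731  d_allele_freq = 0.0964  corrected_repro_diff = 0.666
CJS (decreased):   p_inf = 0.0181  p_uninf = 0.0259  delta_p = -0.0078  converged = True
CJS (control):     p_inf = 0.0263  p_uninf = 0.0217  delta_p = +0.0046
```

Reading it: under-sampling infected hosts (c ≈ 0.62) inflates the
measured relative risk (3.73 vs the true 2.90) and the apparent
allele-frequency change (0.096 vs 0.053), while the corrected
reproductive-success difference stays close to truth (0.67 vs 0.62) —
and the CJS fit flags the bias with a clearly negative Δp, against a
near-zero Δp in the paired unbiased sample.

The same pipeline is scriptable from the shell:

```bash
capturebias simulate --seed 3 --out sim_out/          # population + histories + CJS JSON
capturebias experiment --outcome rr --scheme het --runs 200 --seed 1 --out het.csv
capturebias summarize het.csv --outcome relative_risk
capturebias reproduce-headline --seed 1 --runs 200 --out reproduction/
```

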