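# Methods

## The simulated system

`capturebias` models one generation of a closed host population under
sublethal parasite pressure, loosely patterned on lizard–malaria
systems: infection reduces lifetime reproductive success but neither
kills nor is cleared, so an individual's infection state is fixed within
a run and survival between sampling bouts is exactly 1. A single
biallelic autosomal locus controls infection risk through one of two
schemes:

- **heterozygote advantage** — heterozygotes carry the low risk (an
  analogue of MHC-diversity benefits), both homozygotes the high risk;
- **resistance allele** — any carrier of the focal allele `a` carries
  the low risk, non-carriers the high risk.

Individual infection probability mixes the genotype class risk *g*
(defaults 0.8 / 0.2) with an individual random component
`r ~ Normal(0.5, 0.2)` through the genotype prediction weight *w*:
`P = clamp(w·g + (1−w)·r, 0, 1)`. At *w* = 0 infection is genotype-blind
with prevalence ≈ 0.5; at *w* = 1 it is fully genotype-determined. The
noise draw is fresh for every individual, including offspring.

Reproduction is monogamous and exhaustive: a uniformly random perfect
matching of the 5,000 founders into 2,500 pairs, each breeding once.
Offspring number per pair is Poisson with rate λ built from the base
fecundity 10 and the infection penalty ρ, interpreted as the *retained*
share of an infected parent's half of the pair's expectation: both
parents healthy → λ = 10; one infected → `5 + round(ρ·5)`; both →
`ρ·10` (left unrounded; a Poisson rate need not be integral). The
rounding of the single-infected term follows the construction of the
fecundity rule; round-half-up is the default, with banker's rounding
available (`rounding="half_even"`). The inverted reading of ρ as the
share *lost* is available as `penalty_is_loss=True`. Gametes are
Mendelian: each offspring draws one uniformly chosen allele per parent,
independently per offspring. Offspring are then exposed to infection by
the same risk model, and both generations are pooled for sampling.

## Biased robust-design sampling

Each of the 5 bouts captures exactly 500 distinct individuals from the
pooled population (~12,500–30,000 animals depending on ρ). The capture
bias *c* is defined as the **ratio of per-capita capture rates** of
infected to uninfected hosts. With the bout total fixed, the expected
infected share of a bout is therefore the renormalised composition

    E[infected share] = prev·c / (prev·c + 1 − prev),

realised as a rounded count of infected individuals drawn uniformly
without replacement, the remainder uninfected. The renormalisation is
the substantive choice here: it makes *c* an interpretable per-capita
hazard ratio (the infected and uninfected classes compete for a fixed
number of capture slots), keeps the construction well-defined at any
prevalence, and produces the characteristic asymmetry in the detection
diagnostic — at prevalence 0.5 a decreased rate c < 1 shifts
`Δp` by `(c−1)/(1−(1−c)·prev)`, which is larger in magnitude than the
increased-rate mirror image. The unnormalised alternative
(`E[share] = prev·c`) degenerates at `prev·c > 1` and implies per-capita
rate ratios far more extreme than the nominal *c* at moderate
prevalence. If the target count exceeds what a class can supply it is
clamped and back-filled from the other class (logged, since it
attenuates realised bias). Bouts are independent: no trap shyness or
happiness, and recapture is not distinguished from first capture when
sampling.

## Cormack–Jolly–Seber fit

The CJS model conditions on first capture. Structure: constant apparent
survival φ shared by groups (the simulation has no mortality and static
infection, so group- or time-varying survival would fit pure noise), and
time-constant detection *p* per infection group. For a history with
first capture at bout *f*, last at *l*, *m* detections after first
capture, out of *T* bouts:

    L = φ^(l−f) · p^m · (1−p)^(l−f−m) · χ(T−l),
    χ(0) = 1,  χ(k) = (1−φ) + φ(1−p)·χ(k−1).

Histories are collapsed to distinct-pattern counts per group;
individuals never detected do not enter (the model conditions on first
capture), and a lone final-bout capture contributes probability one —
such histories are counted but uninformative. Estimation maximises the
per-history mean log-likelihood on the logit scale with an analytic
gradient (the χ recursion is differentiated alongside) and BFGS from the
neutral start (all logits 0), with up to three jittered restarts;
convergence requires the optimizer's gradient criterion (sup-norm below
1e-6 on the scaled objective). Scaling by the history count makes the
tolerance sample-size-free. With *T* = 5 and φ near 1, absolute φ and
*p* are weakly identified (the classic terminal confounding); the
diagnostic is the *difference* `Δp = p̂_inf − p̂_uninf`, which is
identified and centred on zero under unbiased sampling. Fits with no
recapture anywhere are flagged `converged=False` with NaN estimates
rather than raising, so replicate experiments record the failure and
continue.

## Metric conventions

All sampled metrics use the set of **distinct individuals detected in at
least one bout**. Relative risk and allele-frequency change are
evaluated on that set (pooled generations for RR; detected parents vs
detected offspring for the frequency change). Undefined values — an
empty genotype class, no infected individuals in the low-risk class, a
missing generation — are recorded as NaN and pairwise-deleted from the
statistics, with counts logged, never silently dropped.

Reproductive success is parent-level: every offspring credits both
parents. Detection is imperfect for offspring (an offspring counts if
captured in ≥ 1 bout) and, by default, for parents too
(`require_parent_detected=True`): a parent enters the comparison only if
it was itself captured, as in a field study where the parental roster is
assembled by capture. In the paired design the roster is taken from the
**control** sample for all three variants of a run, reflecting a
mark–recapture campaign in which the marked-parent list comes from the
unbiased reference sampling and the biased conditions re-detect
offspring; this also keeps the roster's infection composition
independent of the bias being studied. The corrected difference divides
by the mean detected-offspring count of uninfected roster parents, which
cancels uniform detection thinning — the raw difference scales with the
thinning rate while the corrected one is invariant (verified as a
property test).

## Experiments and reference scenario

An experiment is 200 independent runs. Fitness experiments redraw the
penalty ρ ~ U(0, 1) per run with *w* fixed at 0.5; relative-risk and
allele-change experiments redraw *w* ~ U(0, 1) with ρ fixed at its
reference value. Per run, one control, one increased
(c ~ U(1.1, 1.9)) and one decreased (c ~ U(0.1, 0.9)) history set are
drawn from the same population, each with its own CJS fit.

The reference value of the unperturbed penalty is **ρ = 0**: an
infected parent's share of the pair's expected fecundity is lost
entirely. This is the scenario in which genotype-mediated selection is
strongest and the intergenerational allele-frequency signal clearest —
at ρ = 0 and *w* = 1 the expected per-generation change of the
resistance allele is ≈ 0.06, against a sampling noise floor of ≈ 0.017
in the detected subsets, whereas by ρ = 0.5 the signal halves and the
drift variance shrinks with the larger offspring pool. The across-run
spread of the true change under this scenario is what gives the
sampled-vs-true SMA slopes their scale, so ρ is deliberately a single
documented constant rather than a per-experiment fit.

Statistical battery per experiment (raw p-values, with the family-wise
Bonferroni threshold 0.005 reported alongside): SMA slope tests against
1; Fligner–Killeen variance tests of each sampled variant against the
full values; Welch t-tests of Δp, control vs each biased condition; and
a two-step OLS diagnostic (residuals of sampled-on-full, regressed on
|Δp|). The SMA estimator is `sign(r)·sd(y)/sd(x)`; its one-sample test
correlates residual scores `y − b₀x` with axis scores `y + b₀x` and
refers `r²(n−2)/(1−r²)` to F(1, n−2); the 95% CI inverts the same
pivot. Reproductive-success comparisons are paired within runs, so the
biased variants' slopes are taken against the control sample; all other
slopes are against the full-population truth. Both the residual-axis
correlation at the test slope and the plain x–y correlation are
reported (`r` and `r_xy`), as the two are easily conflated in slope-test
output.

## Randomness and determinism

One master seed drives everything. Each (run, stage) pair — founders,
parent infection, pairing, reproduction, offspring infection, each
sampling condition, bias draws, parameter perturbation — gets an
independent generator via a keyed `SeedSequence` spawn, so any stage of
any run replays in isolation and adding a stage never perturbs earlier
ones. A `RunManifest` (config snapshot, seed, stage list, outputs)
suffices to reproduce an experiment table bit-for-bit.

## What the generator does and does not emulate

The simulation gives the best case for every inference step: exact
parentage assignment, perfect pathogen diagnosis, a closed population
with no mortality, migration, density dependence or mate choice, capture
heterogeneity driven by infection state only, and infection assigned
independently per individual (no contact or vector transmission, no
spatial clustering). Passing tests therefore demonstrate the *intrinsic*
distortions of sampling and capture bias — what goes wrong even when
everything else is ideal — and say nothing about the additional error
sources of real field campaigns (false-negative diagnostics, pedigree
error, spatially structured capture effort), which would compound them.

## Known limitations

- Absolute CJS φ and *p* are weakly identified at 5 bouts with survival
  1; only Δp should be interpreted.
- The decreased-capture relative-risk slope is heavy-tailed (rare-class
  sampling error at small *c* and large *w*); its across-experiment
  replication spread is noticeably wider than its within-experiment SMA
  CI suggests, and single-experiment values should be read accordingly.
- Metrics are analysed linearly; the boundedness of several outcome
  distributions induces nonlinearity that a linear correction only
  approximates.
- Scenario defaults that the underlying study design leaves open (the
  unperturbed ρ, the fitness-experiment *w*) are single documented
  constants here; sensitivity to them is real, particularly for the
  allele-frequency-change slopes.
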