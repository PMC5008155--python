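# Methods

## Pedigree quantities

Kinship f(i,j) is computed by the classical tabular method: individuals are
topologically sorted (every known parent before its offspring), then

    f(i,i) = (1 + f(dam_i, sire_i)) / 2
    f(i,j) = (f(dam_i, j) + f(sire_i, j)) / 2   for j earlier than i,

with the kinship of an unknown parent taken as 0. Additive relatedness is
a = 2f (so a_ii = 1 + F_i) and the inbreeding coefficient is
F_i = f(dam_i, sire_i). Conventions:

* Founders (both parents unknown) are non-inbred and mutually unrelated.
  Pedigree-derived F and r are therefore only meaningful for individuals
  whose parents are assigned — which is exactly why the cohort filters
  condition on assigned parentage.
* An individual with one known parent is treated as if the missing side
  were a unique phantom founder; this keeps the recursion total and gives
  F = 0 whenever any parent is unknown.
* The full dense matrix is computed by dynamic programming rather than
  on-demand path counting; populations of a few thousand individuals fit
  comfortably.

Gene dropping validates the recursion: each founder receives two globally
unique alleles (and each missing parent side one), every non-founder
inherits one uniformly chosen allele per parent, independently per
replicate. Label equality is then identity by descent by construction, so
the replicate fraction of IBD allele pairs estimates F and the mean
cross-pair match fraction estimates f. The oracle shares nothing with the
recursion except the pedigree itself.

## Study-record model and filters

Five canonical CSV tables (group membership per attempt, attempts,
parentage with assignment confidences, guard observations, outcomes) plus
the pedigree form a `StudyDataset`. Design choices:

* "Adult" means age > 365 days at the attempt's oestrus start; members of
  unknown age are excluded from adult-dependent rules rather than guessed.
* "Confidently assigned" means both dam and sire at confidence ≥ 0.8, the
  same threshold used to accept parentage into the pedigree.
* Natal status is the recorded birth group, not inferred from the pedigree.
* Offspring are attributed to an oestrus event if born 40–80 days after
  its start; a guard is *successful* if some attributable offspring of his
  guarded female has him as sire, and guard–female rows whose female has
  no attributable offspring are excluded rather than classified.
* The candidate-father pool for the 80% rule is the within-group adult
  males — the same pool the randomization draws from, keeping criterion
  and test aligned. Similarly, the candidate females for the guard-side
  rule are the females guarded in the same event (the reshuffling pool).
* Extra-pair (EPP) rows require exactly one non-guard sire; rows with two
  or more distinct EPP identities are excluded because no single paired
  comparison exists. The EPP male is within-group if he appears on the
  attempt's roster.
* Filter reports attribute each dropped row to the first criterion it
  fails (criteria in their stated order), so n_input always reconciles
  with n_retained plus the drop counts; retention itself is the
  conjunction and order-independent.

## Permutation tests

The statistic is the mean pairwise relatedness of the retained dyads. Two
constrained nulls:

* **Breeding pairs.** Each mother keeps her attempt and her number of
  distinct sires k; a null draw gives her k distinct males uniformly from
  her group's adult males (males reusable across females). Mothers whose
  pool is smaller than k cannot be randomized and are excluded from both
  the observed and null sets, with a log entry. Sampling without
  replacement mirrors the observed count of *distinct* sires.
* **Guard–female links.** Within each oestrus event the female endpoints
  of the observed edges are permuted; draws with a duplicated
  (guard, female) edge are rejected. Because every valid configuration
  corresponds to the same number of endpoint permutations, accepted draws
  are uniform over configurations. After 10 000 rejections (tiny events
  only) the sampler falls back to exact enumeration of the distinct valid
  endpoint sequences. Events admitting a single configuration contribute
  their observed edges unchanged.

The one-tailed Monte Carlo P (direction fixed at "observed relatedness
lower than the null") is (1 + #{null mean ≤ observed}) / (n_perms + 1):
never zero, and ties count toward the null — the conservative choice.
Default n_perms is 10 000. All randomness flows from one integer seed via
named substreams (`SeedSequence` keyed by a CRC32 of the stage name), so
stage results are independent of execution order.

## Paired comparison and mixed models

Guard-vs-EPP relatedness differences d = r(guard, female) − r(EPP male,
female) are tested with a paired t-test, t = mean(d)/(sd(d)/√n) on n−1
degrees of freedom, two-tailed (the direction of interest is large
positive t; the two-tailed choice is immaterial at the effect sizes that
matter and is the safer default). Constant differences raise an error
rather than producing an infinite t.

The regression stage fits generalized linear mixed models with crossed
random intercepts — yearling mass (Gaussian; group, attempt, mother,
father, individual) restricted to records at 350–370 days; survival to one
year (binomial-logit; same minus individual); guard success
(binomial-logit; group, attempt, guard, female). Model simplification
follows the classical backward-elimination protocol: terms are dropped
(least significant first, likelihood-ratio χ² with 1 df between ML fits)
until all remaining terms have P < 0.05, then every eliminated term is put
back into the minimal model individually to obtain its reported χ², P and
effect size. Numerical choices:

* All model comparisons use maximum-likelihood (not REML) fits — required
  for fixed-effect likelihood-ratio tests.
* Negative χ² from optimizer noise is clamped at 0.
* Singular random-effect fits (a variance component estimated at zero) are
  reported with a `singular` flag rather than refitted with terms removed.
* Maternal age is measured in months at the offspring's birth; group sex
  ratio is the proportion of the attempt's adults that are male; male age
  rank is 1 for the oldest adult male.
* The fitting engine is lme4, driven through an Rscript subprocess with
  CSV/JSON interchange. Convergence warnings are counted and surfaced via
  the `converged` flag; a failed fit returns a structured error rather
  than crashing the batch.

## Synthetic population generator

The generator emulates the study system's design: n_groups
social groups (default 6) each founded by 6 females and 6 males of
staggered adult ages, running 12 breeding attempts at 90-day intervals.
Each adult female enters oestrus with probability 0.6 (at most 10 per
event, matching the observed 1–10 synchronous females); each oestrous
female receives 1 + Poisson(0.35) guards; litters are 1 + Poisson(2)
(mean 3); births occur 60 days after oestrus, inside the 40–80-day
attribution window; offspring mature at 365 days. Paternity per pup: with
probability 0.10 an extra-group adult male, otherwise the guard with
probability 0.4, otherwise a within-group non-guard. Sire and guard
choices weight male m for female f by exp(−β·r(m,f)); β_guard and
β_paternity default to 0, making the default generator an exact
random-mating null (choice marginally uniform over adult males, which the
type-I calibration tests rely on). Adults die at 5 years, so over twelve
attempts the founder cohort turns over and late attempts are dominated by
pedigree-born adults — reproducing both the wide within-group relatedness
variation of a philopatric plural breeder and realistic pass rates for the
assigned-parentage filters.

Fitness effects: yearling mass = 807.5 + 1.15·age_days + γ_mass·F + group
+ attempt + mother + father + individual random intercepts + residual
(SDs 10/15/15/10/25/40 g), with γ_mass defaulting to −347.9 g per unit F;
survival is Bernoulli on logit = intercept + γ_surv·F + 0.20·rainfall +
random intercepts (SD 0.3), with γ_surv defaulting to 0 and the intercept
set to 0 so that roughly 60% of pups recruit and the simulated population
sustains itself across attempts. Rainfall is Normal(2, 1) truncated at 0
mm/day. Parentage is emitted at confidence 1.0 by default. The emitted
pedigree's F values equal the analysis recursion exactly because the
generator maintains the identical kinship recursion incrementally.

What the generator does *not* emulate: group fission and eviction,
territory dynamics, genotyping error or partial parentage assignment
(confidence is a scalar dial, not a genetic model), age-structured
fecundity, and observation gaps. Passing tests therefore demonstrate that
the statistics are correct and calibrated for data of this structure —
not that any particular field dataset satisfies the generator's
assumptions.

## Problem sizes in the validation suite

The acceptance tests run at sizes chosen to exercise each property
decisively on a single CPU: 20 random five-generation pedigrees (≤ 60
individuals) against 100 000-replicate gene drops; exhaustive enumeration
on a 2-mother × 3-male fixture against 100 000 Monte Carlo permutations
and 30 000 draws of a 2 × 2 guard reshuffle; 200 replicate null datasets
(6 groups × 12 attempts) for type-I calibration at 1 000 permutations
each; 200 replicates per point of the β_paternity ∈ {0, 2, 10} power
grid; 60 replicates (~780 yearlings each) for mixed-model CI coverage and
40 for null-term elimination. Statistical pass thresholds are exact
binomial or Kolmogorov–Smirnov critical values at the stated nominal
rates.

## Known limitations

* The guard-reshuffle exact-enumeration fallback is factorial in event
  size and intended only for the tiny events that can actually exhaust
  the rejection budget.
* Binomial GLMM backward elimination on very small frames can be
  singular-boundary-heavy; results carry the `singular`/`converged` flags
  and should be read accordingly.
* Pedigree-derived relatedness between an assigned-parent individual and
  an unassigned one is reported under the phantom-founder convention
  (typically an underestimate); the filters are designed to keep such
  pairs out of the tested sets.
* The deposited-data adapter is declarative (a column map); it does not
  attempt to guess foreign schemas.
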