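# Methods

This note records the modelling assumptions, the numerical and design
choices, and the known limitations of the package. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## The analytic model

A mating group is founded by *n* mated females, each contributing *N*
offspring, with *N* large. Offspring mate at random within the group (each
female once, males arbitrarily often), males die, and mated daughters
disperse to found new groups drawn at random from the whole population;
sister co-foundress groups are a rare alternative. The focal female's
inclusive-fitness valuation of the group, *H*, counts her genetic stake in
the group's daughters directly and in the group's matings through sons,
weighted by consanguinities (p_d, p_s, p_f, p_m) and by the class
reproductive values (v_f, v_m). The unbeatable allocation z* is the zero of
∂H/∂δ at δ = 0, equivalently Frank's ½·R·P.

Assumptions worth keeping in view:

* **Allocation = sex ratio.** Sons and daughters are assumed equally
  costly, so proportional allocation to sons and proportion of offspring
  male are used interchangeably throughout.
* **Large broods.** All closed forms are the N → ∞ limit. Integer brood
  effects (e.g. the 1/N optimum for a lone foundress that must produce at
  least one son) are real biology but outside the analytic model; the
  simulator quantifies how they bias small-brood runs (below).
* **Pure LMC.** Mating is strictly local, all mated females disperse; no
  partial male dispersal, no local resource competition, no mixed
  sister/nonsister groups.
* **p_f for haplodiploid sister groups** is not determined by the theory:
  it multiplies a term that cancels from ∂H/∂δ. `consanguinities` exposes
  it as an explicit parameter, default 0, and a test asserts the marginal
  effect is invariant to it.
* **n = 1 with a "sisters" label** is accepted and returns z* = 0: the
  kinship of absent co-foundresses is vacuous, and experiments include
  single-foundress controls in both arms.

Exact inputs (ints, `Fraction`s) flow through exact rational arithmetic, so
identities like closed-form = general solver = ½·R·P hold with `==`, not
tolerances; float inputs take a float path.

`marginal_effect` uses a central finite difference with step
1e-6 · max(z, 1−z), falling back to a one-sided stencil at the boundary of
[0, 1]. H is smooth and mildly nonlinear in δ (through the mating-share
ratio), so the truncation error is far below the 1e-6 stationarity
tolerance used in tests when H is evaluated at N = 1. Note that H scales
linearly with N: stationarity checks should use N = 1 or a relative
tolerance.

The harmonic-mean foundress number is female-weighted: a female descends
from a size-n group with probability ∝ n·q(n), which makes the
harmonic mean over females equal the group-frequency arithmetic mean
Σ n q(n) / Σ q(n); the implementation computes it from the weighted form
and the tests pin it to a direct enumeration.

## The individual-based simulator

The simulator is an independent oracle for the closed forms: nothing in it
knows z*; it just runs the life cycle.

* **State.** n·G mated foundresses per generation, each carrying two
  alleles per strategy locus and her mate's gametic contribution.
  Haplodiploid males are haploid (one maternal allele); diplodiploid males
  are diploid. Sex allocation is under maternal control: each offspring is
  male with probability equal to the mother's allelic mean (her sister-locus
  mean instead, inside sister groups, when the facultative locus is
  enabled).
* **Mating and dispersal.** Each daughter mates one male drawn uniformly
  from her natal group's males (this weights mothers by son production,
  which is where selection on male function enters); male-less groups leave
  only unmated daughters. The next generation's foundresses are a uniform
  without-replacement sample of mated daughters, implemented as a
  multivariate hypergeometric draw of per-mother counts followed by random
  placement into groups — the cost is independent of brood size, which is
  what lets the simulator run at N_off = 10⁴ and approximate the analytic
  large-N limit properly. Males are not persisted as individuals: a mating
  samples the chosen male's gametes from his mother's stored genotypes.
  Two matings drawing "the same" male are treated as independent sons of
  that mother — exactly the idealization of the analytic model, where mate
  coincidence has probability zero.
* **Mutation.** Per transmitted allele, probability mu of a Gaussian step
  of scale sigma_mu, reflected at [0, 1]. Defaults mu = 2e-3,
  sigma_mu = 0.05. Larger mutation rates (1e-2) keep enough variance for
  fast convergence but produce a measurable mutation-load shift of the
  stationary mean (order +0.01 at the haplodiploid n = 2 optimum) because
  the selection curvature around z* is asymmetric; 2e-3 keeps that shift
  below the Monte-Carlo error at the default run lengths while still
  converging from a distant start within ~2000 generations.
* **Run sizes.** Defaults G = 500 groups, N_off = 10⁴, 5000 generations
  with 2000 discarded, chosen so a five-replicate convergence check per
  (ploidy, n) setting completes in well under a minute while the
  finite-brood biases (below) are negligible.
* **Standard errors.** Within a run, the post-burn-in series is summarized
  by batch means; but the strategy mean wanders slowly under
  mutation-drift-selection and a single run's batch SE understates the
  uncertainty of its time average. Convergence checks therefore use
  `run_replicates`: independent seeded replicates, SE = SD of replicate
  means / √R.
* **Finite-brood biases** (quantified during development, reproducible by
  lowering N_off): with N_off ~ 10–100 the evolved mean sits above z*
  (mating-share nonlinearity in small male cohorts, and the fitness cliff
  of male-less groups) and the realized sib-mating rate sits slightly below
  1/n (selecting a daughter from a fixed-size brood implies fewer sons in
  it). Both decay like 1/N_off; at N_off = 10⁴ they are far below the
  replicate SE.
* **Inbredness estimation.** For sampled foundresses, the coancestry of the
  two parents is computed by exact recursion over the recorded pedigree
  (mother and mate's-mother indices per generation), haplodiploid-aware,
  truncated at `pedigree_depth` with founders treated as unrelated and
  outbred. The truncation error contracts by 3/(4n) per generation; at the
  default depth 8 the expected shortfall at n = 2 is ~1e-3, below the
  Monte-Carlo error, and the cost of the recursion grows roughly 4^depth,
  which is why the default is 8 rather than deeper. (A small opposing
  upward term comes from background relatedness in the finite population.)
* **Facultative sister locus.** With probability ε per group, a group is
  formed from n daughters of one mother, and members express a second
  locus there. Selection on that locus is O(ε) (capped at 0.05 to stay in
  the rare-sister regime the theory assumes), so it is tested at reduced
  scale: the run used in the tests (G = 400, N_off = 200) verifies that the
  sister-expressed mean is driven most of the way (≥ 70% of the gap) from
  the unconditional optimum toward the sister-group closed form. It
  equilibrates a little above the analytic value because at affordable
  brood sizes the male-less-group cliff and mating-share effects are
  first-order relative to ε-weak selection; the residual shrinks with
  N_off but testing its disappearance is beyond a desk-scale run.

The neutrality control (sexes drawn at a fixed ratio regardless of
genotype) verifies that absent selection the strategy mean performs an
unbiased walk.

## Synthetic brood data

The generator emulates the shape of a foundress-number × kinship brood
experiment on a gregarious parasitoid: foundress groups of {1, 2, 4, 8},
sister and nonsister arms, brood-level male/female counts. Brood size is a
sum of zero-truncated Poisson per-foundress productivities (mean 10 —
a realistic gregarious-parasitoid clutch; the real experiment's brood-size
distribution lives in its archived data, not in its report, so this is a
labelled stand-in). Male counts are binomial around a truth model:

* **curve-based** (default): logistic curves in foundress number per arm;
  the default slopes/intercepts are the unweighted fits reported for the
  re-analysed experiment (0.084, −1.132 nonsister; 0.071, −2.072 sister).
  Single-foundress broods, generated once and shared by both arms exactly
  as both regression arms pool them, use the sister curve by default — the
  closer of the two to the observed single-foundress sex ratio (~0.1).
* **model-based**: the closed-form predictions at a chosen ploidy and f.

A single large outlier brood with an aberrant sex ratio is appended by
default (76 offspring, sex ratio 0.7 — a synthetic stand-in mirroring the
influential outlier the original analysis kept). Developmental mortality
is off by default; a uniform thinning switch exists for robustness
experiments only, since mortality is a recognized confound rather than
part of the model.

What passing tests on these data do *not* show: that the estimator
decisions reproduce the archived dataset's numbers exactly. Synthetic
broods are cleaner (no observer effects, known truth), so variance
explained on them is much higher than any real re-analysis would give.

## Fitting pipeline

* **"Unweighted logistic"** is implemented as the equal-weight
  Bernoulli-form quasi-likelihood on fractional brood sex ratios — one
  observation per brood, maximized by statsmodels' binomial GLM. The point
  estimates coincide with a quasi-binomial fit; a test verifies exact
  invariance to brood size at fixed sex ratios. Non-convergence or
  separation is flagged on the result, not raised.
* **Grid search over f** uses a 0.01-step grid on [0, 1] with a smallest-f
  tie-break. SST uses the mean of the subset being fitted (all broods, or
  multi-foundress only); the multi-foundress variant exists because LMC
  models are knowingly unrealistic for lone foundresses.
* **Comparison to the classic model** is defined as the proportional SSE
  reduction (SSE_classic − SSE_model)/SSE_classic, with the classic
  reference z = (n−1)(2n−1)/(n(4n−1)) applied to every brood regardless of
  kinship. Other "variance explained" definitions exist; this one is the
  package's documented choice.

## Known limitations

* Mixed sister/nonsister groups, partial male dispersal, limited female
  dispersal, and familiarity-only discrimination are out of scope.
* The simulator uses one group size per run; group-size mixtures (and the
  harmonic-mean-ν predictions) are checked analytically, not by
  simulation.
* The pedigree estimator's truncation depth trades bias (geometric, small)
  against cost (exponential); depths much beyond ~12 are impractical for
  routine in-run measurement.
* Re-analysis of the archived experimental dataset requires that file; the
  ingestion path (`read_brood_csv` with a column map) and the estimator
  pipeline are in place, and tests exercise them on synthetic stand-ins.
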