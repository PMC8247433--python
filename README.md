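# foundress

Sex allocation under local mate competition (LMC) with facultative
adjustment to co-foundress number and kinship.

In many parasitoid wasps and other insects with structured mating, a few
mated females ("foundresses") lay their broods on a shared patch; the
offspring mate among themselves and only mated daughters disperse.
Competition among related males then favours female-biased sex ratios —
Hamilton's classic result that a female who shares a patch with *n* − 1
unrelated co-foundresses should allocate a proportion (*n* − 1)/(2*n*) of
her reproduction to sons.  Some wasps (e.g. *Goniozus* bethylids) go
further: they discriminate kin, and broods produced alongside sister
co-foundresses are more female-biased than broods produced alongside
unrelated ones.  This package implements the inclusive-fitness theory for
that situation and the tools to confront it with brood-level data.

## The model

A focal foundress in a group of *n* values the mating group at

```
H = N_d p_d v_f + N_f p_f v_f
    + (N_d + N_f) (N_s / (N_s + N_m)) p_s v_m
    + (N_d + N_f) (N_m / (N_s + N_m)) p_m v_m
```

where *N_d*, *N_s* (*N_f*, *N_m*) are her own (her co-foundresses')
daughters and sons, *p_d*, *p_s*, *p_f*, *p_m* her consanguinities to those
four classes, and *v_f*, *v_m* the reproductive values of a mated female's
eggs and of the sperm fertilizing them.  Setting the marginal inclusive-
fitness effect of a small deviation in her allocation to zero gives the
unbeatable (ESS) allocation to sons

```
z* = (n − 1)(p_s − p_m) v_m / (n (p_d v_f + p_s v_m))
   = ½ · R · P        (Frank's factorization)
```

which specializes, by ploidy (D/H) and co-foundress kinship (U = unrelated,
S = sisters), to

| case | z* |
|------|----|
| D,U | (n−1)/(2n) |
| D,S | (n−1)(1−f) / (4n(1+3f)) |
| H,U | (n−1)(1+f) / (2n(1+2f)) |
| H,S | (n−1)(1−f) / (8n(1+2f)) |

with *f* the female's "inbredness" (the consanguinity of her parents).  At
demographic equilibrium *f* = 1/(4*n* − 3) under constant group size, or
1/(4*ν* − 3) with *ν* the female-weighted harmonic-mean group size.

The package provides:

* `foundress.kin` — the closed forms, the general solver, consanguinities,
  reproductive values, the fitness function *H* and its marginal effect,
  Frank's ½·R·P decomposition (exact rational arithmetic for exact inputs);
* `foundress.simulate` — an individual-based evolutionary simulation
  (haplo- and diplodiploid, optional facultative sister-group locus) with a
  pedigree-recursion estimator of inbredness, used as an independent check
  that the closed forms really are the evolutionary attractors;
* `foundress.broods` — a synthetic generator of brood-level sex-ratio
  datasets shaped like a foundress-number × kinship experiment;
* `foundress.fit` — the analysis pipeline: unweighted logistic regressions
  of brood sex ratio on foundress number, a sums-of-squares grid search
  over candidate *f*, and variance-explained comparison against the classic
  haplodiploid LMC prediction;
* a `foundress` command-line interface (`predict`, `simulate`, `generate`,
  `fit`).

## Worked example

Predictions for two foundresses under haplodiploidy, with every group in
the population having two foundresses (so f = 1/(4·2−3) = 0.2):

```
$ foundress predict --mode H --kinship U --n 2 --equal-groups
z* = 3/14 = 0.214286
formula: z* = (n-1)(1+f)/(2n(1+2f))  (mode=haplodiploid, kinship=unrelated, n=2, f=0.200000)
Frank decomposition: 1/2 * R * P with R=0.857143, P=0.500000, product=0.214286
```

A fifth of reproduction goes to sons: the inheritance asymmetry of
haplodiploidy (R < 1, daughters are the more valuable sex) and the half-sib
structure of the mating group (P = ½) both pull below Fisher's ½.  With
sister co-foundresses and complete outbreeding the bias is four times
stronger:

```
$ foundress predict --mode H --kinship S --n 2 --f 0
z* = 0.062500
formula: z* = (n-1)(1-f)/(8n(1+2f))  (mode=haplodiploid, kinship=sisters, n=2, f=0.000000)
Frank decomposition: 1/2 * R * P with R=1.000000, P=0.125000, product=0.062500
```

Generate a synthetic 123-brood dataset (shaped like the *Goniozus*
experiment: foundress groups of 1, 2, 4 and 8, sister and nonsister arms,
one large outlier brood) and run the fitting pipeline on it:

```
$ foundress --seed 5 --out broods.csv generate
123 broods written to broods.csv
$ foundress fit broods.csv
{
  "n_broods": 123,
  "logistic_nonsisters": {"slope": 0.136, "intercept": -1.446, ...},
  "logistic_sisters":    {"slope": 0.129, "intercept": -2.497, ...},
  "fit_all": {"best_f": 0.0, "prop_explained_at_best_f": 0.509,
              "better_than_mean_up_to_f": 0.73, ...},
  "vs_hamilton_all": {"prop_explained_vs_hamilton": 0.642, ...},
  ...
}
```

(Output abridged; numbers are for this seed.)  The grid search picks the
inbredness that minimizes the sum of squared brood-level residuals from
the kinship-aware predictions; `prop_explained` is (SST − SSE)/SST, and
`prop_explained_vs_hamilton` is the proportional SSE reduction relative to
applying the classic haplodiploid prediction z = (n−1)(2n−1)/(n(4n−1)) to
every brood regardless of kinship.

To re-analyse an archived brood table with different column names, pass a
column mapping to `foundress.read_brood_csv` (see its docstring); sister
and nonsister arms are fitted with each brood weighted equally regardless
of size.

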