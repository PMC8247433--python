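"""Individual-based evolutionary simulation of sex allocation under LMC.

The simulator is an independent check on the closed-form theory in
:mod:`foundress.kin`: a population of ``G`` mating groups, each founded by
``n`` mated females, evolves a continuous sex-allocation strategy under
mutation, drift and selection.  Each generation:

1. every foundress produces ``N_off`` offspring, each male with probability
   equal to the mother's expressed strategy (maternal control, additive
   alleles, stochastic sex determination);
2. offspring mate at random within their natal group (each daughter mates
   one male drawn uniformly from the group's males; males may mate many
   times); groups that produced no males leave only unmated daughters;
3. mated daughters disperse: the next generation's ``n * G`` foundresses are
   drawn uniformly without replacement from the pool of mated daughters and
   placed into fresh groups at random — or, with probability
   ``sister_group_prob`` per group, a whole group is formed from ``n``
   daughters of a single mother (a sister cohort);
4. each transmitted allele mutates with probability ``mu`` by a reflected
   Gaussian step of scale ``sigma_mu``.

Haplodiploid transmission: males develop from unfertilized eggs and carry a
single maternal allele per locus; daughters carry one maternal and one
paternal allele.  Diplodiploid males are diploid and transmit a random
allele per sperm.  Males are not stored as persistent individuals: a mating
draws a male uniformly from the group's male brood (weighting mothers by
their son production, which is where selection on male function acts) and
samples his gametes from his mother's stored genotypes at that point.  In
the analytic model the chance that two females mate the same male vanishes
as N grows large, so this is the matching idealization.

Inbredness is estimated from the recorded pedigree: for each foundress, the
coancestry of her mother and father is computed by exact recursive descent
through the stored parent arrays, truncated at a configurable depth with
founders assumed unrelated and non-inbred.  The truncation error contracts
by a factor 3/(4n) per generation and is negligible at the default depth.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Tuple

import numpy as np

from .kin import Ploidy

logger = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "SimResult",
    "Population",
    "SimulationError",
    "run_simulation",
    "run_replicates",
    "pedigree_consanguinity",
    "conditional_ess_check",
]


class SimulationError(RuntimeError):
    """The configured life cycle could not be completed (e.g. too few mated
    daughters to found the next generation, after bounded retries)."""


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one simulation run.

    Parameters
    ----------
    mode
        Genetic system, diplodiploid or haplodiploid.
    n
        Foundresses per mating group.
    G
        Groups per generation (population of ``n * G`` foundresses).
    N_off
        Offspring per foundress per generation.
    mu, sigma_mu
        Per-allele, per-transmission mutation probability and the scale of
        the reflected Gaussian mutation step.
    generations, burn_in
        Total generations simulated and the number discarded before
        averaging.
    seed
        Seed for all randomness in the run.
    sister_group_prob
        Probability that a group is founded as a sister cohort.
    conditional
        If true, a second strategy locus is carried and expressed only in
        sister groups (facultative kin-discriminating allocation).
    z_init, sperm_init
        Initial allele value for female-carried and mate-carried alleles.
    neutral_z
        If set, offspring sex is drawn at this fixed ratio regardless of
        genotype — selection on the strategy loci is switched off.
    pedigree_depth, f_sample, f_interval
        Truncation depth, per-measurement sample size, and generation
        spacing for pedigree inbredness estimates.
    """

    mode: Ploidy
    n: int
    G: int = 500
    N_off: int = 10_000
    mu: float = 2e-3
    sigma_mu: float = 0.05
    generations: int = 5000
    burn_in: int = 2000
    seed: int = 0
    sister_group_prob: float = 0.0
    conditional: bool = False
    z_init: float = 0.3
    sperm_init: Optional[float] = None
    neutral_z: Optional[float] = None
    pedigree_depth: int = 8
    f_sample: int = 100
    f_interval: int = 100
    max_retries: int = 5

    def __post_init__(self) -> None:
        object.__setattr__(self, "mode", Ploidy.coerce(self.mode))
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.G < 1:
            raise ValueError("G must be >= 1")
        if not (0 <= self.mu <= 1):
            raise ValueError("mu must lie in [0, 1]")
        if not (0 <= self.sister_group_prob <= 1):
            raise ValueError("sister_group_prob must lie in [0, 1]")
        if not (self.generations > self.burn_in >= 0):
            raise ValueError("need generations > burn_in >= 0")
        if self.N_off < 1:
            raise ValueError("N_off must be >= 1")
        if self.pedigree_depth < 1:
            raise ValueError("pedigree_depth must be >= 1")


@dataclass
class Population:
    """Final state of a run: genotypes plus the retained pedigree window.

    ``pedigree_M[k][j]`` is the index (into generation ``k-1`` of the window)
    of the mother of foundress ``j`` of window generation ``k``;
    ``pedigree_Mm[k][j]`` is the index of the mother of that foundress's
    mate.  ``window[0]`` is the oldest retained generation; individuals one
    step older are founders, assumed unrelated and outbred.
    """

    mode: Ploidy
    n: int
    female_alleles: np.ndarray  # (F, 2) z-locus alleles of foundresses
    mate_alleles: np.ndarray  # (F,) haplodiploid or (F, 2) diplodiploid
    pedigree_M: List[np.ndarray]
    pedigree_Mm: List[np.ndarray]
    female_alleles_sister: Optional[np.ndarray] = None
    mate_alleles_sister: Optional[np.ndarray] = None


@dataclass
class SimResult:
    """Post-burn-in summary of a run.

    Means carry Monte-Carlo standard errors from batch means over the
    post-burn-in series (strategy loci) or over repeated pedigree
    measurements (inbredness).
    """

    mean_z: float
    se_z: float
    f_hat: float
    se_f: float
    mean_z_sister: Optional[float] = None
    se_z_sister: Optional[float] = None
    config: Optional[SimConfig] = None
    trace_mean_z: Optional[np.ndarray] = None
    trace_mean_z_sister: Optional[np.ndarray] = None
    f_measurements: Optional[List[Tuple[int, float]]] = None
    population: Optional[Population] = None
    retries_used: int = 0


# ---------------------------------------------------------------------------
# Pedigree coancestry (exact truncated recursion)
# ---------------------------------------------------------------------------

def _coancestry(
    x: Tuple[int, int, int],
    y: Tuple[int, int, int],
    M: List[np.ndarray],
    Mm: List[np.ndarray],
    haplo: bool,
    memo: Dict[Tuple, float],
) -> float:
    """Coancestry of individuals x, y encoded as (level, kind, index).

    kind 0 = foundress, kind 1 = her mate.  Level 0 individuals are
    founders: unrelated to everyone else and non-inbred.  ``M[g-1]`` /
    ``Mm[g-1]`` give the level-(g-1) mother indices for level-g foundresses
    and their mates.
    """
    if x == y:
        g, kind, j = x
        if kind == 1 and haplo:
            return 1.0  # haploid male: his one allele is IBD to itself
        if g == 0:
            return 0.5  # outbred diploid founder
        mom_idx = int(M[g - 1][j]) if kind == 0 else int(Mm[g - 1][j])
        mother = (g - 1, 0, mom_idx)
        father = (g - 1, 1, mom_idx)
        return 0.5 * (1.0 + _coancestry(mother, father, M, Mm, haplo, memo))

    key = (x, y) if x <= y else (y, x)
    hit = memo.get(key)
    if hit is not None:
        return hit

    # expand the individual in the later generation (never a descendant of
    # the other); at a tie expand the first
    if x[0] < y[0]:
        x, y = y, x
    g, kind, j = x
    if g == 0:
        val = 0.0  # two distinct founders
    else:
        mom_idx = int(M[g - 1][j]) if kind == 0 else int(Mm[g - 1][j])
        mother = (g - 1, 0, mom_idx)
        if kind == 1 and haplo:
            val = _coancestry(mother, y, M, Mm, haplo, memo)
        else:
            father = (g - 1, 1, mom_idx)
            val = 0.5 * (
                _coancestry(mother, y, M, Mm, haplo, memo)
                + _coancestry(father, y, M, Mm, haplo, memo)
            )
    memo[key] = val
    return val


def pedigree_consanguinity(
    population: Population,
    depth: int = 12,
    sample: Optional[np.ndarray] = None,
) -> float:
    """Mean inbredness of (a sample of) current foundresses.

    For each female, computes the coancestry of her two parents by recursive
    pedigree descent, truncated ``depth`` generations back with an
    unrelated-founder assumption; haplodiploid-aware (a male contributes his
    single maternal genome).  Returns the mean over the selected females.
    """
    stored = len(population.pedigree_M)
    if depth > stored:
        raise ValueError(f"depth {depth} exceeds stored pedigree window of {stored} generations")
    M = population.pedigree_M[stored - depth :]
    Mm = population.pedigree_Mm[stored - depth :]
    W = len(M)
    F = len(M[-1])
    idx = np.arange(F) if sample is None else np.asarray(sample)
    haplo = population.mode is Ploidy.HAPLODIPLOID
    memo: Dict[Tuple, float] = {}
    total = 0.0
    for j in idx:
        mom = int(M[-1][int(j)])
        mother = (W - 1, 0, mom)
        father = (W - 1, 1, mom)
        total += _coancestry(mother, father, M[:-1], Mm[:-1], haplo, memo)
    return total / len(idx)


# ---------------------------------------------------------------------------
# The generation step
# ---------------------------------------------------------------------------

def _mutate(alleles: np.ndarray, mu: float, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Mutate a 1-D array of transmitted alleles in place and return it.

    With probability ``mu`` per allele, add a Gaussian step of scale
    ``sigma``, reflect at the [0, 1] boundaries, and clip (clipping only
    matters for steps longer than the interval)."""
    hit = rng.random(alleles.shape) < mu
    k = int(hit.sum())
    if k:
        stepped = alleles[hit] + rng.normal(0.0, sigma, size=k)
        stepped = np.abs(stepped)
        stepped = np.where(stepped > 1.0, 2.0 - stepped, stepped)
        alleles[hit] = np.clip(stepped, 0.0, 1.0)
    return alleles


def _batch_se(series: np.ndarray, n_batches: int = 10) -> float:
    """Standard error of the series mean by batch means."""
    L = len(series)
    B = min(n_batches, L)
    if B < 2:
        return float("nan")
    cut = L - (L % B)
    batches = series[:cut].reshape(B, -1).mean(axis=1)
    return float(batches.std(ddof=1) / np.sqrt(B))


def run_simulation(config: SimConfig) -> SimResult:
    """Run the life cycle for ``config.generations`` generations.

    Deterministic given the config (bit-identical results for identical
    configs).  Raises :class:`SimulationError` if a generation cannot be
    completed after ``config.max_retries`` retries.
    """
    cfg = config
    haplo = cfg.mode is Ploidy.HAPLODIPLOID
    n, G = cfg.n, cfg.G
    F = n * G
    ss = np.random.SeedSequence(cfg.seed)
    rng, rng_measure = [np.random.default_rng(s) for s in ss.spawn(2)]

    sperm_init = cfg.z_init if cfg.sperm_init is None else cfg.sperm_init
    za = np.full((F, 2), float(cfg.z_init))
    sperm_a = np.full(F if haplo else (F, 2), float(sperm_init))
    if cfg.conditional:
        zb = np.full((F, 2), float(cfg.z_init))
        sperm_b = np.full(F if haplo else (F, 2), float(sperm_init))
    else:
        zb = sperm_b = None
    sister_flag = np.zeros(G, dtype=bool)

    window = max(12, cfg.pedigree_depth)
    ped_M: deque = deque(maxlen=window)
    ped_Mm: deque = deque(maxlen=window)

    trace_z = np.empty(cfg.generations)
    trace_zb = np.empty(cfg.generations) if cfg.conditional else None
    f_measurements: List[Tuple[int, float]] = []
    retries_used = 0

    group_of = np.arange(F) // n

    for gen in range(cfg.generations):
        trace_z[gen] = za.mean()
        if cfg.conditional:
            trace_zb[gen] = zb.mean()

        # pedigree inbredness measurement on the current foundresses
        if (
            gen >= cfg.burn_in
            and (gen - cfg.burn_in) % cfg.f_interval == 0
            and len(ped_M) >= cfg.pedigree_depth
        ):
            pop = Population(cfg.mode, n, za, sperm_a, list(ped_M), list(ped_Mm))
            k = min(cfg.f_sample, F)
            idx = rng_measure.choice(F, size=k, replace=False)
            f_measurements.append((gen, pedigree_consanguinity(pop, cfg.pedigree_depth, idx)))

        # expressed strategy under maternal control
        if cfg.neutral_z is not None:
            z_expr = np.full(F, float(cfg.neutral_z))
        else:
            z_expr = za.mean(axis=1)
            if cfg.conditional:
                in_sister = sister_flag[group_of]
                z_expr = np.where(in_sister, zb.mean(axis=1), z_expr)
        z_expr = np.clip(z_expr, 0.0, 1.0)

        for attempt in range(cfg.max_retries + 1):
            ok, state = _next_generation(cfg, rng, z_expr, za, sperm_a, zb, sperm_b)
            if ok:
                break
            retries_used += 1
        else:
            raise SimulationError(
                f"generation {gen}: could not assemble {F} mated daughters after "
                f"{cfg.max_retries} retries (all-female or extinct groups?)"
            )
        za, sperm_a, zb, sperm_b, sister_flag, M_new, Mm_new = state
        ped_M.append(M_new)
        ped_Mm.append(Mm_new)

    post = trace_z[cfg.burn_in :]
    mean_z = float(post.mean())
    se_z = _batch_se(post)
    if f_measurements:
        fs = np.array([v for _, v in f_measurements])
        f_hat = float(fs.mean())
        se_f = float(fs.std(ddof=1) / np.sqrt(len(fs))) if len(fs) > 1 else float("nan")
    else:
        f_hat, se_f = float("nan"), float("nan")

    result = SimResult(
        mean_z=mean_z,
        se_z=se_z,
        f_hat=f_hat,
        se_f=se_f,
        config=cfg,
        trace_mean_z=trace_z,
        f_measurements=f_measurements,
        population=Population(
            cfg.mode, n, za, sperm_a, list(ped_M), list(ped_Mm), zb, sperm_b
        ),
        retries_used=retries_used,
    )
    if cfg.conditional:
        post_b = trace_zb[cfg.burn_in :]
        result.mean_z_sister = float(post_b.mean())
        result.se_z_sister = _batch_se(post_b)
        result.trace_mean_z_sister = trace_zb
    return result


def _next_generation(cfg, rng, z_expr, za, sperm_a, zb, sperm_b):
    """One pass of reproduction, mating, dispersal; returns (ok, state)."""
    haplo = cfg.mode is Ploidy.HAPLODIPLOID
    n, G, N_off = cfg.n, cfg.G, cfg.N_off
    F = n * G

    # reproduction: sons per foundress; daughters are the remainder
    sons = rng.binomial(N_off, z_expr)
    daughters = N_off - sons
    males_per_group = sons.reshape(G, n).sum(axis=1)
    viable = males_per_group > 0  # male-less groups leave unmated daughters

    d_elig = np.where(viable[np.arange(F) // n], daughters, 0)

    # sister cohorts: whole groups formed from n daughters of one mother
    n_sister = 0
    if cfg.sister_group_prob > 0:
        n_sister = int(rng.binomial(G, cfg.sister_group_prob))
    d_pool = d_elig.copy()
    sister_mothers = np.empty(0, dtype=np.int64)
    if n_sister:
        candidates = np.flatnonzero(d_elig >= n)
        if len(candidates) < n_sister:
            return False, None
        sister_mothers = rng.choice(candidates, size=n_sister, replace=False)
        d_pool[sister_mothers] -= n
    n_random = F - n_sister * n
    if int(d_pool.sum()) < n_random:
        return False, None

    # uniform sample without replacement from the remaining daughter pool:
    # a multivariate hypergeometric draw of per-mother counts (cost is
    # independent of brood size), then a random placement into groups
    counts = rng.multivariate_hypergeometric(d_pool, n_random, method="marginals")
    random_mothers = rng.permutation(np.repeat(np.arange(F), counts))

    mo = np.concatenate([np.repeat(sister_mothers, n), random_mothers]).astype(np.int64)
    sister_flag_new = np.zeros(G, dtype=bool)
    sister_flag_new[:n_sister] = True

    # each selected daughter mates one male drawn uniformly from her natal
    # group's male brood; the male's mother is recovered by cumulative counts
    natal_group = mo // n
    cum_sons = np.cumsum(sons)
    group_starts = np.arange(G) * n
    offsets = np.where(group_starts > 0, cum_sons[group_starts - 1], 0)
    pick = rng.integers(0, males_per_group[natal_group])
    male_flat = offsets[natal_group] + pick
    mm = np.searchsorted(cum_sons, male_flat, side="right").astype(np.int64)

    def transmit(fem, spm):
        """Build daughter genotypes and their mates' genotypes for one locus."""
        # daughter: maternal gamete + paternal gamete (from mother's mate)
        maternal = _mutate(fem[mo, rng.integers(0, 2, size=F)].copy(), cfg.mu, cfg.sigma_mu, rng)
        if haplo:
            paternal = spm[mo].copy()
        else:
            paternal = spm[mo, rng.integers(0, 2, size=F)].copy()
        paternal = _mutate(paternal, cfg.mu, cfg.sigma_mu, rng)
        fem_new = np.stack([maternal, paternal], axis=1)
        # her mate: a son of foundress mm — haploid males carry a single
        # maternal allele; diploid males carry a maternal and a paternal one
        mate_maternal = _mutate(
            fem[mm, rng.integers(0, 2, size=F)].copy(), cfg.mu, cfg.sigma_mu, rng
        )
        if haplo:
            spm_new = mate_maternal
        else:
            mate_paternal = _mutate(
                spm[mm, rng.integers(0, 2, size=F)].copy(), cfg.mu, cfg.sigma_mu, rng
            )
            spm_new = np.stack([mate_maternal, mate_paternal], axis=1)
        return fem_new, spm_new

    za_new, sperm_a_new = transmit(za, sperm_a)
    if cfg.conditional:
        zb_new, sperm_b_new = transmit(zb, sperm_b)
    else:
        zb_new = sperm_b_new = None

    return True, (za_new, sperm_a_new, zb_new, sperm_b_new, sister_flag_new, mo, mm)


def run_replicates(config: SimConfig, n_replicates: int = 5) -> SimResult:
    """Average ``n_replicates`` independent runs of the same configuration.

    Strategy means wander slowly under mutation-drift-selection, so the
    within-run batch-mean standard error understates the uncertainty of a
    single run's time average.  Replicate runs with independent seeds
    (spawned from ``config.seed``) give an honest standard error: the
    reported SE is the standard deviation of replicate means over
    sqrt(n_replicates).  The returned ``population`` and traces come from
    the last replicate.
    """
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    seeds = [int(s.generate_state(1, dtype=np.uint64)[0] & 0x7FFFFFFF) for s in
             np.random.SeedSequence(config.seed).spawn(n_replicates)]
    results = [run_simulation(replace(config, seed=s)) for s in seeds]

    def pool(values):
        arr = np.array(values, dtype=float)
        return float(arr.mean()), float(arr.std(ddof=1) / np.sqrt(len(arr)))

    mean_z, se_z = pool([r.mean_z for r in results])
    f_hat, se_f = pool([r.f_hat for r in results])
    out = SimResult(
        mean_z=mean_z, se_z=se_z, f_hat=f_hat, se_f=se_f,
        config=config, trace_mean_z=results[-1].trace_mean_z,
        f_measurements=results[-1].f_measurements,
        population=results[-1].population,
        retries_used=sum(r.retries_used for r in results),
    )
    if config.conditional:
        out.mean_z_sister, out.se_z_sister = pool([r.mean_z_sister for r in results])
        out.trace_mean_z_sister = results[-1].trace_mean_z_sister
    return out


def conditional_ess_check(config: SimConfig) -> SimResult:
    """Run a conditional-strategy simulation suitable for checking that the
    sister-expressed locus converges toward the sister-group optimum.

    Requires ``conditional=True`` and a small sister-group probability
    (selection on the sister locus is of that order, so runs must be long).
    """
    if not config.conditional:
        raise ValueError("conditional_ess_check requires conditional=True")
    if not (0 < config.sister_group_prob <= 0.05):
        raise ValueError(
            "conditional_ess_check expects 0 < sister_group_prob <= 0.05; "
            "larger values leave the analytic model's rare-sister regime"
        )
    return run_simulation(config)
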