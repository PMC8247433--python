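"""Inclusive-fitness theory of sex allocation under local mate competition (LMC).

A focal foundress shares a discrete mating patch with ``n - 1`` co-foundresses,
each contributing ``N`` offspring; offspring mate at random within the patch,
males die, and mated daughters disperse to found new patches.  The focal
female's unbeatable (unbeatable = uninvadable by small deviations, the ESS)
proportional allocation to sons is

    z* = (n - 1) (p_s - p_m) v_m / (n (p_d v_f + p_s v_m))

where ``p_d, p_s, p_f, p_m`` are her consanguinities to her own daughters and
sons and to her co-foundresses' daughters and sons, and ``v_f, v_m`` are the
class reproductive values of a mated female's eggs and of the sperm that
fertilize them.  The same quantity factorizes as Frank's ``(1/2) * R * P``:
the rarer-sex half, an inheritance-asymmetry coefficient R, and Wright's
index of panmixia P as assessed by the focal female.

All consanguinities depend on the focal female's "inbredness" f — the
consanguinity of her own parents — which at demographic equilibrium equals
``1/(4n - 3)`` for constant group size n, or ``1/(4*nu - 3)`` where nu is the
(female-weighted) harmonic-mean foundress number when group size varies.

Closed forms, by ploidy (D/H) and co-foundress kinship (U = unrelated,
S = sisters):

    z*_{D,U} = (n-1)/(2n)
    z*_{D,S} = (n-1)(1-f) / (4n(1+3f))
    z*_{H,U} = (n-1)(1+f) / (2n(1+2f))
    z*_{H,S} = (n-1)(1-f) / (8n(1+2f))

Arithmetic is exact (``fractions.Fraction``) whenever the inputs are exact
(ints / Fractions), and floating point otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from fractions import Fraction
from numbers import Rational
from typing import Iterable, Mapping, Optional, Tuple, Union

Number = Union[int, float, Fraction]

__all__ = [
    "Ploidy",
    "Kinship",
    "GroupContext",
    "KinCoefficients",
    "ReproductiveValues",
    "OffspringCounts",
    "SexAllocationStrategy",
    "Prediction",
    "FrankDecomposition",
    "equilibrium_inbredness",
    "harmonic_mean_foundress_number",
    "consanguinities",
    "reproductive_values",
    "inclusive_fitness",
    "marginal_effect",
    "unbeatable_z_general",
    "unbeatable_z_closed",
    "unbeatable_z_equal_groups",
    "unbeatable_z_variable_groups",
    "frank_decomposition",
    "DegenerateGroupError",
]


class Ploidy(str, Enum):
    """Mode of genetic inheritance."""

    DIPLODIPLOID = "diplodiploid"
    HAPLODIPLOID = "haplodiploid"

    @classmethod
    def coerce(cls, value: "Ploidy | str") -> "Ploidy":
        if isinstance(value, cls):
            return value
        key = str(value).strip().lower()
        aliases = {
            "d": cls.DIPLODIPLOID,
            "diplo": cls.DIPLODIPLOID,
            "diplodiploid": cls.DIPLODIPLOID,
            "h": cls.HAPLODIPLOID,
            "haplo": cls.HAPLODIPLOID,
            "haplodiploid": cls.HAPLODIPLOID,
        }
        try:
            return aliases[key]
        except KeyError:
            raise ValueError(f"unknown ploidy mode: {value!r}") from None


class Kinship(str, Enum):
    """Kinship of the focal female to her co-foundresses."""

    UNRELATED = "unrelated"
    SISTERS = "sisters"

    @classmethod
    def coerce(cls, value: "Kinship | str") -> "Kinship":
        if isinstance(value, cls):
            return value
        key = str(value).strip().lower()
        aliases = {
            "u": cls.UNRELATED,
            "unrelated": cls.UNRELATED,
            "nonsisters": cls.UNRELATED,
            "s": cls.SISTERS,
            "sisters": cls.SISTERS,
        }
        try:
            return aliases[key]
        except KeyError:
            raise ValueError(f"unknown kinship class: {value!r}") from None


def _check_unit_interval(x: Number, name: str) -> None:
    if not (0 <= x <= 1):
        raise ValueError(f"{name} must lie in [0, 1], got {x!r}")


@dataclass(frozen=True)
class GroupContext:
    """A focal female's demographic context.

    Parameters
    ----------
    n
        Number of foundresses in her group (>= 1, includes herself).
    f
        Her inbredness: consanguinity of her parents, in [0, 1].
    nu
        Harmonic-mean foundress number across the population (>= 1);
        optional, only meaningful for variable group sizes.
    N
        Offspring per foundress; the analytic model takes N large and all
        results are N-free, so this only matters for evaluating H itself.
    """

    n: int
    f: Number = 0
    nu: Optional[Number] = None
    N: Number = 1_000_000

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"foundress number n must be >= 1, got {self.n}")
        _check_unit_interval(self.f, "inbredness f")
        if self.nu is not None and self.nu < 1:
            raise ValueError(f"harmonic-mean foundress number nu must be >= 1, got {self.nu}")
        if self.N < 1:
            raise ValueError(f"per-foundress offspring count N must be >= 1, got {self.N}")


@dataclass(frozen=True)
class KinCoefficients:
    """Consanguinities of a focal foundress to the four offspring classes.

    ``p_d``/``p_s``: to her own daughters / sons; ``p_f``/``p_m``: to her
    co-foundresses' daughters / sons.  Each is a probability of identity by
    descent between homologous alleles.
    """

    p_d: Number
    p_s: Number
    p_f: Number
    p_m: Number

    def __post_init__(self) -> None:
        for name in ("p_d", "p_s", "p_f", "p_m"):
            _check_unit_interval(getattr(self, name), name)


@dataclass(frozen=True)
class ReproductiveValues:
    """Class reproductive values: eggs of a mated female (v_f) and the sperm
    fertilizing them (v_m).  Only the ratio matters downstream."""

    v_f: Number
    v_m: Number

    def __post_init__(self) -> None:
        if self.v_f <= 0 or self.v_m <= 0:
            raise ValueError("reproductive values must be positive")


@dataclass(frozen=True)
class OffspringCounts:
    """Continuous offspring counts: focal daughters/sons (N_d, N_s) and
    co-foundress daughters/sons (N_f, N_m)."""

    N_d: Number
    N_s: Number
    N_f: Number
    N_m: Number

    def __post_init__(self) -> None:
        for name in ("N_d", "N_s", "N_f", "N_m"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass(frozen=True)
class SexAllocationStrategy:
    """Resident allocation z to sons, plus the focal deviation delta."""

    z: Number
    delta: Number = 0

    def __post_init__(self) -> None:
        _check_unit_interval(self.z, "z")
        if not (0 <= self.z + self.delta <= 1):
            raise ValueError(f"z + delta must lie in [0, 1], got {self.z + self.delta!r}")


@dataclass(frozen=True)
class Prediction:
    """An unbeatable sex allocation z*, with its provenance."""

    z_star: Number
    mode: Optional[Ploidy] = None
    kinship: Optional[Kinship] = None
    context: Optional[GroupContext] = None

    def __post_init__(self) -> None:
        if not (0 <= self.z_star < 1):
            raise ValueError(f"z_star must lie in [0, 1), got {self.z_star!r}")

    def __float__(self) -> float:
        return float(self.z_star)


@dataclass(frozen=True)
class FrankDecomposition:
    """Frank's factorization z* = (1/2) * R * P."""

    half: Number
    R: Number
    P: Number

    @property
    def product(self) -> Number:
        return self.half * self.R * self.P


class DegenerateGroupError(ValueError):
    """The mating group contains no males, so mating shares are undefined."""


# ---------------------------------------------------------------------------
# Inbredness and group-size statistics
# ---------------------------------------------------------------------------

def equilibrium_inbredness(n_or_nu: Number) -> Number:
    """Equilibrium inbredness f = 1/(4x - 3) for (harmonic-mean) group size x.

    Exact when the input is exact: ``equilibrium_inbredness(2) == Fraction(1, 5)``.
    """
    x = n_or_nu
    if x < 1:
        raise ValueError(f"group size must be >= 1, got {x!r}")
    if isinstance(x, Rational):
        return Fraction(1, 1) / (4 * Fraction(x) - 3)
    return 1.0 / (4.0 * x - 3.0)


def harmonic_mean_foundress_number(
    group_size_distribution: Union[Mapping[Number, Number], Iterable[Tuple[Number, Number]]],
) -> Number:
    """Female-weighted harmonic mean of mothers' foundress-group sizes.

    ``group_size_distribution`` maps group size n to the frequency q(n) of
    such groups.  Because a size-n group contains n foundresses, a randomly
    chosen female descends from a size-n group with probability proportional
    to ``n * q(n)``; the harmonic mean over females is then

        nu = [sum_n w(n)/n]^(-1),   w(n) = n q(n) / sum_m m q(m)

    which simplifies to ``sum n q(n) / sum q(n)`` — the group-frequency
    arithmetic mean.  Both forms are computed from the same weights here.
    """
    if isinstance(group_size_distribution, Mapping):
        items = list(group_size_distribution.items())
    else:
        items = list(group_size_distribution)
        sizes = [s for s, _ in items]
        if len(sizes) != len(set(sizes)):
            raise ValueError("duplicate group sizes in distribution")
    if not items:
        raise ValueError("empty group-size distribution")
    for size, freq in items:
        if size < 1:
            raise ValueError(f"group size must be >= 1, got {size!r}")
        if freq < 0:
            raise ValueError(f"frequency must be >= 0, got {freq!r}")
    total = sum(freq for _, freq in items)
    if total == 0:
        raise ValueError("all-zero group-size distribution")
    weighted = sum(size * freq for size, freq in items)
    if all(isinstance(v, Rational) for pair in items for v in pair):
        return Fraction(weighted) / Fraction(total)
    return weighted / total


# ---------------------------------------------------------------------------
# Consanguinities and reproductive values
# ---------------------------------------------------------------------------

def consanguinities(
    mode: Ploidy | str,
    kinship: Kinship | str,
    f: Number,
    p_f_sisters_haplodiploid: Number = 0,
) -> KinCoefficients:
    """Consanguinity coefficients for a focal foundress with inbredness f.

    Diplodiploid: p_d = p_s = (1+3f)/4; sisters' sons p_m = (1+7f)/8.
    Haplodiploid: p_d = (1+3f)/4, p_s = (1+f)/2; sisters' sons p_m = (3+5f)/8.
    Unrelated co-foundresses have p_f = p_m = 0.  For diplodiploid sisters
    p_f = p_m (niece and nephew are symmetric under diplodiploidy).  For
    haplodiploid sisters p_f cancels from the marginal fitness effect and is
    taken as an explicit input (default 0); any value in [0, 1] yields the
    same z*.
    """
    mode = Ploidy.coerce(mode)
    kinship = Kinship.coerce(kinship)
    _check_unit_interval(f, "inbredness f")
    exact = isinstance(f, Rational)
    f = Fraction(f) if exact else f
    one = Fraction(1) if exact else 1.0

    if mode is Ploidy.DIPLODIPLOID:
        p_d = (one + 3 * f) / 4
        p_s = p_d
        if kinship is Kinship.UNRELATED:
            p_f = p_m = 0 * one
        else:
            p_m = (one + 7 * f) / 8
            p_f = p_m
    else:
        p_d = (one + 3 * f) / 4
        p_s = (one + f) / 2
        if kinship is Kinship.UNRELATED:
            p_f = p_m = 0 * one
        else:
            p_m = (3 * one + 5 * f) / 8
            p_f = p_f_sisters_haplodiploid
    return KinCoefficients(p_d=p_d, p_s=p_s, p_f=p_f, p_m=p_m)


def reproductive_values(mode: Ploidy | str) -> ReproductiveValues:
    """Class reproductive values, normalized to v_m = 1.

    v_f = v_m under diplodiploidy; v_f = 2 v_m under haplodiploidy (a
    haploid father contributes to daughters only).
    """
    mode = Ploidy.coerce(mode)
    if mode is Ploidy.DIPLODIPLOID:
        return ReproductiveValues(v_f=Fraction(1), v_m=Fraction(1))
    return ReproductiveValues(v_f=Fraction(2), v_m=Fraction(1))


# ---------------------------------------------------------------------------
# The inclusive-fitness function H and its stationarity
# ---------------------------------------------------------------------------

def inclusive_fitness(
    strategy: SexAllocationStrategy,
    context: GroupContext,
    kin: KinCoefficients,
    rv: ReproductiveValues,
    z_others: Number,
) -> Number:
    """Total inclusive-fitness value H the focal female places on the group.

    H = N_d p_d v_f + N_f p_f v_f
        + (N_d + N_f) * (N_s / (N_s + N_m)) * p_s v_m
        + (N_d + N_f) * (N_m / (N_s + N_m)) * p_m v_m

    with N_d = N(1-z-delta), N_s = N(z+delta) for the focal female and
    N_f = (n-1)N(1-z_others), N_m = (n-1)N z_others for her co-foundresses.
    Daughter terms count transmitted eggs; the mating-share ratios allot the
    group's (N_d + N_f) matings to focal vs co-foundress sons.
    """
    _check_unit_interval(z_others, "z_others")
    n, N = context.n, context.N
    z, delta = strategy.z, strategy.delta
    N_d = N * (1 - z - delta)
    N_s = N * (z + delta)
    N_f = (n - 1) * N * (1 - z_others)
    N_m = (n - 1) * N * z_others
    males = N_s + N_m
    if males == 0:
        raise DegenerateGroupError("no males in the mating group; mating shares undefined")
    daughters = N_d + N_f
    return (
        N_d * kin.p_d * rv.v_f
        + N_f * kin.p_f * rv.v_f
        + daughters * (N_s / males) * kin.p_s * rv.v_m
        + daughters * (N_m / males) * kin.p_m * rv.v_m
    )


def marginal_effect(
    z: Number,
    context: GroupContext,
    kin: KinCoefficients,
    rv: ReproductiveValues,
    step: Optional[float] = None,
) -> float:
    """dH/d(delta) at delta = 0, all co-foundresses playing z.

    Central finite difference with step ``1e-6 * max(z, 1-z)`` by default,
    falling back to a one-sided difference at the boundary of [0, 1].
    Positive for z < z*, zero at z*, negative for z > z*.
    """
    z = float(z)
    _check_unit_interval(z, "z")
    h = step if step is not None else 1e-6 * max(z, 1.0 - z, 1e-9)

    def H(delta: float) -> float:
        return float(
            inclusive_fitness(SexAllocationStrategy(z=z, delta=delta), context, kin, rv, z_others=z)
        )

    lo, hi = -h, h
    if z + lo < 0:
        lo = 0.0
    if z + hi > 1:
        hi = 0.0
    if lo == hi:
        raise ValueError("cannot form a finite-difference stencil at this z")
    return (H(hi) - H(lo)) / (hi - lo)


# ---------------------------------------------------------------------------
# Unbeatable strategies
# ---------------------------------------------------------------------------

def unbeatable_z_general(
    n: int,
    kin: KinCoefficients,
    rv: ReproductiveValues,
    mode: Optional[Ploidy] = None,
    kinship: Optional[Kinship] = None,
    context: Optional[GroupContext] = None,
) -> Prediction:
    """General unbeatable allocation from arbitrary kin coefficients:

    z* = (n - 1)(p_s - p_m) v_m / (n (p_d v_f + p_s v_m)).
    """
    if n < 1:
        raise ValueError(f"foundress number n must be >= 1, got {n}")
    if kin.p_s < kin.p_m:
        raise ValueError(
            "p_s < p_m lies outside the model's scope (would give negative allocation)"
        )
    num = (n - 1) * (kin.p_s - kin.p_m) * rv.v_m
    den = n * (kin.p_d * rv.v_f + kin.p_s * rv.v_m)
    z = num / den
    return Prediction(z_star=z, mode=mode, kinship=kinship, context=context)


def unbeatable_z_closed(
    mode: Ploidy | str, kinship: Kinship | str, n: int, f: Number
) -> Prediction:
    """Closed-form unbeatable allocation for the four (ploidy, kinship) cases."""
    mode = Ploidy.coerce(mode)
    kinship = Kinship.coerce(kinship)
    if n < 1:
        raise ValueError(f"foundress number n must be >= 1, got {n}")
    _check_unit_interval(f, "inbredness f")
    exact = isinstance(f, Rational)
    f = Fraction(f) if exact else float(f)
    one = Fraction(1) if exact else 1.0

    if mode is Ploidy.DIPLODIPLOID and kinship is Kinship.UNRELATED:
        z = (n - one) / (2 * n)
    elif mode is Ploidy.DIPLODIPLOID:
        z = (n - one) * (1 - f) / (4 * n * (1 + 3 * f))
    elif kinship is Kinship.UNRELATED:
        z = (n - one) * (1 + f) / (2 * n * (1 + 2 * f))
    else:
        z = (n - one) * (1 - f) / (8 * n * (1 + 2 * f))
    ctx = GroupContext(n=n, f=f)
    return Prediction(z_star=z, mode=mode, kinship=kinship, context=ctx)


def unbeatable_z_equal_groups(mode: Ploidy | str, kinship: Kinship | str, n: int) -> Prediction:
    """z* when every group in the population has exactly n foundresses.

    Substitutes the equilibrium inbredness f = 1/(4n - 3) into the closed
    forms; algebraically equal to the reduced expressions
    (n-1)^2/(4n^2) [D,S], (n-1)(2n-1)/(n(4n-1)) [H,U], (n-1)^2/(2n(4n-1)) [H,S].
    """
    return unbeatable_z_closed(mode, kinship, n, equilibrium_inbredness(n))


def unbeatable_z_variable_groups(
    mode: Ploidy | str, kinship: Kinship | str, n: int, nu: Number
) -> Prediction:
    """z* for local group size n in a population with harmonic-mean size nu.

    Substitutes f = 1/(4 nu - 3); reduces to the equal-group case at nu = n.
    """
    if nu < 1:
        raise ValueError(f"harmonic-mean foundress number nu must be >= 1, got {nu!r}")
    return unbeatable_z_closed(mode, kinship, n, equilibrium_inbredness(nu))


def frank_decomposition(
    n: int, kin: KinCoefficients, rv: ReproductiveValues
) -> FrankDecomposition:
    """Frank's factorization of z* into (1/2) * R * P.

    R = 2 p_s v_m / (p_d v_f + p_s v_m) measures inheritance asymmetry
    between the sexes; P = ((n-1)/n)(p_s - p_m)/p_s is the index of panmixia
    as assessed by the focal female.
    """
    if n < 1:
        raise ValueError(f"foundress number n must be >= 1, got {n}")
    if kin.p_s == 0:
        raise ValueError("p_s = 0: Frank decomposition undefined")
    exact = all(isinstance(v, Rational) for v in (kin.p_d, kin.p_s, kin.p_m, rv.v_f, rv.v_m))
    half = Fraction(1, 2) if exact else 0.5
    R = 2 * kin.p_s * rv.v_m / (kin.p_d * rv.v_f + kin.p_s * rv.v_m)
    if exact:
        P = Fraction(n - 1, n) * (kin.p_s - kin.p_m) / kin.p_s
    else:
        P = ((n - 1) / n) * (kin.p_s - kin.p_m) / kin.p_s
    return FrankDecomposition(half=half, R=R, P=P)
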