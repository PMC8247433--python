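"""Synthetic brood-level sex-ratio datasets.

Generates datasets with the structure of a foundress-number x kinship
experiment on a gregarious parasitoid (single foundresses, plus
multi-foundress groups of sisters or of unrelated females, with brood-level
male and female counts): per-brood male counts are binomial around a
treatment-dependent true sex ratio, brood sizes vary around a per-foundress
productivity, an optional large outlier brood with an aberrant sex ratio can
be appended, and single-foundress broods are generated once and shared
between the two kinship arms (both regression arms include them).

The "truth" behind the generated sex ratios is either model-based (the
closed-form LMC predictions at a chosen ploidy and inbredness) or
curve-based (a logistic curve in foundress number per treatment arm).
Default replicate counts and brood sizes are synthetic stand-ins chosen to
mirror the published experiment's shape (~123 broods over foundress groups
of 1-8); the real per-cell design lives in the archived dataset, not here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Literal, Optional, Tuple

import numpy as np

from .kin import Kinship, Ploidy, unbeatable_z_closed

__all__ = [
    "BroodRecord",
    "CurveTruth",
    "ModelTruth",
    "OutlierSpec",
    "GeneratorDesign",
    "generate_dataset",
]

KINSHIP_LEVELS = ("single", "sisters", "nonsisters")


@dataclass(frozen=True)
class BroodRecord:
    """One brood: foundress number, kinship treatment, and sex counts."""

    foundress_number: int
    kinship: str  # 'single' | 'sisters' | 'nonsisters'
    males: int
    females: int

    def __post_init__(self) -> None:
        if self.kinship not in KINSHIP_LEVELS:
            raise ValueError(f"kinship must be one of {KINSHIP_LEVELS}, got {self.kinship!r}")
        if not (1 <= self.foundress_number):
            raise ValueError(f"foundress_number must be >= 1, got {self.foundress_number}")
        if (self.kinship == "single") != (self.foundress_number == 1):
            raise ValueError("kinship 'single' if and only if foundress_number == 1")
        if self.males < 0 or self.females < 0:
            raise ValueError("male and female counts must be nonnegative")
        if self.males + self.females < 1:
            raise ValueError("brood must contain at least one offspring")

    @property
    def size(self) -> int:
        return self.males + self.females

    @property
    def sex_ratio(self) -> float:
        """Proportion of the brood that is male."""
        return self.males / (self.males + self.females)


@dataclass(frozen=True)
class CurveTruth:
    """Logistic truth: z(n) = 1/(1 + exp(-(slope * n + intercept))) per arm.

    Defaults are the unweighted maximum-likelihood fits to the published
    brood data (nonsister and sister arms).  Single-foundress broods use the
    ``single`` curve, defaulting to the sister arm's, which matches the
    observed single-foundress sex ratio (~0.1) more closely.
    """

    nonsisters: Tuple[float, float] = (0.084, -1.132)  # (slope, intercept)
    sisters: Tuple[float, float] = (0.071, -2.072)
    single: Optional[Tuple[float, float]] = None

    def z(self, n: int, kinship: str) -> float:
        if kinship == "single":
            slope, intercept = self.single if self.single is not None else self.sisters
        elif kinship == "sisters":
            slope, intercept = self.sisters
        else:
            slope, intercept = self.nonsisters
        return 1.0 / (1.0 + math.exp(-(slope * n + intercept)))


@dataclass(frozen=True)
class ModelTruth:
    """Closed-form truth: z(n) from the LMC predictions at (mode, f)."""

    mode: Ploidy = Ploidy.HAPLODIPLOID
    f: float = 0.0

    def z(self, n: int, kinship: str) -> float:
        kin = Kinship.SISTERS if kinship == "sisters" else Kinship.UNRELATED
        return float(unbeatable_z_closed(self.mode, kin, n, float(self.f)).z_star)


@dataclass(frozen=True)
class OutlierSpec:
    """A single large brood with an aberrant sex ratio (synthetic stand-in
    for the influential outlier brood of the original experiment)."""

    foundress_number: int = 2
    kinship: str = "nonsisters"
    size: int = 76
    sex_ratio: float = 0.7


@dataclass(frozen=True)
class GeneratorDesign:
    """Design of a synthetic dataset.

    ``replicates`` maps (foundress_number, kinship) cells to brood counts;
    the default mirrors the published experiment's shape: 14 single-foundress
    broods plus 18 broods per multi-foundress cell over n in {2, 4, 8} and
    both kinship arms, plus the outlier — 123 broods in total.  ``mean_offspring`` is the
    per-foundress productivity (brood size is a zero-truncated Poisson sum
    over foundresses).  ``noise='none'`` replaces binomial sampling with
    males = round(z * size), for noiseless self-consistency checks.
    ``thinning`` optionally applies uniform random developmental mortality
    (off by default; a robustness switch, not part of the model).
    """

    replicates: Optional[Dict[Tuple[int, str], int]] = None
    mean_offspring: float = 10.0
    truth: object = field(default_factory=CurveTruth)
    outlier: Optional[OutlierSpec] = field(default_factory=OutlierSpec)
    noise: Literal["binomial", "none"] = "binomial"
    thinning: float = 0.0
    fixed_brood_size: Optional[int] = None
    seed: int = 0

    def cells(self) -> Dict[Tuple[int, str], int]:
        if self.replicates is not None:
            return dict(self.replicates)
        cells: Dict[Tuple[int, str], int] = {(1, "single"): 14}
        for n in (2, 4, 8):
            for kinship in ("sisters", "nonsisters"):
                cells[(n, kinship)] = 18
        return cells


def _brood_size(design: GeneratorDesign, n: int, rng: np.random.Generator) -> int:
    if design.fixed_brood_size is not None:
        return design.fixed_brood_size
    # sum over foundresses of zero-truncated Poisson productivities
    total = 0
    for _ in range(n):
        k = 0
        while k == 0:
            k = int(rng.poisson(design.mean_offspring))
        total += k
    return total


def generate_dataset(design: GeneratorDesign) -> List[BroodRecord]:
    """Generate a brood dataset; deterministic for a fixed design (seed).

    Single-foundress broods are generated once under the 'single' label and
    serve both kinship arms downstream.  Raises on an empty design.
    """
    cells = design.cells()
    if not cells or all(v == 0 for v in cells.values()):
        raise ValueError("empty generator design")
    for (n, kinship), count in cells.items():
        if count < 0:
            raise ValueError("replicate counts must be nonnegative")
        if kinship not in KINSHIP_LEVELS:
            raise ValueError(f"unknown kinship level {kinship!r}")
        if (kinship == "single") != (n == 1):
            raise ValueError("kinship 'single' if and only if foundress_number == 1")

    rng = np.random.default_rng(design.seed)
    records: List[BroodRecord] = []
    for (n, kinship) in sorted(cells):
        count = cells[(n, kinship)]
        z = design.truth.z(n, kinship)
        for _ in range(count):
            size = _brood_size(design, n, rng)
            if design.noise == "binomial":
                males = int(rng.binomial(size, z))
            else:
                males = int(round(z * size))
            females = size - males
            if design.thinning > 0:
                males = int(rng.binomial(males, 1.0 - design.thinning))
                females = int(rng.binomial(females, 1.0 - design.thinning))
                if males + females == 0:
                    females = 1  # a surviving brood is observed by definition
            records.append(BroodRecord(n, kinship, males, females))
    if design.outlier is not None:
        o = design.outlier
        males = int(round(o.size * o.sex_ratio))
        records.append(BroodRecord(o.foundress_number, o.kinship, males, o.size - males))
    return records
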