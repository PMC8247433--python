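"""Brood sex-ratio analysis: unweighted logistic fits, inbredness grid
search, and variance-explained model comparison.

The pipeline treats each brood as one observation with fractional response
s_i = males / (males + females):

* ``fit_logistic_unweighted`` maximizes the Bernoulli-form log-likelihood
  sum_i [s_i log pi_i + (1 - s_i) log(1 - pi_i)] with
  pi_i = logistic(slope * n_i + intercept).  Every brood is weighted
  equally regardless of its size, which de-emphasizes large broods relative
  to a count-weighted binomial fit.  Each regression arm pools the
  single-foundress broods with that arm's multi-foundress broods.

* ``sse_profile`` evaluates the haplodiploid LMC predictions over a grid of
  candidate inbredness values f: for each brood the predicted sex ratio is
  the nonsister closed form (single or nonsister broods) or the sister
  closed form (sister broods) at that brood's foundress number, and
  SSE(f) = sum_i (s_i - zhat_i(f))^2 is compared against
  SST = sum_i (s_i - mean(s))^2.

* ``compare_to_hamilton`` measures the SSE reduction of the kinship-aware
  model relative to the classic haplodiploid LMC prediction
  z = (n-1)(2n-1)/(n(4n-1)) applied to every brood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Literal, Optional, Sequence

import numpy as np

from .broods import BroodRecord
from .kin import Kinship, Ploidy, unbeatable_z_closed, unbeatable_z_equal_groups

__all__ = [
    "LogisticFit",
    "FitSummary",
    "ModelComparison",
    "fit_logistic_unweighted",
    "sse_profile",
    "compare_to_hamilton",
    "mean_vs_model_threshold",
    "predicted_sex_ratio",
    "default_f_grid",
]

Subset = Literal["all", "multifoundress_only"]


@dataclass(frozen=True)
class LogisticFit:
    """Unweighted logistic regression of brood sex ratio on foundress number."""

    slope: float
    intercept: float
    converged: bool
    n_broods: int

    def predict(self, n: np.ndarray | float) -> np.ndarray | float:
        return 1.0 / (1.0 + np.exp(-(self.slope * np.asarray(n, dtype=float) + self.intercept)))


@dataclass(frozen=True)
class FitSummary:
    """Sums-of-squares profile of the LMC model over candidate inbredness."""

    SST: float
    SSE_profile: Dict[float, float]
    best_f: float
    prop_explained: float  # (SST - SSE)/SST at best_f
    better_than_mean_up_to_f: Optional[float]
    subset: Subset


@dataclass(frozen=True)
class ModelComparison:
    """Kinship-aware model vs the classic haplodiploid LMC prediction."""

    SSE_model: float
    SSE_hamilton: float
    prop_explained_vs_hamilton: float
    subset: Subset


def default_f_grid(step: float = 0.01) -> np.ndarray:
    return np.round(np.arange(0.0, 1.0 + step / 2, step), 10)


def _subset_records(records: Sequence[BroodRecord], subset: Subset) -> List[BroodRecord]:
    if subset == "all":
        return list(records)
    if subset == "multifoundress_only":
        return [r for r in records if r.foundress_number > 1]
    raise ValueError(f"unknown subset {subset!r}")


def predicted_sex_ratio(
    record: BroodRecord, f: float, mode: Ploidy | str = Ploidy.HAPLODIPLOID
) -> float:
    """Model-predicted sex ratio for one brood at inbredness f.

    Sister broods use the sister closed form; single and nonsister broods
    use the unrelated one (at n = 1 all forms give 0).
    """
    kin = Kinship.SISTERS if record.kinship == "sisters" else Kinship.UNRELATED
    return float(unbeatable_z_closed(mode, kin, record.foundress_number, float(f)).z_star)


def fit_logistic_unweighted(
    records: Sequence[BroodRecord], arm: Literal["nonsisters", "sisters"]
) -> LogisticFit:
    """Fit sex ratio ~ foundress number for one kinship arm.

    The arm's data are its multi-foundress broods plus all single-foundress
    broods.  The fit maximizes the equal-weight Bernoulli-form likelihood of
    the fractional brood sex ratios (statsmodels GLM, binomial family, one
    observation per brood); the point estimates coincide with a
    quasi-binomial fit.  Requires >= 3 broods spanning >= 2 distinct
    foundress numbers.  Non-convergence or perfect separation is reported
    through ``converged`` rather than raised.
    """
    if arm not in ("nonsisters", "sisters"):
        raise ValueError(f"arm must be 'nonsisters' or 'sisters', got {arm!r}")
    sub = [r for r in records if r.kinship in ("single", arm)]
    ns = np.array([r.foundress_number for r in sub], dtype=float)
    if len(sub) < 3 or len(np.unique(ns)) < 2:
        raise ValueError("need >= 3 broods spanning >= 2 foundress numbers")
    s = np.array([r.sex_ratio for r in sub])

    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import DomainWarning, PerfectSeparationWarning

    X = sm.add_constant(ns)
    with warnings.catch_warnings():
        # fractional responses are intentional (quasi-binomial point estimates)
        warnings.simplefilter("ignore", DomainWarning)
        warnings.simplefilter("ignore", PerfectSeparationWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        model = sm.GLM(s, X, family=sm.families.Binomial())
        try:
            res = model.fit(maxiter=200)
            intercept, slope = (float(v) for v in np.asarray(res.params))
            converged = bool(res.converged and np.isfinite(slope) and np.isfinite(intercept))
        except Exception:  # perfect separation and kin: flagged, not raised
            intercept = slope = float("nan")
            converged = False
    return LogisticFit(slope=slope, intercept=intercept, converged=converged, n_broods=len(sub))


def _sse_at_f(
    records: Sequence[BroodRecord], f: float, mode: Ploidy | str
) -> float:
    return float(
        sum((r.sex_ratio - predicted_sex_ratio(r, f, mode)) ** 2 for r in records)
    )


def sse_profile(
    records: Sequence[BroodRecord],
    mode: Ploidy | str = Ploidy.HAPLODIPLOID,
    f_grid: Optional[Iterable[float]] = None,
    subset: Subset = "all",
) -> FitSummary:
    """Profile SSE(f) of the kinship-aware model over candidate inbredness.

    ``best_f`` is the grid argmin (smallest-f tie-break); ``SST`` uses the
    subset's own mean sex ratio.  Vectorized over the foundress-number x
    kinship cells present in the data.
    """
    mode = Ploidy.coerce(mode)
    sub = _subset_records(records, subset)
    if not sub:
        raise ValueError(f"no broods in subset {subset!r}")
    grid = default_f_grid() if f_grid is None else np.asarray(list(f_grid), dtype=float)
    if np.any((grid < 0) | (grid > 1)):
        raise ValueError("f grid must lie within [0, 1]")

    s = np.array([r.sex_ratio for r in sub])
    SST = float(((s - s.mean()) ** 2).sum())

    # group broods by (n, kinship-class) so each grid point costs O(cells)
    cells: Dict[tuple, List[float]] = {}
    for r in sub:
        kin = Kinship.SISTERS if r.kinship == "sisters" else Kinship.UNRELATED
        cells.setdefault((r.foundress_number, kin), []).append(r.sex_ratio)
    profile: Dict[float, float] = {}
    for f in grid:
        sse = 0.0
        for (n, kin), ratios in cells.items():
            zhat = float(unbeatable_z_closed(mode, kin, n, float(f)).z_star)
            arr = np.asarray(ratios)
            sse += float(((arr - zhat) ** 2).sum())
        profile[float(f)] = sse

    best_f = min(profile, key=lambda f: (profile[f], f))
    prop = (SST - profile[best_f]) / SST if SST > 0 else float("nan")
    passing = [f for f in sorted(profile) if profile[f] < SST]
    return FitSummary(
        SST=SST,
        SSE_profile=profile,
        best_f=best_f,
        prop_explained=prop,
        better_than_mean_up_to_f=max(passing) if passing else None,
        subset=subset,
    )


def compare_to_hamilton(
    records: Sequence[BroodRecord],
    f: float = 0.0,
    subset: Subset = "all",
    mode: Ploidy | str = Ploidy.HAPLODIPLOID,
) -> ModelComparison:
    """SSE reduction of the kinship-aware model over the classic prediction.

    The reference model applies the equal-group haplodiploid form
    z = (n-1)(2n-1)/(n(4n-1)) to every brood regardless of kinship; the
    kinship-aware model uses the closed forms at the supplied f.  The
    improvement is (SSE_hamilton - SSE_model) / SSE_hamilton.
    """
    sub = _subset_records(records, subset)
    if not sub:
        raise ValueError(f"no broods in subset {subset!r}")
    SSE_model = _sse_at_f(sub, f, mode)
    SSE_ham = float(
        sum(
            (
                r.sex_ratio
                - float(
                    unbeatable_z_equal_groups(
                        Ploidy.HAPLODIPLOID, Kinship.UNRELATED, r.foundress_number
                    ).z_star
                )
            )
            ** 2
            for r in sub
        )
    )
    if SSE_ham == 0:
        raise ValueError("reference model fits perfectly; comparison undefined")
    return ModelComparison(
        SSE_model=SSE_model,
        SSE_hamilton=SSE_ham,
        prop_explained_vs_hamilton=(SSE_ham - SSE_model) / SSE_ham,
        subset=subset,
    )


def mean_vs_model_threshold(
    records: Sequence[BroodRecord],
    f_grid: Optional[Iterable[float]] = None,
    subset: Subset = "all",
    mode: Ploidy | str = Ploidy.HAPLODIPLOID,
) -> Optional[float]:
    """Largest grid f at which the model outperforms the subset mean
    (SSE(f) < SST), scanning a 0.01-step grid by default; ``None`` if no
    grid value passes (e.g. SST = 0)."""
    summary = sse_profile(records, mode=mode, f_grid=f_grid, subset=subset)
    return summary.better_than_mean_up_to_f
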