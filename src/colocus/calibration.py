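"""Empirical calibration of the shared-causal-variant prior p12.

The colocalisation analysis is repeated on the same data over a grid of p12
values.  For each grid value, pairwise analyses with posterior evidence of
association with both traits (PP3 + PP4 above a threshold) contribute their
relative posterior support for colocalisation, PP4/(PP3 + PP4); the mean is
compared with the mean relative *prior* support, P4/(P3 + P4), over the same
pairs.  The chosen p12 is the grid value where posterior and prior
expectations agree most closely.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .core import ColocPriors, ColocResult, hypothesis_priors

__all__ = ["CalibrationResult", "prior_h4_fraction", "calibrate_p12", "DEFAULT_GRID"]

DEFAULT_GRID = (1e-7, 1e-6, 1e-5)
DEFAULT_INCLUSION_THRESHOLD = 0.8


@dataclass
class CalibrationResult:
    grid: list[float]
    prior_mean: dict[float, float]
    posterior_mean: dict[float, float]
    chosen_p12: float
    inclusion_threshold: float
    n_included: dict[float, int]
    #: per-pair curve table (p12, Q, prior_fraction, posterior_fraction)
    curves: pd.DataFrame = field(repr=False, default=None)

    @property
    def gaps(self) -> dict[float, float]:
        return {
            g: abs(self.posterior_mean[g] - self.prior_mean[g])
            for g in self.prior_mean
        }

    def to_dict(self) -> dict:
        return {
            "grid": list(self.grid),
            "chosen_p12": self.chosen_p12,
            "inclusion_threshold": self.inclusion_threshold,
            "prior_mean": {str(k): v for k, v in self.prior_mean.items()},
            "posterior_mean": {str(k): v for k, v in self.posterior_mean.items()},
            "n_included": {str(k): v for k, v in self.n_included.items()},
        }


def prior_h4_fraction(Q: int, priors: ColocPriors) -> float:
    """Relative prior support for a shared causal variant, P4/(P3 + P4)."""
    if Q < 2:
        raise ValueError(f"Q must be >= 2, got {Q}")
    pv = hypothesis_priors(Q, priors)
    return pv.h4 / (pv.h3 + pv.h4)


def calibrate_p12(
    pair_results: dict[float, list[ColocResult]],
    grid: tuple[float, ...] = DEFAULT_GRID,
    threshold: float = DEFAULT_INCLUSION_THRESHOLD,
    base_priors: ColocPriors | None = None,
) -> CalibrationResult:
    """Choose p12 by matching posterior to prior colocalisation expectation.

    Parameters
    ----------
    pair_results
        For each grid value, the colocalisation results of *the same*
        pairwise analyses recomputed with that p12.
    grid
        Candidate p12 values; defaults to (1e-7, 1e-6, 1e-5).
    threshold
        Pairs enter the average only when PP3 + PP4 exceeds this value; the
        inclusion mask is recomputed per grid value.
    base_priors
        Supplies p1 and p2 for the prior fractions (p12 is substituted per
        grid value).

    Each included pair is weighted equally.  Grid values at which no pair
    passes the threshold are excluded with a warning; ties are broken
    towards the smaller p12.
    """
    base_priors = base_priors or ColocPriors()
    grid = tuple(sorted(grid))
    prior_mean: dict[float, float] = {}
    posterior_mean: dict[float, float] = {}
    n_included: dict[float, int] = {}
    curve_rows = []
    for p12 in grid:
        if p12 not in pair_results:
            raise KeyError(f"no pair results supplied for grid value {p12}")
        priors = base_priors.with_p12(p12)
        included = [r for r in pair_results[p12] if r.pp3_plus_pp4 > threshold]
        if not included:
            warnings.warn(
                f"no pairs pass PP3+PP4 > {threshold} at p12 = {p12}; grid value excluded",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        post_fracs = [r.pp4 / r.pp3_plus_pp4 for r in included]
        prior_fracs = [prior_h4_fraction(r.Q, priors) for r in included]
        for r, pf, qf in zip(included, post_fracs, prior_fracs):
            curve_rows.append(
                {"p12": p12, "Q": r.Q, "prior_fraction": qf, "posterior_fraction": pf}
            )
        posterior_mean[p12] = sum(post_fracs) / len(post_fracs)
        prior_mean[p12] = sum(prior_fracs) / len(prior_fracs)
        n_included[p12] = len(included)
    if not posterior_mean:
        raise ValueError("no grid value retained any pair above the inclusion threshold")
    # smallest gap; ties towards smaller p12 (grid is sorted ascending)
    chosen = min(posterior_mean, key=lambda g: (abs(posterior_mean[g] - prior_mean[g]), g))
    return CalibrationResult(
        grid=list(grid),
        prior_mean=prior_mean,
        posterior_mean=posterior_mean,
        chosen_p12=chosen,
        inclusion_threshold=threshold,
        n_included=n_included,
        curves=pd.DataFrame(
            curve_rows, columns=["p12", "Q", "prior_fraction", "posterior_fraction"]
        ),
    )
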