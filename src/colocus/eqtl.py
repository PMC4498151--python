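"""Per-SNP expression effect estimation and fixed-effects meta-analysis.

Expression effects are estimated by single-SNP ordinary least squares of a
(unit-variance) probe trait on allele-2 dosage.  Two independent cohorts
measuring the same cell state can be combined per SNP by inverse-variance
weighting after allele harmonisation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AssocStat",
    "EqtlDataset",
    "DegenerateTraitError",
    "AlleleMismatchError",
    "StrandAmbiguousError",
    "fit_cis_eqtl",
    "response_expression",
    "fixed_effects_meta",
    "meta_analyse",
]

_AMBIGUOUS_PAIRS = {frozenset(("A", "T")), frozenset(("C", "G"))}


class DegenerateTraitError(ValueError):
    """Raised when a derived trait has zero variance."""


class AlleleMismatchError(ValueError):
    """Raised when two studies report irreconcilable alleles for a SNP."""


class StrandAmbiguousError(ValueError):
    """Raised for strand-ambiguous (A/T, C/G) SNPs that cannot be harmonised."""


@dataclass
class AssocStat:
    """Association summary for one SNP and one trait.

    At least one of the two evidence routes must be present: the effect route
    (``beta`` + ``varbeta``) or the summary route (``p`` + ``maf`` + ``n``).
    Case-control records additionally carry ``case_fraction``.
    """

    snp_id: str
    beta: float | None = None
    varbeta: float | None = None
    p: float | None = None
    maf: float | None = None
    n: int | None = None
    trait_type: str = "quantitative"
    case_fraction: float | None = None
    chrom: str | None = None
    pos: int | None = None
    allele1: str | None = None
    allele2: str | None = None

    def __post_init__(self) -> None:
        has_effect = self.beta is not None and self.varbeta is not None
        has_summary = self.p is not None and self.maf is not None and self.n is not None
        if not (has_effect or has_summary):
            raise ValueError(
                f"{self.snp_id}: need either beta+varbeta or p+maf+n"
            )
        if self.beta is not None:
            if self.varbeta is None or not self.varbeta > 0:
                raise ValueError(f"{self.snp_id}: varbeta must be > 0 when beta is present")
        if self.p is not None and not 0.0 < self.p <= 1.0:
            raise ValueError(f"{self.snp_id}: p must be in (0, 1], got {self.p}")
        if self.maf is not None and not 0.0 < self.maf <= 0.5:
            raise ValueError(f"{self.snp_id}: maf must be in (0, 0.5], got {self.maf}")
        if self.trait_type not in ("quantitative", "case-control"):
            raise ValueError(f"unknown trait type {self.trait_type!r}")
        if self.trait_type == "case-control":
            if self.case_fraction is None or not 0.0 < self.case_fraction < 1.0:
                raise ValueError(f"{self.snp_id}: case-control requires case_fraction in (0,1)")


@dataclass
class EqtlDataset:
    """Genotype dosages plus per-probe expression for one cohort.

    ``dosages`` is an ``n_samples x Q`` float matrix (NaN = missing call);
    ``expression`` maps probe ids to length-``n_samples`` vectors.
    """

    dosages: np.ndarray
    expression: dict[str, np.ndarray]
    sample_ids: list[str]
    snp_ids: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, q = self.dosages.shape
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} dosage rows")
        if len(self.snp_ids) != q:
            raise ValueError(f"{len(self.snp_ids)} snp ids for {q} dosage columns")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.dosages, initial=0.0) < 0 or np.nanmax(self.dosages, initial=0.0) > 2:
                raise ValueError("dosages must lie in [0, 2]")
        for pid, vec in self.expression.items():
            vec = np.asarray(vec, dtype=float)
            if vec.shape != (n,):
                raise ValueError(f"expression vector {pid} has shape {vec.shape}, expected ({n},)")
            if not np.all(np.isfinite(vec)):
                raise ValueError(f"expression vector {pid} contains non-finite values")
            self.expression[pid] = vec

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def Q(self) -> int:
        return self.dosages.shape[1]


def _standardize(y: np.ndarray) -> np.ndarray:
    sd = np.std(y, ddof=1)
    if sd == 0:
        raise DegenerateTraitError("trait has zero variance")
    return (y - np.mean(y)) / sd


def fit_cis_eqtl(
    dataset: EqtlDataset,
    probe_id: str,
    *,
    standardize: bool = True,
    min_samples: int = 3,
) -> list[AssocStat]:
    """Single-SNP OLS of a probe trait on dosage, one fit per SNP.

    The trait is standardised to unit variance before fitting (disable with
    ``standardize=False`` to obtain effects on the raw expression scale).
    Missing dosages are dropped pairwise.  Per SNP the slope ``beta``, its
    squared standard error ``varbeta`` (residual variance with an ``n - 2``
    denominator) and a two-sided t-test p-value are returned.  SNPs with a
    constant dosage or fewer than ``min_samples`` complete pairs are skipped
    with a warning.
    """
    if probe_id not in dataset.expression:
        raise KeyError(f"unknown probe {probe_id!r}")
    y_all = dataset.expression[probe_id]
    if standardize:
        y_all = _standardize(y_all)

    out: list[AssocStat] = []
    for j, snp_id in enumerate(dataset.snp_ids):
        g = dataset.dosages[:, j]
        mask = np.isfinite(g)
        n = int(mask.sum())
        if n < min_samples:
            warnings.warn(f"{snp_id}: only {n} complete pairs, skipped", RuntimeWarning, stacklevel=2)
            continue
        x = g[mask]
        y = y_all[mask]
        xbar = x.mean()
        sxx = float(np.sum((x - xbar) ** 2))
        if sxx == 0.0:
            warnings.warn(f"{snp_id}: constant dosage, skipped", RuntimeWarning, stacklevel=2)
            continue
        sxy = float(np.sum((x - xbar) * (y - y.mean())))
        beta = sxy / sxx
        resid = y - y.mean() - beta * (x - xbar)
        if n > 2:
            s2 = float(np.sum(resid**2)) / (n - 2)
        else:
            s2 = 0.0
        varbeta = s2 / sxx
        if varbeta > 0:
            t = beta / math.sqrt(varbeta)
            p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
        else:
            p = 0.0
        p = max(p, 1e-300)
        f2 = xbar / 2.0
        maf = min(f2, 1.0 - f2)
        out.append(
            AssocStat(
                snp_id=snp_id,
                beta=beta,
                varbeta=varbeta if varbeta > 0 else 1e-300,
                p=p,
                maf=maf if 0.0 < maf <= 0.5 else None,
                n=n,
                trait_type="quantitative",
            )
        )
    return out


def response_expression(
    baseline: pd.Series,
    stimulated: pd.Series,
    paired_ids: list[str] | None = None,
) -> pd.Series:
    """Per-sample stimulated-minus-baseline trait, standardised.

    Only samples present in both series (optionally restricted to
    ``paired_ids``) contribute.  The derived trait can be fed to
    :func:`fit_cis_eqtl` like any probe.  A zero-variance difference (e.g.
    stimulation shifting every sample by the same constant) raises
    :class:`DegenerateTraitError`.
    """
    shared = baseline.index.intersection(stimulated.index)
    if paired_ids is not None:
        shared = shared.intersection(pd.Index(paired_ids))
    if len(shared) == 0:
        raise ValueError("no paired samples between baseline and stimulated expression")
    diff = (stimulated.loc[shared] - baseline.loc[shared]).astype(float)
    return pd.Series(_standardize(diff.to_numpy()), index=shared)


def _harmonise(s1: AssocStat, s2: AssocStat) -> AssocStat:
    """Align study 2's effect allele with study 1's; may flip beta's sign."""
    a = (s1.allele1, s1.allele2)
    b = (s2.allele1, s2.allele2)
    if None in a or None in b:
        return s2  # no allele information: assume aligned
    if {*a} != {*b}:
        raise AlleleMismatchError(f"{s1.snp_id}: alleles {a} vs {b} are irreconcilable")
    if frozenset(a) in _AMBIGUOUS_PAIRS:
        maf = max(x for x in (s1.maf, s2.maf) if x is not None) if (s1.maf or s2.maf) else None
        if maf is not None and maf > 0.4:
            raise StrandAmbiguousError(
                f"{s1.snp_id}: strand-ambiguous alleles {a} with maf {maf} > 0.4"
            )
    if a == b:
        return s2
    # swapped effect allele: flip the effect direction
    return replace(
        s2,
        beta=-s2.beta if s2.beta is not None else None,
        allele1=s2.allele2,
        allele2=s2.allele1,
        maf=s2.maf,
    )


def fixed_effects_meta(stats1: AssocStat, stats2: AssocStat) -> AssocStat:
    """Inverse-variance fixed-effects combination of two study estimates.

    With weights ``w = 1/varbeta``::

        beta    = (w1 b1 + w2 b2) / (w1 + w2)
        varbeta = 1 / (w1 + w2)

    the combined p-value derives from the combined z, and ``n = n1 + n2``.
    Study 2 is harmonised to study 1's allele coding first; a swapped
    allele1/allele2 flips the sign of ``beta2``, and strand-ambiguous A/T or
    C/G SNPs with maf > 0.4 are refused (:class:`StrandAmbiguousError`).
    """
    if stats1.snp_id != stats2.snp_id:
        raise ValueError(f"snp ids differ: {stats1.snp_id} vs {stats2.snp_id}")
    stats2 = _harmonise(stats1, stats2)
    for s in (stats1, stats2):
        if s.beta is None or s.varbeta is None:
            raise ValueError(f"{s.snp_id}: meta-analysis requires beta and varbeta")
    w1 = 1.0 / stats1.varbeta
    w2 = 1.0 / stats2.varbeta
    beta = (w1 * stats1.beta + w2 * stats2.beta) / (w1 + w2)
    varbeta = 1.0 / (w1 + w2)
    z = beta / math.sqrt(varbeta)
    p = max(float(2.0 * sps.norm.sf(abs(z))), 1e-300)
    n = None
    if stats1.n is not None and stats2.n is not None:
        n = stats1.n + stats2.n
    maf = None
    if stats1.maf is not None and stats2.maf is not None and n:
        maf = (stats1.maf * stats1.n + stats2.maf * stats2.n) / n
    elif stats1.maf is not None:
        maf = stats1.maf
    return AssocStat(
        snp_id=stats1.snp_id,
        beta=beta,
        varbeta=varbeta,
        p=p,
        maf=maf,
        n=n,
        trait_type=stats1.trait_type,
        chrom=stats1.chrom,
        pos=stats1.pos,
        allele1=stats1.allele1,
        allele2=stats1.allele2,
    )


def meta_analyse(
    stats1: list[AssocStat], stats2: list[AssocStat]
) -> list[AssocStat]:
    """Combine two per-SNP stat collections; pass through singleton SNPs.

    SNPs present in both studies are combined with
    :func:`fixed_effects_meta`; strand-ambiguous SNPs are dropped with a
    warning.  SNPs present in only one study pass through unchanged, matching
    the use of a single study when the other has no data.
    """
    by_id2 = {s.snp_id: s for s in stats2}
    seen: set[str] = set()
    out: list[AssocStat] = []
    for s1 in stats1:
        s2 = by_id2.get(s1.snp_id)
        if s2 is None:
            out.append(s1)
            continue
        seen.add(s1.snp_id)
        try:
            out.append(fixed_effects_meta(s1, s2))
        except StrandAmbiguousError as exc:
            warnings.warn(str(exc), RuntimeWarning, stacklevel=2)
    out.extend(s for s in stats2 if s.snp_id not in seen)
    return out
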