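"""Five-hypothesis Bayesian colocalisation from per-SNP summary evidence.

A region of ``Q`` SNPs is scored under five mutually exclusive hypotheses:

* ``H0`` — no causal variant for either trait;
* ``H1`` — a causal variant for the disease trait only;
* ``H2`` — a causal variant for the expression trait only;
* ``H3`` — two distinct causal variants, one per trait;
* ``H4`` — a single causal variant shared by both traits.

Evidence enters as per-SNP approximate Bayes factors (ABFs) computed either
from an effect estimate and its variance or from a p-value, allele frequency
and sample size.  Posterior probabilities ``PP0..PP4`` are obtained by
combining per-SNP ABFs with per-SNP causal priors ``p1``, ``p2``, ``p12``
under the at-most-one-causal-variant-per-trait assumption.  All Bayes-factor
arithmetic is carried out in log space.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import logsumexp, ndtri

__all__ = [
    "ColocPriors",
    "PriorVector",
    "AbfSettings",
    "ColocResult",
    "log_abf",
    "abf_from_pvalue",
    "log_abf_from_stat",
    "hypothesis_priors",
    "coloc_posteriors",
    "classify_pair",
    "CLASSIFICATIONS",
    "GWAS_P_GATE",
    "EQTL_P_GATE",
]

#: Genome-wide significance gate applied to the disease trait before a pair
#: may be called an overlap (the convention 5e-8; configurable per call).
GWAS_P_GATE = 5e-8

#: Significance gate applied to the eQTL trait (P < 1e-10).
EQTL_P_GATE = 1e-10

CLASSIFICATIONS = ("no_assoc", "one_trait", "distinct", "suggestive", "convincing")

_P_FLOOR = 1e-300


@dataclass(frozen=True)
class ColocPriors:
    """Per-SNP causal priors.

    Parameters
    ----------
    p1
        Prior probability that a given SNP is causal for the disease trait
        only.
    p2
        Prior probability that a given SNP is causal for the expression trait
        only.
    p12
        Prior probability that a given SNP is causal for both traits.

    ``p0 = 1 - p1 - p2 - p12`` is derived.  ``p12`` must be strictly smaller
    than both single-trait priors and the three must sum to less than one.
    """

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-6

    def __post_init__(self) -> None:
        if not (0.0 < self.p12 < min(self.p1, self.p2)):
            raise ValueError(
                f"require 0 < p12 < min(p1, p2); got p1={self.p1}, p2={self.p2}, p12={self.p12}"
            )
        if not self.p1 + self.p2 + self.p12 < 1.0:
            raise ValueError("p1 + p2 + p12 must be < 1")

    @property
    def p0(self) -> float:
        return 1.0 - self.p1 - self.p2 - self.p12

    def with_p12(self, p12: float) -> "ColocPriors":
        return replace(self, p12=p12)


@dataclass(frozen=True)
class PriorVector:
    """Region-level prior probabilities of the five hypotheses."""

    Q: int
    h0: float
    h1: float
    h2: float
    h3: float
    h4: float
    #: Prior odds of a shared vs distinct causal variants, h4/h3
    #: (infinite when Q == 1, where H3 is impossible).
    ratio_h4_h3: float

    def as_array(self) -> np.ndarray:
        return np.array([self.h0, self.h1, self.h2, self.h3, self.h4])


@dataclass(frozen=True)
class AbfSettings:
    """Prior variance of the (standardised) effect size used in the ABF.

    ``w_quant`` applies to quantitative traits (expression measured in SD
    units), ``w_cc`` to case-control traits (log-odds scale).
    """

    w_quant: float = 0.2**2
    w_cc: float = 0.15**2

    def __post_init__(self) -> None:
        if not (self.w_quant > 0 and self.w_cc > 0):
            raise ValueError("prior effect variances must be positive")

    def for_trait(self, trait_type: str) -> float:
        if trait_type == "case-control":
            return self.w_cc
        if trait_type == "quantitative":
            return self.w_quant
        raise ValueError(f"unknown trait type {trait_type!r}")


@dataclass
class ColocResult:
    """Posterior summary of one disease x probe x cell-state comparison."""

    Q: int
    pp0: float
    pp1: float
    pp2: float
    pp3: float
    pp4: float
    sum_log_abf1: float
    sum_log_abf2: float
    gwas_min_p: float | None = None
    eqtl_min_p: float | None = None
    classification: str | None = None
    region: str = ""
    disease: str = ""
    probe: str = ""
    gene: str = ""
    cell_state: str = ""

    def __post_init__(self) -> None:
        total = self.pp0 + self.pp1 + self.pp2 + self.pp3 + self.pp4
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"posterior probabilities sum to {total}, not 1")
        if self.Q == 1 and self.pp3 != 0.0:
            raise ValueError("PP3 must be exactly 0 when Q == 1")

    @property
    def pp(self) -> np.ndarray:
        return np.array([self.pp0, self.pp1, self.pp2, self.pp3, self.pp4])

    @property
    def pp3_plus_pp4(self) -> float:
        return self.pp3 + self.pp4

    @property
    def pp4_over_pp3(self) -> float:
        """Posterior odds of shared vs distinct causal variants.

        ``+inf`` when PP3 is exactly zero but PP4 is not; ``nan`` when both
        are zero.
        """
        if self.pp3 > 0.0:
            return self.pp4 / self.pp3
        return math.inf if self.pp4 > 0.0 else math.nan


def log_abf(beta: float, varbeta: float, w: float) -> float:
    """Log approximate Bayes factor for a single SNP association.

    Ratio of the marginal likelihood of the observed effect ``beta`` (with
    sampling variance ``varbeta``) under ``effect ~ Normal(0, w)`` versus the
    point null.  With shrinkage ``r = w / (w + varbeta)`` and Wald statistic
    ``z = beta / sqrt(varbeta)``::

        log ABF = 0.5 * log(1 - r) + 0.5 * r * z**2
    """
    if not (math.isfinite(beta) and math.isfinite(varbeta) and math.isfinite(w)):
        raise ValueError("log_abf requires finite inputs")
    if varbeta <= 0:
        raise ValueError(f"varbeta must be > 0, got {varbeta}")
    if w < 0:
        raise ValueError(f"prior variance must be >= 0, got {w}")
    r = w / (w + varbeta)
    z2 = beta * beta / varbeta
    return 0.5 * math.log1p(-r) + 0.5 * r * z2


def abf_from_pvalue(
    p: float,
    maf: float,
    n: float,
    trait_type: str = "quantitative",
    case_fraction: float | None = None,
    settings: AbfSettings | None = None,
) -> float:
    """Log ABF from a p-value, minor allele frequency and sample size.

    The Wald statistic is recovered as ``|z| = Phi^-1(1 - p/2)`` and the
    effect variance approximated from the information carried by an additive
    genotype: ``varbeta = 1 / (2 n maf (1 - maf))`` for a quantitative trait,
    additionally divided by ``case_fraction * (1 - case_fraction)`` for a
    case-control trait.  p-values below 1e-300 are clamped with a warning.
    """
    settings = settings or AbfSettings()
    if not 0.0 < p <= 1.0:
        raise ValueError(f"p must be in (0, 1], got {p}")
    if not 0.0 < maf <= 0.5:
        raise ValueError(f"maf must be in (0, 0.5], got {maf}")
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    if p < _P_FLOOR:
        warnings.warn(f"p-value {p} clamped to {_P_FLOOR}", RuntimeWarning, stacklevel=2)
        p = _P_FLOOR
    z = abs(ndtri(p / 2.0))  # lower-tail form stays finite down to p ~ 1e-300
    varbeta = 1.0 / (2.0 * n * maf * (1.0 - maf))
    if trait_type == "case-control":
        if case_fraction is None or not 0.0 < case_fraction < 1.0:
            raise ValueError("case-control traits require case_fraction in (0, 1)")
        varbeta /= case_fraction * (1.0 - case_fraction)
    elif trait_type != "quantitative":
        raise ValueError(f"unknown trait type {trait_type!r}")
    beta = z * math.sqrt(varbeta)
    return log_abf(beta, varbeta, settings.for_trait(trait_type))


def log_abf_from_stat(stat, settings: AbfSettings | None = None) -> float:
    """Log ABF from an association record, preferring the effect/SE route.

    Accepts any object with the attributes of
    :class:`colocus.eqtl.AssocStat`; falls back to the p/MAF/n route when no
    effect estimate is present.
    """
    settings = settings or AbfSettings()
    if stat.beta is not None and stat.varbeta is not None:
        return log_abf(stat.beta, stat.varbeta, settings.for_trait(stat.trait_type))
    return abf_from_pvalue(
        stat.p, stat.maf, stat.n, stat.trait_type, stat.case_fraction, settings
    )


def hypothesis_priors(Q: int, priors: ColocPriors) -> PriorVector:
    """Prior probabilities of the five hypotheses for a region of ``Q`` SNPs.

    With per-SNP priors ``p0, p1, p2, p12``::

        P(H0) = p0^Q
        P(H1) = Q p0^(Q-1) p1
        P(H2) = Q p0^(Q-1) p2
        P(H3) = Q (Q-1) p0^(Q-2) p1 p2
        P(H4) = Q p0^(Q-1) p12

    and the prior odds of colocalisation given association with both traits
    is ``P4/P3 = p0 p12 / ((Q-1) p1 p2)``.
    """
    if Q < 1:
        raise ValueError(f"Q must be >= 1, got {Q}")
    p0, p1, p2, p12 = priors.p0, priors.p1, priors.p2, priors.p12
    h0 = p0**Q
    h1 = Q * p0 ** (Q - 1) * p1
    h2 = Q * p0 ** (Q - 1) * p2
    h3 = Q * (Q - 1) * p0 ** (Q - 2) * p1 * p2
    h4 = Q * p0 ** (Q - 1) * p12
    ratio = math.inf if Q == 1 else p0 * p12 / ((Q - 1) * p1 * p2)
    return PriorVector(Q=Q, h0=h0, h1=h1, h2=h2, h3=h3, h4=h4, ratio_h4_h3=ratio)


def coloc_posteriors(
    logabf_disease: np.ndarray,
    logabf_eqtl: np.ndarray,
    priors: ColocPriors,
    *,
    gwas_min_p: float | None = None,
    eqtl_min_p: float | None = None,
    region: str = "",
    disease: str = "",
    probe: str = "",
    gene: str = "",
    cell_state: str = "",
) -> ColocResult:
    """Posterior probabilities PP0..PP4 from per-SNP log ABF vectors.

    Both vectors must cover the same ordered set of ``Q`` SNPs.  The
    unnormalised hypothesis weights are::

        h0 = 1
        h1 = p1  * sum_i BF1_i
        h2 = p2  * sum_j BF2_j
        h3 = p1 p2 * (sum_i BF1_i * sum_j BF2_j - sum_i BF1_i BF2_i)
        h4 = p12 * sum_i BF1_i BF2_i

    evaluated in log space with log-sum-exp; posteriors are the normalised
    weights.  The ``h3`` cross term subtracts the diagonal (same-SNP)
    configurations, which is done via ``log1p(-exp(.))`` so that Q = 1 yields
    PP3 = 0 exactly.
    """
    l1 = np.asarray(logabf_disease, dtype=float)
    l2 = np.asarray(logabf_eqtl, dtype=float)
    if l1.ndim != 1 or l1.shape != l2.shape:
        raise ValueError(
            f"log-ABF vectors must be 1-d with equal length, got {l1.shape} and {l2.shape}"
        )
    if l1.size < 1:
        raise ValueError("at least one SNP is required")
    if not (np.all(np.isfinite(l1)) and np.all(np.isfinite(l2))):
        raise ValueError("log-ABF vectors must be finite")
    Q = l1.size

    s1 = logsumexp(l1)
    s2 = logsumexp(l2)
    s_both = logsumexp(l1 + l2)

    lh = np.empty(5)
    lh[0] = 0.0
    lh[1] = math.log(priors.p1) + s1
    lh[2] = math.log(priors.p2) + s2
    diff = s_both - (s1 + s2)  # <= 0 by the rearrangement inequality
    if Q == 1 or diff >= 0.0:
        lh[3] = -math.inf
    else:
        lh[3] = math.log(priors.p1) + math.log(priors.p2) + s1 + s2 + math.log1p(-math.exp(diff))
    lh[4] = math.log(priors.p12) + s_both

    pp = np.exp(lh - logsumexp(lh))
    pp /= pp.sum()
    if Q == 1:
        pp[3] = 0.0
        pp /= pp.sum()

    return ColocResult(
        Q=Q,
        pp0=float(pp[0]),
        pp1=float(pp[1]),
        pp2=float(pp[2]),
        pp3=float(pp[3]),
        pp4=float(pp[4]),
        sum_log_abf1=float(s1),
        sum_log_abf2=float(s2),
        gwas_min_p=gwas_min_p,
        eqtl_min_p=eqtl_min_p,
        region=region,
        disease=disease,
        probe=probe,
        gene=gene,
        cell_state=cell_state,
    )


def classify_pair(
    result: ColocResult,
    gwas_min_p: float | None = None,
    eqtl_min_p: float | None = None,
    *,
    gwas_gate: float = GWAS_P_GATE,
    eqtl_gate: float = EQTL_P_GATE,
    overlap_threshold: float = 0.99,
    suggestive_ratio: float = 1.0,
    convincing_ratio: float = 5.0,
) -> str:
    """Classify a pairwise comparison.

    A pair may only be called an overlap (and thence suggestive/convincing)
    when the disease trait reaches genome-wide significance
    (``gwas_min_p <= 5e-8``) and the eQTL trait reaches ``eqtl_min_p <=
    1e-10``.  Gated pairs with ``PP3 + PP4 >= 0.99`` are *convincing* when
    ``PP4/PP3 > 5``, *suggestive* when ``> 1`` and *distinct* otherwise.
    Below the overlap threshold the pair is *one_trait* when the modal
    hypothesis is H1 or H2, else *no_assoc*.

    Missing gate p-values (``None``) are treated as passing, which supports
    purely synthetic inputs that carry no per-SNP p-values.
    """
    if gwas_min_p is None:
        gwas_min_p = result.gwas_min_p
    if eqtl_min_p is None:
        eqtl_min_p = result.eqtl_min_p
    gates_pass = (gwas_min_p is None or gwas_min_p <= gwas_gate) and (
        eqtl_min_p is None or eqtl_min_p <= eqtl_gate
    )
    if gates_pass and result.pp3_plus_pp4 >= overlap_threshold:
        ratio = result.pp4_over_pp3
        if ratio > convincing_ratio:
            return "convincing"
        if ratio > suggestive_ratio:
            return "suggestive"
        return "distinct"
    modal = int(np.argmax(result.pp))
    return "one_trait" if modal in (1, 2) else "no_assoc"


def classified(result: ColocResult, **kwargs) -> ColocResult:
    """Return a copy of ``result`` with its ``classification`` field set."""
    label = classify_pair(result, **kwargs)
    return replace(result, classification=label)
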