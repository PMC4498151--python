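"""Candidate-gene enrichment and per-disease classification summaries.

Among pairwise analyses showing evidence of association with both traits
(PP3 + PP4 > 0.8), we ask whether pairs in a supplied candidate-gene set
more often favour a shared causal variant (PP4 > PP3) than pairs outside
it, via the odds in each stratum, their ratio and a two-sided Fisher exact
test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import pandas as pd
from scipy import stats as sps

from .core import ColocResult

__all__ = ["EnrichmentTable", "candidate_gene_enrichment", "enrichment_from_counts", "summarize_counts"]

ASSOC_THRESHOLD = 0.8

#: classification labels ordered by increasing evidence
_CLASS_ORDER = {"no_assoc": 0, "one_trait": 1, "distinct": 2, "suggestive": 3, "convincing": 4}


@dataclass
class EnrichmentTable:
    """2x2 cross-classification of candidate membership by PP4 > PP3."""

    n_candidate_pairs: int
    n_other_pairs: int
    candidate_successes: int
    other_successes: int
    odds_candidate: float
    odds_other: float
    odds_ratio: float
    #: ratio of the odds after rounding each to 3 decimals, the form in
    #: which published odds tables are typically reproduced
    odds_ratio_rounded: float
    fisher_p: float

    def to_dict(self) -> dict:
        return {
            "n_candidate_pairs": self.n_candidate_pairs,
            "n_other_pairs": self.n_other_pairs,
            "candidate_successes": self.candidate_successes,
            "other_successes": self.other_successes,
            "odds_candidate": self.odds_candidate,
            "odds_other": self.odds_other,
            "odds_ratio": self.odds_ratio,
            "odds_ratio_rounded": self.odds_ratio_rounded,
            "fisher_p": self.fisher_p,
        }


def enrichment_from_counts(
    candidate_successes: int,
    candidate_failures: int,
    other_successes: int,
    other_failures: int,
) -> EnrichmentTable:
    """Build the enrichment table directly from 2x2 counts."""
    if candidate_successes + candidate_failures == 0 or other_successes + other_failures == 0:
        raise ValueError("both strata must be non-empty")

    def _odds(s: int, f: int) -> float:
        if f == 0:
            warnings.warn("zero failures in a stratum: odds are infinite", RuntimeWarning, stacklevel=3)
            return math.inf
        return s / f

    odds_c = _odds(candidate_successes, candidate_failures)
    odds_o = _odds(other_successes, other_failures)
    if odds_o == 0.0:
        odds_ratio = math.inf if odds_c > 0 else math.nan
        warnings.warn("zero odds in comparison stratum: odds ratio infinite", RuntimeWarning, stacklevel=2)
    else:
        odds_ratio = odds_c / odds_o
    rc, ro = round(odds_c, 3), round(odds_o, 3)
    odds_ratio_rounded = rc / ro if ro > 0 else math.inf
    _, fisher_p = sps.fisher_exact(
        [[candidate_successes, candidate_failures], [other_successes, other_failures]],
        alternative="two-sided",
    )
    return EnrichmentTable(
        n_candidate_pairs=candidate_successes + candidate_failures,
        n_other_pairs=other_successes + other_failures,
        candidate_successes=candidate_successes,
        other_successes=other_successes,
        odds_candidate=odds_c,
        odds_other=odds_o,
        odds_ratio=odds_ratio,
        odds_ratio_rounded=odds_ratio_rounded,
        fisher_p=float(fisher_p),
    )


def candidate_gene_enrichment(
    pairs: list[ColocResult],
    candidates: set[str],
    assoc_threshold: float = ASSOC_THRESHOLD,
) -> EnrichmentTable:
    """Test whether candidate genes are enriched for colocalising pairs.

    Pairs are restricted to those with PP3 + PP4 > ``assoc_threshold``, then
    cross-classified by candidate-gene membership against whether the pair
    favours a shared causal variant (PP4 > PP3).  Both strata must be
    non-empty; a stratum with zero failures yields infinite odds with a
    warning.
    """
    included = [r for r in pairs if r.pp3_plus_pp4 > assoc_threshold]
    counts = {(True, True): 0, (True, False): 0, (False, True): 0, (False, False): 0}
    for r in included:
        counts[(r.gene in candidates, r.pp4 > r.pp3)] += 1
    return enrichment_from_counts(
        candidate_successes=counts[(True, True)],
        candidate_failures=counts[(True, False)],
        other_successes=counts[(False, True)],
        other_failures=counts[(False, False)],
    )


def summarize_counts(results: list[ColocResult]) -> pd.DataFrame:
    """Per-disease gene counts of overlapping/suggestive/convincing eQTLs.

    A gene is counted once per disease using its maximum-evidence
    classification across probes and cell states.  ``overlaps`` counts genes
    whose best pair passed the overlap threshold at all (classification
    distinct or better), ``suggestive`` those at suggestive or better and
    ``convincing`` the convincing ones.  A final ``at_least_one_disease``
    row de-duplicates genes across diseases.
    """
    best: dict[tuple[str, str], int] = {}
    best_any: dict[str, int] = {}
    for r in results:
        if r.classification is None:
            raise ValueError("summarize_counts requires classified results")
        level = _CLASS_ORDER[r.classification]
        key = (r.disease, r.gene)
        best[key] = max(best.get(key, -1), level)
        best_any[r.gene] = max(best_any.get(r.gene, -1), level)

    def _row(levels: list[int]) -> dict:
        return {
            "overlaps": sum(1 for v in levels if v >= _CLASS_ORDER["distinct"]),
            "suggestive": sum(1 for v in levels if v >= _CLASS_ORDER["suggestive"]),
            "convincing": sum(1 for v in levels if v >= _CLASS_ORDER["convincing"]),
        }

    diseases = sorted({d for d, _ in best})
    rows = {d: _row([v for (dd, _), v in best.items() if dd == d]) for d in diseases}
    rows["at_least_one_disease"] = _row(list(best_any.values()))
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "disease"
    return df
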