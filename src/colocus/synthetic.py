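"""LD-structured region simulation with paired disease and eQTL cohorts.

The linkage-disequilibrium model is a first-order Markov copy process over a
haplotype panel: each SNP copies its left neighbour's allele with
probability ``rho`` and is otherwise redrawn at its own target frequency.
Genotypes are formed by pairing haplotypes.  Disease status follows a
logistic model with a fixed 10% baseline prevalence; per-SNP disease
summaries come from a 1-df allelic score test, with MAF taken from
controls, matching the p-value/MAF granularity of real GWAS downloads.

All generators are pure functions of their arguments and a seed; cohorts
draw from disjoint sub-streams of the master seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .eqtl import AssocStat, EqtlDataset

__all__ = [
    "HaplotypePanel",
    "ScenarioSpec",
    "HYPOTHESES",
    "simulate_haplotype_panel",
    "simulate_case_control_gwas",
    "simulate_eqtl_study",
    "ld_r2",
    "pick_low_ld_pair",
    "pick_tagging_snp",
]

HYPOTHESES = ("H0", "H1", "H2", "H3", "H4", "H4_plus_secondary")

#: Sub-stream tags mixed with the master seed, one per cohort.
_STREAM_GWAS = 11
_STREAM_EQTL = {"study1": 21, "study2": 22}

#: Effect of a configured secondary eQTL relative to the primary one.
SECONDARY_EFFECT_FRACTION = 0.5

BASELINE_PREVALENCE = 0.10


@dataclass(frozen=True)
class HaplotypePanel:
    """Binary haplotypes (n_hap x Q) with realised allele-2 frequencies."""

    alleles: np.ndarray
    freqs: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.alleles)
        if a.ndim != 2 or not np.isin(a, (0, 1)).all():
            raise ValueError("alleles must be a binary 2-d matrix")
        if not np.allclose(self.freqs, a.mean(axis=0)):
            raise ValueError("freqs must equal the column means of alleles")

    @property
    def Q(self) -> int:
        return self.alleles.shape[1]

    @property
    def n_hap(self) -> int:
        return self.alleles.shape[0]

    @property
    def snp_ids(self) -> list[str]:
        return [f"rs{j + 1:05d}" for j in range(self.Q)]


@dataclass(frozen=True)
class ScenarioSpec:
    """Causal configuration for one simulated region.

    The indices must be consistent with the hypothesis: H4 shares one index
    between the traits, H3 uses two distinct indices, H1/H2 set only one
    trait's index and H0 sets neither.  ``H4_plus_secondary`` adds a second,
    weaker eQTL at ``secondary_eqtl_idx``.
    """

    hypothesis: str
    causal_disease_idx: int | None = None
    causal_eqtl_idx: int | None = None
    secondary_eqtl_idx: int | None = None
    log_or: float = 0.0
    beta_expr: float = 0.0
    n_cases: int = 1000
    n_controls: int = 1000
    n_eqtl1: int = 300
    n_eqtl2: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        h = self.hypothesis
        if h not in HYPOTHESES:
            raise ValueError(f"unknown hypothesis {h!r}")
        d, e = self.causal_disease_idx, self.causal_eqtl_idx
        if h == "H0" and not (d is None and e is None):
            raise ValueError("H0 requires no causal indices")
        if h == "H1" and not (d is not None and e is None):
            raise ValueError("H1 requires only a disease causal index")
        if h == "H2" and not (d is None and e is not None):
            raise ValueError("H2 requires only an eQTL causal index")
        if h == "H3" and (d is None or e is None or d == e):
            raise ValueError("H3 requires two distinct causal indices")
        if h in ("H4", "H4_plus_secondary") and (d is None or d != e):
            raise ValueError("H4 requires matching causal indices")
        if h == "H4_plus_secondary":
            if self.secondary_eqtl_idx is None or self.secondary_eqtl_idx == e:
                raise ValueError("H4_plus_secondary requires a distinct secondary index")
        elif self.secondary_eqtl_idx is not None:
            raise ValueError("secondary_eqtl_idx is only valid under H4_plus_secondary")


def simulate_haplotype_panel(
    Q: int,
    n_hap: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    rho: float = 0.9,
    seed: int = 0,
) -> HaplotypePanel:
    """Simulate a binary haplotype panel with Markov LD decay.

    SNP 1 is drawn independently per haplotype at its target frequency; SNP
    ``k+1`` copies SNP ``k``'s allele with probability ``rho`` and is
    otherwise redrawn.  Adjacent-SNP correlation decays roughly as
    ``rho**distance``; ``rho = 0`` gives independent SNPs.
    """
    if Q < 1:
        raise ValueError(f"Q must be >= 1, got {Q}")
    if n_hap < 2:
        raise ValueError(f"n_hap must be >= 2, got {n_hap}")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError(f"maf_range must be a non-empty subinterval of (0, 0.5], got {maf_range}")
    if not 0.0 <= rho < 1.0:
        raise ValueError(f"rho must be in [0, 1), got {rho}")
    rng = np.random.default_rng(seed)
    targets = rng.uniform(lo, hi, size=Q)
    H = np.empty((n_hap, Q), dtype=np.int8)
    H[:, 0] = rng.random(n_hap) < targets[0]
    for k in range(1, Q):
        fresh = rng.random(n_hap) < targets[k]
        copy = rng.random(n_hap) < rho
        H[:, k] = np.where(copy, H[:, k - 1], fresh)
    return HaplotypePanel(alleles=H, freqs=H.mean(axis=0))


def _draw_genotypes(panel: HaplotypePanel, n: int, rng: np.random.Generator) -> np.ndarray:
    idx = rng.integers(0, panel.n_hap, size=(n, 2))
    return (panel.alleles[idx[:, 0]] + panel.alleles[idx[:, 1]]).astype(np.int8)


def _score_test(genotypes: np.ndarray, status: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """1-df allelic score test of case status on dosage, all SNPs at once."""
    y = status.astype(float)
    ybar = y.mean()
    gbar = genotypes.mean(axis=0)
    u = (y - ybar) @ genotypes  # centring y suffices: sum((y-ybar)*gbar) = 0
    v = ybar * (1 - ybar) * np.sum((genotypes - gbar) ** 2, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(v > 0, u / np.sqrt(v), 0.0)
    p = 2.0 * sps.norm.sf(np.abs(z))
    return z, np.clip(p, 1e-300, 1.0)


def simulate_case_control_gwas(
    panel: HaplotypePanel, scenario: ScenarioSpec, max_batches: int = 50
) -> tuple[np.ndarray, np.ndarray, list[AssocStat]]:
    """Simulate a case-control cohort and summarise it per SNP.

    Disease risk is logistic with intercept ``logit(0.10)`` (10% baseline
    prevalence) and per-allele log-odds ``log_or`` at the causal disease SNP
    (none under H0/H2).  Individuals are sampled in batches until the
    requested case and control counts are reached; exceeding ``max_batches``
    raises.  Returns the retained genotype matrix, case status and one
    p/MAF summary per SNP (MAF from controls; monomorphic SNPs are
    omitted).
    """
    rng = np.random.default_rng([scenario.seed, _STREAM_GWAS])
    b0 = math.log(BASELINE_PREVALENCE / (1.0 - BASELINE_PREVALENCE))
    causal = scenario.causal_disease_idx
    log_or = scenario.log_or if causal is not None else 0.0

    need_cases, need_controls = scenario.n_cases, scenario.n_controls
    batch = int(1.5 * max(need_cases / BASELINE_PREVALENCE, need_controls / (1 - BASELINE_PREVALENCE)))
    case_rows, control_rows = [], []
    n_cases = n_controls = 0
    for _ in range(max_batches):
        g = _draw_genotypes(panel, batch, rng)
        eta = b0 + (log_or * g[:, causal] if causal is not None else 0.0)
        y = rng.random(batch) < 1.0 / (1.0 + np.exp(-eta))
        if n_cases < need_cases:
            case_rows.append(g[y])
            n_cases += int(y.sum())
        if n_controls < need_controls:
            control_rows.append(g[~y])
            n_controls += int((~y).sum())
        if n_cases >= need_cases and n_controls >= need_controls:
            break
    else:
        raise RuntimeError(
            f"could not reach {need_cases}/{need_controls} cases/controls in {max_batches} batches"
        )
    cases = np.concatenate(case_rows)[:need_cases]
    controls = np.concatenate(control_rows)[:need_controls]
    genotypes = np.concatenate([cases, controls])
    status = np.concatenate([np.ones(need_cases, dtype=bool), np.zeros(need_controls, dtype=bool)])

    _, pvals = _score_test(genotypes, status)
    f_controls = controls.mean(axis=0) / 2.0
    case_fraction = need_cases / (need_cases + need_controls)
    stats: list[AssocStat] = []
    for j, snp_id in enumerate(panel.snp_ids):
        maf = min(f_controls[j], 1.0 - f_controls[j])
        if maf <= 0.0:
            continue  # monomorphic in controls: no usable summary
        stats.append(
            AssocStat(
                snp_id=snp_id,
                p=float(pvals[j]),
                maf=float(maf),
                n=need_cases + need_controls,
                trait_type="case-control",
                case_fraction=case_fraction,
            )
        )
    return genotypes, status, stats


def simulate_eqtl_study(
    panel: HaplotypePanel,
    scenario: ScenarioSpec,
    which: str = "study1",
    probe_id: str = "P1",
) -> EqtlDataset:
    """Simulate one eQTL cohort: dosages plus a single expression trait.

    Expression is ``beta_expr * dosage(causal_eqtl_idx)`` plus standard
    normal noise (plus a secondary effect of
    ``SECONDARY_EFFECT_FRACTION * beta_expr`` per allele when the scenario
    configures one).  The two studies use disjoint sub-seeds so they are
    independent given the panel.
    """
    if which not in _STREAM_EQTL:
        raise ValueError(f"which must be 'study1' or 'study2', got {which!r}")
    n = scenario.n_eqtl1 if which == "study1" else scenario.n_eqtl2
    if n < 10:
        raise ValueError(f"{which} requires n >= 10, got {n}")
    rng = np.random.default_rng([scenario.seed, _STREAM_EQTL[which]])
    g = _draw_genotypes(panel, n, rng)
    expr = rng.standard_normal(n)
    if scenario.causal_eqtl_idx is not None:
        expr = expr + scenario.beta_expr * g[:, scenario.causal_eqtl_idx]
    if scenario.secondary_eqtl_idx is not None:
        expr = expr + SECONDARY_EFFECT_FRACTION * scenario.beta_expr * g[:, scenario.secondary_eqtl_idx]
    return EqtlDataset(
        dosages=g.astype(float),
        expression={probe_id: expr},
        sample_ids=[f"{which}_s{i + 1:04d}" for i in range(n)],
        snp_ids=panel.snp_ids,
    )


def ld_r2(dosages1: np.ndarray, dosages2: np.ndarray) -> float:
    """Squared Pearson correlation between two dosage (or allele) vectors."""
    x = np.asarray(dosages1, dtype=float)
    y = np.asarray(dosages2, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("ld_r2 requires two equal-length vectors of length >= 2")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise ValueError("r2 is undefined for a constant vector")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def pick_low_ld_pair(
    panel: HaplotypePanel, max_r2: float = 0.05
) -> tuple[int, int]:
    """Deterministically pick two panel SNPs with haplotype r2 below a bound.

    Scans outward from the first- and third-quartile positions, preferring
    well-separated SNPs (the Markov LD model decays with distance).  Raises
    if no such pair exists.
    """
    Q = panel.Q
    a0, b0 = Q // 4, (3 * Q) // 4
    H = panel.alleles.astype(float)
    for a in list(range(a0, -1, -1)) + list(range(a0 + 1, Q)):
        if np.std(H[:, a]) == 0:
            continue
        for b in list(range(b0, Q)) + list(range(b0 - 1, -1, -1)):
            if b == a or np.std(H[:, b]) == 0:
                continue
            if ld_r2(H[:, a], H[:, b]) < max_r2:
                return (a, b) if a < b else (b, a)
    raise RuntimeError(f"no SNP pair with r2 < {max_r2} in panel")


def pick_tagging_snp(
    panel: HaplotypePanel, primary: int, target_r2: float = 0.3
) -> int:
    """Pick the panel SNP whose haplotype r2 with ``primary`` is closest to
    ``target_r2`` (used to plant a partially correlated secondary eQTL)."""
    H = panel.alleles.astype(float)
    if np.std(H[:, primary]) == 0:
        raise ValueError("primary SNP is monomorphic in the panel")
    best, best_gap = None, math.inf
    for j in range(panel.Q):
        if j == primary or np.std(H[:, j]) == 0:
            continue
        gap = abs(ld_r2(H[:, primary], H[:, j]) - target_r2)
        if gap < best_gap:
            best, best_gap = j, gap
    if best is None:
        raise RuntimeError("no candidate secondary SNP in panel")
    return best
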