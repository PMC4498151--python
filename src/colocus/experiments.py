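"""Reusable simulation experiments: hypothesis recovery and p12 calibration.

These drive the full stack — panel simulation, case-control and eQTL
cohorts, OLS estimation, ABFs and posteriors — and are used both by the
validation suite and for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import CalibrationResult, calibrate_p12
from .core import AbfSettings, ColocPriors, ColocResult, coloc_posteriors, log_abf_from_stat
from .eqtl import fit_cis_eqtl
from .synthetic import (
    HaplotypePanel,
    ScenarioSpec,
    pick_low_ld_pair,
    simulate_case_control_gwas,
    simulate_eqtl_study,
    simulate_haplotype_panel,
)

__all__ = ["scenario_coloc", "recovery_batch", "calibration_mixture"]


def scenario_coloc(
    panel: HaplotypePanel,
    scenario: ScenarioSpec,
    priors: ColocPriors | None = None,
    settings: AbfSettings | None = None,
    *,
    grid: tuple[float, ...] | None = None,
) -> ColocResult | dict[float, ColocResult]:
    """Simulate both cohorts for a scenario and colocalise them.

    The disease trait enters through the p-value/MAF route (as for real GWAS
    downloads) and the expression trait through the effect/SE route.  With
    ``grid`` set, returns one result per p12 value computed on identical
    evidence (for calibration experiments).
    """
    priors = priors or ColocPriors()
    settings = settings or AbfSettings()
    _, _, gstats = simulate_case_control_gwas(panel, scenario)
    dataset = simulate_eqtl_study(panel, scenario, "study1")
    estats = fit_cis_eqtl(dataset, "P1")
    gd = {s.snp_id: s for s in gstats}
    ed = {s.snp_id: s for s in estats}
    common = [s for s in panel.snp_ids if s in gd and s in ed]
    if len(common) < 2:
        raise RuntimeError("fewer than 2 SNPs shared between simulated cohorts")
    l1 = np.array([log_abf_from_stat(gd[s], settings) for s in common])
    l2 = np.array([log_abf_from_stat(ed[s], settings) for s in common])
    kwargs = dict(
        gwas_min_p=min(gd[s].p for s in common),
        eqtl_min_p=min(ed[s].p for s in common),
    )
    if grid is None:
        return coloc_posteriors(l1, l2, priors, **kwargs)
    return {g: coloc_posteriors(l1, l2, priors.with_p12(g), **kwargs) for g in grid}


def _scenario_for(hypothesis: str, panel: HaplotypePanel, seed: int, *,
                  log_or: float, beta_expr: float,
                  n_cases: int, n_controls: int, n_eqtl: int) -> ScenarioSpec:
    mid = panel.Q // 2
    if hypothesis == "H0":
        d_idx = e_idx = None
    elif hypothesis == "H1":
        d_idx, e_idx = mid, None
    elif hypothesis == "H2":
        d_idx, e_idx = None, mid
    elif hypothesis == "H3":
        d_idx, e_idx = pick_low_ld_pair(panel, max_r2=0.05)
    elif hypothesis == "H4":
        d_idx = e_idx = mid
    else:
        raise ValueError(f"unsupported hypothesis {hypothesis!r}")
    return ScenarioSpec(
        hypothesis=hypothesis,
        causal_disease_idx=d_idx,
        causal_eqtl_idx=e_idx,
        log_or=log_or if d_idx is not None else 0.0,
        beta_expr=beta_expr if e_idx is not None else 0.0,
        n_cases=n_cases, n_controls=n_controls,
        n_eqtl1=n_eqtl, seed=seed,
    )


def recovery_batch(
    hypothesis: str,
    n_seeds: int = 50,
    *,
    Q: int = 300,
    n_hap: int = 1000,
    rho: float = 0.9,
    n_cases: int = 2000,
    n_controls: int = 2000,
    n_eqtl: int = 400,
    log_or: float = 0.5,
    beta_expr: float = 1.0,
    seed0: int = 0,
    priors: ColocPriors | None = None,
) -> list[ColocResult]:
    """Colocalisation results for ``n_seeds`` independent replicates of one
    causal hypothesis, used to measure hypothesis recovery rates."""
    out = []
    for k in range(n_seeds):
        seed = seed0 + k
        panel = simulate_haplotype_panel(Q, n_hap, rho=rho, seed=seed)
        scenario = _scenario_for(
            hypothesis, panel, seed, log_or=log_or, beta_expr=beta_expr,
            n_cases=n_cases, n_controls=n_controls, n_eqtl=n_eqtl,
        )
        out.append(scenario_coloc(panel, scenario, priors))
    return out


def calibration_mixture(
    n_regions: int = 200,
    *,
    Q: int = 101,
    n_hap: int = 600,
    rho: float = 0.9,
    shared_fraction: float = 0.5,
    n_cases: int = 1000,
    n_controls: int = 1000,
    n_eqtl: int = 300,
    log_or: float = 0.5,
    beta_expr: float = 1.0,
    grid: tuple[float, ...] = (1e-7, 1e-6, 1e-5),
    threshold: float = 0.8,
    seed0: int = 0,
    priors: ColocPriors | None = None,
) -> CalibrationResult:
    """Calibrate p12 on a synthetic region set with a known shared-causal mix.

    Every region carries causal variants for both traits; a fraction
    ``shared_fraction`` share one variant (H4) and the rest use two variants
    in low LD (H3).  At Q = 101 and a 50% mixture the matching grid value is
    1e-6, whose prior colocalisation fraction is ~0.5.
    """
    priors = priors or ColocPriors()
    n_shared = int(round(shared_fraction * n_regions))
    pair_results: dict[float, list[ColocResult]] = {g: [] for g in grid}
    for k in range(n_regions):
        seed = seed0 + k
        hypothesis = "H4" if k < n_shared else "H3"
        panel = simulate_haplotype_panel(Q, n_hap, rho=rho, seed=seed)
        scenario = _scenario_for(
            hypothesis, panel, seed, log_or=log_or, beta_expr=beta_expr,
            n_cases=n_cases, n_controls=n_controls, n_eqtl=n_eqtl,
        )
        per_grid = scenario_coloc(panel, scenario, priors, grid=grid)
        for g, res in per_grid.items():
            pair_results[g].append(res)
    return calibrate_p12(pair_results, grid=grid, threshold=threshold, base_priors=priors)
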