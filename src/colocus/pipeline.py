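"""End-to-end orchestration: QC -> eQTL estimation -> colocalisation ->
classification -> enrichment -> p12 calibration, driven by a YAML config.

Config schema (paths are resolved relative to the config file)::

    seed: 1                      # recorded in the log; the pipeline itself
                                 # is deterministic given its inputs
    out_dir: results
    priors: {p1: 1.0e-4, p2: 1.0e-4, p12: 1.0e-6}
    calibration: {grid: [1.0e-7, 1.0e-6, 1.0e-5], threshold: 0.8}
    thresholds: {overlap: 0.99, gwas_p: 5.0e-8, eqtl_p: 1.0e-10, assoc: 0.8}
    regions: {path: regions.bed, dialect: bed}
    probes: probes.tsv
    candidates: candidates.txt   # optional, one gene per line
    diseases:
      - {name: T1D, gwas: gwas_T1D.tsv, n_cases: 2000, n_controls: 2000}
    cell_states:
      - name: monocytes
        studies:
          - {vcf: study1.vcf, expression: expr1.tsv}
          - {vcf: study2.vcf, expression: expr2.tsv}

Results are written as ``results.tsv`` (one row per disease x probe x cell
state), ``enrichment.json``, ``calibration.json`` plus per-pair curves, a
``qc_report.tsv`` of removed SNPs and ``summary_counts.tsv``.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import calibration as calib_mod
from . import data_io, qc
from .core import AbfSettings, ColocPriors, classify_pair, coloc_posteriors, log_abf_from_stat
from .enrichment import candidate_gene_enrichment, summarize_counts
from .eqtl import EqtlDataset, fit_cis_eqtl, meta_analyse

__all__ = ["run_pipeline", "PipelineError"]

log = logging.getLogger("colocus.pipeline")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message is tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _resolve(base: Path, p) -> Path:
    p = Path(p)
    return p if p.is_absolute() else base / p


def _load_config(config_path) -> dict:
    config_path = Path(config_path)
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh)
    cfg["_base"] = config_path.parent
    return cfg


class _Stage:
    """Context manager that logs wall time and tags failures by stage."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        self.t0 = time.perf_counter()
        log.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.perf_counter() - self.t0
        if exc_type is None:
            log.info("stage %s: done in %.2fs", self.name, dt)
            return False
        if isinstance(exc, PipelineError):
            return False
        raise PipelineError(self.name, str(exc)) from exc


def _study_data(base: Path, study_cfg: dict):
    dosage = data_io.read_dosages(_resolve(base, study_cfg["vcf"]))
    expr = data_io.read_expression(_resolve(base, study_cfg["expression"]))
    shared = [s for s in dosage.sample_ids if s in expr.columns]
    if not shared:
        raise ValueError(f"no shared samples between {study_cfg['vcf']} and {study_cfg['expression']}")
    row_idx = [dosage.sample_ids.index(s) for s in shared]
    dosages = dosage.dosages[row_idx, :]
    report = qc.filter_snps(qc.snp_records_from_dosages(dosages, dosage.snps))
    kept_ids = {r.snp_id for r in report.kept}
    return {
        "dosages": dosages,
        "sample_ids": shared,
        "snps": dosage.snps,
        "expression": expr[shared],
        "qc": report,
        "kept_ids": kept_ids,
    }


def _fit_region_probe(study: dict, probe_id: str, kept_region_ids: list[str]):
    """OLS stats for one probe over the QC-passing SNPs inside one region."""
    if probe_id not in study["expression"].index:
        return None
    snp_ids = study["snps"]["snp_id"].tolist()
    cols = [snp_ids.index(s) for s in kept_region_ids]
    ds = EqtlDataset(
        dosages=study["dosages"][:, cols],
        expression={probe_id: study["expression"].loc[probe_id].to_numpy(dtype=float)},
        sample_ids=study["sample_ids"],
        snp_ids=kept_region_ids,
    )
    return fit_cis_eqtl(ds, probe_id)


def run_pipeline(config_path, out_dir=None) -> Path:
    """Run the full analysis described by a YAML config; returns the output
    directory.  Deterministic given the config and input files."""
    logging.basicConfig(stream=sys.stderr, level=logging.INFO, format="%(message)s")
    cfg = _load_config(config_path)
    base: Path = cfg["_base"]

    with _Stage("config"):
        priors = ColocPriors(**{k: float(v) for k, v in cfg.get("priors", {}).items()})
        thr = cfg.get("thresholds", {})
        overlap_thr = float(thr.get("overlap", 0.99))
        gwas_gate = float(thr.get("gwas_p", 5e-8))
        eqtl_gate = float(thr.get("eqtl_p", 1e-10))
        assoc_thr = float(thr.get("assoc", 0.8))
        cal_cfg = cfg.get("calibration", {})
        grid = tuple(float(g) for g in cal_cfg.get("grid", calib_mod.DEFAULT_GRID))
        cal_threshold = float(cal_cfg.get("threshold", 0.8))
        out = Path(out_dir) if out_dir is not None else _resolve(base, cfg.get("out_dir", "results"))
        out.mkdir(parents=True, exist_ok=True)
        settings = AbfSettings()

    with _Stage("inputs"):
        regions_cfg = cfg["regions"]
        if isinstance(regions_cfg, str):
            regions_cfg = {"path": regions_cfg, "dialect": "bed"}
        regions = data_io.read_regions(
            _resolve(base, regions_cfg["path"]), regions_cfg.get("dialect", "bed")
        )
        probes = data_io.read_probes(_resolve(base, cfg["probes"]))
        candidates: set[str] = set()
        if cfg.get("candidates"):
            candidates = {
                line.strip()
                for line in open(_resolve(base, cfg["candidates"]))
                if line.strip()
            }
        gwas = {}
        for d in cfg["diseases"]:
            gwas[d["name"]] = data_io.read_gwas_summary(
                _resolve(base, d["gwas"]), int(d["n_cases"]), int(d["n_controls"])
            )

    with _Stage("qc"):
        cell_states = {}
        qc_rows = []
        for cs in cfg["cell_states"]:
            studies = [_study_data(base, s) for s in cs["studies"]]
            cell_states[cs["name"]] = studies
            for i, st in enumerate(studies, start=1):
                for rec, reason in st["qc"].removed:
                    qc_rows.append(
                        {"cell_state": cs["name"], "study": i, "snp": rec.snp_id, "reason": reason}
                    )
                log.info(
                    "qc %s study %d: kept %d / removed %d SNPs",
                    cs["name"], i, len(st["qc"].kept), len(st["qc"].removed),
                )
        pd.DataFrame(qc_rows, columns=["cell_state", "study", "snp", "reason"]).to_csv(
            out / "qc_report.tsv", sep="\t", index=False
        )

    probe_gene = {p.probe_id: p.gene for p in probes}
    results = []
    grid_results: dict[float, list] = {g: [] for g in grid}

    with _Stage("coloc"):
        for region in regions:
            cis = qc.cis_window_probes(region, probes)
            for dname, gstats in gwas.items():
                if region.disease and region.disease != dname:
                    continue
                in_region = {
                    s.snp_id: s
                    for s in gstats
                    if s.chrom == region.chrom and region.start <= (s.pos or -1) <= region.end
                }
                for cs_name, studies in cell_states.items():
                    for probe in cis:
                        per_study = []
                        for st in studies:
                            kept_region = [
                                sid
                                for sid, chrom, pos in zip(
                                    st["snps"]["snp_id"], st["snps"]["chrom"], st["snps"]["pos"]
                                )
                                if sid in st["kept_ids"]
                                and str(chrom) == region.chrom
                                and region.start <= pos <= region.end
                                and sid in in_region
                            ]
                            stats = _fit_region_probe(st, probe.probe_id, kept_region)
                            if stats:
                                per_study.append(stats)
                        if not per_study:
                            continue
                        estats = per_study[0] if len(per_study) == 1 else meta_analyse(*per_study[:2])
                        estats = {s.snp_id: s for s in estats}
                        common = sorted(
                            set(estats) & set(in_region),
                            key=lambda sid: in_region[sid].pos,
                        )
                        ok, reasons = qc.region_eligible(region, cis, len(common))
                        if not ok:
                            log.info(
                                "skip %s/%s/%s/%s: %s",
                                region.region_id, dname, cs_name, probe.probe_id, ",".join(reasons),
                            )
                            continue
                        l1 = np.array([log_abf_from_stat(in_region[s], settings) for s in common])
                        l2 = np.array([log_abf_from_stat(estats[s], settings) for s in common])
                        gwas_min_p = min(in_region[s].p for s in common)
                        eqtl_min_p = min(estats[s].p for s in common)
                        res = coloc_posteriors(
                            l1, l2, priors,
                            gwas_min_p=gwas_min_p, eqtl_min_p=eqtl_min_p,
                            region=region.region_id, disease=dname,
                            probe=probe.probe_id, gene=probe_gene[probe.probe_id],
                            cell_state=cs_name,
                        )
                        res.classification = classify_pair(
                            res,
                            gwas_gate=gwas_gate,
                            eqtl_gate=eqtl_gate,
                            overlap_threshold=overlap_thr,
                        )
                        results.append(res)
                        for g in grid:
                            grid_results[g].append(
                                coloc_posteriors(l1, l2, priors.with_p12(g))
                            )
        data_io.write_coloc_table(results, out / "results.tsv")
        summarize = summarize_counts(results) if results else pd.DataFrame()
        summarize.to_csv(out / "summary_counts.tsv", sep="\t")

    with _Stage("enrichment"):
        enrich_out = {"error": "no results"} if not results else None
        if results:
            try:
                enrich_out = candidate_gene_enrichment(results, candidates, assoc_thr).to_dict()
            except ValueError as exc:
                enrich_out = {"error": str(exc)}
        with open(out / "enrichment.json", "w") as fh:
            json.dump(enrich_out, fh, indent=2)

    with _Stage("calibration"):
        cal_out = {"error": "no results"}
        try:
            cal = calib_mod.calibrate_p12(
                grid_results, grid=grid, threshold=cal_threshold, base_priors=priors
            )
            cal_out = cal.to_dict()
            cal.curves.to_csv(out / "calibration_curves.tsv", sep="\t", index=False)
        except (ValueError, KeyError) as exc:
            cal_out = {"error": str(exc)}
        with open(out / "calibration.json", "w") as fh:
            json.dump(cal_out, fh, indent=2)

    log.info("pipeline complete: %d pairwise analyses -> %s", len(results), out)
    return out
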