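"""Readers and writers for the tabular and VCF formats the pipeline touches.

All coordinates are normalised to 1-based inclusive internally (the VCF
convention); BED input/output is converted at the boundary.  Readers reject
records that violate type invariants with an error that locates the
offending row — no silent coercion.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .eqtl import AssocStat

__all__ = [
    "DataFormatError",
    "RegionSpec",
    "ProbeSpec",
    "SnpRecord",
    "DosageData",
    "read_gwas_summary",
    "write_gwas_summary",
    "read_regions",
    "write_regions",
    "read_probes",
    "write_probes",
    "read_dosages",
    "write_dosages",
    "read_expression",
    "write_expression",
    "read_coloc_table",
    "write_coloc_table",
]

GWAS_COLUMNS = ["snp", "chrom", "pos", "a1", "a2", "maf", "p"]


class DataFormatError(ValueError):
    """A file does not conform to its documented format."""


@dataclass(frozen=True)
class RegionSpec:
    """A disease-associated region in 1-based inclusive coordinates."""

    region_id: str
    chrom: str
    start: int
    end: int
    disease: str = ""

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError(f"{self.region_id}: chrom must be non-empty")
        if self.start > self.end:
            raise ValueError(f"{self.region_id}: start {self.start} > end {self.end}")


@dataclass(frozen=True)
class ProbeSpec:
    """An expression probe; start/end span the min/max of its position windows."""

    probe_id: str
    gene: str
    chrom: str
    start: int
    end: int
    quality_ok: bool = True

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.probe_id}: start {self.start} > end {self.end}")


@dataclass(frozen=True)
class SnpRecord:
    """One variant with the per-SNP QC metrics.

    ``info`` (imputation quality) must be absent for genotyped SNPs; imputed
    SNPs may carry it (its absence there is caught at filter time).
    """

    snp_id: str
    chrom: str
    pos: int
    allele1: str
    allele2: str
    maf: float
    call_rate: float = 1.0
    hwe_z: float = 0.0
    info: float | None = None
    source: str = "genotyped"

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf <= 0.5:
            raise ValueError(f"{self.snp_id}: maf must be in [0, 0.5], got {self.maf}")
        if not 0.0 <= self.call_rate <= 1.0:
            raise ValueError(f"{self.snp_id}: call_rate must be in [0, 1]")
        if self.source not in ("genotyped", "imputed"):
            raise ValueError(f"{self.snp_id}: source must be genotyped or imputed")
        if self.source == "genotyped" and self.info is not None:
            raise ValueError(f"{self.snp_id}: genotyped SNPs must not carry an info score")
        if self.info is not None and not 0.0 <= self.info <= 1.0:
            raise ValueError(f"{self.snp_id}: info must be in [0, 1]")


@dataclass
class DosageData:
    """Genotype dosages keyed by sample and SNP id (NaN = missing)."""

    dosages: np.ndarray  # n_samples x n_snps
    sample_ids: list[str]
    snps: pd.DataFrame  # columns: snp_id, chrom, pos, a1, a2

    @property
    def snp_ids(self) -> list[str]:
        return self.snps["snp_id"].tolist()


# ---------------------------------------------------------------------------
# GWAS summary statistics
# ---------------------------------------------------------------------------

def read_gwas_summary(path, n_cases: int, n_controls: int) -> list[AssocStat]:
    """Read tab-delimited disease summary statistics (p/MAF route).

    Required header columns: ``snp chrom pos a1 a2 maf p``; optional ``beta``
    and ``varbeta`` are carried through when present.  Rows with ``p``
    outside (0, 1] or ``maf`` outside (0, 0.5] are rejected with an error
    naming the file line, as are duplicate SNP ids.
    """
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("n_cases and n_controls must be positive")
    df = pd.read_csv(path, sep="\t", dtype={"snp": str, "chrom": str})
    for col in GWAS_COLUMNS:
        if col not in df.columns:
            raise DataFormatError(f"{path}: missing required column {col!r}")
    dups = df["snp"][df["snp"].duplicated()]
    if len(dups):
        raise DataFormatError(f"{path}: duplicate snp id {dups.iloc[0]!r}")
    case_fraction = n_cases / (n_cases + n_controls)
    n = n_cases + n_controls
    has_effect = "beta" in df.columns and "varbeta" in df.columns
    out: list[AssocStat] = []
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        p = float(row["p"])
        maf = float(row["maf"])
        if not 0.0 < p <= 1.0:
            raise DataFormatError(f"{path} line {line}: p = {p} outside (0, 1]")
        if not 0.0 < maf <= 0.5:
            raise DataFormatError(f"{path} line {line}: maf = {maf} outside (0, 0.5]")
        beta = varbeta = None
        if has_effect and math.isfinite(row["beta"]) and math.isfinite(row["varbeta"]):
            beta = float(row["beta"])
            varbeta = float(row["varbeta"])
        out.append(
            AssocStat(
                snp_id=str(row["snp"]),
                beta=beta,
                varbeta=varbeta,
                p=p,
                maf=maf,
                n=n,
                trait_type="case-control",
                case_fraction=case_fraction,
                chrom=str(row["chrom"]),
                pos=int(row["pos"]),
                allele1=str(row["a1"]),
                allele2=str(row["a2"]),
            )
        )
    return out


def write_gwas_summary(stats: list[AssocStat], path) -> None:
    rows = []
    for s in stats:
        rows.append(
            {
                "snp": s.snp_id,
                "chrom": s.chrom or "",
                "pos": s.pos if s.pos is not None else -1,
                "a1": s.allele1 or "N",
                "a2": s.allele2 or "N",
                "maf": s.maf,
                "p": s.p,
            }
        )
    pd.DataFrame(rows, columns=GWAS_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Regions and probes
# ---------------------------------------------------------------------------

def read_regions(path, dialect: str = "bed") -> list[RegionSpec]:
    """Read region definitions.

    ``bed`` lines are 0-based half-open (``chrom start end name [disease]``,
    no header); ``tsv1based`` files are headered, 1-based inclusive.  Output
    is always 1-based inclusive.
    """
    regions: list[RegionSpec] = []
    if dialect == "bed":
        with open(path) as fh:
            for line_no, raw in enumerate(fh, start=1):
                line = raw.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split()
                if len(fields) < 4:
                    raise DataFormatError(f"{path} line {line_no}: expected >= 4 BED fields")
                chrom, start, end, name = fields[:4]
                disease = fields[4] if len(fields) > 4 else ""
                try:
                    start_i, end_i = int(start), int(end)
                except ValueError as exc:
                    raise DataFormatError(f"{path} line {line_no}: non-integer coordinate") from exc
                try:
                    regions.append(
                        RegionSpec(
                            region_id=name, chrom=chrom, start=start_i + 1, end=end_i, disease=disease
                        )
                    )
                except ValueError as exc:
                    raise DataFormatError(f"{path} line {line_no}: {exc}") from exc
    elif dialect == "tsv1based":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "region_id": str})
        for col in ("region_id", "chrom", "start", "end"):
            if col not in df.columns:
                raise DataFormatError(f"{path}: missing required column {col!r}")
        for idx, row in df.iterrows():
            try:
                regions.append(
                    RegionSpec(
                        region_id=str(row["region_id"]),
                        chrom=str(row["chrom"]),
                        start=int(row["start"]),
                        end=int(row["end"]),
                        disease=str(row["disease"]) if "disease" in df.columns and pd.notna(row["disease"]) else "",
                    )
                )
            except ValueError as exc:
                raise DataFormatError(f"{path} line {idx + 2}: {exc}") from exc
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    ids = [r.region_id for r in regions]
    if len(set(ids)) != len(ids):
        dup = next(i for i in ids if ids.count(i) > 1)
        raise DataFormatError(f"{path}: duplicate region_id {dup!r}")
    return regions


def write_regions(regions: list[RegionSpec], path, dialect: str = "bed") -> None:
    if dialect == "bed":
        with open(path, "w") as fh:
            for r in regions:
                fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.region_id}\t{r.disease}\n")
    elif dialect == "tsv1based":
        pd.DataFrame(
            [
                {"region_id": r.region_id, "chrom": r.chrom, "start": r.start, "end": r.end, "disease": r.disease}
                for r in regions
            ],
            columns=["region_id", "chrom", "start", "end", "disease"],
        ).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_probes(path) -> list[ProbeSpec]:
    """Read probe annotations: ``probe_id gene chrom start end quality_ok``."""
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "gene": str, "chrom": str})
    for col in ("probe_id", "gene", "chrom", "start", "end"):
        if col not in df.columns:
            raise DataFormatError(f"{path}: missing required column {col!r}")
    probes = []
    for idx, row in df.iterrows():
        quality = True
        if "quality_ok" in df.columns:
            quality = str(row["quality_ok"]).strip().lower() in ("1", "true", "yes")
        try:
            probes.append(
                ProbeSpec(
                    probe_id=str(row["probe_id"]),
                    gene=str(row["gene"]),
                    chrom=str(row["chrom"]),
                    start=int(row["start"]),
                    end=int(row["end"]),
                    quality_ok=quality,
                )
            )
        except ValueError as exc:
            raise DataFormatError(f"{path} line {idx + 2}: {exc}") from exc
    return probes


def write_probes(probes: list[ProbeSpec], path) -> None:
    pd.DataFrame(
        [
            {
                "probe_id": p.probe_id,
                "gene": p.gene,
                "chrom": p.chrom,
                "start": p.start,
                "end": p.end,
                "quality_ok": p.quality_ok,
            }
            for p in probes
        ],
        columns=["probe_id", "gene", "chrom", "start", "end", "quality_ok"],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF dosages
# ---------------------------------------------------------------------------

def _prescan_vcf(path) -> None:
    """Structural validation pass so parse errors carry a line number."""
    n_fixed = 9
    n_samples = None
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            fields = line.split("\t")
            if line.startswith("#CHROM"):
                if len(fields) < n_fixed:
                    raise DataFormatError(f"{path} line {line_no}: truncated VCF header")
                n_samples = len(fields) - n_fixed
                continue
            if n_samples is None:
                raise DataFormatError(f"{path} line {line_no}: data before #CHROM header")
            if len(fields) != n_fixed + n_samples:
                raise DataFormatError(
                    f"{path} line {line_no}: expected {n_fixed + n_samples} fields, got {len(fields)}"
                )
            try:
                int(fields[1])
            except ValueError as exc:
                raise DataFormatError(f"{path} line {line_no}: non-integer POS {fields[1]!r}") from exc
    if n_samples is None:
        raise DataFormatError(f"{path}: no #CHROM header line")


def read_dosages(path) -> DosageData:
    """Read genotype dosages from a VCF.

    A per-sample ``DS`` FORMAT field is used when present; otherwise ``GT``
    is converted to a dosage by counting copies of allele 2 (ALT).  Missing
    entries become NaN and are never imputed.
    """
    from cyvcf2 import VCF

    _prescan_vcf(path)
    vcf = VCF(os.fspath(path))
    sample_ids = list(vcf.samples)
    rows: list[np.ndarray] = []
    meta: list[dict] = []
    for variant in vcf:
        ds = None
        try:
            ds = variant.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            vals = np.asarray(ds, dtype=float).reshape(len(sample_ids))
            vals = np.where((vals < 0) | (vals > 2), np.nan, vals)
        else:
            gts = np.asarray(variant.genotypes)  # per sample: [allele1, allele2, phased]
            alleles = gts[:, :2].astype(float)
            alleles[alleles < 0] = np.nan
            vals = alleles.sum(axis=1)
        rows.append(vals)
        meta.append(
            {
                "snp_id": variant.ID or f"{variant.CHROM}:{variant.POS}",
                "chrom": variant.CHROM,
                "pos": variant.POS,
                "a1": variant.REF,
                "a2": variant.ALT[0] if variant.ALT else ".",
            }
        )
    dosages = np.array(rows, dtype=float).T if rows else np.empty((len(sample_ids), 0))
    return DosageData(dosages=dosages, sample_ids=sample_ids, snps=pd.DataFrame(meta, columns=["snp_id", "chrom", "pos", "a1", "a2"]))


def write_dosages(data: DosageData, path) -> None:
    """Write dosages as an uncompressed VCF with GT and DS FORMAT fields."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage of ALT allele">\n')
        for chrom in pd.unique(data.snps["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(data.sample_ids) + "\n")
        for j, snp in data.snps.iterrows():
            col = data.dosages[:, j]
            cells = []
            for v in col:
                if not np.isfinite(v):
                    cells.append("./.:.")
                    continue
                if float(v).is_integer():
                    k = int(v)
                    gt = ["0/0", "0/1", "1/1"][k]
                else:
                    gt = "./."
                cells.append(f"{gt}:{v:.6g}")
            fh.write(
                f"{snp['chrom']}\t{int(snp['pos'])}\t{snp['snp_id']}\t{snp['a1']}\t{snp['a2']}\t.\t.\t.\tGT:DS\t"
                + "\t".join(cells)
                + "\n"
            )


# ---------------------------------------------------------------------------
# Expression tables
# ---------------------------------------------------------------------------

def read_expression(path) -> pd.DataFrame:
    """Read a probe-by-sample expression table (first column ``probe_id``)."""
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str})
    if "probe_id" not in df.columns:
        raise DataFormatError(f"{path}: missing required column 'probe_id'")
    df = df.set_index("probe_id")
    if not np.all(np.isfinite(df.to_numpy(dtype=float))):
        raise DataFormatError(f"{path}: non-finite expression values")
    return df


def write_expression(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=True, index_label="probe_id")


# ---------------------------------------------------------------------------
# Colocalisation result tables
# ---------------------------------------------------------------------------

_COLOC_COLUMNS = [
    "region", "disease", "probe", "gene", "cell_state", "Q",
    "PP0", "PP1", "PP2", "PP3", "PP4", "PP3+PP4", "PP4/PP3", "class",
]


def write_coloc_table(results, path) -> None:
    """Write colocalisation results as a tab-delimited table.

    Columns: region, disease, probe, gene, cell_state, Q, PP0..PP4,
    PP3+PP4, PP4/PP3 and the classification.  Read-back with
    :func:`read_coloc_table` reproduces all probabilities to 6 decimals.
    """
    rows = []
    for r in results:
        rows.append(
            {
                "region": r.region,
                "disease": r.disease,
                "probe": r.probe,
                "gene": r.gene,
                "cell_state": r.cell_state,
                "Q": r.Q,
                "PP0": r.pp0,
                "PP1": r.pp1,
                "PP2": r.pp2,
                "PP3": r.pp3,
                "PP4": r.pp4,
                "PP3+PP4": r.pp3_plus_pp4,
                "PP4/PP3": r.pp4_over_pp3,
                "class": r.classification or "",
            }
        )
    pd.DataFrame(rows, columns=_COLOC_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def read_coloc_table(path) -> list:
    from .core import ColocResult

    df = pd.read_csv(path, sep="\t", dtype={"region": str, "disease": str, "probe": str, "gene": str, "cell_state": str}, keep_default_na=False, na_values=["nan"])
    for col in _COLOC_COLUMNS:
        if col not in df.columns:
            raise DataFormatError(f"{path}: missing required column {col!r}")
    results = []
    for _, row in df.iterrows():
        pp = np.array([float(row[f"PP{k}"]) for k in range(5)])
        pp = pp / pp.sum()  # undo 10-digit rounding drift so invariants hold
        results.append(
            ColocResult(
                Q=int(row["Q"]),
                pp0=pp[0], pp1=pp[1], pp2=pp[2], pp3=pp[3], pp4=pp[4],
                sum_log_abf1=math.nan,
                sum_log_abf2=math.nan,
                classification=str(row["class"]) or None,
                region=str(row["region"]),
                disease=str(row["disease"]),
                probe=str(row["probe"]),
                gene=str(row["gene"]),
                cell_state=str(row["cell_state"]),
            )
        )
    return results
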