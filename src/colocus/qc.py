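"""SNP, probe and region quality control applied before colocalisation.

Thresholds (inclusive as printed): genotyped SNPs kept when MAF >= 0.005,
call rate >= 0.99 and |HWE z| <= 4; imputed SNPs when MAF >= 0.005,
|HWE z| <= 4 and imputation info >= 0.3.  Probes must fall within +/-200 kb
of a region and carry a good quality score; regions need at least one
retained probe and >= 20 SNPs common to the disease and eQTL datasets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import ProbeSpec, RegionSpec, SnpRecord
from .synthetic import ld_r2

__all__ = [
    "QcReport",
    "hwe_zscore",
    "filter_snps",
    "cis_window_probes",
    "region_eligible",
    "probe_overlap_ld_filter",
    "snp_records_from_dosages",
    "MAF_MIN",
    "CALL_RATE_MIN",
    "HWE_Z_MAX",
    "INFO_MIN",
    "CIS_WINDOW",
    "MIN_COMMON_SNPS",
]

MAF_MIN = 0.005
CALL_RATE_MIN = 0.99
HWE_Z_MAX = 4.0
INFO_MIN = 0.3
CIS_WINDOW = 200_000
MIN_COMMON_SNPS = 20

#: Removal reason codes, in the order the rules are applied.
REASONS = ("MAF", "CALL_RATE", "HWE", "INFO", "PROBE_QUALITY", "PROBE_LD_OVERLAP")


@dataclass
class QcReport:
    """Partition of the input SNPs into kept and removed (with one reason)."""

    kept: list[SnpRecord]
    removed: list[tuple[SnpRecord, str]]

    def reason_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for _, reason in self.removed:
            counts[reason] = counts.get(reason, 0) + 1
        return counts


def hwe_zscore(nAA: int, nAB: int, nBB: int) -> float:
    """Signed Hardy-Weinberg z-score from genotype counts.

    The magnitude is the square root of the 1-df chi-square statistic of the
    observed genotype counts against the counts expected under HWE at the
    allele frequency estimated from the same counts; the sign is positive
    for a heterozygote excess.  Monomorphic input returns 0 by convention.
    """
    for name, v in (("nAA", nAA), ("nAB", nAB), ("nBB", nBB)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0, got {v}")
    n = nAA + nAB + nBB
    if n < 1:
        raise ValueError("at least one genotype is required")
    p = (2 * nAA + nAB) / (2 * n)
    if p == 0.0 or p == 1.0:
        return 0.0
    q = 1.0 - p
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    observed = np.array([nAA, nAB, nBB], dtype=float)
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    sign = 1.0 if nAB >= expected[1] else -1.0
    return sign * math.sqrt(chi2)


def filter_snps(records: list[SnpRecord]) -> QcReport:
    """Apply the per-SNP QC rules; the first failing rule is the reason.

    Genotyped: MAF, then call rate, then HWE.  Imputed: MAF, then HWE, then
    imputation info (an imputed record without an info score is an error).
    Idempotent: filtering the kept set removes nothing further.
    """
    kept: list[SnpRecord] = []
    removed: list[tuple[SnpRecord, str]] = []
    for rec in records:
        reason = None
        if rec.maf < MAF_MIN:
            reason = "MAF"
        elif rec.source == "genotyped":
            if rec.call_rate < CALL_RATE_MIN:
                reason = "CALL_RATE"
            elif abs(rec.hwe_z) > HWE_Z_MAX:
                reason = "HWE"
        else:
            if rec.info is None:
                raise ValueError(f"{rec.snp_id}: imputed SNP lacks an info score")
            if abs(rec.hwe_z) > HWE_Z_MAX:
                reason = "HWE"
            elif rec.info < INFO_MIN:
                reason = "INFO"
        if reason is None:
            kept.append(rec)
        else:
            removed.append((rec, reason))
    return QcReport(kept=kept, removed=removed)


def cis_window_probes(
    region: RegionSpec, probes: list[ProbeSpec], window: int = CIS_WINDOW
) -> list[ProbeSpec]:
    """Probes on the region's chromosome whose span intersects the +/-window.

    Intervals are closed; a probe ending exactly ``window`` bp before the
    region start is retained.  Probes flagged with poor quality are excluded.
    """
    lo = region.start - window
    hi = region.end + window
    return [
        p
        for p in probes
        if p.quality_ok and p.chrom == region.chrom and p.start <= hi and p.end >= lo
    ]


def region_eligible(
    region: RegionSpec,
    probes: list[ProbeSpec],
    common_snps: int,
    min_common: int = MIN_COMMON_SNPS,
) -> tuple[bool, list[str]]:
    """A region is analysed only with >= 1 cis probe and >= 20 common SNPs.

    ``common_snps`` counts QC-passing SNPs present in both the disease and
    eQTL datasets for the region.
    """
    reasons = []
    if len(probes) == 0:
        reasons.append("NO_PROBES")
    if common_snps < min_common:
        reasons.append("TOO_FEW_SNPS")
    return (len(reasons) == 0, reasons)


def probe_overlap_ld_filter(
    peak_snp: str,
    overlap_snps: list[str],
    dosages: pd.DataFrame,
    threshold: float = 0.6,
) -> tuple[bool, float]:
    """Exclude signals whose peak SNP tags a probe-overlapping SNP.

    ``dosages`` columns are SNP ids.  Returns ``(excluded, max_r2)`` where
    the signal is excluded iff the maximum r-squared between the peak SNP
    and any overlap SNP exceeds ``threshold``.  An empty overlap set retains
    the signal with max_r2 = 0.
    """
    if peak_snp not in dosages.columns:
        raise KeyError(f"peak SNP {peak_snp!r} absent from dosage matrix")
    if not overlap_snps:
        return False, 0.0
    peak = dosages[peak_snp].to_numpy(dtype=float)
    max_r2 = 0.0
    for snp in overlap_snps:
        if snp not in dosages.columns:
            raise KeyError(f"overlap SNP {snp!r} absent from dosage matrix")
        r2 = ld_r2(peak, dosages[snp].to_numpy(dtype=float))
        max_r2 = max(max_r2, r2)
    return max_r2 > threshold, max_r2


def snp_records_from_dosages(
    dosages: np.ndarray,
    snps: pd.DataFrame,
    source: str = "genotyped",
    info: np.ndarray | None = None,
) -> list[SnpRecord]:
    """Derive per-SNP QC metrics (MAF, call rate, HWE z) from a dosage matrix.

    HWE is evaluated on hard genotype counts (dosages rounded to 0/1/2);
    non-integral dosages contribute to MAF and call rate but not HWE.
    """
    records = []
    n_samples = dosages.shape[0]
    for j in range(dosages.shape[1]):
        col = dosages[:, j]
        obs = col[np.isfinite(col)]
        call_rate = len(obs) / n_samples if n_samples else 0.0
        f2 = float(np.mean(obs) / 2.0) if len(obs) else 0.0
        maf = min(f2, 1.0 - f2)
        hard = obs[np.isclose(obs, np.round(obs))]
        counts = [int(np.sum(np.round(hard) == k)) for k in (0, 1, 2)]
        z = hwe_zscore(*counts) if sum(counts) else 0.0
        row = snps.iloc[j]
        records.append(
            SnpRecord(
                snp_id=str(row["snp_id"]),
                chrom=str(row["chrom"]),
                pos=int(row["pos"]),
                allele1=str(row["a1"]),
                allele2=str(row["a2"]),
                maf=maf,
                call_rate=call_rate,
                hwe_z=z,
                info=None if source == "genotyped" else (float(info[j]) if info is not None else None),
                source=source,
            )
        )
    return records
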