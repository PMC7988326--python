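"""Tumor mutational burden in three nested flavors, normalized per callable Mb.

Overall TMB counts every somatic call; nonsynonymous TMB counts protein-
altering calls; clonal nonsynonymous TMB additionally requires the mutation
to be present in essentially every tumor cell, judged from its cancer cell
fraction (CCF). Rates divide the counts by the number of megabases at which
the tumor's coverage, purity and ploidy gave adequate power to detect a
clonal mutation, so patients sequenced more deeply or with purer tumors are
not artifactually inflated.

The CCF of a somatic mutation follows from the variant allele fraction (VAF)
via the standard copy-number-aware relation

    CCF = VAF * (purity * CN_tumor + (1 - purity) * CN_normal) / (purity * m)

where m is the mutation multiplicity (copies of the mutant allele per tumor
cell). A 95% interval is obtained by pushing the Clopper-Pearson binomial
interval on the VAF through the same linear map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .records import ClinicalRecord, CoverageSummary, MafRecord, VariantClass, maf_to_frame

logger = logging.getLogger(__name__)


@dataclass
class CancerCellFraction:
    point_estimate: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.point_estimate <= self.ci_high):
            raise ValueError("CCF interval must bracket the point estimate")


@dataclass
class TMBProfile:
    patient_id: str
    overall_count: int
    nonsyn_count: int
    clonal_nonsyn_count: int
    callable_mb: float
    overall_per_mb: float
    nonsyn_per_mb: float
    clonal_nonsyn_per_mb: float


def expected_vaf(ccf, purity, tumor_total_cn, multiplicity=1, normal_cn=2):
    """Expected VAF of a mutation at the given CCF, purity and copy state.

    This is the forward model inverted by :func:`compute_ccf`; the synthetic
    cohort generator draws read counts from the same relation.
    """
    ccf = np.asarray(ccf, dtype=float)
    denom = purity * np.asarray(tumor_total_cn, dtype=float) + (1.0 - purity) * normal_cn
    return purity * np.asarray(multiplicity, dtype=float) * ccf / denom


def infer_multiplicity(vaf, purity, tumor_total_cn, normal_cn=2):
    """Most likely integer multiplicity: round(VAF * total DNA / purity), in [1, CN]."""
    vaf = np.asarray(vaf, dtype=float)
    cn = np.asarray(tumor_total_cn, dtype=float)
    raw = vaf * (purity * cn + (1.0 - purity) * normal_cn) / purity
    mult = np.maximum(1, np.round(raw))
    return np.minimum(mult, np.maximum(cn, 1)).astype(int)


def _ccf_arrays(alt, total, purity, cn, mult, normal_cn=2, alpha=0.05):
    """Vectorized CCF point estimates and Clopper-Pearson 95% intervals."""
    alt = np.asarray(alt, dtype=float)
    total = np.asarray(total, dtype=float)
    vaf = np.where(total > 0, alt / np.maximum(total, 1), 0.0)
    scale = (purity * np.asarray(cn, dtype=float) + (1.0 - purity) * normal_cn) / (
        purity * np.asarray(mult, dtype=float)
    )
    point = np.maximum(vaf * scale, 0.0)
    # Clopper-Pearson on the VAF, pushed through the same linear map.
    with np.errstate(invalid="ignore"):
        lo = stats.beta.ppf(alpha / 2, alt, total - alt + 1)
        hi = stats.beta.ppf(1 - alpha / 2, alt + 1, total - alt)
    lo = np.where(alt == 0, 0.0, lo)
    hi = np.where(alt == total, 1.0, hi)
    return point, np.maximum(lo * scale, 0.0), hi * scale


def compute_ccf(vaf: float, purity: float, tumor_total_cn: int, multiplicity: int = 1,
                normal_cn: int = 2, alt_count: int | None = None,
                total_count: int | None = None) -> CancerCellFraction:
    """CCF of one mutation with a 95% interval propagated from binomial counts.

    If read counts are omitted the interval degenerates to the point estimate.
    """
    if purity <= 0:
        raise ValueError("purity must be positive")
    if tumor_total_cn == 0:
        raise ValueError("tumor_total_cn must be >= 1 for CCF estimation")
    scale = (purity * tumor_total_cn + (1.0 - purity) * normal_cn) / (purity * multiplicity)
    point = max(vaf * scale, 0.0)
    if alt_count is None or total_count is None:
        return CancerCellFraction(point, point, point)
    if total_count <= 0:
        raise ValueError("total_count must be positive")
    pt, lo, hi = _ccf_arrays(
        np.array([alt_count]), np.array([total_count]), purity,
        np.array([tumor_total_cn]), np.array([multiplicity]), normal_cn,
    )
    return CancerCellFraction(float(pt[0]), min(float(lo[0]), float(pt[0])), float(hi[0]))


def classify_clonality(ccf: CancerCellFraction, clonal_ccf_threshold: float = 0.95,
                       ci_floor: float = 0.75) -> str:
    """Label a mutation clonal or subclonal from its CCF estimate.

    Clonal iff the point estimate reaches ``clonal_ccf_threshold``, or the 95%
    interval reaches 1.0 while the point estimate is at least ``ci_floor`` —
    the second clause keeps moderately-covered truly-clonal mutations from
    being misclassified by binomial noise alone.
    """
    if ccf.point_estimate >= clonal_ccf_threshold:
        return "clonal"
    if ccf.ci_high >= 1.0 and ccf.point_estimate >= ci_floor:
        return "clonal"
    return "subclonal"


def callable_megabases(coverage: CoverageSummary, purity: float, ploidy: float,
                       min_power: float = 0.8, min_alt_reads: int = 4) -> float:
    """Megabases of sequence powered to detect a clonal single-copy mutation.

    A site of depth d is callable iff P(Binomial(d, f_exp) >= min_alt_reads)
    >= min_power, where f_exp is the expected VAF of a clonal mutation present
    at one copy given the tumor's purity and (rounded) ploidy. Computed from
    the depth histogram, never per site.
    """
    if len(coverage.depths) == 0:
        raise ValueError("empty depth histogram")
    if purity <= 0:
        raise ValueError("purity must be positive")
    depths = np.asarray(coverage.depths, dtype=int)
    counts = np.asarray(coverage.site_counts, dtype=float)
    f_exp = purity / (purity * round(ploidy) + (1.0 - purity) * 2.0)
    power = stats.binom.sf(min_alt_reads - 1, depths, f_exp)
    return float(counts[power >= min_power].sum() / 1e6)


def ccf_table(maf: pd.DataFrame, clinical: pd.DataFrame, normal_cn: int = 2,
              clonal_ccf_threshold: float = 0.95, ci_floor: float = 0.75) -> pd.DataFrame:
    """Annotate a somatic mutation frame with CCF and clonality, vectorized.

    Mutations at tumor copy number 0 are dropped with a logged count (a
    mutation cannot reside on zero copies; these are CN-call artifacts).
    """
    df = maf.merge(clinical[["patient_id", "purity", "ploidy"]], on="patient_id", how="left")
    cn_zero = df["tumor_total_cn"] == 0
    if cn_zero.any():
        logger.warning("excluding %d mutations at tumor copy number 0", int(cn_zero.sum()))
        df = df[~cn_zero].copy()
    total = df["alt_count"].to_numpy() + df["ref_count"].to_numpy()
    if (total <= 0).any():
        logger.warning("excluding %d mutations with zero total reads", int((total <= 0).sum()))
        df = df[total > 0].copy()
        total = df["alt_count"].to_numpy() + df["ref_count"].to_numpy()
    purity = df["purity"].to_numpy(dtype=float)
    cn = df["tumor_total_cn"].to_numpy(dtype=float)
    vaf = df["alt_count"].to_numpy(dtype=float) / total
    mult = infer_multiplicity(vaf, purity, cn, normal_cn)
    point, lo, hi = _ccf_arrays(df["alt_count"].to_numpy(), total, purity, cn, mult, normal_cn)
    clonal = (point >= clonal_ccf_threshold) | ((hi >= 1.0) & (point >= ci_floor))
    out = df.copy()
    out["vaf"] = vaf
    out["multiplicity"] = mult
    out["ccf"] = point
    out["ccf_ci_low"] = np.minimum(lo, point)
    out["ccf_ci_high"] = hi
    out["clonal"] = clonal
    return out


def compute_tmb_profiles(maf: pd.DataFrame, clinical: pd.DataFrame,
                         coverage: dict[str, CoverageSummary],
                         min_power: float = 0.8, min_alt_reads: int = 4,
                         normal_cn: int = 2, clonal_ccf_threshold: float = 0.95,
                         ci_floor: float = 0.75) -> pd.DataFrame:
    """Per-patient TMB table (counts and per-Mb rates for all three metrics).

    Patients with zero callable megabases are excluded with a warning; their
    TMB is undefined.
    """
    annotated = ccf_table(maf, clinical, normal_cn, clonal_ccf_threshold, ci_floor)
    nonsyn = annotated["variant_classification"] == VariantClass.NONSYNONYMOUS.value
    per_patient = pd.DataFrame({
        "overall_count": annotated.groupby("patient_id").size(),
        "nonsyn_count": annotated[nonsyn].groupby("patient_id").size(),
        "clonal_nonsyn_count": annotated[nonsyn & annotated["clonal"]].groupby("patient_id").size(),
    })
    rows = []
    for rec in clinical.itertuples(index=False):
        pid = rec.patient_id
        if pid not in coverage:
            logger.warning("patient %s has no coverage summary; excluded", pid)
            continue
        mb = callable_megabases(coverage[pid], rec.purity, rec.ploidy, min_power, min_alt_reads)
        if mb <= 0:
            logger.warning("patient %s has zero callable Mb; TMB undefined, excluded", pid)
            continue
        counts = per_patient.reindex([pid]).fillna(0).iloc[0] if pid in per_patient.index \
            else pd.Series({"overall_count": 0, "nonsyn_count": 0, "clonal_nonsyn_count": 0})
        rows.append({
            "patient_id": pid,
            "overall_count": int(counts["overall_count"]),
            "nonsyn_count": int(counts["nonsyn_count"]),
            "clonal_nonsyn_count": int(counts["clonal_nonsyn_count"]),
            "callable_mb": mb,
            "overall_per_mb": counts["overall_count"] / mb,
            "nonsyn_per_mb": counts["nonsyn_count"] / mb,
            "clonal_nonsyn_per_mb": counts["clonal_nonsyn_count"] / mb,
        })
    return pd.DataFrame(rows)


def compute_tmb(mutations: list[MafRecord], clinical: ClinicalRecord,
                coverage: CoverageSummary, **kwargs) -> TMBProfile:
    """TMB profile for a single patient from typed records."""
    from .records import clinical_to_frame

    maf = maf_to_frame([m for m in mutations if m.patient_id == clinical.patient_id])
    df = compute_tmb_profiles(maf, clinical_to_frame([clinical]),
                              {clinical.patient_id: coverage}, **kwargs)
    if df.empty:
        raise ValueError(f"TMB undefined for patient {clinical.patient_id} "
                         "(zero callable megabases)")
    row = df.iloc[0]
    return TMBProfile(
        patient_id=row["patient_id"],
        overall_count=int(row["overall_count"]),
        nonsyn_count=int(row["nonsyn_count"]),
        clonal_nonsyn_count=int(row["clonal_nonsyn_count"]),
        callable_mb=float(row["callable_mb"]),
        overall_per_mb=float(row["overall_per_mb"]),
        nonsyn_per_mb=float(row["nonsyn_per_mb"]),
        clonal_nonsyn_per_mb=float(row["clonal_nonsyn_per_mb"]),
    )
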