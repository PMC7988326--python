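"""Typed records for the pipeline's external tables.

The io readers return lists of these dataclasses (the stable, typed contract);
the computational modules work on pandas DataFrames for speed. Converters
between the two live here so the mapping is defined in exactly one place.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, fields
from typing import Iterable, Sequence

import pandas as pd


class VariantClass(str, enum.Enum):
    """Collapsed somatic effect classes."""

    SYNONYMOUS = "synonymous"
    NONSYNONYMOUS = "nonsynonymous"
    OTHER = "other"


#: MAF Variant_Classification values collapsed to the three-level scheme.
MAF_CLASSIFICATION_MAP = {
    "missense_mutation": VariantClass.NONSYNONYMOUS,
    "nonsense_mutation": VariantClass.NONSYNONYMOUS,
    "frame_shift_del": VariantClass.NONSYNONYMOUS,
    "frame_shift_ins": VariantClass.NONSYNONYMOUS,
    "splice_site": VariantClass.NONSYNONYMOUS,
    "nonstop_mutation": VariantClass.NONSYNONYMOUS,
    "silent": VariantClass.SYNONYMOUS,
    # the package's own simplified labels round-trip unchanged
    "nonsynonymous": VariantClass.NONSYNONYMOUS,
    "synonymous": VariantClass.SYNONYMOUS,
}


class Recist(enum.IntEnum):
    """RECIST categories ordered worst to best: PD < SD < PR < CR."""

    PD = 0
    SD = 1
    PR = 2
    CR = 3


@dataclass
class MafRecord:
    patient_id: str
    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    gene_symbol: str
    variant_classification: VariantClass
    alt_count: int
    ref_count: int
    tumor_total_cn: int = 2
    tri_context: str | None = None


@dataclass
class GermlineVariantRecord:
    patient_id: str
    gene_symbol: str
    variant_id: str
    pathogenic: bool


@dataclass
class ClinicalRecord:
    patient_id: str
    cancer_type: str
    age: float
    sex: str
    purity: float
    ploidy: float
    ancestry_covariates: tuple[float, ...] = ()


@dataclass
class OutcomeRecord:
    patient_id: str
    pfs_time: float
    pfs_event: bool
    recist: Recist | None = None


@dataclass
class GeneSet:
    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        self.genes = frozenset(self.genes)
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")


@dataclass
class CoverageSummary:
    """Per-patient depth histogram over callable-candidate sites.

    ``depths[i]`` sites were sequenced at depth ``site_counts[i]``; storing the
    histogram rather than per-site depths keeps a 30 Mb exome summary tiny.
    """

    patient_id: str
    depths: tuple[int, ...]
    site_counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.depths) != len(self.site_counts):
            raise ValueError("depths and site_counts differ in length")

    @property
    def total_sites(self) -> int:
        return int(sum(self.site_counts))


# ---------------------------------------------------------------------------
# DataFrame converters

def maf_to_frame(records: Iterable[MafRecord]) -> pd.DataFrame:
    rows = [
        (
            r.patient_id, r.chrom, r.pos, r.ref_allele, r.alt_allele,
            r.gene_symbol, r.variant_classification.value, r.alt_count,
            r.ref_count, r.tumor_total_cn, r.tri_context,
        )
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id", "chrom", "pos", "ref_allele", "alt_allele",
            "gene_symbol", "variant_classification", "alt_count", "ref_count",
            "tumor_total_cn", "tri_context",
        ],
    )


def frame_to_maf(frame: pd.DataFrame) -> list[MafRecord]:
    return [
        MafRecord(
            patient_id=str(row.patient_id),
            chrom=str(row.chrom),
            pos=int(row.pos),
            ref_allele=str(row.ref_allele),
            alt_allele=str(row.alt_allele),
            gene_symbol=str(row.gene_symbol),
            variant_classification=VariantClass(row.variant_classification),
            alt_count=int(row.alt_count),
            ref_count=int(row.ref_count),
            tumor_total_cn=int(row.tumor_total_cn),
            tri_context=None if pd.isna(row.tri_context) else str(row.tri_context),
        )
        for row in frame.itertuples(index=False)
    ]


def clinical_to_frame(records: Iterable[ClinicalRecord]) -> pd.DataFrame:
    records = list(records)
    n_anc = max((len(r.ancestry_covariates) for r in records), default=0)
    rows = []
    for r in records:
        anc = list(r.ancestry_covariates) + [0.0] * (n_anc - len(r.ancestry_covariates))
        rows.append([r.patient_id, r.cancer_type, r.age, r.sex, r.purity, r.ploidy, *anc])
    cols = ["patient_id", "cancer_type", "age", "sex", "purity", "ploidy"]
    cols += [f"ancestry_pc{i + 1}" for i in range(n_anc)]
    return pd.DataFrame(rows, columns=cols)


def frame_to_clinical(frame: pd.DataFrame) -> list[ClinicalRecord]:
    anc_cols = [c for c in frame.columns if c.startswith("ancestry_pc")]
    return [
        ClinicalRecord(
            patient_id=str(row["patient_id"]),
            cancer_type=str(row["cancer_type"]),
            age=float(row["age"]),
            sex=str(row["sex"]),
            purity=float(row["purity"]),
            ploidy=float(row["ploidy"]),
            ancestry_covariates=tuple(float(row[c]) for c in anc_cols),
        )
        for _, row in frame.iterrows()
    ]


def germline_to_frame(records: Iterable[GermlineVariantRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.patient_id, r.gene_symbol, r.variant_id, r.pathogenic) for r in records],
        columns=["patient_id", "gene_symbol", "variant_id", "pathogenic"],
    )


def outcomes_to_frame(records: Iterable[OutcomeRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.patient_id, r.pfs_time, r.pfs_event,
             None if r.recist is None else r.recist.name)
            for r in records
        ],
        columns=["patient_id", "pfs_time", "pfs_event", "recist"],
    )


def frame_to_outcomes(frame: pd.DataFrame) -> list[OutcomeRecord]:
    out = []
    for row in frame.itertuples(index=False):
        recist = None
        if isinstance(row.recist, str) and row.recist in Recist.__members__:
            recist = Recist[row.recist]
        out.append(
            OutcomeRecord(
                patient_id=str(row.patient_id),
                pfs_time=float(row.pfs_time),
                pfs_event=bool(row.pfs_event),
                recist=recist,
            )
        )
    return out
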