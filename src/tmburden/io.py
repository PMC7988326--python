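"""Readers and writers for the pipeline's external file formats.

All disk access in the package goes through this module. Formats are plain
tab-separated text: MAF-like somatic calls, GMT gene-set collections, and
simple TSV tables for clinical, germline, outcome and coverage data. Readers
are order-preserving and deterministic; writers round-trip exactly through
the corresponding reader.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .records import (
    ClinicalRecord,
    CoverageSummary,
    GeneSet,
    GermlineVariantRecord,
    MafRecord,
    MAF_CLASSIFICATION_MAP,
    OutcomeRecord,
    Recist,
    VariantClass,
)

logger = logging.getLogger(__name__)

# Canonical field -> accepted header aliases (all matched case-insensitively).
_MAF_ALIASES = {
    "patient_id": ("patient_id", "tumor_sample_barcode", "sample", "patient"),
    "chrom": ("chrom", "chromosome", "chr"),
    "pos": ("pos", "start_position", "start"),
    "ref_allele": ("ref_allele", "reference_allele", "ref"),
    "alt_allele": ("alt_allele", "tumor_seq_allele2", "alt"),
    "gene_symbol": ("gene_symbol", "hugo_symbol", "gene"),
    "variant_classification": ("variant_classification", "variant_class"),
    "alt_count": ("alt_count", "t_alt_count"),
    "ref_count": ("ref_count", "t_ref_count"),
    "tumor_total_cn": ("tumor_total_cn", "total_cn", "tcn"),
    "tri_context": ("tri_context", "context", "trinucleotide_context"),
}
_MAF_REQUIRED = (
    "patient_id", "chrom", "pos", "ref_allele", "alt_allele", "gene_symbol",
    "variant_classification", "alt_count", "ref_count",
)


def _resolve_columns(columns: Sequence[str], aliases: dict, required: Sequence[str],
                     path) -> dict[str, str]:
    lower = {c.lower(): c for c in columns}
    mapping = {}
    for field, names in aliases.items():
        for name in names:
            if name in lower:
                mapping[field] = lower[name]
                break
    missing = [f for f in required if f not in mapping]
    if missing:
        raise ValueError(f"{path}: header is missing required column(s): {missing}")
    return mapping


def classify_variant(raw: str) -> VariantClass:
    """Collapse a MAF Variant_Classification string to the 3-level scheme."""
    return MAF_CLASSIFICATION_MAP.get(str(raw).strip().lower(), VariantClass.OTHER)


def read_maf(path) -> list[MafRecord]:
    """Read a MAF-like tab-separated somatic mutation file.

    Accepts canonical TCGA MAF headers or this package's simplified headers
    (case-insensitive). Rows whose numeric fields cannot be parsed are skipped
    with a logged count.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    cols = _resolve_columns(df.columns, _MAF_ALIASES, _MAF_REQUIRED, path)
    records: list[MafRecord] = []
    skipped = 0
    has_cn = "tumor_total_cn" in cols
    has_ctx = "tri_context" in cols
    for row in df.itertuples(index=False):
        row = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        get = lambda f: row[cols[f]]  # noqa: E731
        try:
            pos = int(get("pos"))
            alt_count = int(float(get("alt_count")))
            ref_count = int(float(get("ref_count")))
            cn = int(float(get("tumor_total_cn"))) if has_cn and not pd.isna(get("tumor_total_cn")) else 2
        except (TypeError, ValueError):
            skipped += 1
            continue
        ctx = get("tri_context") if has_ctx else None
        if ctx is not None and (pd.isna(ctx) or str(ctx).strip() in ("", ".")):
            ctx = None
        records.append(
            MafRecord(
                patient_id=str(get("patient_id")),
                chrom=str(get("chrom")),
                pos=pos,
                ref_allele=str(get("ref_allele")),
                alt_allele=str(get("alt_allele")),
                gene_symbol=str(get("gene_symbol")),
                variant_classification=classify_variant(get("variant_classification")),
                alt_count=alt_count,
                ref_count=ref_count,
                tumor_total_cn=cn,
                tri_context=None if ctx is None else str(ctx).upper(),
            )
        )
    if skipped:
        logger.warning("%s: skipped %d rows with unparseable numeric fields", path, skipped)
    return records


def write_maf(records: Iterable[MafRecord], path) -> None:
    rows = [
        {
            "patient_id": r.patient_id,
            "chrom": r.chrom,
            "pos": r.pos,
            "ref_allele": r.ref_allele,
            "alt_allele": r.alt_allele,
            "gene_symbol": r.gene_symbol,
            "variant_classification": r.variant_classification.value,
            "alt_count": r.alt_count,
            "ref_count": r.ref_count,
            "tumor_total_cn": r.tumor_total_cn,
            "tri_context": "." if r.tri_context is None else r.tri_context,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_gmt(path) -> list[GeneSet]:
    """Read a GMT gene-set collection: name <tab> description <tab> genes..."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                logger.warning("%s:%d: GMT line has <3 fields, skipped", path, lineno)
                continue
            name = parts[0]
            genes = frozenset(g for g in parts[2:] if g)
            sets.append(GeneSet(name=name, genes=genes))
    return sets


def write_gmt(sets: Iterable[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, "na", *sorted(s.genes)]) + "\n")


def read_clinical(path) -> list[ClinicalRecord]:
    """Read the clinical TSV; rejects records with purity outside (0, 1]."""
    df = pd.read_csv(path, sep="\t")
    anc_cols = [c for c in df.columns if c.lower().startswith("ancestry_pc")]
    records = []
    for row in df.itertuples(index=False):
        row = row._asdict()
        purity = float(row["purity"])
        if not (0.0 < purity <= 1.0):
            logger.warning("clinical: patient %s rejected (purity %.3f outside (0,1])",
                           row["patient_id"], purity)
            continue
        records.append(
            ClinicalRecord(
                patient_id=str(row["patient_id"]),
                cancer_type=str(row["cancer_type"]),
                age=float(row["age"]),
                sex=str(row["sex"]),
                purity=purity,
                ploidy=float(row["ploidy"]),
                ancestry_covariates=tuple(float(row[c]) for c in anc_cols),
            )
        )
    return records


def write_clinical(records: Iterable[ClinicalRecord], path) -> None:
    from .records import clinical_to_frame

    clinical_to_frame(records).to_csv(path, sep="\t", index=False)


def read_germline(path) -> list[GermlineVariantRecord]:
    df = pd.read_csv(path, sep="\t")
    truthy = {"true", "1", "yes", "pathogenic"}
    return [
        GermlineVariantRecord(
            patient_id=str(row.patient_id),
            gene_symbol=str(row.gene_symbol),
            variant_id=str(row.variant_id),
            pathogenic=str(row.pathogenic).strip().lower() in truthy,
        )
        for row in df.itertuples(index=False)
    ]


def write_germline(records: Iterable[GermlineVariantRecord], path) -> None:
    from .records import germline_to_frame

    germline_to_frame(records).to_csv(path, sep="\t", index=False)


def read_outcomes(path) -> list[OutcomeRecord]:
    """Read the outcomes TSV; unknown RECIST strings become missing."""
    df = pd.read_csv(path, sep="\t")
    records = []
    for row in df.itertuples(index=False):
        raw = str(row.recist).strip().upper()
        recist = Recist[raw] if raw in Recist.__members__ else None
        records.append(
            OutcomeRecord(
                patient_id=str(row.patient_id),
                pfs_time=float(row.pfs_time),
                pfs_event=bool(row.pfs_event) if not isinstance(row.pfs_event, str)
                else str(row.pfs_event).strip().lower() in {"true", "1", "yes"},
                recist=recist,
            )
        )
    return records


def write_outcomes(records: Iterable[OutcomeRecord], path) -> None:
    from .records import outcomes_to_frame

    df = outcomes_to_frame(records)
    df["recist"] = df["recist"].fillna("NA")
    df.to_csv(path, sep="\t", index=False)


def read_coverage(path) -> dict[str, CoverageSummary]:
    """Read per-patient depth histograms (patient_id, depth, n_sites)."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, CoverageSummary] = {}
    for pid, grp in df.groupby("patient_id", sort=False):
        out[str(pid)] = CoverageSummary(
            patient_id=str(pid),
            depths=tuple(int(d) for d in grp["depth"]),
            site_counts=tuple(int(n) for n in grp["n_sites"]),
        )
    return out


def write_coverage(summaries: Iterable[CoverageSummary], path) -> None:
    rows = []
    for s in summaries:
        for d, n in zip(s.depths, s.site_counts):
            rows.append({"patient_id": s.patient_id, "depth": d, "n_sites": n})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Configuration

#: Every tunable threshold in the pipeline, with its module default.
DEFAULT_CONFIG = {
    "min_carriers": 5,
    "min_power": 0.8,
    "min_alt_reads": 4,
    "clonal_ccf_threshold": 0.95,
    "clonal_ci_floor": 0.75,
    "normal_cn": 2,
    "min_carriers_validation": 10,
    "min_events_validation": 10,
    "convergence_variant_classes": ["nonsynonymous"],
}


def load_config(path=None) -> dict:
    """Load a YAML config of thresholds, filling unspecified keys from defaults."""
    config = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        unknown = set(user) - set(DEFAULT_CONFIG)
        if unknown:
            logger.warning("config: ignoring unknown keys %s", sorted(unknown))
        config.update({k: v for k, v in user.items() if k in DEFAULT_CONFIG})
    return config
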