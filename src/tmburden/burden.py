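"""Collapse pathogenic germline variants into testable carrier units.

A "unit" is either a single gene or a gene set. A patient is a carrier of a
unit if they harbor at least one pathogenic germline variant in any of the
unit's genes — binary, regardless of how many distinct variants they carry.
Units with fewer than ``min_carriers`` carriers in scope are not testable
and are dropped. Gene-set units whose *contributing* genes (member genes
actually carrying variants in scope) coincide exactly are statistically
identical and are merged into a single unit before testing, so a duplicated
carrier column is never tested twice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .records import GeneSet, GermlineVariantRecord

SCOPES = ("gene_per_cancer", "gene_pan_cancer", "geneset_per_cancer", "geneset_pan_cancer")


@dataclass
class CarrierMatrix:
    """Patients x units binary carrier indicators for one analysis scope."""

    unit_names: list[str]
    patient_ids: list[str]
    carrier: np.ndarray  # bool, shape (n_patients, n_units)
    contributing_genes: dict[str, frozenset[str]]
    scope: str
    cancer: str = "PAN"

    def __post_init__(self) -> None:
        if self.scope not in SCOPES:
            raise ValueError(f"unknown scope {self.scope!r}")
        self.carrier = np.asarray(self.carrier, dtype=bool)
        if self.carrier.shape != (len(self.patient_ids), len(self.unit_names)):
            raise ValueError("carrier matrix shape does not match labels")

    @property
    def n_units(self) -> int:
        return len(self.unit_names)

    def carrier_counts(self) -> dict[str, int]:
        sums = self.carrier.sum(axis=0)
        return {u: int(s) for u, s in zip(self.unit_names, sums)}

    def column(self, unit: str) -> np.ndarray:
        return self.carrier[:, self.unit_names.index(unit)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.carrier.astype(int), index=self.patient_ids,
                            columns=self.unit_names)


def _pathogenic_frame(germline: list[GermlineVariantRecord], patients: list[str]) -> pd.DataFrame:
    in_scope = set(patients)
    rows = [(g.patient_id, g.gene_symbol) for g in germline
            if g.pathogenic and g.patient_id in in_scope]
    return pd.DataFrame(rows, columns=["patient_id", "gene_symbol"])


def build_gene_units(germline: list[GermlineVariantRecord], patients: list[str],
                     min_carriers: int = 5, scope: str = "gene_pan_cancer",
                     cancer: str = "PAN") -> CarrierMatrix:
    """One unit per gene with >= min_carriers pathogenic carriers in scope."""
    path = _pathogenic_frame(germline, patients)
    pidx = {p: i for i, p in enumerate(patients)}
    names: list[str] = []
    cols: list[np.ndarray] = []
    contributing: dict[str, frozenset[str]] = {}
    if not path.empty:
        for gene, grp in path.groupby("gene_symbol", sort=True):
            carriers = set(grp["patient_id"])  # idempotent: duplicates collapse
            if len(carriers) < min_carriers:
                continue
            col = np.zeros(len(patients), dtype=bool)
            col[[pidx[p] for p in carriers]] = True
            names.append(gene)
            cols.append(col)
            contributing[gene] = frozenset([gene])
    carrier = np.column_stack(cols) if cols else np.zeros((len(patients), 0), dtype=bool)
    return CarrierMatrix(names, list(patients), carrier, contributing, scope, cancer)


def build_geneset_units(germline: list[GermlineVariantRecord], gene_sets: list[GeneSet],
                        patients: list[str], min_carriers: int = 5,
                        scope: str = "geneset_pan_cancer", cancer: str = "PAN") -> CarrierMatrix:
    """One unit per gene set; carrier = pathogenic variant in ANY member gene."""
    path = _pathogenic_frame(germline, patients)
    pidx = {p: i for i, p in enumerate(patients)}
    by_gene: dict[str, set[str]] = {}
    if not path.empty:
        for gene, grp in path.groupby("gene_symbol"):
            by_gene[gene] = set(grp["patient_id"])
    names, cols = [], []
    contributing: dict[str, frozenset[str]] = {}
    for gs in gene_sets:
        hit_genes = frozenset(g for g in gs.genes if g in by_gene)
        if not hit_genes:
            continue
        carriers: set[str] = set()
        for g in hit_genes:
            carriers |= by_gene[g]
        if len(carriers) < min_carriers:
            continue
        col = np.zeros(len(patients), dtype=bool)
        col[[pidx[p] for p in carriers]] = True
        names.append(gs.name)
        cols.append(col)
        contributing[gs.name] = hit_genes
    carrier = np.column_stack(cols) if cols else np.zeros((len(patients), 0), dtype=bool)
    return CarrierMatrix(names, list(patients), carrier, contributing, scope, cancer)


def merge_equivalent_units(matrix: CarrierMatrix) -> CarrierMatrix:
    """Merge units whose contributing genes coincide exactly.

    Merged units share an identical carrier column by construction; the merged
    unit keeps one column and a comma-joined name in original order. Merging
    is idempotent and leaves matrices without duplicates unchanged.
    """
    groups: dict[frozenset[str], list[int]] = {}
    for i, name in enumerate(matrix.unit_names):
        groups.setdefault(matrix.contributing_genes[name], []).append(i)
    names, cols = [], []
    contributing: dict[str, frozenset[str]] = {}
    seen: set[frozenset[str]] = set()
    for i, name in enumerate(matrix.unit_names):
        key = matrix.contributing_genes[name]
        if key in seen:
            continue
        seen.add(key)
        members = groups[key]
        merged_name = ", ".join(matrix.unit_names[j] for j in members)
        names.append(merged_name)
        cols.append(matrix.carrier[:, members[0]])
        contributing[merged_name] = key
    carrier = np.column_stack(cols) if cols else np.zeros((len(matrix.patient_ids), 0), dtype=bool)
    return CarrierMatrix(names, list(matrix.patient_ids), carrier, contributing,
                         matrix.scope, matrix.cancer)


def pool_units(matrix: CarrierMatrix, unit_names_to_pool: list[str]) -> np.ndarray:
    """Union carrier vector over the selected units (for pooled validation)."""
    missing = [u for u in unit_names_to_pool if u not in matrix.unit_names]
    if missing:
        raise KeyError(f"units not in matrix: {missing}")
    idx = [matrix.unit_names.index(u) for u in unit_names_to_pool]
    if not idx:
        raise ValueError("no units selected to pool")
    return matrix.carrier[:, idx].any(axis=1)


def unit_metadata(matrix: CarrierMatrix) -> pd.DataFrame:
    """Unit-level metadata table (unit, scope, cancer, contributing genes, n)."""
    counts = matrix.carrier_counts()
    return pd.DataFrame([
        {
            "unit": u,
            "scope": matrix.scope,
            "cancer": matrix.cancer,
            "contributing_genes": ";".join(sorted(matrix.contributing_genes[u])),
            "n_carriers": counts[u],
        }
        for u in matrix.unit_names
    ])
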