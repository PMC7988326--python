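"""Burden association of carrier units with clonal nonsynonymous TMB per Mb.

Each testable unit is a binary carrier indicator regressed (OLS) against
clonal nonsynonymous TMB per Mb with demographic covariates — age, sex,
optional ancestry components — plus cancer-type indicators in the pan-cancer
scopes. The carrier coefficient is reported on the raw per-Mb scale
("additional clonal nonsynonymous mutations per Mb"), with a two-sided
t-test p-value.

Benjamini-Hochberg correction is applied within each scope's test family:
per cancer for the per-cancer scopes (each cancer its own family), one
family for each pan-cancer scope. ``bh_adjust`` supports an explicit family
size larger than the supplied p-vector, so published subsets of a family can
be re-adjusted exactly, and handles ties by assigning the whole tie group
the largest rank in the group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .burden import CarrierMatrix, build_gene_units, build_geneset_units, merge_equivalent_units

logger = logging.getLogger(__name__)


@dataclass
class AssociationResult:
    unit: str
    scope: str
    cancer: str
    n_carriers: int
    effect: float  # additional clonal nonsynonymous mutations per Mb
    p_raw: float
    p_adjusted: float = np.nan
    #: optional heavy-tail sanity check (rank-based, unadjusted); never the
    #: headline p, reported alongside because per-Mb TMB is heavy-tailed
    p_rank: float = np.nan


def bh_adjust(p_values, total_tests: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values with an optional family-size override.

    ``total_tests`` may exceed ``len(p_values)`` when the supplied values are
    the smallest members of a larger family (e.g. only the significant rows of
    a published table); ranks are then still 1..len within the supplied subset,
    valid because the subset is rank-leading. Tied p-values all receive the
    largest rank in their tie group before the step-up minimum. Output in
    input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("p_values must be a non-empty 1-D sequence")
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = len(p) if total_tests is None else int(total_tests)
    if m < len(p):
        raise ValueError("total_tests must be >= number of supplied p-values")
    order = np.argsort(p, kind="stable")
    ps = p[order]
    # largest rank within each tie group
    ranks = np.empty(len(p))
    i = 0
    while i < len(p):
        j = i
        while j + 1 < len(p) and ps[j + 1] == ps[i]:
            j += 1
        ranks[i:j + 1] = j + 1
        i = j + 1
    q = ps * m / ranks
    q = np.minimum.accumulate(q[::-1])[::-1]  # step-up: min over j >= i
    q = np.minimum(q, 1.0)
    out = np.empty(len(p))
    out[order] = q
    return out


def _design_matrix(covariates: pd.DataFrame | np.ndarray | None, n: int) -> pd.DataFrame:
    if covariates is None:
        return pd.DataFrame(index=range(n))
    if isinstance(covariates, np.ndarray):
        covariates = pd.DataFrame(
            covariates, columns=[f"x{i}" for i in range(covariates.shape[1])]
        )
    return covariates.reset_index(drop=True)


def _drop_collinear(X: pd.DataFrame) -> pd.DataFrame:
    """Greedily drop columns that are linear combinations of earlier ones."""
    keep: list[str] = []
    for col in X.columns:
        trial = X[keep + [col]].to_numpy(dtype=float)
        if np.linalg.matrix_rank(trial) == trial.shape[1]:
            keep.append(col)
        else:
            logger.warning("dropping collinear covariate %r", col)
    return X[keep]


def fit_burden_association(tmb, carrier, covariates=None) -> tuple[float, float]:
    """OLS of TMB per Mb on carrier status plus covariates.

    Returns (effect, p_raw): the carrier coefficient in additional clonal
    nonsynonymous mutations per Mb and its two-sided t-test p-value. With no
    covariates this is exactly the carrier/non-carrier difference in means.
    """
    tmb = np.asarray(tmb, dtype=float)
    carrier = np.asarray(carrier, dtype=float)
    if carrier.min() == carrier.max():
        raise ValueError("carrier vector is constant (all carriers or none)")
    X = _design_matrix(covariates, len(tmb))
    # covariates take precedence: a carrier collinear with them is an error,
    # while redundant covariates are merely dropped
    X.insert(0, "const", 1.0)
    X["carrier"] = carrier
    X = _drop_collinear(X)
    if "carrier" not in X.columns:
        raise ValueError("carrier vector is collinear with the covariates")
    fit = sm.OLS(tmb, X.to_numpy(dtype=float)).fit()
    idx = list(X.columns).index("carrier")
    return float(fit.params[idx]), float(fit.pvalues[idx])


def covariate_frame(clinical: pd.DataFrame, pan_cancer: bool) -> pd.DataFrame:
    """Default adjustment set: age, sex, ancestry PCs; + cancer type if pan-cancer."""
    cov = pd.DataFrame(index=clinical.index)
    cov["age"] = clinical["age"].astype(float)
    cov["sex_male"] = (clinical["sex"].astype(str).str.lower()
                       .isin(["male", "m", "1"])).astype(float)
    for c in clinical.columns:
        if c.startswith("ancestry_pc"):
            cov[c] = clinical[c].astype(float)
    if pan_cancer:
        dummies = pd.get_dummies(clinical["cancer_type"], prefix="cancer", drop_first=True)
        cov = pd.concat([cov, dummies.astype(float)], axis=1)
    return cov


def _test_matrix(matrix: CarrierMatrix, tmb: np.ndarray, covariates: pd.DataFrame,
                 results: list[AssociationResult], rank_check: bool = False) -> None:
    from scipy import stats as _stats

    counts = matrix.carrier_counts()
    for unit in matrix.unit_names:
        col = matrix.column(unit)
        try:
            effect, p_raw = fit_burden_association(tmb, col, covariates)
        except ValueError as exc:
            logger.warning("skipping unit %r in %s/%s: %s", unit, matrix.scope,
                           matrix.cancer, exc)
            continue
        p_rank = np.nan
        if rank_check:
            p_rank = float(_stats.mannwhitneyu(tmb[col], tmb[~col],
                                               alternative="two-sided").pvalue)
        results.append(AssociationResult(unit, matrix.scope, matrix.cancer,
                                         counts[unit], effect, p_raw,
                                         p_rank=p_rank))


def run_scope(scope: str, germline, tmb_table: pd.DataFrame, clinical: pd.DataFrame,
              gene_sets=None, min_carriers: int = 5,
              total_tests: int | None = None,
              rank_check: bool = False) -> list[AssociationResult]:
    """Run one of the four analysis scopes end to end.

    Builds carrier matrices (restricted per cancer for the per-cancer scopes),
    fits every testable unit, and BH-adjusts within the scope's family — each
    cancer forms its own family in per-cancer scopes.
    """
    merged = tmb_table.merge(clinical, on="patient_id", how="inner")
    per_cancer = scope.endswith("per_cancer")
    geneset = scope.startswith("geneset")
    if geneset and gene_sets is None:
        raise ValueError("gene_sets required for gene-set scopes")
    results: list[AssociationResult] = []
    families = (
        [(c, grp) for c, grp in merged.groupby("cancer_type", sort=True)]
        if per_cancer else [("PAN", merged)]
    )
    for cancer, grp in families:
        grp = grp.reset_index(drop=True)
        patients = list(grp["patient_id"])
        tmb = grp["clonal_nonsyn_per_mb"].to_numpy(dtype=float)
        cov = covariate_frame(grp, pan_cancer=not per_cancer)
        if geneset:
            matrix = build_geneset_units(germline, gene_sets, patients, min_carriers,
                                         scope, cancer)
            matrix = merge_equivalent_units(matrix)
        else:
            matrix = build_gene_units(germline, patients, min_carriers, scope, cancer)
        if matrix.n_units == 0:
            logger.info("scope %s/%s: no testable units", scope, cancer)
            continue
        family: list[AssociationResult] = []
        _test_matrix(matrix, tmb, cov, family, rank_check)
        if family:
            adj = bh_adjust([r.p_raw for r in family],
                            total_tests if total_tests else None)
            for r, q in zip(family, adj):
                r.p_adjusted = float(q)
        results.extend(family)
    return results


def results_frame(results: list[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "unit": r.unit, "scope": r.scope, "cancer": r.cancer,
            "n_carriers": r.n_carriers, "effect": r.effect,
            "p_raw": r.p_raw, "p_adjusted": r.p_adjusted, "p_rank": r.p_rank,
        }
        for r in results
    ])


def manhattan_table(results: list[AssociationResult],
                    matrices: list[CarrierMatrix] | None = None,
                    clinical: pd.DataFrame | None = None) -> pd.DataFrame:
    """Plot-ready table: unit, -log10 adjusted p, per-cancer carrier fractions."""
    df = results_frame(results)
    df["neg_log10_p_adjusted"] = -np.log10(df["p_adjusted"])
    if matrices is not None and clinical is not None:
        by_cancer = clinical.groupby("cancer_type")["patient_id"].apply(set)
        frac_rows = []
        lookup = {(m.scope, m.cancer): m for m in matrices}
        for r in results:
            m = lookup.get((r.scope, r.cancer))
            fracs = {}
            if m is not None and r.unit in m.unit_names:
                carriers = {p for p, c in zip(m.patient_ids, m.column(r.unit)) if c}
                for cancer, pts in by_cancer.items():
                    if not pts:
                        continue
                    fracs[f"frac_{cancer}"] = len(carriers & pts) / len(pts)
            frac_rows.append(fracs)
        df = pd.concat([df, pd.DataFrame(frac_rows)], axis=1)
    return df
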