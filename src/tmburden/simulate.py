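"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator produces, per patient: a cancer type and demographics; binary
carrier status for each configured germline unit; a latent clonal
nonsynonymous mutation rate equal to the cancer baseline plus the carried
units' effects, times mean-one lognormal noise (TMB is heavy-tailed, and
multiplicative noise preserves the additive carrier effect in expectation);
somatic mutations with clonal/subclonal cancer cell fractions, copy states,
read counts binomial around the expected VAF, and trinucleotide contexts
drawn from a configurable signature mixture; a depth histogram; and
immunotherapy outcomes (exponential progression times with a carrier hazard
ratio, RECIST via a proportional-odds latent variable with a carrier odds).

Mutations whose simulated alt read count falls below the detection threshold
are dropped, mirroring the power model used for the callable-megabase
denominator, so observed per-Mb rates are consistent with the latent rates.

The read-count model and the CCF estimator share one expected-VAF formula
(:func:`tmburden.tmb.expected_vaf`); a cross-module test asserts this.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

from . import io as tio
from .records import CoverageSummary, GeneSet
from .signatures import CONTEXT_LABELS, reverse_complement, synthetic_catalog
from .tmb import expected_vaf


@dataclass
class CarrierUnitSpec:
    """One germline unit: its genes, population frequency, and effects."""

    name: str
    genes: tuple[str, ...]
    carrier_fraction: float
    effect: float = 0.0  # additional clonal nonsynonymous mutations per Mb
    signature_mixture: dict[str, float] | None = None  # overrides default for carriers
    somatic_target_odds: float | None = None  # odds of a somatic hit in the unit's genes

    def __post_init__(self) -> None:
        if not (0.0 <= self.carrier_fraction <= 1.0):
            raise ValueError("carrier_fraction must be in [0, 1]")


@dataclass
class OutcomeSpec:
    """Immunotherapy outcome model for carriers (union over outcome units)."""

    hazard_ratio: float = 0.7
    response_odds: float = 1.8
    units: tuple[str, ...] | None = None  # None = union of all configured units
    median_pfs_days: float = 180.0
    censor_range: tuple[float, float] = (100.0, 1000.0)
    recist_base_probs: tuple[float, float, float, float] = (0.4, 0.3, 0.2, 0.1)


@dataclass
class SimulationConfig:
    n_patients: int = 500
    cancer_type_proportions: dict[str, float] = field(
        default_factory=lambda: {"UCEC": 0.25, "SKCM": 0.25, "COAD": 0.25, "BRCA": 0.25}
    )
    # mean clonal nonsynonymous mutations per Mb by cancer type
    baseline_tmb_rate: dict[str, float] = field(
        default_factory=lambda: {"UCEC": 3.0, "SKCM": 5.0, "COAD": 2.5, "BRCA": 1.0}
    )
    tmb_noise_scale: float = 0.5  # sigma of the mean-one lognormal noise
    carrier_spec: list[CarrierUnitSpec] = field(
        default_factory=lambda: [
            CarrierUnitSpec("MMR", ("MSH2", "MSH6", "PMS2", "MLH1"), 0.02, 8.0)
        ]
    )
    purity_beta_params: tuple[float, float] = (8.0, 3.0)
    purity_fixed: float | None = None  # overrides the Beta draw when set
    ploidy_range: tuple[float, float] = (1.8, 4.2)
    mean_depth: float = 80.0
    depth_dispersion: float = 30.0  # negative-binomial size parameter
    exome_mb: float = 30.0
    clonal_fraction: float = 0.85  # fraction of mutations with CCF = 1
    nonsyn_fraction: float = 0.7  # nonsynonymous share of all somatic calls
    min_alt_detect: int = 4  # alt reads required for a mutation to be observed
    signature_mixture: dict[str, float] = field(
        default_factory=lambda: {"SBS_FLAT": 0.6, "SBS_CTDEAM": 0.4}
    )
    n_background_genes: int = 200
    outcome_spec: OutcomeSpec = field(default_factory=OutcomeSpec)
    # logistic model for injected somatic convergence (used when a unit sets
    # somatic_target_odds): P(hit) = expit(alpha + gamma * z_tmb + log(odds) * carrier)
    convergence_alpha: float = logit(0.15)
    convergence_gamma: float = 0.5
    seed: int = 0


@dataclass
class SyntheticCohort:
    clinical: pd.DataFrame
    germline: pd.DataFrame
    maf: pd.DataFrame
    outcomes: pd.DataFrame
    coverage: dict[str, CoverageSummary]
    carrier_truth: pd.DataFrame  # patients x units (bool)
    latent_rate: pd.Series  # latent clonal nonsynonymous mutations per Mb
    config: SimulationConfig

    def gene_sets(self) -> list[GeneSet]:
        return [GeneSet(u.name, frozenset(u.genes)) for u in self.config.carrier_spec]


def null_units(n: int, carrier_fraction: float = 0.02, genes_per_unit: int = 3,
               prefix: str = "NULL") -> list[CarrierUnitSpec]:
    """Convenience: n zero-effect units over disjoint synthetic genes."""
    units = []
    for i in range(n):
        genes = tuple(f"{prefix}{i:03d}_G{j}" for j in range(genes_per_unit))
        units.append(CarrierUnitSpec(f"{prefix}{i:03d}", genes, carrier_fraction, 0.0))
    return units


@lru_cache(maxsize=8)
def _depth_pmf(mean_depth: float, dispersion: float) -> tuple[np.ndarray, np.ndarray]:
    r = dispersion
    p = r / (r + mean_depth)
    dmax = int(stats.nbinom.ppf(1 - 1e-9, r, p)) + 1
    depths = np.arange(dmax + 1)
    pmf = stats.nbinom.pmf(depths, r, p)
    return depths, pmf / pmf.sum()


def simulate_coverage(patient_id: str, mean_depth: float, exome_mb: float,
                      rng: np.random.Generator, dispersion: float = 30.0) -> CoverageSummary:
    """Depth histogram: NB(mean_depth) site depths over exome_mb * 1e6 sites."""
    n_sites = int(round(exome_mb * 1e6))
    depths, pmf = _depth_pmf(float(mean_depth), float(dispersion))
    counts = rng.multinomial(n_sites, pmf)
    keep = counts > 0
    return CoverageSummary(patient_id, tuple(depths[keep].tolist()),
                           tuple(counts[keep].tolist()))


def _sample_contexts(rng, n, mixture, catalog):
    """Draw n 96-class indices from a signature mixture over the catalog."""
    if n == 0:
        return np.empty(0, dtype=int)
    sigs = list(mixture)
    w = np.array([mixture[s] for s in sigs], dtype=float)
    w = w / w.sum()
    probs = catalog[sigs].to_numpy(dtype=float) @ w
    probs = probs / probs.sum()
    return rng.choice(96, size=n, p=probs)


# (tri_context, ref, alt) per 96-class on the pyrimidine strand, plus the
# same triple reported on the purine (reverse-complement) strand
_LABEL_PARTS = [(lab[0] + lab[2] + lab[6], lab[2], lab[4]) for lab in CONTEXT_LABELS]
_LABEL_PARTS_RC = [
    (reverse_complement(t), reverse_complement(r), reverse_complement(a))
    for t, r, a in _LABEL_PARTS
]


def simulate_cohort(config: SimulationConfig, seed: int | None = None) -> SyntheticCohort:
    """Generate a complete cohort bundle; fully reproducible from the seed."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_patients
    empty = SyntheticCohort(
        clinical=pd.DataFrame(columns=["patient_id", "cancer_type", "age", "sex",
                                       "purity", "ploidy"]),
        germline=pd.DataFrame(columns=["patient_id", "gene_symbol", "variant_id",
                                       "pathogenic"]),
        maf=pd.DataFrame(columns=["patient_id", "chrom", "pos", "ref_allele",
                                  "alt_allele", "gene_symbol",
                                  "variant_classification", "alt_count", "ref_count",
                                  "tumor_total_cn", "tri_context"]),
        outcomes=pd.DataFrame(columns=["patient_id", "pfs_time", "pfs_event", "recist"]),
        coverage={}, carrier_truth=pd.DataFrame(), latent_rate=pd.Series(dtype=float),
        config=config,
    )
    if n == 0:
        return empty

    cancers = sorted(config.cancer_type_proportions)
    probs = np.array([config.cancer_type_proportions[c] for c in cancers], dtype=float)
    if not np.isclose(probs.sum(), 1.0):
        raise ValueError("cancer_type_proportions must sum to 1")
    patient_ids = [f"P{i:05d}" for i in range(n)]
    cancer = rng.choice(len(cancers), size=n, p=probs)
    cancer_names = np.array(cancers)[cancer]
    age = np.clip(rng.normal(62, 11, size=n), 25, 90)
    sex = rng.choice(["female", "male"], size=n)
    a, b = config.purity_beta_params
    purity = np.clip(rng.beta(a, b, size=n), 0.05, 1.0)
    if config.purity_fixed is not None:
        purity = np.full(n, float(config.purity_fixed))
    ploidy = rng.uniform(*config.ploidy_range, size=n)
    clinical = pd.DataFrame({
        "patient_id": patient_ids, "cancer_type": cancer_names,
        "age": np.round(age, 1), "sex": sex,
        "purity": np.round(purity, 4), "ploidy": np.round(ploidy, 3),
    })

    # --- carrier status and germline variants
    units = config.carrier_spec
    carrier = np.zeros((n, len(units)), dtype=bool)
    germ_rows = []
    for j, u in enumerate(units):
        carrier[:, j] = rng.random(n) < u.carrier_fraction
        for i in np.flatnonzero(carrier[:, j]):
            gene = u.genes[rng.integers(len(u.genes))]
            germ_rows.append((patient_ids[i], gene,
                              f"{gene}_var{rng.integers(1, 1000)}", True))
    germline = pd.DataFrame(germ_rows, columns=["patient_id", "gene_symbol",
                                                "variant_id", "pathogenic"])
    carrier_truth = pd.DataFrame(carrier, index=patient_ids,
                                 columns=[u.name for u in units])

    # --- latent clonal nonsynonymous rate (per Mb)
    baseline = np.array([config.baseline_tmb_rate[c] for c in cancer_names])
    effects = carrier @ np.array([u.effect for u in units], dtype=float)
    sigma = config.tmb_noise_scale
    noise = rng.lognormal(-0.5 * sigma ** 2, sigma, size=n)  # mean one
    lam = np.maximum(baseline + effects, 0.01) * noise
    latent_rate = pd.Series(lam, index=patient_ids, name="latent_clonal_nonsyn_per_mb")

    # --- mutation counts per patient and class
    mb = config.exome_mb
    cf, nf = config.clonal_fraction, config.nonsyn_fraction
    n_clonal_ns = rng.poisson(lam * mb)
    n_sub_ns = rng.poisson(lam * mb * (1 - cf) / cf) if cf < 1.0 else np.zeros(n, dtype=int)
    other_rate = (lam / cf) * (1 / nf - 1)
    n_other = rng.poisson(other_rate * mb)
    # other calls split between synonymous and "other" classes, same clonal mix
    counts = {"clonal_ns": n_clonal_ns, "sub_ns": n_sub_ns, "other": n_other}

    # --- per-mutation attributes, fully vectorized across the cohort
    pid_idx = np.concatenate([
        np.repeat(np.arange(n), counts["clonal_ns"]),
        np.repeat(np.arange(n), counts["sub_ns"]),
        np.repeat(np.arange(n), counts["other"]),
    ])
    m_total = len(pid_idx)
    is_clonal = np.concatenate([
        np.ones(counts["clonal_ns"].sum(), dtype=bool),
        np.zeros(counts["sub_ns"].sum(), dtype=bool),
        rng.random(counts["other"].sum()) < cf,
    ])
    vclass = np.concatenate([
        np.repeat("nonsynonymous", counts["clonal_ns"].sum() + counts["sub_ns"].sum()),
        rng.choice(["synonymous", "other"], size=counts["other"].sum(), p=[0.75, 0.25]),
    ])
    ccf = np.where(is_clonal, 1.0, rng.uniform(0.1, 0.6, size=m_total))
    cn = rng.choice([1, 2, 3], size=m_total, p=[0.1, 0.8, 0.1])
    depth = rng.negative_binomial(
        config.depth_dispersion,
        config.depth_dispersion / (config.depth_dispersion + config.mean_depth),
        size=m_total,
    )
    vaf_exp = expected_vaf(ccf, purity[pid_idx], cn, 1, 2)
    alt = rng.binomial(depth, np.clip(vaf_exp, 0, 1))
    ref = depth - alt

    # --- trinucleotide contexts from per-group signature mixtures
    catalog = synthetic_catalog()
    ctx_idx = np.empty(m_total, dtype=int)
    default_members = np.ones(n, dtype=bool)
    groups = []
    for j, u in enumerate(units):
        if u.signature_mixture:
            groups.append((carrier[:, j].copy(), u.signature_mixture))
            default_members &= ~carrier[:, j]
    groups.append((default_members, config.signature_mixture))
    for members, mixture in groups:
        mask = members[pid_idx]
        ctx_idx[mask] = _sample_contexts(rng, int(mask.sum()), mixture, catalog)
    flip = rng.random(m_total) < 0.5  # report half on the purine strand
    fwd, rc = np.array(_LABEL_PARTS), np.array(_LABEL_PARTS_RC)
    parts = np.where(flip[:, None], rc[ctx_idx], fwd[ctx_idx])
    tri, ref_base, alt_base = parts[:, 0], parts[:, 1], parts[:, 2]

    # --- gene assignment
    bg_genes = np.array([f"BG{i:04d}" for i in range(config.n_background_genes)])
    all_unit_genes = sorted({g for u in units for g in u.genes})
    gene_pool = np.concatenate([bg_genes, np.array(all_unit_genes)]) if all_unit_genes \
        else bg_genes
    gene = gene_pool[rng.integers(len(gene_pool), size=m_total)]

    maf = pd.DataFrame({
        "patient_id": np.array(patient_ids)[pid_idx],
        "chrom": rng.integers(1, 23, size=m_total).astype(str),
        "pos": rng.integers(1, 200_000_000, size=m_total),
        "ref_allele": ref_base,
        "alt_allele": alt_base,
        "gene_symbol": gene,
        "variant_classification": vclass,
        "alt_count": alt,
        "ref_count": ref,
        "tumor_total_cn": cn,
        "tri_context": tri,
    })
    # detection thinning: a caller needs min_alt_detect supporting reads
    maf = maf[maf["alt_count"] >= config.min_alt_detect].reset_index(drop=True)

    # --- injected somatic convergence for units that request it
    z_tmb = (lam - lam.mean()) / max(lam.std(), 1e-12)
    for j, u in enumerate(units):
        if u.somatic_target_odds is None:
            continue
        p_hit = expit(config.convergence_alpha + config.convergence_gamma * z_tmb
                      + np.log(u.somatic_target_odds) * carrier[:, j])
        hit = rng.random(n) < p_hit
        target = set(u.genes)
        in_target = maf["gene_symbol"].isin(target) & \
            (maf["variant_classification"] == "nonsynonymous")
        for i, pid in enumerate(patient_ids):
            rows = maf.index[(maf["patient_id"] == pid)]
            t_rows = maf.index[(maf["patient_id"] == pid) & in_target]
            if hit[i] and len(t_rows) == 0:
                ns_rows = rows[(maf.loc[rows, "variant_classification"] == "nonsynonymous")
                               & ~maf.loc[rows, "gene_symbol"].isin(target)]
                if len(ns_rows):
                    pick = ns_rows[rng.integers(len(ns_rows))]
                    maf.loc[pick, "gene_symbol"] = u.genes[rng.integers(len(u.genes))]
            elif not hit[i] and len(t_rows) > 0:
                maf.loc[t_rows, "gene_symbol"] = bg_genes[
                    rng.integers(len(bg_genes), size=len(t_rows))
                ]

    # --- coverage histograms
    coverage = {
        pid: simulate_coverage(pid, config.mean_depth, config.exome_mb, rng,
                               config.depth_dispersion)
        for pid in patient_ids
    }

    # --- outcomes
    spec = config.outcome_spec
    out_units = spec.units if spec.units is not None else tuple(u.name for u in units)
    uidx = [k for k, u in enumerate(units) if u.name in out_units]
    out_carrier = carrier[:, uidx].any(axis=1) if uidx else np.zeros(n, dtype=bool)
    base_rate = np.log(2) / spec.median_pfs_days
    rate = base_rate * np.where(out_carrier, spec.hazard_ratio, 1.0)
    t_event = rng.exponential(1.0 / rate)
    t_censor = rng.uniform(*spec.censor_range, size=n)
    pfs_time = np.minimum(t_event, t_censor)
    pfs_event = t_event <= t_censor
    base = np.asarray(spec.recist_base_probs, dtype=float)
    base = base / base.sum()
    cuts = logit(np.cumsum(base)[:-1])  # latent-logistic cutpoints
    u_lat = rng.logistic(size=n) + np.log(spec.response_odds) * out_carrier
    recist_code = np.searchsorted(cuts, u_lat)
    recist = np.array(["PD", "SD", "PR", "CR"])[recist_code]
    outcomes = pd.DataFrame({
        "patient_id": patient_ids,
        "pfs_time": np.round(pfs_time, 1),
        "pfs_event": pfs_event,
        "recist": recist,
    })

    return SyntheticCohort(clinical, germline, maf, outcomes, coverage,
                           carrier_truth, latent_rate, config)


def write_cohort(cohort: SyntheticCohort, out_dir) -> dict[str, Path]:
    """Write the cohort as the TSV/MAF/GMT files the pipeline consumes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "maf": out / "somatic.maf",
        "clinical": out / "clinical.tsv",
        "germline": out / "germline.tsv",
        "outcomes": out / "outcomes.tsv",
        "coverage": out / "coverage.tsv",
        "gene_sets": out / "units.gmt",
    }
    cohort.maf.to_csv(paths["maf"], sep="\t", index=False)
    cohort.clinical.to_csv(paths["clinical"], sep="\t", index=False)
    cohort.germline.to_csv(paths["germline"], sep="\t", index=False)
    cohort.outcomes.to_csv(paths["outcomes"], sep="\t", index=False)
    tio.write_coverage(cohort.coverage.values(), paths["coverage"])
    tio.write_gmt(cohort.gene_sets(), paths["gene_sets"])
    return paths
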