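"""Trinucleotide-context spectra, signature exposures, and carrier enrichment.

Single-nucleotide substitutions are tallied in the standard 96-class scheme:
six pyrimidine-centered substitution types (C>A, C>G, C>T, T>A, T>C, T>G)
crossed with the 4x4 flanking-base contexts. Substitutions reported on the
purine strand are reverse-complemented first. Exposures of a tumor's
spectrum over a reference catalog are obtained by non-negative least
squares, and carrier-vs-non-carrier enrichment of a signature is tested on
per-patient exposure *fractions* (decoupling enrichment from total burden)
with a two-sided Mann-Whitney U test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import nnls

from .records import MafRecord

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
SUBSTITUTION_TYPES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = "ACGT"

#: Canonical 96-class labels, e.g. "A[C>A]A", in COSMIC ordering.
CONTEXT_LABELS = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTION_TYPES
    for five in _BASES
    for three in _BASES
)
_LABEL_INDEX = {lab: i for i, lab in enumerate(CONTEXT_LABELS)}


@dataclass
class ContextSpectrum:
    patient_id: str
    counts: np.ndarray  # length 96

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (96,):
            raise ValueError("spectrum must have exactly 96 classes")
        if (self.counts < 0).any():
            raise ValueError("spectrum counts must be non-negative")


@dataclass
class SignatureExposure:
    patient_id: str
    exposures: np.ndarray
    residual: float

    def fractions(self) -> np.ndarray:
        total = self.exposures.sum()
        return self.exposures / total if total > 0 else np.zeros_like(self.exposures)


@dataclass
class EnrichmentResult:
    unit: str
    cancer: str
    signature: str
    fold_enrichment: float
    p: float


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def context_class(ref: str, alt: str, tri_context: str) -> str | None:
    """Map a substitution plus 3-mer context to its 96-class label, or None.

    Returns None for non-SNVs, malformed contexts, or contexts whose middle
    base disagrees with the reference allele.
    """
    ref, alt = ref.upper(), alt.upper()
    if len(ref) != 1 or len(alt) != 1 or ref == alt or ref not in _BASES or alt not in _BASES:
        return None
    if tri_context is None:
        return None
    ctx = tri_context.upper()
    if len(ctx) != 3 or any(b not in _BASES for b in ctx) or ctx[1] != ref:
        return None
    if ref in "GA":  # purine reference: fold onto the pyrimidine strand
        ref, alt, ctx = reverse_complement(ref), reverse_complement(alt), reverse_complement(ctx)
    label = f"{ctx[0]}[{ref}>{alt}]{ctx[2]}"
    return label if label in _LABEL_INDEX else None


def spectrum_from_maf(records: list[MafRecord], patient_id: str | None = None) -> ContextSpectrum:
    """Tally a patient's SNVs into the 96-class spectrum.

    Indels and records lacking a usable context are skipped (counted in a log
    message).
    """
    counts = np.zeros(96)
    skipped = 0
    pid = patient_id
    for r in records:
        if pid is None:
            pid = r.patient_id
        label = context_class(r.ref_allele, r.alt_allele, r.tri_context)
        if label is None:
            skipped += 1
            continue
        counts[_LABEL_INDEX[label]] += 1
    if skipped:
        logger.debug("spectrum: skipped %d records without usable SNV context", skipped)
    return ContextSpectrum(patient_id=pid or "", counts=counts)


def spectra_from_frame(maf: pd.DataFrame) -> dict[str, ContextSpectrum]:
    """Per-patient spectra from a somatic mutation frame, vectorized."""
    df = maf.copy()
    labels = [
        context_class(r, a, c)
        for r, a, c in zip(df["ref_allele"], df["alt_allele"], df["tri_context"])
    ]
    df["ctx96"] = labels
    out: dict[str, ContextSpectrum] = {}
    for pid, grp in df.groupby("patient_id", sort=True):
        counts = np.zeros(96)
        vc = grp["ctx96"].value_counts()
        for label, n in vc.items():
            if label is not None:
                counts[_LABEL_INDEX[label]] = n
        out[str(pid)] = ContextSpectrum(str(pid), counts)
    return out


def read_catalog(path) -> pd.DataFrame:
    """Read a 96 x K signature catalog TSV (rows = context labels)."""
    cat = pd.read_csv(path, sep="\t", index_col=0)
    return cat.reindex(list(CONTEXT_LABELS))


def fit_exposures(spectrum: ContextSpectrum, reference: pd.DataFrame | np.ndarray) -> SignatureExposure:
    """Non-negative least-squares attribution of a spectrum over a catalog.

    ``reference`` is 96 x K with columns summing to 1. Returns non-negative
    exposures (in mutation units) and the attained residual norm.
    """
    R = reference.to_numpy(dtype=float) if isinstance(reference, pd.DataFrame) else np.asarray(reference, dtype=float)
    if R.shape[0] != 96:
        raise ValueError("reference catalog must have 96 rows")
    if not np.allclose(R.sum(axis=0), 1.0, atol=1e-6):
        raise ValueError("reference catalog columns must sum to 1")
    if spectrum.counts.sum() == 0:
        return SignatureExposure(spectrum.patient_id, np.zeros(R.shape[1]), 0.0)
    e, residual = nnls(R, spectrum.counts)
    return SignatureExposure(spectrum.patient_id, e, float(residual))


def exposure_frame(spectra: dict[str, ContextSpectrum], reference: pd.DataFrame) -> pd.DataFrame:
    """Per-patient exposures (patients x signatures) plus a residual column."""
    names = list(reference.columns)
    rows = []
    for pid in sorted(spectra):
        exp = fit_exposures(spectra[pid], reference)
        rows.append({"patient_id": pid, **dict(zip(names, exp.exposures)),
                     "residual": exp.residual})
    return pd.DataFrame(rows)


def enrichment_test(exposures: pd.DataFrame, carrier: np.ndarray, signature: str,
                    unit: str = "", cancer: str = "PAN") -> EnrichmentResult:
    """Carrier vs non-carrier enrichment of one signature's exposure fraction.

    fold = mean carrier fraction / mean non-carrier fraction; p from a
    two-sided Mann-Whitney U on the per-patient fractions.
    """
    carrier = np.asarray(carrier, dtype=bool)
    sig_cols = [c for c in exposures.columns if c not in ("patient_id", "residual")]
    if signature not in sig_cols:
        raise KeyError(f"signature {signature!r} not in exposure table")
    mat = exposures[sig_cols].to_numpy(dtype=float)
    totals = mat.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals > 0, exposures[signature].to_numpy(dtype=float) / totals, 0.0)
    if carrier.all() or not carrier.any():
        raise ValueError("both carrier groups must be non-empty")
    f_car, f_non = frac[carrier], frac[~carrier]
    mean_non = f_non.mean()
    if f_car.mean() == 0 and mean_non == 0:
        raise ValueError("fold enrichment undefined: both group means are zero")
    fold = np.inf if mean_non == 0 else f_car.mean() / mean_non
    if np.all(f_car == f_car[0]) and np.all(f_non == f_car[0]):
        p = 1.0  # identical constant groups: no evidence either way
    else:
        p = float(stats.mannwhitneyu(f_car, f_non, alternative="two-sided").pvalue)
    return EnrichmentResult(unit=unit, cancer=cancer, signature=signature,
                            fold_enrichment=float(fold), p=p)


def synthetic_catalog(n_signatures: int = 4) -> pd.DataFrame:
    """A small deterministic catalog of stylized signature profiles.

    Not a copy of any published catalog: profiles are simple parametric
    shapes (flat background, NpCpG-skewed C>T "deamination-like", C>A-heavy
    "oxidative-like", mixed C>T/T>C "mismatch-repair-like") adequate for
    exercising deconvolution and enrichment machinery on synthetic cohorts.
    """
    profiles = {}
    idx = np.arange(96)
    sub_of = idx // 16  # substitution type index
    three_prime = idx % 4  # 3' base index (A,C,G,T)
    flat = np.ones(96)
    profiles["SBS_FLAT"] = flat
    deam = np.where(sub_of == 2, 1.0, 0.02) * np.where(three_prime == 2, 8.0, 1.0)
    profiles["SBS_CTDEAM"] = deam  # C>T, strongest at CpG (3' G)
    oxid = np.where(sub_of == 0, 1.0, 0.05)
    profiles["SBS_CAOX"] = oxid  # C>A dominated
    mmr = np.where(sub_of == 2, 1.0, 0.0) + np.where(sub_of == 4, 0.8, 0.0) + 0.05
    profiles["SBS_MMR"] = mmr  # C>T plus T>C
    names = list(profiles)[:n_signatures]
    cat = pd.DataFrame({n: profiles[n] / profiles[n].sum() for n in names},
                       index=list(CONTEXT_LABELS))
    return cat
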