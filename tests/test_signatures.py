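"""96-context spectra, NNLS exposures, carrier enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import tmburden as tb
from tmburden.records import MafRecord, VariantClass
from tmburden.signatures import (
    CONTEXT_LABELS,
    context_class,
    enrichment_test,
    exposure_frame,
    spectrum_from_maf,
)


def snv(ref, alt, ctx, pid="P1"):
    return MafRecord(pid, "1", 100, ref, alt, "G1",
                     VariantClass.NONSYNONYMOUS, 10, 20, 2, ctx)


class TestSpectrum:
    def test_pyrimidine_snv_counted(self):
        spec = spectrum_from_maf([snv("C", "T", "ACA")])
        assert spec.counts.sum() == 1
        assert spec.counts[CONTEXT_LABELS.index("A[C>T]A")] == 1

    def test_purine_snv_reverse_complemented(self):
        # G>A at TGT folds to C>T at ACA on the pyrimidine strand
        spec = spectrum_from_maf([snv("G", "A", "TGT")])
        assert spec.counts[CONTEXT_LABELS.index("A[C>T]A")] == 1

    def test_indel_and_missing_context_ignored(self):
        records = [
            MafRecord("P1", "1", 1, "AT", "A", "G1", VariantClass.OTHER, 5, 5, 2, None),
            snv("C", "T", None),
            snv("C", "T", "AGA"),  # middle base disagrees with ref
        ]
        assert spectrum_from_maf(records).counts.sum() == 0

    def test_context_class_labels(self):
        assert context_class("T", "G", "ATC") == "A[T>G]C"
        assert context_class("A", "C", "GAG") == "C[T>G]C"  # revcomp of GAG/A>C


class TestFitExposures:
    def test_exact_disjoint_mixture(self):
        ref = np.zeros((96, 2))
        ref[:48, 0] = 1 / 48
        ref[48:, 1] = 1 / 48
        counts = 30 * ref[:, 0] + 70 * ref[:, 1]  # 30 sigA + 70 sigB mutations
        spec = tb.ContextSpectrum("P1", counts)
        exp = tb.fit_exposures(spec, ref)
        np.testing.assert_allclose(exp.exposures, [30, 70], rtol=1e-10)
        assert exp.residual < 1e-8

    def test_zero_spectrum_zero_exposures(self):
        ref = tb.synthetic_catalog()
        exp = tb.fit_exposures(tb.ContextSpectrum("P1", np.zeros(96)), ref)
        assert np.all(exp.exposures == 0) and exp.residual == 0

    def test_counts_orthogonal_to_signature(self):
        ref = np.zeros((96, 1))
        ref[:48, 0] = 1 / 48
        counts = np.zeros(96)
        counts[48:] = 5.0  # mass only where the signature has none
        exp = tb.fit_exposures(tb.ContextSpectrum("P1", counts), ref)
        assert exp.exposures[0] == pytest.approx(0.0, abs=1e-12)

    def test_unnormalized_catalog_rejected(self):
        bad = np.full((96, 2), 0.5)
        with pytest.raises(ValueError):
            tb.fit_exposures(tb.ContextSpectrum("P1", np.ones(96)), bad)

    def test_noisy_mixture_weight_recovery(self, rng):
        """Poisson-noised 3-signature mixtures: fraction MAE < 0.05 at 200 muts."""
        cat = tb.synthetic_catalog(3)
        R = cat.to_numpy()
        errs = []
        for _ in range(200):
            w = rng.dirichlet([1.5, 1.5, 1.5])
            counts = rng.poisson(200 * (R @ w))
            exp = tb.fit_exposures(tb.ContextSpectrum("P", counts), cat)
            errs.append(np.abs(exp.fractions() - w).mean())
        assert np.mean(errs) < 0.05

    def test_matches_projected_gradient_oracle(self, rng):
        """NNLS objective matches a brute-force projected-gradient solver."""
        cat = tb.synthetic_catalog(4).to_numpy()
        for _ in range(100):
            counts = rng.poisson(rng.uniform(20, 200), size=96).astype(float)
            exp = tb.fit_exposures(tb.ContextSpectrum("P", counts), cat)
            # projected gradient descent on ||c - R e||^2, e >= 0
            e = np.ones(4)
            lr = 1.0 / np.linalg.norm(cat.T @ cat, 2)
            for _ in range(20_000):
                grad = cat.T @ (cat @ e - counts)
                e = np.maximum(e - lr * grad, 0.0)
            obj_pg = np.linalg.norm(counts - cat @ e)
            assert exp.residual <= obj_pg + 1e-6
            np.testing.assert_allclose(exp.exposures, e, atol=1e-3)


class TestEnrichment:
    def _exposures(self, fracs_a, fracs_b):
        rows = []
        for i, (fa, fb) in enumerate(zip(fracs_a, fracs_b)):
            rows.append({"patient_id": f"P{i}", "sigA": fa, "sigB": fb, "residual": 0.0})
        return pd.DataFrame(rows)

    def test_fold_is_ratio_of_group_mean_fractions(self):
        exp = self._exposures([40, 40, 10, 10], [60, 60, 90, 90])
        carrier = np.array([True, True, False, False])
        res = enrichment_test(exp, carrier, "sigA")
        assert res.fold_enrichment == pytest.approx(4.0)

    def test_identical_groups_fold_one_p_one(self):
        exp = self._exposures([30, 30, 30, 30], [70, 70, 70, 70])
        res = enrichment_test(exp, np.array([True, True, False, False]), "sigA")
        assert res.fold_enrichment == pytest.approx(1.0)
        assert res.p == pytest.approx(1.0)

    def test_simulated_threefold_carriers_recovered(self):
        """Carriers with 3x signature weight: fold estimate lands in [2, 4.5]."""
        cat = tb.synthetic_catalog(2)
        folds = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 60
            carrier = np.arange(n) < 15
            w_car, w_non = np.array([0.6, 0.4]), np.array([0.2, 0.8])
            spectra = {}
            for i in range(n):
                w = w_car if carrier[i] else w_non
                counts = rng.poisson(300 * (cat.to_numpy() @ w))
                spectra[f"P{i:03d}"] = tb.ContextSpectrum(f"P{i:03d}", counts)
            exp = exposure_frame(spectra, cat)
            folds.append(enrichment_test(exp, carrier, cat.columns[0]).fold_enrichment)
        assert 2.0 <= np.mean(folds) <= 4.5

    def test_permuted_labels_give_uniform_p(self, rng):
        n = 80
        exp = self._exposures(rng.uniform(1, 100, n), rng.uniform(1, 100, n))
        pvals = []
        for _ in range(200):
            carrier = np.zeros(n, dtype=bool)
            carrier[rng.choice(n, 20, replace=False)] = True
            pvals.append(enrichment_test(exp, carrier, "sigA").p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01
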