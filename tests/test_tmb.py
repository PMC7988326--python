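"""CCF estimation, clonality classification, callable megabases, TMB nesting."""

import numpy as np
import pytest
from scipy import stats
from scipy.optimize import brentq

import tmburden as tb
from tmburden.records import CoverageSummary
from tmburden.tmb import ccf_table, expected_vaf, infer_multiplicity


class TestComputeCcf:
    @pytest.mark.parametrize("vaf,purity,cn,mult,expected", [
        (0.5, 1.0, 2, 1, 1.0),   # fully clonal het in a pure diploid tumor
        (0.25, 0.5, 2, 1, 1.0),  # halved VAF at 50% purity is still clonal
        (0.0, 0.8, 2, 1, 0.0),
        (0.25, 1.0, 2, 1, 0.5),
    ])
    def test_point_estimate(self, vaf, purity, cn, mult, expected):
        ccf = tb.compute_ccf(vaf, purity, cn, mult)
        assert ccf.point_estimate == pytest.approx(expected, abs=1e-12)

    def test_interval_brackets_point_and_shrinks_with_depth(self):
        wide = tb.compute_ccf(0.5, 1.0, 2, 1, alt_count=5, total_count=10)
        tight = tb.compute_ccf(0.5, 1.0, 2, 1, alt_count=500, total_count=1000)
        for ccf in (wide, tight):
            assert ccf.ci_low <= ccf.point_estimate <= ccf.ci_high
        assert (tight.ci_high - tight.ci_low) < (wide.ci_high - wide.ci_low)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            tb.compute_ccf(0.5, 0.0, 2)
        with pytest.raises(ValueError):
            tb.compute_ccf(0.5, 0.5, 0)

    def test_matches_root_inversion_of_expected_vaf(self, rng):
        """Point estimate equals brute-force inversion of the forward VAF map."""
        for _ in range(1000):
            purity = rng.uniform(0.1, 1.0)
            cn = rng.integers(1, 6)
            mult = rng.integers(1, cn + 1)
            true_ccf = rng.uniform(0.0, 1.5)
            vaf = float(expected_vaf(true_ccf, purity, cn, mult))
            est = tb.compute_ccf(vaf, purity, int(cn), int(mult)).point_estimate
            if vaf == 0:
                inverted = 0.0
            else:
                inverted = brentq(
                    lambda c: float(expected_vaf(c, purity, cn, mult)) - vaf,
                    0.0, 10.0, xtol=1e-12)
            assert est == pytest.approx(inverted, abs=1e-9)
            assert est == pytest.approx(true_ccf, abs=1e-9)


class TestClonality:
    @pytest.mark.parametrize("point,lo,hi,expected", [
        (1.0, 0.9, 1.1, "clonal"),
        (0.3, 0.2, 0.4, "subclonal"),
        (0.8, 0.7, 1.02, "clonal"),     # CI reaches 1 and point above the floor
        (0.7, 0.6, 1.05, "subclonal"),  # CI reaches 1 but point below the floor
        (0.96, 0.9, 0.99, "clonal"),    # point alone crosses the threshold
    ])
    def test_rule(self, point, lo, hi, expected):
        assert tb.classify_clonality(tb.CancerCellFraction(point, lo, hi)) == expected


class TestCallableMegabases:
    def test_all_zero_depth_gives_zero_mb(self):
        cov = CoverageSummary("P1", (0,), (30_000_000,))
        assert tb.callable_megabases(cov, 0.8, 2.0) == 0.0

    def test_depth30_pure_diploid_is_callable(self):
        # f_exp = 0.5; P(Bin(30, 0.5) >= 4) > 0.999 >= 0.8
        cov = CoverageSummary("P1", (30,), (1_000_000,))
        assert tb.callable_megabases(cov, 1.0, 2.0) == pytest.approx(1.0)
        assert stats.binom.sf(3, 30, 0.5) > 0.999

    def test_matches_independent_binomial_tail(self, rng):
        depths = tuple(range(0, 61, 5))
        counts = tuple(int(c) for c in rng.integers(1000, 10_000, len(depths)))
        cov = CoverageSummary("P1", depths, counts)
        purity, ploidy = 0.6, 3.1
        f = purity / (purity * round(ploidy) + (1 - purity) * 2)
        expected = sum(
            n for d, n in zip(depths, counts) if stats.binom.sf(3, d, f) >= 0.8
        ) / 1e6
        assert tb.callable_megabases(cov, purity, ploidy) == pytest.approx(expected)

    def test_raising_min_power_is_monotone(self):
        cov = CoverageSummary("P1", tuple(range(0, 100, 3)),
                              tuple([10_000] * 34))
        mbs = [tb.callable_megabases(cov, 0.7, 2.4, min_power=p)
               for p in (0.5, 0.7, 0.8, 0.9, 0.99)]
        assert all(a >= b for a, b in zip(mbs, mbs[1:]))

    def test_empty_histogram_rejected(self):
        with pytest.raises(ValueError):
            tb.callable_megabases(CoverageSummary("P1", (), ()), 0.8, 2.0)


class TestComputeTmb:
    def _profile(self, maf_rows, purity=1.0, ploidy=2.0, depth=60):
        from tmburden.records import ClinicalRecord, MafRecord, VariantClass

        records = []
        for i, (vclass, alt, ref) in enumerate(maf_rows):
            records.append(MafRecord(
                patient_id="P1", chrom="1", pos=1000 + i, ref_allele="C",
                alt_allele="T", gene_symbol=f"G{i}",
                variant_classification=VariantClass(vclass),
                alt_count=alt, ref_count=ref, tumor_total_cn=2))
        clin = ClinicalRecord("P1", "UCEC", 60.0, "female", purity, ploidy)
        cov = CoverageSummary("P1", (depth,), (10_000_000,))
        return tb.compute_tmb(records, clin, cov)

    def test_hand_counted_profile(self):
        # 3 clonal nonsyn (VAF .5), 2 subclonal nonsyn (VAF .1), 2 synonymous
        # clonal, over 10 callable Mb -> (0.7, 0.5, 0.3) per Mb
        rows = [("nonsynonymous", 30, 30)] * 3 + [("nonsynonymous", 6, 54)] * 2 \
            + [("synonymous", 30, 30)] * 2
        prof = self._profile(rows)
        assert (prof.overall_count, prof.nonsyn_count, prof.clonal_nonsyn_count) == (7, 5, 3)
        assert prof.callable_mb == pytest.approx(10.0)
        assert prof.overall_per_mb == pytest.approx(0.7)
        assert prof.nonsyn_per_mb == pytest.approx(0.5)
        assert prof.clonal_nonsyn_per_mb == pytest.approx(0.3)

    def test_no_mutations_all_rates_zero(self):
        prof = self._profile([])
        assert prof.overall_per_mb == 0.0 and prof.clonal_nonsyn_per_mb == 0.0

    def test_zero_callable_mb_excluded(self):
        with pytest.raises(ValueError, match="callable"):
            self._profile([("nonsynonymous", 30, 30)], depth=0)


class TestCohortProperties:
    def test_nesting_invariant(self, small_tmb):
        assert (small_tmb.clonal_nonsyn_count <= small_tmb.nonsyn_count).all()
        assert (small_tmb.nonsyn_count <= small_tmb.overall_count).all()
        assert (small_tmb.clonal_nonsyn_per_mb <= small_tmb.nonsyn_per_mb + 1e-12).all()

    def test_metrics_highly_rank_correlated(self, small_tmb):
        """Shared latent rate drives all three metrics: Spearman rho > 0.9."""
        cols = ["overall_per_mb", "nonsyn_per_mb", "clonal_nonsyn_per_mb"]
        rho = small_tmb[cols].corr(method="spearman")
        assert rho.min().min() > 0.9

    def test_per_mb_equals_count_over_callable(self, small_tmb):
        np.testing.assert_allclose(
            small_tmb["clonal_nonsyn_per_mb"],
            small_tmb["clonal_nonsyn_count"] / small_tmb["callable_mb"])


class TestMultiplicity:
    def test_het_diploid_is_one(self):
        assert infer_multiplicity(0.5, 1.0, 2) == 1

    def test_high_vaf_amplified_locus(self):
        # VAF 0.75 at CN 4, purity 1: raw = 3 -> multiplicity 3
        assert infer_multiplicity(0.75, 1.0, 4) == 3

    def test_capped_at_copy_number(self):
        assert infer_multiplicity(0.99, 1.0, 2) == 2
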