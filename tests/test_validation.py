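"""PFS Cox tests, RECIST proportional-odds tests, powered-unit selection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.optimize import minimize
from scipy.special import expit

import tmburden as tb
from tmburden.records import Recist


def outcome_frame(times, events, recist, pids=None):
    n = len(times)
    return pd.DataFrame({
        "patient_id": pids or [f"P{i}" for i in range(n)],
        "pfs_time": times, "pfs_event": events, "recist": recist,
    })


def prop_odds_oracle(codes, carrier):
    """Brute-force proportional-odds MLE via numerical optimization."""
    codes = np.asarray(codes)
    carrier = np.asarray(carrier, dtype=float)
    cats = np.sort(np.unique(codes))
    k = len(cats) - 1

    def negll(theta):
        beta = theta[0]
        cuts = np.concatenate([[theta[1]], theta[1] + np.cumsum(np.exp(theta[2:]))]) \
            if k > 1 else np.array([theta[1]])
        eta = beta * carrier
        ll = 0.0
        for i, c in enumerate(codes):
            j = np.searchsorted(cats, c)
            upper = 1.0 if j == k else expit(cuts[j] - eta[i])
            lower = 0.0 if j == 0 else expit(cuts[j - 1] - eta[i])
            ll += np.log(max(upper - lower, 1e-300))
        return -ll

    x0 = np.zeros(1 + k)
    best = minimize(negll, x0, method="Nelder-Mead",
                    options={"maxiter": 20000, "xatol": 1e-10, "fatol": 1e-12})
    return best.x[0]


class TestPfs:
    def test_doubled_event_times_give_half_hazard(self):
        """Exponential times doubled for carriers: HR estimates near 0.5."""
        hrs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 300
            carrier = np.arange(n) < n // 2
            t = rng.exponential(np.where(carrier, 200.0, 100.0))
            df = outcome_frame(t, [True] * n, ["SD"] * n)
            hrs.append(tb.pfs_test(df, carrier).hazard_ratio)
        assert 0.4 <= np.mean(hrs) <= 0.62

    def test_all_zero_carrier_rejected(self):
        df = outcome_frame([10, 20, 30], [True, True, False], ["PD"] * 3)
        with pytest.raises(ValueError):
            tb.pfs_test(df, np.zeros(3, dtype=bool))

    def test_no_events_rejected(self):
        df = outcome_frame([10, 20, 30, 40], [False] * 4, ["PD"] * 4)
        with pytest.raises(ValueError):
            tb.pfs_test(df, np.array([True, True, False, False]))

    def test_null_p_uniform_across_seeds(self):
        pvals = []
        for seed in range(60):
            rng = np.random.default_rng(seed)
            n = 120
            carrier = rng.random(n) < 0.3
            if carrier.all() or not carrier.any():
                continue
            t = rng.exponential(150.0, n)
            event = t < rng.uniform(100, 1000, n)
            df = outcome_frame(np.minimum(t, 1000), event, ["SD"] * n)
            try:
                pvals.append(tb.pfs_test(df, carrier).p)
            except ValueError:
                continue
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_reports_both_wald_and_logrank(self, rng):
        n = 200
        carrier = rng.random(n) < 0.4
        t = rng.exponential(np.where(carrier, 250.0, 120.0))
        df = outcome_frame(t, [True] * n, ["SD"] * n)
        res = tb.pfs_test(df, carrier)
        assert 0 < res.p <= 1 and 0 < res.p_logrank <= 1
        assert res.n_carriers == carrier.sum() and res.n_total == n


class TestRecist:
    def test_identical_distributions_odds_one(self):
        recist = (["PD"] * 10 + ["SD"] * 10 + ["PR"] * 5 + ["CR"] * 5) * 2
        carrier = np.array([True] * 30 + [False] * 30)
        df = outcome_frame([100] * 60, [True] * 60, recist)
        res = tb.recist_test(df, carrier)
        assert res.odds == pytest.approx(1.0, abs=0.05)

    def test_single_category_rejected(self):
        df = outcome_frame([10] * 6, [True] * 6, ["SD"] * 6)
        with pytest.raises(ValueError):
            tb.recist_test(df, np.array([True] * 3 + [False] * 3))

    def test_odds_recovery_at_n400(self):
        """Simulated carrier odds 2.0 recovered within [1.5, 2.7] over 20 seeds."""
        odds_list = []
        base = np.array([0.4, 0.3, 0.2, 0.1])
        cuts = np.log(np.cumsum(base)[:-1] / (1 - np.cumsum(base)[:-1]))
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 400
            carrier = rng.random(n) < 0.4
            u = rng.logistic(size=n) + np.log(2.0) * carrier
            codes = np.searchsorted(cuts, u)
            recist = np.array(["PD", "SD", "PR", "CR"])[codes]
            df = outcome_frame([100] * n, [True] * n, recist)
            odds_list.append(tb.recist_test(df, carrier).odds)
        assert 1.5 <= np.mean(odds_list) <= 2.7

    def test_matches_brute_force_proportional_odds_oracle(self, rng):
        n = 30
        carrier = np.array([True] * 12 + [False] * 18)
        codes = rng.integers(0, 4, n)
        recist = np.array(["PD", "SD", "PR", "CR"])[codes]
        df = outcome_frame([50] * n, [True] * n, recist)
        res = tb.recist_test(df, carrier)
        beta_oracle = prop_odds_oracle(codes, carrier)
        assert np.log(res.odds) == pytest.approx(beta_oracle, abs=1e-4)


class TestOrientation:
    def test_relabeling_inverts_hr_and_odds(self, rng):
        n = 200
        carrier = rng.random(n) < 0.35
        t = rng.exponential(np.where(carrier, 220.0, 140.0))
        codes = rng.integers(0, 4, n)
        recist = np.array(["PD", "SD", "PR", "CR"])[codes]
        df = outcome_frame(t, [True] * n, recist)
        s1, s2 = tb.pfs_test(df, carrier), tb.pfs_test(df, ~carrier)
        assert s1.hazard_ratio * s2.hazard_ratio == pytest.approx(1.0, rel=1e-6)
        r1, r2 = tb.recist_test(df, carrier), tb.recist_test(df, ~carrier)
        assert r1.odds * r2.odds == pytest.approx(1.0, rel=1e-3)


class TestPoweredUnitsAndSummary:
    def test_powered_units_threshold(self, small_cohort, germline_records):
        patients = list(small_cohort.outcomes["patient_id"])
        matrix = tb.build_geneset_units(germline_records, small_cohort.gene_sets(),
                                        patients, min_carriers=5)
        units = tb.powered_units(matrix, small_cohort.outcomes,
                                 min_carriers_validation=10,
                                 min_events_validation=5)
        counts = matrix.carrier_counts()
        for u in units:
            assert counts[u] >= 10

    def test_tmb_summary_medians(self):
        tmb = pd.DataFrame({
            "overall_count": [10, 20, 2, 4],
            "nonsyn_count": [8, 15, 1, 3],
            "clonal_nonsyn_count": [6, 12, 1, 2],
        })
        res = tb.tmb_by_carrier_summary(tmb, np.array([True, True, False, False]))
        row = res[res["metric"] == "overall_count"].iloc[0]
        assert row["median_carrier"] == 15.0 and row["median_non_carrier"] == 3.0
        assert (res["p_mannwhitney"] > 0).all()
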