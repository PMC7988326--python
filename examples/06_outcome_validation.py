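"""Validate carrier units against immunotherapy outcomes.

Simulates a melanoma-sized validation cohort in which carriers progress
later (hazard ratio 0.7) and respond better (proportional odds 1.8), then
fits both with a Cox proportional-hazards model and an ordinal logistic
model on RECIST (PD < SD < PR < CR). HR < 1 and odds > 1 mean carriers do
better; the median-count summary shows how raw mutation counts differ by
carrier status, typically without reaching significance at this size.
"""

import tmburden as tb

units = [tb.CarrierUnitSpec("DISEASE", ("D1", "D2", "D3"), carrier_fraction=0.35,
                            effect=1.0)]  # mild burden shift: counts differ, rarely significantly
cfg = tb.SimulationConfig(
    n_patients=140,  # validation-cohort scale
    cancer_type_proportions={"SKCM": 1.0}, baseline_tmb_rate={"SKCM": 5.0},
    carrier_spec=units,
    outcome_spec=tb.OutcomeSpec(hazard_ratio=0.7, response_odds=1.8,
                                units=("DISEASE",)),
    seed=6)
cohort = tb.simulate_cohort(cfg)
carrier = cohort.carrier_truth["DISEASE"].to_numpy()

surv = tb.pfs_test(cohort.outcomes, carrier, label="DISEASE")
resp = tb.recist_test(cohort.outcomes, carrier, label="DISEASE")
print(f"n = {surv.n_total}, carriers = {surv.n_carriers}")
print(f"PFS: hazard ratio = {surv.hazard_ratio:.3f} "
      f"(Cox Wald p = {surv.p:.4f}, log-rank p = {surv.p_logrank:.4f})")
print(f"RECIST: odds = {resp.odds:.3f} (LR p = {resp.p:.4f})")

tmb = tb.compute_tmb_profiles(cohort.maf, cohort.clinical, cohort.coverage)
summary = tb.tmb_by_carrier_summary(tmb, carrier)
print("\nmedian mutation counts by carrier status:")
print(summary.to_string(index=False, float_format=lambda x: f"{x:.3g}"))
print("\nAt n=140 with 36 carriers the estimates are noisy: a true HR of 0.7")
print("can even flip direction by chance. This run illustrates the power")
print("limitation at validation-cohort scale; increase n_patients (or pool")
print("units) to see the injected HR 0.7 / odds 1.8 emerge reliably.")
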