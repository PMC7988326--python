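"""Simulate a cohort and compute the three TMB metrics per patient.

Builds a 300-patient synthetic cohort (four cancer types, one mismatch-repair
carrier unit raising clonal nonsynonymous TMB by 8 mutations/Mb), then
computes overall, nonsynonymous and clonal nonsynonymous TMB normalized per
callable megabase. The printed Spearman correlations show the three metrics
track a shared underlying mutation rate; carriers sit visibly above
non-carriers on the clonal nonsynonymous scale.
"""

import tmburden as tb

units = [tb.CarrierUnitSpec("MMR", ("MSH2", "MSH6", "PMS2", "MLH1"),
                            carrier_fraction=0.05, effect=8.0)]
cohort = tb.simulate_cohort(tb.SimulationConfig(n_patients=300,
                                                carrier_spec=units, seed=1))
tmb = tb.compute_tmb_profiles(cohort.maf, cohort.clinical, cohort.coverage)

print(f"patients: {len(tmb)}, somatic calls: {len(cohort.maf)}")
print(f"mean callable Mb: {tmb['callable_mb'].mean():.2f}")
cols = ["overall_per_mb", "nonsyn_per_mb", "clonal_nonsyn_per_mb"]
print("\nper-Mb TMB summary:")
print(tmb[cols].describe().loc[["mean", "50%", "max"]].round(2))
rho = tmb[cols].corr(method="spearman")
print(f"\nminimum pairwise Spearman rho: {rho.min().min():.3f} "
      "(all three metrics share one latent rate)")

carrier = cohort.carrier_truth["MMR"].reindex(tmb["patient_id"]).to_numpy()
print(f"\nclonal nonsyn TMB/Mb: carriers {tmb.loc[carrier, cols[2]].mean():.2f} "
      f"vs non-carriers {tmb.loc[~carrier, cols[2]].mean():.2f} "
      "(difference ~ the injected +8/Mb effect)")
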