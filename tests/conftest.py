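import numpy as np
import pytest

import tmburden as tb


@pytest.fixture(scope="session")
def small_cohort():
    """Shared 300-patient cohort with one true-effect unit and nulls."""
    units = [tb.CarrierUnitSpec("HIT", ("HITG1", "HITG2"), 0.1, 8.0)] + tb.null_units(5, 0.1)
    config = tb.SimulationConfig(n_patients=300, carrier_spec=units, seed=42)
    return tb.simulate_cohort(config)


@pytest.fixture(scope="session")
def small_tmb(small_cohort):
    return tb.compute_tmb_profiles(small_cohort.maf, small_cohort.clinical,
                                   small_cohort.coverage)


@pytest.fixture(scope="session")
def germline_records(small_cohort):
    from tmburden.records import GermlineVariantRecord

    return [
        GermlineVariantRecord(r.patient_id, r.gene_symbol, r.variant_id, bool(r.pathogenic))
        for r in small_cohort.germline.itertuples(index=False)
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
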