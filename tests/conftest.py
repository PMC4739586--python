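"""Shared fixtures: scaled-down synthetic worlds and reusable fits.

Cohorts here are deliberately smaller than the default world so the suite
stays fast; tests that probe calibration of the default world build it
themselves.
"""

import numpy as np
import pandas as pd
import pytest

import wardaudit as wa


def make_config(**overrides) -> wa.SimulationConfig:
    """A small single-type world (40 hospitals x ~4 wards x ~50 patients)."""
    base = dict(
        n_hospitals={"municipal": 40},
        wards_per_hospital_mean={"municipal": 4.0},
        patients_per_ward_mean={"municipal": 50.0},
        seed=42,
    )
    base.update(overrides)
    return wa.SimulationConfig(**base)


def null_config(**overrides) -> wa.SimulationConfig:
    """A world with no cluster variation and no contextual effects."""
    zero_vol = {1: 0.0, 2: 0.0, 3: 0.0}
    zero_type = {"regional": 0.0, "provincial": 0.0, "municipal": 0.0}
    base = dict(
        sigma2_h=0.0,
        sigma2_w=0.0,
        ward_volume_beta=zero_vol,
        hospital_type_beta=zero_type,
    )
    base.update(overrides)
    return make_config(**base)


@pytest.fixture(scope="session")
def small_cohort():
    """One realized small-world cohort plus its truth bundle."""
    return wa.simulate_cohort(make_config())


@pytest.fixture(scope="session")
def small_fit(small_cohort):
    """Three-level Laplace fit of the generating patient covariates."""
    table, _ = small_cohort
    return wa.fit_three_level(
        table,
        ["age", "sex_eth", "cm_cancer", "cm_respiratory"],
        ref_levels={"sex_eth": "swedish_female"},
    )


@pytest.fixture()
def toy_raw_table():
    """Hand-enumerated 10-row raw table for the exclusion cascade.

    2 admissions have prior heart failure, 1 is at a nursing home, and one
    hospital holds a single (otherwise clean) patient; with a minimum
    hospital size of 2 the cascade removes (0, 2, 1, 1) and retains 6.
    """
    rows = []
    for i in range(9):
        rows.append(
            dict(
                patient_id=f"p{i}",
                death30=i % 2,
                age=60 + i,
                sex_eth="swedish_female",
                ward_id="big_w1" if i < 5 else "big_w2",
                hospital_id="big",
                prior_hf=1 if i in (0, 1) else 0,
                facility_kind="nursing_home" if i == 2 else "hospital",
            )
        )
    rows.append(
        dict(
            patient_id="p9",
            death30=0,
            age=70,
            sex_eth="swedish_male",
            ward_id="solo_w1",
            hospital_id="solo",
            prior_hf=0,
            facility_kind="hospital",
        )
    )
    return wa.CohortTable(pd.DataFrame(rows))
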