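import numpy as np
import pandas as pd
import pytest

from gdmrisk import GeneratorConfig, generate_cohort, prepare


def make_record(
    age=25.0,
    bmi=23.0,
    booking_ga=10.0,
    ethnicity="Caucasian",
    family_hx=0,
    prev_gdm=0,
    pcos=0,
    prev_macrosomia=0,
    **labs,
) -> pd.DataFrame:
    """One-row cohort frame with sub-threshold labs unless overridden."""
    defaults = {
        "rbs": 100.0,
        "ppbs": 120.0,
        "hba1c": 5.0,
        "ogtt_fasting": np.nan,
        "ogtt_1h": np.nan,
        "ogtt_2h": np.nan,
    }
    defaults.update(labs)
    return pd.DataFrame(
        [
            {
                "age": age,
                "bmi": bmi,
                "booking_ga": booking_ga,
                "ethnicity": ethnicity,
                "family_hx": family_hx,
                "prev_gdm": prev_gdm,
                "pcos": pcos,
                "prev_macrosomia": prev_macrosomia,
                **defaults,
            }
        ]
    )


@pytest.fixture(scope="session")
def default_cfg() -> GeneratorConfig:
    return GeneratorConfig(n_patients=10_000, seed=42)


@pytest.fixture(scope="session")
def cohort_10k(default_cfg):
    return generate_cohort(default_cfg)


@pytest.fixture(scope="session")
def cohort_small():
    return generate_cohort(GeneratorConfig(n_patients=800, seed=7))


@pytest.fixture(scope="session")
def prepared_small(cohort_small):
    """(balanced_train, test, split) for the n=800 cohort."""
    return prepare(cohort_small)
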