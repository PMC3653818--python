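import numpy as np
import pandas as pd
import pytest

from registat import AgeGroupScheme, RegistrySpec, simulate_registry


@pytest.fixture(scope="session")
def scheme() -> AgeGroupScheme:
    return AgeGroupScheme.default()


@pytest.fixture
def individual_csv(tmp_path):
    """Small individual-records file in the standard layout."""
    text = (
        "Patient_ID,Sex,d_group,d_age,i_month,i_year,f_month,f_year,"
        "Status,Follow_up\n"
        "1,1,Lung,84,3,1995,3,1995,1,0.08\n"
        "2,1,Lung,65,2,1995,12,1999,1,0.83\n"
        "3,1,Lung,63,3,1995,5,1999,1,4.17\n"
        "197,1,Lung,52,5,1995,12,2008,0,12.58\n"
    )
    path = tmp_path / "individual.csv"
    path.write_text(text)
    return path


@pytest.fixture
def aggregated_csv(tmp_path):
    text = (
        "Sex,Age.group,Year,Group,Cases,Population\n"
        "2,16,2004,Stomach,8,26115\n"
        "2,17,2004,Stomach,19,19665\n"
        "2,18,2004,Stomach,15,15737\n"
    )
    path = tmp_path / "aggregated.csv"
    path.write_text(text)
    return path


def make_counts(age_groups, cases, person_years, year=2000, sex=1,
                group="D") -> pd.DataFrame:
    """Counts slice for one sex/disease/year from parallel sequences."""
    return pd.DataFrame({
        "sex": sex,
        "age_group": list(age_groups),
        "year": year,
        "group": group,
        "cases": list(cases),
        "person_years": list(person_years),
    })


@pytest.fixture(scope="session")
def null_registry():
    """Flat-rate, zero-excess-hazard registry (ground truth: EAPC 0,
    RS(5) = 1, all decomposition components 0)."""
    return simulate_registry(RegistrySpec(
        annual_rate_change=1.0, excess_hazard=0.0, seed=11))


@pytest.fixture(scope="session")
def trending_registry():
    """Registry with rates rising 5% per year and moderate excess hazard."""
    return simulate_registry(RegistrySpec(
        annual_rate_change=1.05, excess_hazard=0.25, seed=7))
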