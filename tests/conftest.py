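"""Shared fixtures: hand-built donor table and small synthetic cohorts."""

import numpy as np
import pandas as pd
import pytest

import adglia as ag


def donor_metadata_12() -> pd.DataFrame:
    """Twelve donors exercising every branch of the phenotype rules.

    Expected labels (CERAD canonical 1-4 coding):

    ======  =====  =====  ====  ========================  ==========  ===========
    donor   cerad  braak  cdr   flags                     ad_cerad    ad_clinical
    ======  =====  =====  ====  ========================  ==========  ===========
    d01     2      3      1     none                      case        other (CERAD<3)
    d02     1      1      0     none                      control     control
    d03     4      6      3     psychiatric               other       other
    d04     NaN    4      1     none                      missing     case (1 missing)
    d05     3      4      1     none                      case        case
    d06     3      NaN    2     none                      case        case (1 missing)
    d07     1      NaN    0     none                      control     control (1 missing)
    d08     2      3      0.5   none                      case        other
    d09     1      2      0     sepsis                    other       other
    d10     4      5      2     other_neurodegenerative   other       other
    d11     1      2      0.5   none (age 40)             control     other
    d12     3      3      1     none                      case        case
    ======  =====  =====  ====  ========================  ==========  ===========
    """
    rows = {
        "d01": dict(cerad=2, braak=3, cdr=1.0),
        "d02": dict(cerad=1, braak=1, cdr=0.0),
        "d03": dict(cerad=4, braak=6, cdr=3.0, flag_psychiatric=True),
        "d04": dict(cerad=np.nan, braak=4, cdr=1.0),
        "d05": dict(cerad=3, braak=4, cdr=1.0),
        "d06": dict(cerad=3, braak=np.nan, cdr=2.0),
        "d07": dict(cerad=1, braak=np.nan, cdr=0.0),
        "d08": dict(cerad=2, braak=3, cdr=0.5),
        "d09": dict(cerad=1, braak=2, cdr=0.0, flag_sepsis=True),
        "d10": dict(cerad=4, braak=5, cdr=2.0,
                    flag_other_neurodegenerative=True),
        "d11": dict(cerad=1, braak=2, cdr=0.5, age=40.0),
        "d12": dict(cerad=3, braak=3, cdr=1.0),
    }
    base = dict(age=78.0, sex="female", source="source_1",
                apoe_genotype="3/3",
                flag_psychiatric=False, flag_other_neurodegenerative=False,
                flag_autoimmune=False, flag_brain_cancer=False,
                flag_sepsis=False, flag_alcoholism=False)
    records = {}
    for donor, vals in rows.items():
        rec = dict(base)
        rec.update(vals)
        for k in range(1, 6):
            rec[f"plaque_r{k}"] = float(k)
        records[donor] = rec
    md = pd.DataFrame.from_dict(records, orient="index")
    md.index.name = "donor_id"
    return md


EXPECTED_AD_CERAD = {
    "d01": "case", "d02": "control", "d03": "other", "d04": "missing",
    "d05": "case", "d06": "case", "d07": "control", "d08": "case",
    "d09": "other", "d10": "other", "d11": "control", "d12": "case",
}
EXPECTED_AD_CLINICAL = {
    "d01": "other", "d02": "control", "d03": "other", "d04": "case",
    "d05": "case", "d06": "case", "d07": "control", "d08": "other",
    "d09": "other", "d10": "other", "d11": "other", "d12": "case",
}
EXPECTED_DEMENTIA = {
    "d01": "case", "d02": "control", "d03": "case", "d04": "case",
    "d05": "case", "d06": "case", "d07": "control", "d08": "mci",
    "d09": "control", "d10": "case", "d11": "mci", "d12": "case",
}


@pytest.fixture(scope="session")
def donor_table():
    return donor_metadata_12()


@pytest.fixture(scope="session")
def small_cohort():
    """60-donor, 150-gene cohort reused by fast unit tests."""
    cfg = ag.CohortConfig(n_donors=60, n_genes=150, seed=20240901)
    return ag.simulate_cohort(cfg)
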