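"""Composite AD phenotype construction from clinical/neuropathology fields.

Raw fields per donor: CERAD neuritic-plaque score (canonically coded 1-4, where
1 = no neuritic plaque and 4 = frequent plaque / definite AD), Braak
neurofibrillary-tangle stage (0-6), Clinical Dementia Rating (CDR; 0 healthy,
0.5 mild cognitive impairment, >= 1 dementia), five regional amyloid-beta
plaque densities, ApoE genotype, plus exclusion-diagnosis flags.

Composite labels produced here:

* ``ad_cerad``   -- AD by neuritic plaque burden: case if CERAD >= 2.
* ``ad_clinical`` -- stricter clinico-pathologic AD: CERAD >= 3, Braak >= 3
  and dementia, allowing at most one missing component; controls require
  CERAD = 1, Braak <= 2 and no cognitive impairment, again allowing one
  missing component.
* ``dementia``   -- CDR >= 1, with the harmonized 0 / 0.5 / 1 cognitive scale
  also emitted.
* ``braak_class`` -- high (>= 5) / low (<= 2) / mid.
* ``amyloid_mean`` -- mean plaque density across the measured regions.
* ``apoe4_count`` -- number of epsilon-4 alleles.

Donors with any of six exclusion diagnoses (psychiatric disorder, non-AD/FTD
neurodegeneration, systemic autoimmune disease, brain cancer, sepsis as cause
of death, severe alcoholism) are labelled ``other`` for the AD diagnoses.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Boolean metadata columns that mark a donor as 'Other' for AD diagnoses.
EXCLUSION_FLAGS = (
    "flag_psychiatric",
    "flag_other_neurodegenerative",
    "flag_autoimmune",
    "flag_brain_cancer",
    "flag_sepsis",
    "flag_alcoholism",
)

CASE, CONTROL, OTHER, MISSING = "case", "control", "other", "missing"

#: Amyloid plaque density columns (five measured brain regions).
PLAQUE_COLUMNS = ("plaque_r1", "plaque_r2", "plaque_r3", "plaque_r4", "plaque_r5")


def _is_missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x)) or pd.isna(x)


def apply_exclusions(metadata: pd.DataFrame,
                     flags: Iterable[str] = EXCLUSION_FLAGS) -> pd.Series:
    """Return a boolean Series: True where any exclusion diagnosis is present.

    Missing flag columns or missing values are treated as False (and logged),
    matching an 'in the presence of any of the following' reading.
    """
    flags = list(flags)
    out = pd.Series(False, index=metadata.index)
    for col in flags:
        if col not in metadata.columns:
            logger.warning("exclusion flag %r absent; treated as all-False", col)
            continue
        vals = metadata[col]
        if vals.isna().any():
            logger.warning("missing values in %r treated as False", col)
        out |= vals.fillna(False).astype(bool)
    return out


def normalize_cerad(cerad: pd.Series, coding: str = "1-4") -> pd.Series:
    """Map CERAD scores onto the canonical 1-4 scale.

    ``coding='0-3'`` shifts inputs by +1 (some cohorts code 0 = no plaque).
    """
    if coding == "1-4":
        out = cerad.astype(float)
    elif coding == "0-3":
        out = cerad.astype(float) + 1
    else:
        raise ValueError(f"unknown cerad coding {coding!r}")
    bad = out.dropna()[(out.dropna() < 1) | (out.dropna() > 4)]
    if len(bad):
        raise ValueError(f"CERAD values outside 1-4 after coding: {sorted(set(bad))}")
    return out


def label_ad_cerad(metadata: pd.DataFrame, is_other: pd.Series | None = None,
                   cerad_coding: str = "1-4") -> pd.Series:
    """AD by neuritic plaque: case if CERAD >= 2, control if CERAD = 1."""
    if is_other is None:
        is_other = apply_exclusions(metadata)
    cerad = normalize_cerad(metadata["cerad"], cerad_coding)
    out = pd.Series(MISSING, index=metadata.index, dtype=object)
    out[cerad >= 2] = CASE
    out[cerad == 1] = CONTROL
    out[is_other] = OTHER  # exclusion takes precedence
    return out


def label_ad_clinical(metadata: pd.DataFrame, is_other: pd.Series | None = None,
                      cerad_coding: str = "1-4") -> pd.Series:
    """Strict clinico-pathologic AD combining plaque, tangle and cognition.

    Case requires CERAD >= 3, Braak >= 3 and dementia (CDR >= 1); control
    requires CERAD = 1, Braak <= 2 and no cognitive impairment (CDR = 0).
    Either rule tolerates at most one missing component (the observed
    components must all be satisfied).  Excluded donors are ``other``;
    donors with every component missing are ``missing``.
    """
    if is_other is None:
        is_other = apply_exclusions(metadata)
    cerad = normalize_cerad(metadata["cerad"], cerad_coding)
    braak = metadata["braak"].astype(float)
    cdr = metadata["cdr"].astype(float)

    def _rule(conds: list[pd.Series]) -> pd.Series:
        # satisfied on observed components, at most one missing
        sat = pd.concat(conds, axis=1)
        n_missing = sat.isna().sum(axis=1)
        ok = sat.isna() | sat.astype(object).eq(True)
        return ok.all(axis=1) & (n_missing <= 1)

    def _cond(series: pd.Series, op) -> pd.Series:
        out = op(series).astype(object)
        out[series.isna()] = np.nan
        return out

    case = _rule([
        _cond(cerad, lambda s: s >= 3),
        _cond(braak, lambda s: s >= 3),
        _cond(cdr, lambda s: s >= 1),
    ])
    control = _rule([
        _cond(cerad, lambda s: s == 1),
        _cond(braak, lambda s: s <= 2),
        _cond(cdr, lambda s: s == 0),
    ])

    out = pd.Series(OTHER, index=metadata.index, dtype=object)
    out[case] = CASE
    out[control & ~case] = CONTROL
    all_missing = cerad.isna() & braak.isna() & cdr.isna()
    out[all_missing] = MISSING
    out[is_other] = OTHER  # exclusion takes precedence
    return out


def label_dementia(metadata: pd.DataFrame) -> pd.DataFrame:
    """Dementia by CDR >= 1, plus the harmonized 0 / 0.5 / 1 cognitive scale.

    CDR 0.5 (mild cognitive impairment) is neither case nor control; it is
    kept as the intermediate harmonized value.
    """
    cdr = metadata["cdr"].astype(float)
    label = pd.Series(MISSING, index=metadata.index, dtype=object)
    label[cdr >= 1] = CASE
    label[cdr == 0] = CONTROL
    label[cdr == 0.5] = "mci"
    harmonized = cdr.where(cdr <= 0.5, 1.0)  # collapse 1-5 onto 1 (dementia)
    return pd.DataFrame({"dementia": label, "cdr_harmonized": harmonized})


def derive_quantitative(metadata: pd.DataFrame) -> pd.DataFrame:
    """Amyloid mean across regions, ApoE4 allele count, Braak high/low class."""
    plaque_cols = [c for c in PLAQUE_COLUMNS if c in metadata.columns]
    if len(plaque_cols) != 5:
        raise ValueError("expected exactly 5 plaque region columns "
                         f"{PLAQUE_COLUMNS}, found {plaque_cols}")
    plaques = metadata[plaque_cols].astype(float)
    if (plaques < 0).any().any():
        raise ValueError("negative plaque density")
    amyloid_mean = plaques.mean(axis=1, skipna=True)  # available regions

    apoe4 = metadata["apoe_genotype"].map(_count_e4_alleles)

    braak = metadata["braak"].astype(float)
    braak_class = pd.Series(MISSING, index=metadata.index, dtype=object)
    braak_class[braak >= 5] = "high"
    braak_class[braak <= 2] = "low"
    braak_class[(braak >= 3) & (braak <= 4)] = "mid"

    return pd.DataFrame({
        "amyloid_mean": amyloid_mean,
        "apoe4_count": apoe4,
        "braak_class": braak_class,
    })


def _count_e4_alleles(genotype) -> float:
    if _is_missing(genotype):
        return np.nan
    alleles = str(genotype).replace("|", "/").split("/")
    if len(alleles) != 2 or any(a not in {"2", "3", "4"} for a in alleles):
        raise ValueError(f"malformed ApoE genotype {genotype!r}")
    return float(sum(a == "4" for a in alleles))


def harmonize(metadata: pd.DataFrame, cerad_coding: str = "1-4",
              min_age: float = 45.0) -> pd.DataFrame:
    """Build the full composite-label table, one row per donor.

    ``eligible`` is the age gate (age >= ``min_age``); exclusion diagnoses
    are reflected in the ``other`` labels, and also reported as ``is_other``.
    """
    is_other = apply_exclusions(metadata)
    out = pd.DataFrame(index=metadata.index)
    out["ad_cerad"] = label_ad_cerad(metadata, is_other, cerad_coding)
    out["ad_clinical"] = label_ad_clinical(metadata, is_other, cerad_coding)
    dem = label_dementia(metadata)
    out["dementia"] = dem["dementia"]
    out["cdr_harmonized"] = dem["cdr_harmonized"]
    quant = derive_quantitative(metadata)
    out["braak_class"] = quant["braak_class"]
    out["amyloid_mean"] = quant["amyloid_mean"]
    out["apoe4_count"] = quant["apoe4_count"]
    out["is_other"] = is_other
    age = metadata["age"].astype(float)
    out["eligible"] = (age >= min_age).fillna(False)
    return out
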