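"""Analysis-ready phenotypes for the human cohort.

Builds the combined parental longevity score (PLS), grip-strength
summaries and the covariate encoding shared by every human association
model.

PLS: participants aged 65+ are eligible; parents who died prematurely
(mothers < 49 y, fathers < 52 y) are excluded.  Death ages of the
remaining parents are standardized to z-scores within the eligible
subsample (sample SD, ddof=1) and the PLS is the unweighted mean of the
available parental z-scores, without re-standardization.
"""

from __future__ import annotations

import warnings
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "EDUCATION_LEVELS",
    "SMOKING_LEVELS",
    "COHORT_COLUMNS",
    "compute_pls",
    "pls_category_cutoffs",
    "summarize_grip",
    "build_covariates",
]

EDUCATION_LEVELS = [
    "none",
    "elementary",
    "secondary",
    "high school",
    "professional school",
    "university",
]
SMOKING_LEVELS = ["none", "<20", "20-39", "40+"]
SEX_LEVELS = ["male", "female"]
SITE_LEVELS = ["Greve", "Bagno"]

COHORT_COLUMNS = [
    "participant_id",
    "age",
    "sex",
    "bmi",
    "education",
    "site",
    "smoking",
    "neutrophil_pct",
    "lymphocyte_pct",
    "monocyte_pct",
    "eosinophil_pct",
    "mother_death_age",
    "father_death_age",
    "grip_fu3",
    "grip_fu4",
]

WBC_COLUMNS = ["neutrophil_pct", "lymphocyte_pct", "monocyte_pct", "eosinophil_pct"]

ELIGIBILITY_AGE = 65
PREMATURE_MOTHER_AGE = 49
PREMATURE_FATHER_AGE = 52


def compute_pls(
    records: pd.DataFrame,
    eligibility_age: float = ELIGIBILITY_AGE,
    premature_mother_age: float = PREMATURE_MOTHER_AGE,
    premature_father_age: float = PREMATURE_FATHER_AGE,
    require_both_parents: bool = False,
) -> pd.DataFrame:
    """Compute parental-longevity z-scores and the combined PLS.

    Parameters
    ----------
    records : DataFrame
        Cohort table with at least ``participant_id``, ``age``,
        ``mother_death_age`` and ``father_death_age`` (NaN = missing).
    require_both_parents : bool
        If True, the PLS is defined only when both parental z-scores are
        available; otherwise a single-parent PLS is allowed.

    Returns
    -------
    DataFrame with columns participant_id, z_maternal, z_paternal, pls,
    excluded_reason.  ``excluded_reason`` is one of under_65,
    premature_mother, premature_father, premature_both, no_parent_data,
    none — partial exclusions are recorded even when a (single-parent)
    PLS is still defined.
    """
    eligible = records["age"] >= eligibility_age
    mother = records["mother_death_age"]
    father = records["father_death_age"]
    mother_ok = eligible & mother.notna() & (mother >= premature_mother_age)
    father_ok = eligible & father.notna() & (father >= premature_father_age)

    def _zscore(values: pd.Series, mask: pd.Series) -> pd.Series:
        pop = values[mask]
        if len(pop) < 2:
            return pd.Series(np.nan, index=values.index)
        mean, sd = pop.mean(), pop.std(ddof=1)
        if sd == 0:
            return pd.Series(np.nan, index=values.index)
        z = (values - mean) / sd
        return z.where(mask)

    z_maternal = _zscore(mother, mother_ok)
    z_paternal = _zscore(father, father_ok)

    both = pd.concat([z_maternal, z_paternal], axis=1)
    if require_both_parents:
        pls = both.mean(axis=1).where(both.notna().all(axis=1))
    else:
        pls = both.mean(axis=1)  # skipna: single-parent PLS allowed

    premature_m = eligible & mother.notna() & (mother < premature_mother_age)
    premature_f = eligible & father.notna() & (father < premature_father_age)
    reasons = []
    for i in records.index:
        if not eligible.loc[i]:
            reasons.append("under_65")
        elif premature_m.loc[i] and premature_f.loc[i]:
            reasons.append("premature_both")
        elif premature_m.loc[i]:
            reasons.append("premature_mother")
        elif premature_f.loc[i]:
            reasons.append("premature_father")
        elif mother.isna().loc[i] and father.isna().loc[i]:
            reasons.append("no_parent_data")
        else:
            reasons.append("none")

    return pd.DataFrame(
        {
            "participant_id": records["participant_id"].values,
            "z_maternal": z_maternal.values,
            "z_paternal": z_paternal.values,
            "pls": pls.values,
            "excluded_reason": reasons,
        }
    )


def pls_category_cutoffs(pls: pd.Series) -> dict[str, float]:
    """Tertile-style short/intermediate/long-lived cut-offs.

    Cut-offs are taken from the normal fitted to the defined PLS values
    (33.3rd and 66.7th percentiles of N(mean, sd)).  Reported for audit;
    the association models use the continuous score.
    """
    vals = pls.dropna()
    if len(vals) < 2:
        raise ValueError("need at least 2 defined PLS values")
    from scipy.stats import norm

    mean, sd = vals.mean(), vals.std(ddof=1)
    return {
        "short_max": float(norm.ppf(1 / 3, loc=mean, scale=sd)),
        "long_min": float(norm.ppf(2 / 3, loc=mean, scale=sd)),
    }


def summarize_grip(measurements: pd.DataFrame) -> pd.DataFrame:
    """Summarize repeated grip measurements to one mean per follow-up.

    ``measurements`` is long format with columns ``participant_id``,
    ``follow_up`` ('fu3' or 'fu4') and ``grip_kg``.  Missing repeats are
    ignored; a follow-up with no measurements stays missing.  Returns a
    wide frame with grip_fu3 / grip_fu4 columns.
    """
    required = {"participant_id", "follow_up", "grip_kg"}
    if not required <= set(measurements.columns):
        raise ValueError(f"need columns {sorted(required)}")
    bad = set(measurements["follow_up"].unique()) - {"fu3", "fu4"}
    if bad:
        raise ValueError(f"unknown follow_up labels: {sorted(bad)}")
    wide = (
        measurements.groupby(["participant_id", "follow_up"])["grip_kg"]
        .mean()
        .unstack("follow_up")
    )
    wide = wide.rename(columns={"fu3": "grip_fu3", "fu4": "grip_fu4"})
    for col in ("grip_fu3", "grip_fu4"):
        if col not in wide.columns:
            wide[col] = np.nan
    return wide[["grip_fu3", "grip_fu4"]].reset_index()


def build_covariates(
    records: pd.DataFrame,
    outcome: str = "PLS",
    dummy_code_ordinals: bool = False,
) -> tuple[pd.DataFrame, pd.Series]:
    """Encode the confounder set used by every human association model.

    sex/site become binary indicators, education and smoking ordinal
    integers (or dummy blocks with ``dummy_code_ordinals``), BMI and the
    four WBC percentages stay continuous.  Age is included for every
    outcome except ``age`` itself.  Returns ``(X, complete)`` where
    ``complete`` flags rows with no missing covariate (listwise-deletion
    mask); X is indexed like ``records``.
    """
    for col, levels in (
        ("sex", SEX_LEVELS),
        ("site", SITE_LEVELS),
        ("education", EDUCATION_LEVELS),
        ("smoking", SMOKING_LEVELS),
    ):
        observed = set(records[col].dropna().unique())
        unknown = observed - set(levels)
        if unknown:
            raise ValueError(f"unknown {col} label(s): {sorted(unknown)}")

    X = pd.DataFrame(index=records.index)
    X["sex_female"] = records["sex"].map({"male": 0.0, "female": 1.0})
    X["site_bagno"] = records["site"].map({"Greve": 0.0, "Bagno": 1.0})
    if dummy_code_ordinals:
        for col, levels in (("education", EDUCATION_LEVELS), ("smoking", SMOKING_LEVELS)):
            cat = pd.Categorical(records[col], categories=levels)
            dummies = pd.get_dummies(cat, prefix=col, drop_first=True, dtype=float)
            dummies.index = records.index
            dummies[records[col].isna()] = np.nan
            X = pd.concat([X, dummies], axis=1)
    else:
        X["education_level"] = records["education"].map(
            {lvl: float(i) for i, lvl in enumerate(EDUCATION_LEVELS)}
        )
        X["smoking_level"] = records["smoking"].map(
            {lvl: float(i) for i, lvl in enumerate(SMOKING_LEVELS)}
        )
    X["bmi"] = records["bmi"].astype(float)
    for col in WBC_COLUMNS:
        X[col] = records[col].astype(float)
    if outcome != "age":
        X["age"] = records["age"].astype(float)
    complete = X.notna().all(axis=1)
    complete.name = "complete"
    return X, complete
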