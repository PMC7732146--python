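"""Published reference values from a large community carotid-stiffness screening study.

These constants summarise the printed results of a cross-sectional field survey
(1074 adults enrolled, 983 analyzable) in which local carotid stiffness was
measured with an A-mode ultrasound device alongside standard cardiometabolic
risk factors.  They serve three purposes in this package:

* the multiple-regression coefficient sets are the generative truth used by
  :mod:`carostiff.synthgen` (the β model) and the prediction oracle used by
  :func:`carostiff.popstats.predict_index`;
* the blood-pressure-category group contrasts and enrollment percentages are
  inputs to the printed-arithmetic checks in the acceptance suite;
* the quintile cut-points and cohort summaries are echoed in report tables.

None of these numbers is ever *fitted* here; they are fixed study constants.
"""

from __future__ import annotations

from types import MappingProxyType

#: Covariate order shared by every published regression model.
MODEL_COVARIATES = ("age", "sex_code", "sbp", "dbp", "smoking_years", "n_cmr")

#: Sex coding used by the published regressions: 1 = male, 2 = female.
SEX_CODE = MappingProxyType({"male": 1, "female": 2})

#: Published multiple-regression models for each stiffness index.
#: Keys follow :data:`MODEL_COVARIATES`; values are per-unit coefficients
#: (age and smoking duration in years, pressures in mmHg, risk count 0-5).
PUBLISHED_MODELS = MappingProxyType(
    {
        "beta": MappingProxyType(
            {
                "age": 0.087,
                "sex_code": 1.361,
                "sbp": 0.046,
                "dbp": -0.076,
                "smoking_years": 0.035,
                "n_cmr": 0.124,
                "intercept": 2.099,
            }
        ),
        "ep": MappingProxyType(
            {
                "age": 1.021,
                "sex_code": 22.182,
                "sbp": 1.177,
                "dbp": -0.588,
                "smoking_years": 0.088,
                "n_cmr": 0.668,
                "intercept": -73.246,
            }
        ),
        # The published PWVβ and AC coefficient sets predict implausible
        # central values (e.g. ≈6.8 m/s from the PWVβ intercept + DBP term
        # alone for a normotensive adult) and are therefore never used
        # generatively -- they are kept only for table formatting.
        "pwv_beta": MappingProxyType(
            {
                "age": 0.034,
                "sex_code": 0.502,
                "sbp": 0.014,
                "dbp": 0.067,
                "smoking_years": 0.012,
                "n_cmr": 0.074,
                "intercept": 1.426,
            }
        ),
        "ac": MappingProxyType(
            {
                "age": -0.003,
                "sex_code": -0.124,
                "sbp": 0.006,
                "dbp": 0.005,
                "smoking_years": -0.002,
                "n_cmr": 0.011,
                "intercept": 1.251,
            }
        ),
    }
)

#: Fraction of variance each published model explained in the field data.
PUBLISHED_R2 = 0.65

#: Enrollment flow: percentage of the 1074 enrolled adults excluded, by reason.
ENROLLMENT_TOTAL = 1074
ENROLLMENT_EXCLUSION_PCT = MappingProxyType(
    {
        "recent_cardiac_event_or_stroke": 1.7,
        "statin_use": 0.8,
        "dropout_or_incomplete": 6.0,
    }
)

#: Normal-BP group means of each index in the field study (the contrast baseline).
BP_CONTRAST_BASELINE = MappingProxyType(
    {"beta": 6.62, "ep": 79.25, "pwv_beta": 5.41, "ac": 0.33}
)

#: Published group-mean deltas versus the normal-BP group, by (index, category).
#: Units: β dimensionless, Ep kPa, PWVβ m/s, AC mm²/kPa.
BP_CONTRAST_DELTA = MappingProxyType(
    {
        ("ep", "elevated"): 7.67,
        ("beta", "stage1"): 0.06,
        ("ep", "stage1"): 12.38,
        ("pwv_beta", "stage1"): 0.44,
        ("ac", "stage1"): -0.02,
        ("beta", "stage2"): 0.56,
        ("ep", "stage2"): 33.82,
        ("pwv_beta", "stage2"): 1.03,
        ("ac", "stage2"): -0.04,
        ("beta", "crisis"): 1.05,
        ("ep", "crisis"): 66.78,
        ("pwv_beta", "crisis"): 1.59,
        ("ac", "crisis"): -0.11,
    }
)

#: Number of analyzable subjects per measured BP category in the field study.
BP_CATEGORY_N = MappingProxyType(
    {"normal": 248, "elevated": 112, "stage1": 309, "stage2": 296, "crisis": 18}
)

#: Pooled cohort summaries (mean, SD) of the indices in the field study.
COHORT_INDEX_SUMMARY = MappingProxyType(
    {
        "beta": (7.37, 3.12),
        "ep": (102.82, 46.60),
        "pwv_beta": (6.06, 1.26),
        "ac": (0.58, 0.28),
    }
)

#: Published two-trial group-average relative differences (percent) per index.
PUBLISHED_INDEX_RD_PCT = MappingProxyType(
    {"beta": 20.5, "ep": 22.3, "pwv_beta": 14.1, "ac": 25.1}
)

#: Published quintile cut-points used as odds-ratio thresholds, by (index, sex).
#: Values are quintile floors in index units (Ep kPa, PWVβ m/s).
QUINTILE_CUTPOINTS = MappingProxyType(
    {
        ("ep", "male", "q4"): 93.71,
        ("pwv_beta", "male", "q4"): 6.56,
        ("ep", "female", "q4"): 91.21,
        ("pwv_beta", "female", "q2"): 5.10,
        ("ep", "female", "q5"): 143.50,
        ("pwv_beta", "female", "q5"): 7.31,
    }
)


def published_linear_predictor(
    index_name: str,
    *,
    age: float,
    sex_code: int,
    sbp: float,
    dbp: float,
    smoking_years: float,
    n_cmr: int,
) -> float:
    """Evaluate one published regression model exactly (no noise, no floor)."""
    m = PUBLISHED_MODELS[index_name]
    return (
        m["age"] * age
        + m["sex_code"] * sex_code
        + m["sbp"] * sbp
        + m["dbp"] * dbp
        + m["smoking_years"] * smoking_years
        + m["n_cmr"] * n_cmr
        + m["intercept"]
    )
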