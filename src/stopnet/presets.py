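"""Published summary statistics used to calibrate the synthetic study.

This module freezes the printed population structure of the longitudinal
ADHD-risk cohort the package emulates: the 11-variable Pearson correlation
matrix among the adolescent inhibitory-control outcomes (N2 amplitude,
SSRT), concurrent and childhood ADHD symptom domains, parental ADHD
symptoms and early-childhood effortful control; the marginal means/SDs of
the key outcomes; and standardized path/regression coefficients linking
early precursors to the adolescent N2.

Only the education-N2 correlation (-0.25) is reported for mother's
education; its remaining correlations default to zero — a modelling
choice, not an empirical claim.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .pathmodel import PathModelSpec

__all__ = [
    "STUDY_VARIABLES",
    "study_correlation_matrix",
    "STUDY_MARGINALS",
    "MISSINGNESS_RATES",
    "concurrent_path_model",
    "subscale_path_model",
    "n2_regression_model",
    "ssrt_total_symptoms_model",
]

#: Roster order matches the published correlation table.
STUDY_VARIABLES = (
    "n2",                 # N2 mean amplitude at 17 y (µV; less negative = reduced)
    "ssrt",               # stop-signal reaction time at 17 y (ms)
    "inattention_17",     # concurrent inattention symptoms (T-score)
    "hyperactivity_17",   # concurrent hyperactivity-impulsivity (T-score)
    "inattention_child",  # inattention throughout childhood (standardized composite)
    "hyperactivity_child",
    "father_inattention",
    "father_hyperactivity",
    "mother_inattention",
    "mother_hyperactivity",
    "effortful_control",  # CBQ effortful control at 36 months
)

# Lower triangle of the printed correlation table, row by row.
_LOWER = [
    [0.31],
    [0.14, 0.17],
    [0.17, 0.14, 0.68],
    [0.28, 0.23, 0.50, 0.44],
    [0.20, 0.26, 0.24, 0.40, 0.53],
    [0.25, -0.25, 0.12, 0.00, 0.14, -0.03],
    [0.17, -0.03, 0.01, -0.20, 0.12, 0.01, 0.36],
    [0.20, -0.18, 0.17, 0.10, 0.42, 0.10, 0.37, 0.32],
    [0.21, -0.19, -0.06, 0.02, 0.17, 0.07, 0.23, 0.10, 0.38],
    [-0.32, -0.12, -0.34, -0.38, -0.35, -0.33, 0.00, -0.09, -0.26, -0.20],
]

#: Marginal scalings of variables whose raw units matter downstream.
STUDY_MARGINALS = {
    "n2": (-0.12, 2.06),          # µV
    "ssrt": (159.90, 56.29),      # ms
    "inattention_17": (53.37, 9.28),
    "hyperactivity_17": (58.56, 12.73),
    "father_inattention": (11.31, 5.96),
    "father_hyperactivity": (15.55, 7.59),
    "mother_inattention": (10.67, 5.50),
    "mother_hyperactivity": (12.72, 6.02),
    "effortful_control": (9.64, 1.55),
    "mother_education": (12.80, 1.72),
}

#: Observed MCAR missingness of the early-childhood measures.
MISSINGNESS_RATES = {"father_inattention": 0.03, "effortful_control": 0.10}

#: Education-N2 correlation; all other education correlations default to 0.
EDUCATION_N2_CORRELATION = -0.25


def study_correlation_matrix(include_education: bool = True) -> pd.DataFrame:
    """The study's correlation matrix as a symmetric DataFrame.

    With ``include_education`` a 12th variable, mother's education, is
    appended with its single printed correlation (with N2).
    """
    names = list(STUDY_VARIABLES)
    n = len(names)
    R = np.eye(n)
    for i, row in enumerate(_LOWER, start=1):
        R[i, : len(row)] = row
        R[: len(row), i] = row
    frame = pd.DataFrame(R, index=names, columns=names)
    if include_education:
        frame.loc["mother_education", :] = 0.0
        frame.loc[:, "mother_education"] = 0.0
        frame.loc["mother_education", "mother_education"] = 1.0
        frame.loc["mother_education", "n2"] = EDUCATION_N2_CORRELATION
        frame.loc["n2", "mother_education"] = EDUCATION_N2_CORRELATION
    return frame


def _precursor_model(precursor: str, direct_coef: float) -> tuple[PathModelSpec, pd.DataFrame]:
    """Path model: precursor + paternal inattention -> inattention -> N2,
    with direct precursor/paternal paths to N2 and education as covariate.

    Printed values pin the two direct paths (precursor -> N2 and paternal
    inattention -> N2) and the education-N2 association; the a-paths onto
    inattention symptoms and the residual inattention -> N2 path are set to
    the study's correlation-level values (see methods note).
    """
    arrows = (
        (precursor, "inattention"),
        ("father_inattention", "inattention"),
        (precursor, "n2"),
        ("father_inattention", "n2"),
        ("inattention", "n2"),
        ("mother_education", "n2"),
    )
    coefficients = {
        (precursor, "inattention"): -0.34,
        ("father_inattention", "inattention"): 0.12,
        (precursor, "n2"): direct_coef,
        ("father_inattention", "n2"): 0.35,
        ("inattention", "n2"): 0.15,
        ("mother_education", "n2"): EDUCATION_N2_CORRELATION,
    }
    exog = [precursor, "father_inattention", "mother_education"]
    exog_corr = pd.DataFrame(np.eye(3), index=exog, columns=exog)
    return PathModelSpec(arrows=arrows, coefficients=coefficients), exog_corr


def concurrent_path_model() -> tuple[PathModelSpec, pd.DataFrame]:
    """Concurrent-symptoms model: effortful control and paternal
    inattention predict the adolescent N2 directly (-0.33 and 0.35) and
    indirectly through inattention symptoms."""
    return _precursor_model("effortful_control", -0.33)


def subscale_path_model() -> tuple[PathModelSpec, pd.DataFrame]:
    """Subscale variant: the attentional-focusing subscale replaces the
    effortful-control factor; its direct path to N2 is -0.29."""
    return _precursor_model("attentional_focusing", -0.29)


def n2_regression_model() -> tuple[PathModelSpec, pd.DataFrame]:
    """Linear model behind the hierarchical regression of N2 on mother's
    education (step 1) and the two childhood symptom domains (step 2):
    N2 = 0.31*inattention + 0.00*hyperactivity - 0.25*education + e,
    with r(inattention, hyperactivity) = 0.53 and education orthogonal."""
    arrows = (
        ("inattention_child", "n2"),
        ("hyperactivity_child", "n2"),
        ("mother_education", "n2"),
    )
    coefficients = {
        ("inattention_child", "n2"): 0.31,
        ("hyperactivity_child", "n2"): 0.00,
        ("mother_education", "n2"): -0.25,
    }
    exog = ["inattention_child", "hyperactivity_child", "mother_education"]
    exog_corr = pd.DataFrame(np.eye(3), index=exog, columns=exog)
    exog_corr.loc["inattention_child", "hyperactivity_child"] = 0.53
    exog_corr.loc["hyperactivity_child", "inattention_child"] = 0.53
    return PathModelSpec(arrows=arrows, coefficients=coefficients), exog_corr


def ssrt_total_symptoms_model() -> tuple[PathModelSpec, pd.DataFrame]:
    """Linear model behind the total-symptoms regression on SSRT:
    SSRT = 0.28*total childhood ADHD symptoms - 0.28*education + e,
    predictors orthogonal."""
    arrows = (
        ("adhd_total_child", "ssrt"),
        ("mother_education", "ssrt"),
    )
    coefficients = {
        ("adhd_total_child", "ssrt"): 0.28,
        ("mother_education", "ssrt"): -0.28,
    }
    exog = ["adhd_total_child", "mother_education"]
    exog_corr = pd.DataFrame(np.eye(2), index=exog, columns=exog)
    return PathModelSpec(arrows=arrows, coefficients=coefficients), exog_corr
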