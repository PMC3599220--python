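"""Reference coefficients of the NRP1A fatal-CVD risk models.

These are the published sex-stratified Weibull proportional-hazards estimates
from the Swiss NRP1A cohort (baseline examinations 1977-79, mortality
follow-up to 2008): one model using fasting blood glucose, one using total
cholesterol, both alongside current smoking and systolic blood pressure, with
attained age as the timescale.  They serve two roles here: as ready-made
models for risk charts and external scoring, and as the data-generating truth
for the synthetic-cohort generator.
"""

from __future__ import annotations

from .weibull import WeibullPHModel

#: Glucose-based model: smoking, systolic blood pressure (per mmHg),
#: fasting glucose (per mmol/L).
GLUCOSE_MODEL = WeibullPHModel(
    alpha={"male": -47.7, "female": -58.8},
    shape={"male": 9.9, "female": 12.4},
    beta={"smoking": 0.37, "sbp": 0.01, "glucose": 0.10},
)

#: Cholesterol-based model: smoking, systolic blood pressure (per mmHg),
#: total cholesterol (per mmol/L).
CHOLESTEROL_MODEL = WeibullPHModel(
    alpha={"male": -47.5, "female": -58.5},
    shape={"male": 9.9, "female": 12.5},
    beta={"smoking": 0.34, "sbp": 0.01, "cholesterol": 0.10},
)

#: Published 95% confidence intervals for the same parameters (used by the
#: recovery checks; keys follow the fit's Wald-table naming).
GLUCOSE_MODEL_CI = {
    "alpha_male": (-50.7, -44.4),
    "shape_male": (9.2, 10.6),
    "alpha_female": (-62.7, -54.9),
    "shape_female": (11.5, 13.2),
    "smoking": (0.20, 0.54),
    "sbp": (0.01, 0.02),
    "glucose": (0.06, 0.14),
}

CHOLESTEROL_MODEL_CI = {
    "alpha_male": (-50.7, -44.4),
    "shape_male": (9.2, 10.6),
    "alpha_female": (-62.4, -54.6),
    "shape_female": (11.7, 13.1),
    "smoking": (0.17, 0.51),
    "sbp": (0.01, 0.02),
    "cholesterol": (0.00, 0.20),
}

MODELS = {"glucose": GLUCOSE_MODEL, "cholesterol": CHOLESTEROL_MODEL}
MODEL_CIS = {"glucose": GLUCOSE_MODEL_CI, "cholesterol": CHOLESTEROL_MODEL_CI}
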