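"""Plain-language interpretation templates.

All report wording lives here, in one place, so the phrasing can be audited
and revised without touching any computation.  Templates consume numbers
already present in the report bundle; nothing is recomputed at render time.
"""

FORMULA = "Model formula: {formula}"

SAMPLE = (
    "The model used {n_obs} observations from {n_subjects} individuals"
    "{dropped_clause}."
)
SAMPLE_DROPPED = ", after excluding {n_dropped} rows with missing data"

TREND_UP = (
    "The linear age term is positive ({estimate} per unit of {time}) and its "
    "95% confidence interval excludes zero, so on average {outcome} scores "
    "increase with {time} near the centre of the data."
)
TREND_DOWN = (
    "The linear age term is negative ({estimate} per unit of {time}) and its "
    "95% confidence interval excludes zero, so on average {outcome} scores "
    "decrease with {time} near the centre of the data."
)
TREND_FLAT = (
    "The linear age term ({estimate} per unit of {time}) has a 95% confidence "
    "interval that includes zero, so there is no clear average change in "
    "{outcome} with {time} near the centre of the data."
)
NONLINEAR = (
    "Higher-order age terms ({terms}) are statistically distinguishable from "
    "zero at the 95% level, indicating a non-linear trajectory: the rate of "
    "change itself changes with {time}."
)
LINEAR_OK = (
    "No higher-order age term is statistically distinguishable from zero at "
    "the 95% level; a straight-line summary of the trajectory is not "
    "contradicted by these data."
)

PREDICTION = (
    "The model-predicted {outcome} at {time} {t} is {estimate} "
    "(95% CI {ci_low} to {ci_high})."
)

AUC = (
    "The area under the trajectory between {time} {a} and {b} is {estimate} "
    "(95% CI {ci_low} to {ci_high}); this summarizes the cumulative exposure "
    "to {outcome} over that period."
)

DIFF_CLEAR = (
    "At {time} {t}, the difference in {outcome} between groups "
    "'{level_a}' and '{level_b}' is {estimate} (95% CI {ci_low} to {ci_high}); "
    "the interval excludes zero, so the groups are statistically "
    "distinguishable at the 95% level at this {time}."
)
DIFF_UNCLEAR = (
    "At {time} {t}, the difference in {outcome} between groups "
    "'{level_a}' and '{level_b}' is {estimate} (95% CI {ci_low} to {ci_high}); "
    "the interval includes zero, so there is no clear group difference at "
    "this {time}."
)

AUC_DIFF_CLEAR = (
    "Between {time} {a} and {b}, the difference in area under the curve "
    "between groups '{level_a}' and '{level_b}' is {estimate} "
    "(95% CI {ci_low} to {ci_high}); the interval excludes zero, indicating "
    "a clear difference in cumulative {outcome} between the groups."
)
AUC_DIFF_UNCLEAR = (
    "Between {time} {a} and {b}, the difference in area under the curve "
    "between groups '{level_a}' and '{level_b}' is {estimate} "
    "(95% CI {ci_low} to {ci_high}); the interval includes zero, so there is "
    "no clear difference in cumulative {outcome} between the groups."
)

RANDOM_EFFECTS = (
    "Individuals vary around the average trajectory: the standard deviation "
    "of individual starting levels (random intercept) is {sd_intercept}, and "
    "the residual (occasion-to-occasion) standard deviation is {sd_residual}."
)

DEVIANCE = (
    "Model deviance ({estimator}): {deviance}. Lower deviance indicates "
    "better fit when comparing nested models fitted by ML on the same data."
)

SINGULAR_NOTE = (
    "Note: the random-effect covariance is at the boundary (singular fit); "
    "one or more variance components are effectively zero and the random-"
    "effect structure may be simplified."
)
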