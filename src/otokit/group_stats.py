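"""Cohort statistics for the 2x2 age x sex design.

Implements the statistical pathway applied to every otolith measurement:
a normality screen (Shapiro-Wilk plus Kolmogorov-Smirnov), a two-way ANOVA
with interaction (Type III sums of squares with sum-to-zero contrasts, the
SPSS convention, so unbalanced cells are handled), a Bonferroni-corrected
post-hoc comparison of the four cells when an interaction is present, and
the ordinary-least-squares regression used to cross-validate μCT areas
against tissue-section areas.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .types import DegenerateInputError, ParameterError

ALPHA = 0.05  # significance level used throughout the study design

CELLS = [
    ("young", "female"),
    ("young", "male"),
    ("old", "female"),
    ("old", "male"),
]

#: the four contrasts conventionally reported: within-age sex differences and
#: within-sex age differences (the two "diagonal" pairs are omitted)
REPORTED_CONTRASTS = [
    (("young", "male"), ("young", "female")),
    (("old", "male"), ("old", "female")),
    (("young", "male"), ("old", "male")),
    (("young", "female"), ("old", "female")),
]


@dataclass(frozen=True)
class NormalityResult:
    shapiro_p: float
    ks_p: float
    passed: bool


@dataclass(frozen=True)
class AnovaResult:
    """F and p per effect of the two-way design."""

    f: dict[str, float]  # keys: age, sex, interaction
    p: dict[str, float]
    n: int
    df_resid: float

    @property
    def interaction_significant(self) -> bool:
        return self.p["interaction"] < ALPHA


def normality_screen(values: np.ndarray) -> NormalityResult:
    """Shapiro-Wilk and Kolmogorov-Smirnov normality screen.

    The KS test compares against a normal with the sample mean and sd. The
    screen passes when both p-values are >= 0.05; a failure is reported (and
    warned about downstream), not fatal, since the parametric path is still
    run.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or len(values) < 3:
        raise ParameterError("normality screen needs a 1D sample with n >= 3")
    sw = stats.shapiro(values)
    sd = values.std(ddof=1)
    if sd == 0:
        return NormalityResult(shapiro_p=float(sw.pvalue), ks_p=0.0, passed=False)
    ks = stats.kstest(values, "norm", args=(values.mean(), sd))
    passed = bool(sw.pvalue >= ALPHA and ks.pvalue >= ALPHA)
    return NormalityResult(shapiro_p=float(sw.pvalue), ks_p=float(ks.pvalue), passed=passed)


def _measurement_frame(table: pd.DataFrame, measurement: str) -> pd.DataFrame:
    df = table[table["measurement"] == measurement]
    if df.empty:
        raise ParameterError(f"no records for measurement {measurement!r}")
    if not np.all(np.isfinite(df["value"])):
        raise ParameterError("measurement values must be finite")
    return df


def two_way_anova(table: pd.DataFrame, measurement: str, typ: int = 3) -> AnovaResult:
    """Two-way age x sex ANOVA with interaction for one measurement.

    Expects a long-format cohort table with columns age_group, sex,
    measurement, value. Both factors must have both levels present. Type III
    sums of squares with sum-to-zero contrasts by default (Type II by flag).
    """
    df = _measurement_frame(table, measurement)
    for factor, levels in (("age_group", ("young", "old")), ("sex", ("female", "male"))):
        present = set(df[factor].unique())
        missing = set(levels) - present
        if missing:
            raise DegenerateInputError(f"factor {factor} is missing level(s) {sorted(missing)}")
    if typ not in (2, 3):
        raise ParameterError("typ must be 2 or 3")
    model = smf.ols(
        "value ~ C(age_group, Sum) * C(sex, Sum)", data=df
    ).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # statsmodels emits noisy df warnings
        aov = sm.stats.anova_lm(model, typ=typ)
    rows = {
        "age": "C(age_group, Sum)",
        "sex": "C(sex, Sum)",
        "interaction": "C(age_group, Sum):C(sex, Sum)",
    }
    f = {k: float(aov.loc[v, "F"]) for k, v in rows.items()}
    p = {k: float(aov.loc[v, "PR(>F)"]) for k, v in rows.items()}
    return AnovaResult(f=f, p=p, n=len(df), df_resid=float(model.df_resid))


def bonferroni_posthoc(
    table: pd.DataFrame, measurement: str, family: int = 6
) -> pd.DataFrame:
    """Bonferroni-corrected pairwise t-tests among the four cells.

    ``family`` selects the correction family: 6 compares all pairs of the
    four cells; 4 restricts to the conventionally reported contrasts
    (within-age sex and within-sex age differences). Adjusted p-values are
    min(1, m x raw p). Rows for the reported contrasts are flagged.
    """
    if family not in (4, 6):
        raise ParameterError("family must be 4 (reported contrasts) or 6 (all pairs)")
    df = _measurement_frame(table, measurement)
    samples = {}
    for age, sex in CELLS:
        cell = df[(df["age_group"] == age) & (df["sex"] == sex)]["value"].to_numpy()
        if len(cell) < 2:
            raise DegenerateInputError(f"cell ({age}, {sex}) has fewer than 2 records")
        samples[(age, sex)] = cell
    pairs = (
        REPORTED_CONTRASTS if family == 4 else list(combinations(CELLS, 2))
    )
    m = len(pairs)
    rows = []
    for a, b in pairs:
        res = stats.ttest_ind(samples[a], samples[b])
        raw = float(res.pvalue)
        rows.append(
            {
                "cell_a": f"{a[0]} {a[1]}",
                "cell_b": f"{b[0]} {b[1]}",
                "t": float(res.statistic),
                "p_raw": raw,
                "p_adj": min(1.0, m * raw),
                "reported_contrast": (a, b) in REPORTED_CONTRASTS
                or (b, a) in REPORTED_CONTRASTS,
            }
        )
    return pd.DataFrame(rows)


def area_regression(areas: pd.DataFrame) -> dict:
    """OLS regression of μCT slice areas on tissue-section areas.

    ``areas`` needs columns tissue_area_um2 (explanatory) and ct_area_um2
    (response). Returns slope, intercept, r2 and the slope-test p-value.
    """
    x = np.asarray(areas["tissue_area_um2"], dtype=float)
    y = np.asarray(areas["ct_area_um2"], dtype=float)
    if len(x) < 3:
        raise ParameterError("area regression needs at least 3 paired slices")
    if np.ptp(x) == 0:
        raise DegenerateInputError("tissue areas are constant; slope undefined")
    res = stats.linregress(x, y)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r2": float(res.rvalue**2),
        "p": float(res.pvalue),
        "n": int(len(x)),
    }


def analyze_measurement(
    table: pd.DataFrame,
    measurement: str,
    posthoc: str = "auto",
    family: int = 6,
) -> dict:
    """Full statistical pathway for one measurement.

    Normality screen (warn on failure), two-way ANOVA, and — following the
    study design — the Bonferroni post-hoc when the interaction is
    significant (``posthoc='auto'``), always, or never.
    """
    if posthoc not in ("auto", "always", "never"):
        raise ParameterError("posthoc must be auto, always or never")
    df = _measurement_frame(table, measurement)
    normality = normality_screen(df["value"].to_numpy())
    if not normality.passed:
        warnings.warn(
            f"measurement {measurement!r} failed the normality screen "
            f"(shapiro p={normality.shapiro_p:.3g}, ks p={normality.ks_p:.3g}); "
            "proceeding with the parametric pathway",
            stacklevel=2,
        )
    anova = two_way_anova(table, measurement)
    run_posthoc = posthoc == "always" or (posthoc == "auto" and anova.interaction_significant)
    posthoc_table = bonferroni_posthoc(table, measurement, family) if run_posthoc else None
    return {"normality": normality, "anova": anova, "posthoc": posthoc_table}
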