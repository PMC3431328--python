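"""Gene-by-treatment stage: baseline-adjusted one-year models.

The pooled interaction model, per trait (on the analysis scale — natural
log except raw LDL-C, for the one-year value and its baseline alike):

    y1 ~ y0 + GRS + I(metformin) + I(lifestyle)
            + GRS x I(metformin) + GRS x I(lifestyle)
            + age + sex + ethnicity

with placebo as the reference arm, so each product term's Wald test asks
whether the per-allele score effect on the baseline-adjusted one-year
value differs between that arm and placebo.  BMI is deliberately not a
covariate here (the one-year models condition on the baseline trait
instead); a switch adds it back.  Arm-stratified per-allele effects are
computed by refitting within each arm separately rather than by combining
pooled-model coefficients — both agree in expectation, but the stratified
fit lets each arm carry its own covariate adjustments and residual
variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .containers import CohortTable
from .regress import build_design, fit_ols, ls_means, nested_f_test
from .traits import ARMS, LN, baseline_col, trait_scale, year1_col

_NUMERIC = ["age"]
_FACTORS = ["sex", "ethnicity"]

#: non-reference arms, in model order
_TREAT_ARMS = ("metformin", "lifestyle")


@dataclass
class ArmEffect:
    beta: float
    se: float
    p: float
    n: int


@dataclass
class InteractionResult:
    """Per-trait gene-by-treatment results."""

    trait: str
    scale: str
    #: product-term estimates vs placebo, keyed "metformin"/"lifestyle"
    interactions: Dict[str, ArmEffect]
    #: pooled-model GRS main effect (the placebo-arm slope)
    grs_main: Optional[ArmEffect] = None
    #: per-arm residual score effects from stratified refits
    arm_effects: Dict[str, ArmEffect] = field(default_factory=dict)
    #: joint 2-df F p-value for both product terms (optional extra)
    p_joint: Optional[float] = None
    n: int = 0
    covariates: Tuple[str, ...] = ("baseline", "age", "sex", "ethnicity")


def _year1_frame(
    cohort: CohortTable, scores: pd.Series, trait: str, include_bmi: bool
):
    y1c, y0c = year1_col(trait), baseline_col(trait)
    for c in (y1c, y0c):
        if c not in cohort.data.columns:
            raise ValueError(f"cohort lacks column {c!r}")
    keep = ["age", "sex", "ethnicity", "arm", y0c, y1c] + (
        ["bmi"] if include_bmi else []
    )
    df = cohort.data[keep].copy()
    scale = trait_scale(trait)
    if scale == LN:
        df["_y1"] = np.log(df.pop(y1c).astype(float))
        df["_y0"] = np.log(df.pop(y0c).astype(float))
    else:
        df["_y1"] = df.pop(y1c).astype(float)
        df["_y0"] = df.pop(y0c).astype(float)
    df["_grs"] = scores.reindex(df.index).astype(float)
    df = df.dropna()
    if df.empty:
        raise ValueError(f"no complete cases for trait {trait!r}")
    return df, scale


def fit_interaction_model(
    cohort: CohortTable,
    scores: pd.Series,
    trait: str,
    include_bmi: bool = False,
    joint_test: bool = False,
) -> InteractionResult:
    """Pooled one-year model with score-by-arm product terms.

    Requires all three arms to be present (the interaction contrasts are
    against placebo).  Returns Wald estimates for the two product terms;
    with ``joint_test`` also the 2-df F p-value for dropping both.
    """
    df, scale = _year1_frame(cohort, scores, trait, include_bmi)
    present = set(df["arm"])
    absent = [a for a in ARMS if a not in present]
    if absent:
        raise ValueError(f"arm(s) missing from cohort: {absent}")
    numeric = ["_y0", "_grs", *_NUMERIC] + (["bmi"] if include_bmi else [])
    X = build_design(
        df,
        numeric=numeric,
        factors=["arm", *_FACTORS],
        interactions=[("_grs", "arm")],
    )
    fit = fit_ols(X, df["_y1"])
    inter = {}
    for arm in _TREAT_ARMS:
        term = fit[f"_grs:arm[{arm}]"]
        inter[arm] = ArmEffect(
            beta=term["beta"], se=term["se"], p=term["p"],
            n=int((df["arm"] == arm).sum()),
        )
    p_joint = None
    if joint_test:
        X_red = X.drop(columns=[f"_grs:arm[{a}]" for a in _TREAT_ARMS])
        _, p_joint = nested_f_test(fit, fit_ols(X_red, df["_y1"]))
    covs = ("baseline", "age", "sex", "ethnicity") + (
        ("bmi",) if include_bmi else ()
    )
    main = fit["_grs"]
    return InteractionResult(
        trait=trait,
        scale=scale,
        interactions=inter,
        grs_main=ArmEffect(
            beta=main["beta"], se=main["se"], p=main["p"],
            n=int((df["arm"] == "placebo").sum()),
        ),
        p_joint=p_joint,
        n=len(df),
        covariates=covs,
    )


def arm_stratified_effects(
    cohort: CohortTable,
    scores: pd.Series,
    trait: str,
    include_bmi: bool = False,
) -> Dict[str, ArmEffect]:
    """Residual per-allele score effect within each arm separately:
    y1 ~ y0 + GRS + age + sex + ethnicity, fit per arm."""
    df, _ = _year1_frame(cohort, scores, trait, include_bmi)
    numeric = ["_y0", "_grs", *_NUMERIC] + (["bmi"] if include_bmi else [])
    out: Dict[str, ArmEffect] = {}
    for arm in ARMS:
        sub = df[df["arm"] == arm]
        X = build_design(sub, numeric=numeric, factors=_FACTORS)
        if len(sub) <= X.shape[1]:
            raise ValueError(
                f"arm {arm!r} stratum too small ({len(sub)} individuals, "
                f"{X.shape[1]} terms)"
            )
        fit = fit_ols(X, sub["_y1"])
        term = fit["_grs"]
        out[arm] = ArmEffect(
            beta=term["beta"], se=term["se"], p=term["p"], n=len(sub)
        )
    return out


def analyze_interactions(
    cohort: CohortTable,
    scores: pd.Series,
    trait: str,
    include_bmi: bool = False,
    joint_test: bool = False,
) -> InteractionResult:
    """Pooled interaction model plus arm-stratified refits, in one result."""
    res = fit_interaction_model(
        cohort, scores, trait, include_bmi=include_bmi, joint_test=joint_test
    )
    res.arm_effects = arm_stratified_effects(
        cohort, scores, trait, include_bmi=include_bmi
    )
    return res


def median_split_summary(
    cohort: CohortTable,
    split: pd.Series,
    trait: str,
) -> pd.DataFrame:
    """Ethnicity-adjusted means for the 12 arm x score-stratum x timepoint
    cells of one trait.

    Means are arithmetic for LDL-C and geometric otherwise, adjusted for
    ethnicity only (the display convention for trajectory plots), with the
    upper 95% confidence bound.  Returns a tidy frame with columns arm,
    grs_stratum, timepoint, mean, ci_high, n.  An empty cell is an error.
    """
    scale = trait_scale(trait)
    rows = []
    for timepoint, col in (("baseline", baseline_col(trait)),
                           ("year1", year1_col(trait))):
        if col not in cohort.data.columns:
            raise ValueError(f"cohort lacks column {col!r}")
        df = cohort.data[["arm", "ethnicity", col]].copy()
        df["_split"] = split.reindex(df.index)
        df["_y"] = (
            np.log(df.pop(col).astype(float)) if scale == LN
            else df.pop(col).astype(float)
        )
        df = df.dropna()
        for arm in ARMS:
            sub = df[df["arm"] == arm]
            for stratum in ("low", "high"):
                if (sub["_split"] == stratum).sum() == 0:
                    raise ValueError(
                        f"empty cell: arm={arm}, stratum={stratum}, "
                        f"timepoint={timepoint}"
                    )
            means = ls_means(
                sub,
                response="_y",
                factor="_split",
                other_factors=["ethnicity"],
                scale="ln" if scale == LN else "raw",
            )
            for stratum in ("low", "high"):
                rows.append(
                    {
                        "arm": arm,
                        "grs_stratum": stratum,
                        "timepoint": timepoint,
                        "mean": means.table.loc[stratum, "mean"],
                        "ci_high": means.table.loc[stratum, "ci_high"],
                        "n": int(means.table.loc[stratum, "n"]),
                    }
                )
    return pd.DataFrame(rows)
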