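"""Synthetic multi-ethnic trial cohorts with known injected effects.

The generator produces the minimal data-generating process the downstream
analysis assumes, with every injected quantity recorded for recovery tests:

* genotypes in Hardy-Weinberg equilibrium within each self-reported
  ethnicity (``Binomial(2, f)`` draws at ethnicity-specific risk-allele
  frequencies), with completely-at-random missing calls;
* log-normal lipid traits — a linear model on the natural-log scale with
  additive per-risk-allele effects and age/sex/ethnicity/BMI covariate
  effects — except LDL-C, modelled linearly in raw mg/dl;
* optional composition mode in which total cholesterol is derived as
  HDL-C + LDL-C + TG/5, so the Friedewald identity holds exactly;
* three trial arms with one-year follow-up values carrying a baseline
  carryover, arm main effects, and per-arm GRS interaction effects.

One root seed drives everything; per-stage child streams are derived
deterministically so identical configs give byte-identical studies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, Mapping, Tuple, Union

import numpy as np
import pandas as pd

from ._util import stage_rng
from .containers import CohortTable, GenotypeMatrix
from .panel import RiskTable, default_allele_freqs, default_panel
from .traits import (
    ARMS,
    ETHNICITIES,
    ETHNICITY_PROPORTIONS,
    LN,
    TRAITS,
    TRAIT_NAMES,
    baseline_col,
    year1_col,
)

EffectSpec = Union[float, Mapping[str, float]]  # scalar or per-rsID

#: floor for raw-scale traits so simulated values stay positive
_RAW_FLOOR = 1.0

_COVARIATE_REFERENCE = {"age": 50.0, "bmi": 33.5}


def _default_per_allele_effects() -> Dict[str, EffectSpec]:
    # Per-risk-allele effects on the analysis scale (ln units except raw
    # mg/dl for LDL-C), applied uniformly across the panel so the risk-score
    # slope equals the per-allele value.  Magnitudes are typical of common
    # lipid variants: ~1 mg/dl LDL-C and a few percent per allele elsewhere.
    return {
        "ldl_c": 1.0,
        "hdl_c": -0.011,
        "tg": 0.026,
        "large_hdl_p": -0.023,
        "small_hdl_p": 0.007,
        "total_hdl_p": -0.0013,
        "hdl_size": -0.0011,
        "ldl_size": -0.0059,
        "total_ldl_p": 0.013,
        "small_ldl_p": 0.037,
        "total_vldl_p": 0.027,
        "large_vldl_p": 0.052,
        "vldl_size": 0.0047,
    }


def _default_covariate_effects() -> Dict[str, Dict]:
    eff: Dict[str, Dict] = {}
    for t in TRAIT_NAMES:
        if t == "chol":
            continue  # derived in composition mode; see simulate_baseline_traits
        if TRAITS[t].scale == LN:
            eff[t] = {"age": 0.002, "sex_male": 0.02, "bmi": 0.004,
                      "ethnicity": {}}
        else:  # raw mg/dl
            eff[t] = {"age": 0.4, "sex_male": 2.0, "bmi": 0.4, "ethnicity": {}}
    # lower TG / higher HDL-C in the African-American stratum, a well-known
    # population difference, keeps the ethnicity adjustment non-trivial
    eff["tg"]["ethnicity"] = {"african_american": -0.15}
    eff["hdl_c"]["ethnicity"] = {"african_american": 0.06}
    return eff


def _default_arm_effects() -> Dict[str, Dict[str, float]]:
    # one-year arm main effects on the analysis scale (placebo = 0):
    # lifestyle improves the profile most, metformin modestly
    return {
        "tg": {"metformin": -0.03, "lifestyle": -0.08},
        "hdl_c": {"metformin": 0.01, "lifestyle": 0.04},
        "ldl_c": {"metformin": -1.0, "lifestyle": -4.0},
        "small_ldl_p": {"metformin": -0.02, "lifestyle": -0.10},
        "large_vldl_p": {"metformin": -0.03, "lifestyle": -0.10},
        "total_vldl_p": {"metformin": -0.02, "lifestyle": -0.06},
    }


def _default_interactions() -> Dict[str, Dict[str, float]]:
    # residual per-allele GRS effect at one year, by arm: the lifestyle
    # intervention is less effective at lowering LDL-C and small LDL
    # particles in individuals carrying more risk alleles
    return {
        "ldl_c": {"lifestyle": 0.87},
        "small_ldl_p": {"lifestyle": 0.030},
    }


@dataclass
class SimConfig:
    """Configuration of a simulated study.  All defaults together define the
    package's reference study conditions; see docs/methods.md."""

    n_individuals: int = 3000
    ethnicity_labels: Tuple[str, ...] = ETHNICITIES
    ethnicity_proportions: Tuple[float, ...] = ETHNICITY_PROPORTIONS
    panel: RiskTable = field(default_factory=default_panel)
    #: rsID x ethnicity risk-allele frequencies
    allele_freqs: pd.DataFrame = None  # filled in __post_init__
    per_allele_effects: Dict[str, EffectSpec] = field(
        default_factory=_default_per_allele_effects
    )
    covariate_effects: Dict[str, Dict] = field(
        default_factory=_default_covariate_effects
    )
    noise_sd: Dict[str, float] = field(
        default_factory=lambda: {t: TRAITS[t].noise_sd for t in TRAIT_NAMES}
    )
    missing_rate: float = 0.033
    med_flag_rate: float = 0.048
    arm_proportions: Tuple[float, ...] = (1 / 3, 1 / 3, 1 / 3)
    baseline_carryover: Dict[str, float] = field(
        default_factory=lambda: {t: 0.6 for t in TRAIT_NAMES}
    )
    arm_effects: Dict[str, Dict[str, float]] = field(
        default_factory=_default_arm_effects
    )
    grs_by_arm_interactions: Dict[str, Dict[str, float]] = field(
        default_factory=_default_interactions
    )
    composition_mode: bool = True
    #: which allele the stored calls count: "risk" (orientation is a no-op),
    #: "other" (every SNP needs flipping), or "random" (seeded per-SNP mix)
    counted_allele_mode: str = "risk"
    seed: int = 0

    def __post_init__(self):
        if self.allele_freqs is None:
            self.allele_freqs = default_allele_freqs(self.panel)
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be positive")
        if len(self.ethnicity_labels) != len(self.ethnicity_proportions):
            raise ValueError("ethnicity labels/proportions length mismatch")
        for name, props in [
            ("ethnicity_proportions", self.ethnicity_proportions),
            ("arm_proportions", self.arm_proportions),
        ]:
            if abs(sum(props) - 1.0) > 1e-12:
                raise ValueError(f"{name} must sum to 1 (got {sum(props)!r})")
            if any(p < 0 for p in props):
                raise ValueError(f"{name} must be non-negative")
        freqs = self.allele_freqs
        if list(freqs.index) != self.panel.rsids:
            raise ValueError("allele_freqs rows must match the panel rsIDs")
        if not set(self.ethnicity_labels) <= set(freqs.columns):
            raise ValueError("allele_freqs missing columns for some ethnicities")
        vals = freqs.to_numpy(dtype=float)
        if np.any(vals < 0) or np.any(vals > 1):
            raise ValueError("allele frequencies must lie in [0, 1]")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must lie in [0, 1)")
        if not (0 <= self.med_flag_rate < 1):
            raise ValueError("med_flag_rate must lie in [0, 1)")
        for t, sd in self.noise_sd.items():
            if sd < 0:
                raise ValueError(f"noise_sd[{t!r}] must be >= 0")
        for t in self.per_allele_effects:
            if t not in TRAIT_NAMES:
                raise ValueError(f"per_allele_effects: unknown trait {t!r}")
            spec = self.per_allele_effects[t]
            if isinstance(spec, Mapping):
                unknown = set(spec) - set(self.panel.rsids)
                if unknown:
                    raise ValueError(
                        f"per_allele_effects[{t!r}]: SNPs not in panel: "
                        f"{sorted(unknown)}"
                    )
        for name, table in [
            ("baseline_carryover", self.baseline_carryover),
            ("arm_effects", self.arm_effects),
            ("grs_by_arm_interactions", self.grs_by_arm_interactions),
        ]:
            for t in table:
                if t not in TRAIT_NAMES:
                    raise ValueError(f"{name}: unknown trait {t!r}")
        for table in (self.arm_effects, self.grs_by_arm_interactions):
            for t, per_arm in table.items():
                unknown = set(per_arm) - set(ARMS)
                if unknown:
                    raise ValueError(
                        f"unknown arm(s) {sorted(unknown)} configured for {t!r}"
                    )
        if self.counted_allele_mode not in ("risk", "other", "random"):
            raise ValueError("counted_allele_mode must be risk/other/random")

    # ------------------------------------------------------------- helpers

    def effect_vector(self, trait: str) -> np.ndarray:
        """Per-SNP effect of one risk allele on `trait` (analysis scale)."""
        spec = self.per_allele_effects.get(trait, 0.0)
        if isinstance(spec, Mapping):
            return np.array([float(spec.get(r, 0.0)) for r in self.panel.rsids])
        return np.full(len(self.panel), float(spec))

    def ids(self) -> list:
        width = len(str(self.n_individuals))
        return [f"I{i:0{width}d}" for i in range(1, self.n_individuals + 1)]


@dataclass
class SimulatedStudy:
    """A simulated study: observed data plus the injected ground truth."""

    genotypes: GenotypeMatrix          # with missing calls, as observed
    cohort: CohortTable                # covariates, arms, baseline + 1-year
    truth: dict                        # injected effects and true scores
    complete_genotypes: GenotypeMatrix  # pre-missingness, for truth only
    config: SimConfig


# ---------------------------------------------------------------------------
# Friedewald calculation
# ---------------------------------------------------------------------------

#: triglyceride ceiling (mg/dl; 4.5 mmol/l) above which calculated LDL-C
#: is unreliable and reported as missing
FRIEDEWALD_TG_LIMIT = 400.0


def friedewald_ldl(tc, hdl, tg):
    """LDL-C by the Friedewald equation: TC - HDL-C - TG/5 (all mg/dl).

    Returns NaN where TG exceeds 400 mg/dl (4.5 mmol/l), the regime where
    the TG/5 VLDL approximation breaks down and direct measurement is
    required.  Inputs must be positive; scalars and arrays both work.
    """
    tc = np.asarray(tc, dtype=float)
    hdl = np.asarray(hdl, dtype=float)
    tg = np.asarray(tg, dtype=float)
    if np.any(tc <= 0) or np.any(hdl <= 0) or np.any(tg <= 0):
        raise ValueError("Friedewald inputs must be positive")
    out = np.where(tg > FRIEDEWALD_TG_LIMIT, np.nan, tc - hdl - tg / 5.0)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Stage 1: covariates and genotypes
# ---------------------------------------------------------------------------

def draw_covariates(config: SimConfig) -> pd.DataFrame:
    """Deterministically draw id, ethnicity, age, sex, bmi for the cohort.

    Shared by the genotype and trait stages so both see the same ethnicity
    assignment without passing state around.  Age ~ N(50, 9) truncated to
    [25, 85], BMI ~ N(33.5, 6) truncated to [20, 60], 32% male.
    """
    rng = stage_rng(config.seed, "covariates")
    n = config.n_individuals
    eth = rng.choice(
        list(config.ethnicity_labels), size=n, p=list(config.ethnicity_proportions)
    )
    age = np.clip(rng.normal(50.0, 9.0, size=n), 25.0, 85.0)
    bmi = np.clip(rng.normal(33.5, 6.0, size=n), 20.0, 60.0)
    sex = np.where(rng.random(n) < 0.32, "M", "F")
    df = pd.DataFrame(
        {"ethnicity": eth, "age": age, "sex": sex, "bmi": bmi},
        index=pd.Index(config.ids(), name="id"),
    )
    present = set(df["ethnicity"])
    for label, prop in zip(config.ethnicity_labels, config.ethnicity_proportions):
        if prop > 0 and label not in present:
            warnings.warn(
                f"ethnicity {label!r} has proportion {prop} but drew no "
                "individuals at this sample size",
                stacklevel=2,
            )
    return df


def simulate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Draw HWE genotypes at ethnicity-specific risk-allele frequencies.

    Within each (SNP, ethnicity) cell, risk-allele counts are
    ``Binomial(2, f)`` — Hardy-Weinberg by construction.  Missing calls are
    then inserted completely at random at ``missing_rate``.  The stored
    codes count the allele selected by ``counted_allele_mode``.
    """
    cov = draw_covariates(config)
    rng = stage_rng(config.seed, "genotypes")
    n, m = config.n_individuals, len(config.panel)
    counts = np.zeros((n, m), dtype=float)
    eth = cov["ethnicity"].to_numpy()
    for label in config.ethnicity_labels:
        mask = eth == label
        if not mask.any():
            continue
        f = config.allele_freqs[label].to_numpy(dtype=float)
        counts[mask, :] = rng.binomial(2, f, size=(int(mask.sum()), m))

    # choose which allele the stored codes count
    flip = np.zeros(m, dtype=bool)
    if config.counted_allele_mode == "other":
        flip[:] = True
    elif config.counted_allele_mode == "random":
        flip = rng.random(m) < 0.5
    calls = np.where(flip[None, :], 2.0 - counts, counts)

    if config.missing_rate > 0:
        miss_rng = stage_rng(config.seed, "missing")
        mask = miss_rng.random((n, m)) < config.missing_rate
        calls = np.where(mask, np.nan, calls)

    alleles = {s.rsid: (s.allele_a, s.allele_b) for s in config.panel}
    counted = {}
    for j, snp in enumerate(config.panel):
        counted[snp.rsid] = snp.other_allele if flip[j] else snp.risk_allele
    calls_df = pd.DataFrame(calls, index=cov.index, columns=config.panel.rsids)
    return GenotypeMatrix(calls=calls_df, alleles=alleles, counted_allele=counted)


def _risk_counts(geno: GenotypeMatrix, config: SimConfig) -> pd.DataFrame:
    """Risk-allele counts with missing entries replaced by their ethnic
    expectation 2f (keeps injected effects well defined on masked input)."""
    cov = draw_covariates(config)
    out = {}
    for snp in config.panel:
        col = geno.calls[snp.rsid].to_numpy(dtype=float)
        if geno.counted_allele[snp.rsid] != snp.risk_allele:
            col = 2.0 - col
        if np.isnan(col).any():
            expect = 2.0 * cov["ethnicity"].map(
                config.allele_freqs.loc[snp.rsid]
            ).to_numpy(dtype=float)
            col = np.where(np.isnan(col), expect, col)
        out[snp.rsid] = col
    return pd.DataFrame(out, index=geno.calls.index)


# ---------------------------------------------------------------------------
# Stage 2: baseline traits
# ---------------------------------------------------------------------------

def simulate_baseline_traits(
    geno: GenotypeMatrix, config: SimConfig
) -> CohortTable:
    """Generate covariates, arms, flags, and baseline trait values.

    On each trait's analysis scale (ln except raw LDL-C):
    ``value = intercept + covariate terms + genetic contribution + noise``,
    where the genetic contribution is the centred sum of per-risk-allele
    effects.  Centring (subtracting the population-expected contribution)
    keeps trait medians at their configured typical values regardless of the
    injected effect sizes.  In composition mode total cholesterol is derived
    as HDL-C + LDL-C + TG/5, so the Friedewald identity holds exactly.
    """
    if list(geno.rsids) != config.panel.rsids:
        raise ValueError("genotype matrix SNPs do not match the config panel")
    cov = draw_covariates(config)
    rng = stage_rng(config.seed, "traits")
    n = len(cov)

    risk = _risk_counts(geno, config).to_numpy(dtype=float)
    # population-expected risk count per SNP, for centring
    pop_freq = config.allele_freqs[list(config.ethnicity_labels)].to_numpy(
        dtype=float
    ) @ np.asarray(config.ethnicity_proportions, dtype=float)
    expected_risk = 2.0 * pop_freq

    age_c = cov["age"].to_numpy() - _COVARIATE_REFERENCE["age"]
    bmi_c = cov["bmi"].to_numpy() - _COVARIATE_REFERENCE["bmi"]
    male = (cov["sex"].to_numpy() == "M").astype(float)
    eth = cov["ethnicity"]

    data = cov[["age", "sex", "ethnicity", "bmi"]].copy()
    med_rng = stage_rng(config.seed, "medflag")
    data["lipid_med"] = med_rng.random(n) < config.med_flag_rate
    arm_rng = stage_rng(config.seed, "arms")
    data["arm"] = arm_rng.choice(list(ARMS), size=n, p=list(config.arm_proportions))

    values: Dict[str, np.ndarray] = {}
    for t in TRAIT_NAMES:
        if t == "chol" and config.composition_mode:
            continue
        trait = TRAITS[t]
        ceff = config.covariate_effects.get(
            t, {"age": 0.0, "sex_male": 0.0, "bmi": 0.0, "ethnicity": {}}
        )
        eth_off = eth.map(
            lambda e: ceff.get("ethnicity", {}).get(e, 0.0)
        ).to_numpy(dtype=float)
        effects = config.effect_vector(t)
        genetic = (risk - expected_risk[None, :]) @ effects
        y = (
            trait.intercept
            + ceff.get("age", 0.0) * age_c
            + ceff.get("sex_male", 0.0) * male
            + ceff.get("bmi", 0.0) * bmi_c
            + eth_off
            + genetic
            + rng.normal(0.0, config.noise_sd[t], size=n)
        )
        values[t] = np.exp(y) if trait.scale == LN else np.maximum(y, _RAW_FLOOR)

    if config.composition_mode:
        values["chol"] = values["hdl_c"] + values["ldl_c"] + values["tg"] / 5.0

    for t in TRAIT_NAMES:
        data[baseline_col(t)] = values[t]
    return CohortTable(data)


# ---------------------------------------------------------------------------
# Stage 3: one-year follow-up
# ---------------------------------------------------------------------------

def simulate_followup(
    baseline: CohortTable, grs: pd.Series, config: SimConfig
) -> CohortTable:
    """Add one-year trait values to a baseline cohort.

    On the analysis scale, with m the cohort mean at baseline:
    ``y1 = m + rho*(y0 - m) + arm_effect(arm)
    + interaction(arm)*(GRS - mean GRS) + noise``.
    Centring the GRS keeps arm-level means interpretable (the interaction
    tilts the within-arm slope without shifting the arm mean); interaction
    and arm-stratified estimates are unaffected by the centring.  In
    composition mode total cholesterol at one year is again derived from
    its components.
    """
    rng = stage_rng(config.seed, "followup")
    df = baseline.data.copy()
    arm = df["arm"].to_numpy()
    grs = grs.loc[df.index].to_numpy(dtype=float)
    grs_c = grs - grs.mean()
    n = len(df)

    y1_native: Dict[str, np.ndarray] = {}
    for t in TRAIT_NAMES:
        if t == "chol" and config.composition_mode:
            continue
        trait = TRAITS[t]
        y0 = df[baseline_col(t)].to_numpy(dtype=float)
        y0s = np.log(y0) if trait.scale == LN else y0
        rho = config.baseline_carryover.get(t, 0.0)
        arm_eff = np.array(
            [config.arm_effects.get(t, {}).get(a, 0.0) for a in arm]
        )
        inter = np.array(
            [config.grs_by_arm_interactions.get(t, {}).get(a, 0.0) for a in arm]
        )
        m = y0s.mean()
        y1 = (
            m
            + rho * (y0s - m)
            + arm_eff
            + inter * grs_c
            + rng.normal(0.0, config.noise_sd[t], size=n)
        )
        y1_native[t] = (
            np.exp(y1) if trait.scale == LN else np.maximum(y1, _RAW_FLOOR)
        )

    if config.composition_mode:
        y1_native["chol"] = (
            y1_native["hdl_c"] + y1_native["ldl_c"] + y1_native["tg"] / 5.0
        )
    for t in TRAIT_NAMES:
        df[year1_col(t)] = y1_native[t]
    return CohortTable(df)


# ---------------------------------------------------------------------------
# Full study
# ---------------------------------------------------------------------------

def simulate_study(config: SimConfig) -> SimulatedStudy:
    """Run all stages and package observed data with the injected truth.

    One-year values are generated from the *true* (complete-data) risk
    score, so recovery tests measure the analysis pipeline — including its
    imputation step — against an exactly known target.
    """
    observed = simulate_genotypes(config)

    # reconstruct the complete (pre-missingness) matrix by re-running the
    # genotype stage without masking: same streams, so calls agree wherever
    # the observed matrix is non-missing
    complete = simulate_genotypes(replace(config, missing_rate=0.0))

    cohort = simulate_baseline_traits(complete, config)
    true_risk = _risk_counts(complete, config)
    true_grs = true_risk.sum(axis=1)
    cohort = simulate_followup(cohort, true_grs, config)

    truth = {
        "per_allele_effects": {
            t: (dict(v) if isinstance(v, Mapping) else v)
            for t, v in config.per_allele_effects.items()
        },
        "covariate_effects": config.covariate_effects,
        "arm_effects": config.arm_effects,
        "grs_by_arm_interactions": config.grs_by_arm_interactions,
        "baseline_carryover": dict(config.baseline_carryover),
        "noise_sd": dict(config.noise_sd),
        "missing_rate": config.missing_rate,
        "med_flag_rate": config.med_flag_rate,
        "seed": config.seed,
        "true_grs": true_grs,
    }
    return SimulatedStudy(
        genotypes=observed,
        cohort=cohort,
        truth=truth,
        complete_genotypes=complete,
        config=config,
    )
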