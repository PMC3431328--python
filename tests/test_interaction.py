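"""Gene-by-treatment stage: pooled product-term model, arm-stratified
refits, and the median-split cell summaries."""

import numpy as np
import pandas as pd
import pytest

from lipidgrs import (
    SimConfig,
    analyze_interactions,
    arm_stratified_effects,
    fit_interaction_model,
    median_split_summary,
    score_cohort,
    simulate_study,
)
from lipidgrs.traits import TRAIT_NAMES
from tests.conftest import make_cohort


@pytest.fixture(scope="module")
def interaction_study():
    """n=3000 study with a 0.9 mg/dl/allele lifestyle interaction on LDL-C."""
    cfg = SimConfig(
        n_individuals=3000,
        per_allele_effects={"tg": 0.026, "ldl_c": 1.0},
        grs_by_arm_interactions={"ldl_c": {"lifestyle": 0.9}},
        seed=1234,
    )
    study = simulate_study(cfg)
    scores = score_cohort(
        study.genotypes, cfg.panel, study.cohort.data["ethnicity"]
    )
    return study, scores.grs, scores.scores["median_split"]


class TestInteractionModel:
    def test_recovers_injected_lifestyle_interaction(self, interaction_study):
        study, grs, _ = interaction_study
        res = fit_interaction_model(study.cohort, grs, "ldl_c")
        ils = res.interactions["lifestyle"]
        met = res.interactions["metformin"]
        assert ils.beta == pytest.approx(0.9, abs=3 * ils.se)
        assert met.beta == pytest.approx(0.0, abs=3 * met.se)

    def test_missing_arm_is_error(self):
        cohort = make_cohort(
            60, trait_values={"ldl_c_bl": 120.0, "ldl_c_y1": 115.0},
            arm="placebo",
        )
        grs = pd.Series(
            np.random.default_rng(0).binomial(64, 0.5, 60).astype(float),
            index=cohort.data.index,
        )
        with pytest.raises(ValueError, match="metformin.*lifestyle"):
            fit_interaction_model(cohort, grs, "ldl_c")

    def test_grs_shift_leaves_interactions_unchanged(self, interaction_study):
        study, grs, _ = interaction_study
        a = fit_interaction_model(study.cohort, grs, "ldl_c")
        b = fit_interaction_model(study.cohort, grs + 17.0, "ldl_c")
        for arm in ("lifestyle", "metformin"):
            assert a.interactions[arm].beta == pytest.approx(
                b.interactions[arm].beta, abs=1e-8
            )
            assert a.interactions[arm].se == pytest.approx(
                b.interactions[arm].se, rel=1e-8
            )

    def test_joint_test_available(self, interaction_study):
        study, grs, _ = interaction_study
        res = fit_interaction_model(study.cohort, grs, "ldl_c", joint_test=True)
        assert 0 <= res.p_joint <= 1
        null = fit_interaction_model(study.cohort, grs, "hdl_c", joint_test=True)
        assert 0 <= null.p_joint <= 1

    def test_bmi_switch_changes_covariate_record(self, interaction_study):
        study, grs, _ = interaction_study
        res = fit_interaction_model(study.cohort, grs, "ldl_c", include_bmi=True)
        assert "bmi" in res.covariates


class TestArmStratified:
    def test_full_carryover_zero_noise_gives_zero_effect(self):
        cfg = SimConfig(
            n_individuals=300,
            baseline_carryover={t: 1.0 for t in TRAIT_NAMES},
            arm_effects={},
            grs_by_arm_interactions={},
            noise_sd={t: 0.0 for t in TRAIT_NAMES},
            missing_rate=0.0,
            seed=5,
        )
        study = simulate_study(cfg)
        grs = study.truth["true_grs"]
        effects = arm_stratified_effects(study.cohort, grs, "ldl_c")
        for arm, eff in effects.items():
            assert eff.beta == pytest.approx(0.0, abs=1e-8)

    def test_lifestyle_effect_recovered_per_arm(self, interaction_study):
        study, grs, _ = interaction_study
        effects = arm_stratified_effects(study.cohort, grs, "ldl_c")
        ils, pla = effects["lifestyle"], effects["placebo"]
        assert ils.beta == pytest.approx(0.9, abs=3 * ils.se)
        assert pla.beta == pytest.approx(0.0, abs=3 * pla.se)
        assert sum(e.n for e in effects.values()) == len(study.cohort)

    def test_stratified_agrees_with_pooled_implied_effects(self):
        # without interactions, per-arm slope ~ pooled GRS + product term
        cfg = SimConfig(
            n_individuals=4000,
            per_allele_effects={"ldl_c": 1.0},
            grs_by_arm_interactions={},
            seed=77,
        )
        study = simulate_study(cfg)
        grs = study.truth["true_grs"]
        res = analyze_interactions(study.cohort, grs, "ldl_c")
        for arm in ("placebo", "metformin", "lifestyle"):
            strat = res.arm_effects[arm]
            implied = res.grs_main.beta
            implied_se = res.grs_main.se
            if arm != "placebo":
                implied += res.interactions[arm].beta
                implied_se = res.interactions[arm].se
            assert strat.beta == pytest.approx(
                implied, abs=4 * np.hypot(strat.se, implied_se)
            )
            # with the baseline in the model and no injected interaction the
            # residual per-allele slope is null in every arm
            assert strat.beta == pytest.approx(0.0, abs=4 * strat.se)

    def test_small_stratum_is_error(self):
        rng = np.random.default_rng(1)
        cohort = make_cohort(
            12,
            trait_values={
                "ldl_c_bl": rng.normal(120, 10, 12),
                "ldl_c_y1": rng.normal(115, 10, 12),
            },
            arm=np.array(["placebo", "metformin", "lifestyle"] * 4),
        )
        grs = pd.Series(np.arange(12, dtype=float), index=cohort.data.index)
        with pytest.raises(ValueError, match="too small"):
            arm_stratified_effects(cohort, grs, "ldl_c")


class TestMedianSplitSummary:
    def test_constant_trait_constant_cells(self):
        cohort = make_cohort(
            120, trait_values={"ldl_c_bl": 120.0, "ldl_c_y1": 120.0},
            arm=np.array(["placebo", "metformin", "lifestyle"] * 40),
        )
        split = pd.Series(
            ["low", "high"] * 60, index=cohort.data.index
        )
        cells = median_split_summary(cohort, split, "ldl_c")
        assert len(cells) == 12
        assert np.allclose(cells["mean"], 120.0, rtol=1e-9)

    def test_single_ethnicity_cells_equal_group_means(self):
        # with one ethnicity the adjustment is inert: cells are plain means
        rng = np.random.default_rng(3)
        n = 240
        arm = np.array(["placebo", "metformin", "lifestyle"] * (n // 3))
        y0 = rng.normal(120, 10, n)
        y1 = rng.normal(115, 10, n)
        cohort = make_cohort(
            n, trait_values={"ldl_c_bl": y0, "ldl_c_y1": y1}, arm=arm
        )
        split = pd.Series(
            rng.choice(["low", "high"], n), index=cohort.data.index
        )
        cells = median_split_summary(cohort, split, "ldl_c").set_index(
            ["arm", "grs_stratum", "timepoint"]
        )
        df = cohort.data.assign(split=split)
        for (a, s), sub in df.groupby(["arm", "split"]):
            assert cells.loc[(a, s, "baseline"), "mean"] == pytest.approx(
                sub["ldl_c_bl"].mean(), abs=1e-9
            )
            assert cells.loc[(a, s, "year1"), "mean"] == pytest.approx(
                sub["ldl_c_y1"].mean(), abs=1e-9
            )

    def test_empty_cell_is_error(self):
        cohort = make_cohort(
            30, trait_values={"ldl_c_bl": 120.0, "ldl_c_y1": 115.0},
            arm=np.array(["placebo", "metformin", "lifestyle"] * 10),
        )
        split = pd.Series("low", index=cohort.data.index)
        with pytest.raises(ValueError, match="empty cell"):
            median_split_summary(cohort, split, "ldl_c")

    def test_high_stratum_elevated_at_one_year_under_interaction(
        self, interaction_study
    ):
        study, _, split = interaction_study
        cells = median_split_summary(study.cohort, split, "ldl_c").set_index(
            ["arm", "grs_stratum", "timepoint"]
        )
        gap_ils = (
            cells.loc[("lifestyle", "high", "year1"), "mean"]
            - cells.loc[("lifestyle", "low", "year1"), "mean"]
        )
        gap_pla = (
            cells.loc[("placebo", "high", "year1"), "mean"]
            - cells.loc[("placebo", "low", "year1"), "mean"]
        )
        # the injected lifestyle-arm interaction widens the high-low gap
        assert gap_ils > gap_pla
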