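"""Association follow-ups: interaction test, sex-stratified re-tests and
partial correlation (with an independent pingouin cross-check)."""

import numpy as np
import pandas as pd
import pytest

from connectome_nbs import (
    CohortDesign,
    GroundTruth,
    SimulationConfig,
    default_planted_edges,
    interaction_test,
    partial_correlation,
    sex_matched_retest,
    simulate_cohort,
    subnetwork_mean_connectivity,
)
from connectome_nbs.nbs import NBSComponent
from conftest import make_design, random_functional_matrices


def scores_frame(design, values):
    return pd.DataFrame({"subject_id": design.subject_ids,
                         "score": np.asarray(values, float),
                         "modality": "functional"})


class TestInteraction:
    def test_empty_cell_rejected_with_cell_named(self):
        design = make_design(10, seed=1, male_frac=(1.0, 0.5))
        rng = np.random.default_rng(2)
        scores = scores_frame(design, rng.standard_normal(len(design)))
        with pytest.raises(ValueError, match=r"\('H', 'F'\)"):
            interaction_test(scores, design)

    def test_planted_sex_specific_effect_detected(self):
        design = make_design(40, seed=3)
        t = design.table
        rng = np.random.default_rng(4)
        effect = ((t["group"] == "L") & (t["sex"] == "M")).to_numpy(float)
        scores = scores_frame(design,
                              effect * 1.0 + rng.standard_normal(len(t)) * 0.3)
        res = interaction_test(scores, design)
        assert res.stat_name == "F"
        assert res.p < 0.01
        assert res.n == len(t)

    def test_no_effect_gives_large_p_on_fixed_seed(self):
        design = make_design(40, seed=5)
        rng = np.random.default_rng(6)
        scores = scores_frame(design, rng.standard_normal(len(design)))
        res = interaction_test(scores, design)
        assert res.p > 0.05


@pytest.fixture(scope="module")
def planted():
    cfg = SimulationConfig(n_subjects_per_group=40, n_nodes=10,
                           n_frames=60, seed=8,
                           sex_imbalance=(0.5, 0.7))
    truth = GroundTruth(planted_edges=default_planted_edges(10, 5),
                        effect_size=0.5)
    _, structurals, design = simulate_cohort(cfg, truth)
    component = NBSComponent(edges=sorted(truth.planted_edges),
                             direction_summary=1.0)
    return structurals, design, component


class TestSexMatchedRetest:
    def test_male_only_on_all_male_cohort_equals_unrestricted(self):
        cfg = SimulationConfig(n_subjects_per_group=25, n_nodes=8,
                               n_frames=60, seed=9, sex_imbalance=(1.0, 1.0))
        truth = GroundTruth(planted_edges=default_planted_edges(8, 4),
                            effect_size=0.4)
        _, structurals, design = simulate_cohort(cfg, truth)
        component = NBSComponent(edges=sorted(truth.planted_edges),
                                 direction_summary=1.0)
        male = sex_matched_retest(structurals, design, component,
                                  strategy="male-only")
        matched = sex_matched_retest(structurals, design, component,
                                     strategy="matched-subsample")
        # every subject is male: nothing to drop under either strategy
        assert male.n == len(design) == matched.n
        assert male.statistic == pytest.approx(matched.statistic)

    def test_matched_subsample_with_equal_ratios_drops_nobody(self):
        cfg = SimulationConfig(n_subjects_per_group=30, n_nodes=8,
                               n_frames=60, seed=10,
                               sex_imbalance=(0.5, 0.5))
        _, structurals, design = simulate_cohort(cfg, GroundTruth.null())
        component = NBSComponent(edges=[(0, 1), (1, 2)],
                                 direction_summary=1.0)
        res = sex_matched_retest(structurals, design, component,
                                 strategy="matched-subsample", seed=1)
        assert res.n == len(design)

    def test_direction_preserved_across_strategies(self, planted):
        structurals, design, component = planted
        signs = []
        for strategy in ("matched-subsample", "male-only", "female-only"):
            res = sex_matched_retest(structurals, design, component,
                                     strategy=strategy, seed=2)
            signs.append(np.sign(res.extra["group_coefficient"]))
            assert res.extra["strategy"] == strategy
        assert len(set(signs)) == 1  # hyperconnectivity in L in every stratum

    def test_too_small_subsample_rejected(self, planted):
        structurals, design, component = planted
        with pytest.raises(ValueError, match="too small"):
            sex_matched_retest(structurals, design, component,
                               strategy="female-only", min_per_group=30)

    def test_unknown_strategy_rejected(self, planted):
        structurals, design, component = planted
        with pytest.raises(ValueError, match="strategy"):
            sex_matched_retest(structurals, design, component,
                               strategy="everyone")


class TestPartialCorrelation:
    def test_no_covariates_equals_plain_pearson(self):
        design = make_design(30, seed=11)
        rng = np.random.default_rng(12)
        x = rng.standard_normal(len(design))
        design.table["erq_reappraisal"] = (
            0.5 * x + rng.standard_normal(len(design)))
        scores = scores_frame(design, x)
        res = partial_correlation(scores, "erq_reappraisal", design,
                                  covariates=())
        plain = np.corrcoef(x, design.table["erq_reappraisal"])[0, 1]
        assert res.r == pytest.approx(plain, abs=1e-12)
        assert res.extra["df"] == len(design) - 2

    def test_shared_age_dependence_partialled_out(self):
        """Two variables driven almost entirely by age decorrelate once age
        is partialled out (residualization oracle)."""
        design = make_design(1000, seed=13)
        rng = np.random.default_rng(130)
        n = len(design)
        age = design.table["age"].to_numpy()
        design.table["erq_reappraisal"] = (
            2.0 * age + 1.0 + 0.05 * rng.standard_normal(n))
        scores = scores_frame(design,
                              -3.0 * age + 5.0 + 0.05 * rng.standard_normal(n))
        raw = np.corrcoef(scores["score"],
                          design.table["erq_reappraisal"])[0, 1]
        assert abs(raw) > 0.99  # strongly coupled before adjustment
        res = partial_correlation(scores, "erq_reappraisal", design,
                                  covariates=("age",))
        assert abs(res.r) < 0.05

    def test_matches_pingouin_oracle(self):
        """Independent cross-check of r and p against pingouin on
        dummy-coded covariates."""
        pingouin = pytest.importorskip("pingouin")
        design = make_design(40, seed=14)
        rng = np.random.default_rng(15)
        n = len(design)
        score = rng.standard_normal(n)
        design.table["srrs"] = 0.4 * score + rng.standard_normal(n)
        scores = scores_frame(design, score)
        res = partial_correlation(scores, "srrs", design,
                                  covariates=("age", "sex", "site"))
        df = design.table.copy()
        df["score"] = score
        df["sex01"] = (df["sex"] == "M").astype(float)
        dummies = pd.get_dummies(df["site"], prefix="site",
                                 drop_first=True).astype(float)
        df = pd.concat([df, dummies], axis=1)
        covs = ["age", "sex01"] + list(dummies.columns)
        oracle = pingouin.partial_corr(data=df, x="score", y="srrs",
                                       covar=covs)
        assert res.r == pytest.approx(float(oracle["r"].iloc[0]), abs=1e-10)
        p_col = "p_val" if "p_val" in oracle.columns else "p-val"
        assert res.p == pytest.approx(float(oracle[p_col].iloc[0]),
                                      abs=1e-10)
        assert res.n == n

    def test_symmetric_in_the_two_variables(self):
        design = make_design(30, seed=16)
        rng = np.random.default_rng(17)
        x = rng.standard_normal(len(design))
        design.table["srrs"] = 0.3 * x + rng.standard_normal(len(design))
        scores = scores_frame(design, x)
        res = partial_correlation(scores, "srrs", design)
        swapped_design = CohortDesign(design.table.assign(srrs=x))
        swapped_scores = scores_frame(design,
                                      design.table["srrs"].to_numpy())
        res2 = partial_correlation(swapped_scores, "srrs", swapped_design)
        assert res.r == pytest.approx(res2.r, abs=1e-12)

    def test_invariant_under_affine_covariate_transform(self):
        design = make_design(30, seed=18)
        rng = np.random.default_rng(19)
        x = rng.standard_normal(len(design))
        design.table["erq_suppression"] = (
            0.3 * x + rng.standard_normal(len(design)))
        scores = scores_frame(design, x)
        r1 = partial_correlation(scores, "erq_suppression", design,
                                 covariates=("age",)).r
        design.table["age"] = 10.0 * design.table["age"] - 7.0
        r2 = partial_correlation(scores, "erq_suppression", design,
                                 covariates=("age",)).r
        assert r1 == pytest.approx(r2, abs=1e-10)

    def test_missing_values_dropped_listwise_with_exact_n(self):
        design = make_design(20, seed=20)
        rng = np.random.default_rng(21)
        design.table["srrs"] = rng.standard_normal(len(design))
        design.table.loc[3, "srrs"] = np.nan
        scores = scores_frame(design, rng.standard_normal(len(design)))
        res = partial_correlation(scores, "srrs", design)
        assert res.n == len(design) - 1
        assert res.extra["n_dropped"] == 1

    def test_generator_loading_recovered_in_sign(self):
        """With a positive behavioral loading the structural sub-network
        connectivity correlates positively with the score."""
        cfg = SimulationConfig(
            n_subjects_per_group=30, n_nodes=10, n_frames=60, seed=22,
            behavioral_loading={"erq_reappraisal": 0.5})
        truth = GroundTruth(planted_edges=default_planted_edges(10, 5),
                            effect_size=0.0)
        _, structurals, design = simulate_cohort(cfg, truth)
        component = NBSComponent(edges=sorted(truth.planted_edges),
                                 direction_summary=1.0)
        scores = subnetwork_mean_connectivity(structurals, component)
        res = partial_correlation(scores, "erq_reappraisal", design)
        assert res.r > 0
        assert res.p < 0.05
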