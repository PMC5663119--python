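import numpy as np
import pytest

from dysregdir import (
    MixtureSpec,
    Scenario,
    compute_differences,
    default_scenarios,
    dip_pvalue,
    dip_statistic,
    generate_study,
)
from dysregdir.classify import Color, Label
from dysregdir.synthetic import FactorSpec, FeaturePlan


class TestMixtureSpec:
    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError):
            MixtureSpec(pi_zero=0.5, pi_null=0.5, pi_down=0.5, pi_up=0.0)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            MixtureSpec(pi_zero=-0.1, pi_null=0.6, pi_down=0.25, pi_up=0.25)

    def test_mu_positive(self):
        with pytest.raises(ValueError):
            MixtureSpec(pi_zero=0.25, pi_null=0.25, pi_down=0.25, pi_up=0.25, mu=0.0)

    def test_implied_labels(self):
        down = MixtureSpec(0.1, 0.2, 0.6, 0.1)
        up = MixtureSpec(0.1, 0.2, 0.1, 0.6)
        flat = MixtureSpec(0.1, 0.2, 0.35, 0.35)
        assert down.implied_label() is Label.DOWN
        assert up.implied_label() is Label.UP
        assert flat.implied_label() is Label.NS

    def test_pooled_weights(self):
        a = MixtureSpec(0.0, 0.0, 1.0, 0.0)
        b = MixtureSpec(0.0, 0.0, 0.0, 1.0)
        mix = a.pooled(b, 0.75, 0.25)
        assert mix.pi_down == pytest.approx(0.75)
        assert mix.pi_up == pytest.approx(0.25)


def _mini_scenario(spec, n=60, factors=None, **kw):
    return Scenario(
        name="mini",
        factors=factors or [FactorSpec("F", 0.5, 0.1)],
        features={"f0": FeaturePlan(spec0=spec)},
        n_subjects_per_site={"proximal": n},
        **kw,
    )


class TestGenerateStudy:
    def test_all_zero_mixture(self):
        spec = MixtureSpec(pi_zero=1.0, pi_null=0.0, pi_down=0.0, pi_up=0.0)
        study, _ = generate_study(_mini_scenario(spec), seed=0)
        assert (study.tumor_signal == 0).all()
        assert (study.normal_signal == 0).all()
        d = compute_differences(study, "proximal").diffs
        assert (d == 0).all()

    def test_seed_determinism(self):
        scen = default_scenarios(n_subjects_per_site=40, sites=("proximal",),
                                 n_planted=2, n_balanced=2, n_null=2)["blue"]
        s1, t1 = generate_study(scen, seed=5)
        s2, t2 = generate_study(scen, seed=5)
        np.testing.assert_array_equal(s1.tumor_signal, s2.tumor_signal)
        np.testing.assert_array_equal(s1.normal_signal, s2.normal_signal)
        assert t1.true_levels.equals(t2.true_levels)

    def test_zero_fraction_matches_pi_zero(self):
        pi_zero = 0.3
        spec = MixtureSpec(pi_zero=pi_zero, pi_null=0.7, pi_down=0.0, pi_up=0.0)
        study, _ = generate_study(_mini_scenario(spec, n=800), seed=2)
        d = compute_differences(study, "proximal").diffs
        frac = (d == 0).mean()
        se = np.sqrt(pi_zero * (1 - pi_zero) / 800)
        assert abs(frac - pi_zero) <= 3 * se

    def test_study_passes_core_invariants(self):
        scen = default_scenarios(n_subjects_per_site=50, sites=("proximal", "distal"),
                                 n_planted=2, n_balanced=3, n_null=3)["orange"]
        study, _ = generate_study(scen, seed=1)
        study.validate()  # raises on violation
        assert (study.tumor_signal >= 0).all()
        assert study.n_subjects == 100

    def test_difference_scale_recovered_without_scaling(self):
        spec = MixtureSpec(0.0, 0.0, 1.0, 0.0, mu=2.0, sigma_mode=0.4)
        scen = _mini_scenario(spec, n=400, scale_sd=0.0)
        study, _ = generate_study(scen, seed=3)
        d = compute_differences(study, "proximal").diffs.ravel()
        assert np.mean(d) == pytest.approx(-2.0, abs=0.1)

    def test_balanced_factor_exact_counts_per_site(self):
        scen = Scenario(
            name="b",
            factors=[FactorSpec("F", 0.3, 0.0, balanced=True)],
            features={"f0": FeaturePlan(spec0=MixtureSpec(0.1, 0.9, 0.0, 0.0))},
            n_subjects_per_site={"proximal": 100, "distal": 60},
        )
        study, truth = generate_study(scen, seed=9)
        lv = truth.true_levels["F"].to_numpy()
        assert lv[:100].sum() == 30
        assert lv[100:].sum() == 18

    def test_missingness_rate(self):
        scen = _mini_scenario(
            MixtureSpec(0.1, 0.9, 0.0, 0.0), n=1000,
            factors=[FactorSpec("F", 0.5, 0.25)],
        )
        study, _ = generate_study(scen, seed=4)
        frac = study.factors["F"].isna().mean()
        assert abs(frac - 0.25) <= 3 * np.sqrt(0.25 * 0.75 / 1000)

    def test_strong_bimodality_detected_by_dip(self):
        spec = MixtureSpec(0.0, 0.2, 0.4, 0.4, mu=2.0, sigma_mode=0.5)
        rejections = 0
        n_rep = 20
        for seed in range(n_rep):
            study, _ = generate_study(_mini_scenario(spec, n=500, scale_sd=0.0), seed=seed)
            d = compute_differences(study, "proximal").diffs.ravel()
            res = dip_pvalue(dip_statistic(d), n=500, B=2000, seed=0)
            rejections += res.p_value < 0.05
        assert rejections / n_rep > 0.95

    def test_invalid_subject_count(self):
        scen = _mini_scenario(MixtureSpec(0.1, 0.9, 0.0, 0.0))
        scen.n_subjects_per_site = {"proximal": 0}
        with pytest.raises(ValueError):
            generate_study(scen, seed=0)


class TestDefaultScenarios:
    def test_expected_structure(self):
        scens = default_scenarios(n_subjects_per_site=30, n_planted=2,
                                  n_balanced=2, n_null=2)
        assert set(scens) == {"null", "balanced", "blue", "green", "orange",
                              "purple", "yellow"}
        for color in ("blue", "green", "orange", "purple", "yellow"):
            assert scens[color].expected_color == color

    def test_implied_truth_colors(self):
        scens = default_scenarios(n_subjects_per_site=30, n_planted=2,
                                  n_balanced=2, n_null=2)
        for name, expected in (
            ("blue", Color.BLUE), ("green", Color.GREEN),
            ("orange", Color.ORANGE), ("yellow", Color.YELLOW),
        ):
            _, truth = generate_study(scens[name], seed=0)
            planted = truth.planted_features()
            assert planted
            for f in planted:
                assert truth.implied.loc[f, "color"] == expected.value

    def test_orange_truth_labels(self):
        scens = default_scenarios(n_subjects_per_site=30, n_planted=1,
                                  n_balanced=1, n_null=1)
        _, truth = generate_study(scens["orange"], seed=0)
        row = truth.implied.loc["plant000"]
        assert (row["overall"], row["level0"], row["level1"]) == ("NS", "Down", "Up")

    def test_null_scenario_has_no_direction(self):
        scens = default_scenarios(n_subjects_per_site=30, n_null=3)
        for plan in scens["null"].features.values():
            assert plan.spec0.pi_down == 0.0
            assert plan.spec0.pi_up == 0.0

    def test_blue_scenario_effect_confined_to_one_level(self):
        scens = default_scenarios(n_subjects_per_site=30, n_planted=1,
                                  n_balanced=1, n_null=1)
        plan = scens["blue"].features["plant000"]
        assert plan.spec0.implied_label() is Label.DOWN
        assert plan.spec1.implied_label() is Label.NS

    def test_truth_tsv_round_trip(self, tmp_path):
        scens = default_scenarios(n_subjects_per_site=30, n_planted=1,
                                  n_balanced=1, n_null=1)
        _, truth = generate_study(scens["yellow"], seed=0)
        path = tmp_path / "truth.tsv"
        truth.write(path)
        assert "plant000" in path.read_text()
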