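"""The synthetic-cohort generator: determinism, calibration, planted truth."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import midkit as mk


def single_class_config(r=0.30, n=5000, missing=0.0, change_sd=10.0):
    """All-stable cohort: the marginal correlation equals the planted one."""
    metric = mk.MetricSim(
        "m", "u", 1, 0.95,
        baseline_mean=100.0, baseline_sd=15.0,
        change_mean=0.0, change_sd=change_sd,
    )
    anchor = mk.AnchorSim(
        "a", threshold=6.0, improvement_sign=-1,
        baseline_mean=30.0, baseline_sd=10.0,
        change_mean=0.0, change_sd=8.0, missing_fraction=missing,
    )
    return mk.SimulationConfig(
        n_patients=n,
        mixture=(0.0, 1.0, 0.0),
        metrics=[metric],
        anchors=[anchor],
        correlations={("m", "a"): r},
        death_prob=(0.0, 0.5, 0.0),
    )


class TestDeterminism:
    def test_same_seed_byte_identical_csv(self, tmp_path, calibrated_config):
        paths = []
        for tag in ("one", "two"):
            cohort, _ = mk.generate_cohort(calibrated_config, seed=42)
            path = tmp_path / f"{tag}.csv"
            cohort.to_csv(path)
            paths.append(path)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_different_seeds_differ(self, calibrated_config):
        one, _ = mk.generate_cohort(calibrated_config, seed=1)
        two, _ = mk.generate_cohort(calibrated_config, seed=2)
        assert not one.data.equals(two.data)


class TestClassStructure:
    def test_class_counts_within_binomial_bounds(self, calibrated_config,
                                                 calibrated_cohort):
        _, truth = calibrated_cohort
        counts = truth.latent_class.value_counts()
        n = calibrated_config.n_patients
        for frac, label in zip(calibrated_config.mixture,
                               ("improved", "stable", "worsened")):
            lo = stats.binom.ppf(0.005, n, frac)
            hi = stats.binom.ppf(0.995, n, frac)
            assert lo <= counts[label] <= hi

    def test_anchor_missingness_near_configured(self, calibrated_config):
        config = mk.paper_calibrated_config(n_patients=20000)
        cohort, _ = mk.generate_cohort(config, seed=3)
        for anchor in config.anchors:
            observed = cohort.complete_mask(anchor.name).mean()
            assert observed == pytest.approx(1 - anchor.missing_fraction, abs=0.02)

    def test_survival_fraction(self):
        config = mk.paper_calibrated_config(n_patients=20000)
        cohort, _ = mk.generate_cohort(config, seed=4)
        death = (cohort.data["survived_1yr"] == 0).mean()
        expected = config.mixture @ config.death_prob  # ~0.10, the registry's rate
        assert death == pytest.approx(expected, abs=0.01)


class TestCalibration:
    def test_planted_marginal_correlation_recovered(self):
        config = single_class_config(r=0.30, n=5000)
        cohort, _ = mk.generate_cohort(config, seed=0)
        changes = cohort.compute_changes("m")["absolute_change"].to_numpy()
        anchor = cohort.anchor_changes(config.anchors[0].definition).to_numpy()
        r = stats.pearsonr(changes, anchor).statistic
        assert r == pytest.approx(0.30, abs=0.03)

    def test_mixture_marginal_correlation_recovered(self, calibrated_config):
        config = mk.paper_calibrated_config(n_patients=50000)
        cohort, _ = mk.generate_cohort(config, seed=1)
        changes = cohort.compute_changes("rvesv").set_index("patient_id")
        anchor = cohort.anchor_changes(config.anchor("e10").definition)
        anchor.index = cohort.data.loc[anchor.index, "patient_id"]
        joined = changes.join(anchor.rename("a"), how="inner")
        r = stats.pearsonr(joined["absolute_change"], joined["a"]).statistic
        assert r == pytest.approx(0.32, abs=0.02)

    def test_icc_recovered_with_independent_oracle(self, calibrated_config):
        import pingouin as pg

        for name in ("rvef", "rvsv"):
            x1, x2 = mk.test_retest_pairs(calibrated_config, name, 5000, seed=0)
            long = pd.DataFrame(
                {
                    "subject": np.repeat(np.arange(5000), 2),
                    "rater": np.tile(["scan", "rescan"], 5000),
                    "score": np.column_stack([x1, x2]).ravel(),
                }
            )
            consistency_icc = pg.intraclass_corr(
                long, targets="subject", raters="rater", ratings="score"
            ).set_index("Type").loc["ICC(C,1)", "ICC"]
            assert consistency_icc == pytest.approx(
                calibrated_config.metric(name).icc, abs=0.02
            )

    def test_infeasible_correlation_rejected_before_sampling(self):
        config = single_class_config(r=0.95, change_sd=6.0)
        with pytest.raises(mk.ConfigError):
            mk.generate_cohort(config, seed=0)

    def test_change_sd_below_measurement_error_rejected(self):
        with pytest.raises(mk.ConfigError, match="change sd too small"):
            config = single_class_config(change_sd=3.0)
            # icc 0.95, baseline sd 15 -> sem*sqrt(2) ~ 4.7 > 3
            mk.generate_cohort(config, seed=0)

    def test_heavy_tail_toggle_keeps_moments(self):
        config = single_class_config(r=0.0, n=40000)
        config.heavy_tail_df = 5.0
        cohort, _ = mk.generate_cohort(config, seed=6)
        changes = cohort.compute_changes("m")["absolute_change"]
        assert changes.std() == pytest.approx(10.0, rel=0.05)
        assert stats.kurtosis(changes) > 0.5  # visibly heavier than Gaussian


class TestPlantedTruth:
    def test_calibrated_config_records_registry_facts(self, calibrated_config):
        config = calibrated_config
        assert config.n_patients == 254
        assert config.metric("rvef").change_mean[0] == pytest.approx(10.0)  # 42 - 32
        assert config.anchor("e10").change_mean[0] == pytest.approx(-16.0)  # 21 - 37
        assert config.anchor("iswt").threshold == 47.5

    def test_truth_frame_contains_both_truths(self, calibrated_cohort):
        _, truth = calibrated_cohort
        frame = truth.to_frame()
        assert {"latent_mean_difference", "true_change_difference",
                "analytic_se", "target_marginal_r"} <= set(frame.columns)
        row = frame.set_index(["metric", "anchor", "direction"]).loc[
            ("rvef", "e10", "improvement")
        ]
        assert row["latent_mean_difference"] == pytest.approx(2.0)

    def test_estimand_matches_brute_force_at_large_n(self):
        """The truncated-normal mixture estimand agrees with an empirical
        change-difference computed on a very large cohort."""
        config = mk.paper_calibrated_config(n_patients=120000)
        cohort, truth = mk.generate_cohort(config, seed=9)
        est = truth.estimands.set_index(["metric", "anchor", "direction"])
        changes = cohort.compute_changes("rvedv").set_index("patient_id")
        anchor_def = config.anchor("e10").definition
        labels = cohort.classify_by_anchor(anchor_def)
        labels.index = cohort.data.loc[labels.index, "patient_id"]
        joined = changes.join(labels.rename("label"), how="inner")
        empirical = (
            joined[joined["label"] == "improved"]["absolute_change"].mean()
            - joined[joined["label"] == "stable"]["absolute_change"].mean()
        )
        analytic = est.loc[("rvedv", "e10", "improvement"), "true_change_difference"]
        assert empirical == pytest.approx(analytic, abs=0.8)

    def test_truth_csv_round_trip(self, tmp_path, calibrated_cohort):
        _, truth = calibrated_cohort
        path = tmp_path / "truth.csv"
        truth.to_csv(path)
        frame = pd.read_csv(path)
        assert len(frame) == len(truth.to_frame())


class TestTomlConfig:
    def test_round_trip_through_toml(self, tmp_path):
        toml_text = """
n_patients = 100
mixture = [0.3, 0.5, 0.2]
death_prob = [0.02, 0.08, 0.3]

[metrics.m]
units = "u"
direction_of_benefit = 1
icc = 0.95
baseline_mean = [100.0, 100.0, 100.0]
baseline_sd = 15.0
change_mean = [5.0, 0.0, -5.0]
change_sd = 10.0

[anchors.a]
threshold = 6.0
improvement_sign = -1
baseline_mean = 30.0
baseline_sd = 10.0
change_mean = [-8.0, 0.0, 8.0]
change_sd = 8.0
missing_fraction = 0.2

[correlations]
"m.a" = -0.25
"""
        path = tmp_path / "sim.toml"
        path.write_text(toml_text)
        config = mk.config_from_toml(path)
        cohort, truth = mk.generate_cohort(config, seed=0)
        assert cohort.n_patients == 100
        assert config.correlations[("m", "a")] == -0.25
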