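"""Unit and property tests for the four MID estimators and the SEM floor."""

import numpy as np
import pandas as pd
import pytest

import midkit as mk
from midkit.definitions import IMPROVED, IMPROVEMENT, STABLE, WORSENED, WORSENING
from midkit.estimators import CHANGE_DIFFERENCE, GLM_REGRESSION


def group_mean_contrast_oracle(changes, labels, contrast, reference):
    """Independent oracle: plain group-mean arithmetic."""
    changes = np.asarray(changes, dtype=float)
    labels = np.asarray(labels, dtype=object)
    return changes[labels == contrast].mean() - changes[labels == reference].mean()


class TestHalfSd:
    def test_hand_computed_sd(self):
        est = mk.half_sd_mid([-4, -2, 0, 2, 4], IMPROVEMENT)
        assert est.value == pytest.approx(0.5 * np.sqrt(10), abs=1e-12)

    def test_sign_convention(self):
        # a volume metric (decrease is benefit): improvement MID negative
        est = mk.half_sd_mid([1, 2, 3], IMPROVEMENT, direction_of_benefit=-1)
        assert est.value < 0
        est = mk.half_sd_mid([1, 2, 3], WORSENING, direction_of_benefit=-1)
        assert est.value > 0

    def test_zero_variance_gives_zero(self):
        assert mk.half_sd_mid([5.0, 5.0, 5.0], IMPROVEMENT).value == 0.0

    def test_scale_equivariance(self):
        base = mk.half_sd_mid([-4, -2, 0, 2, 4], IMPROVEMENT).value
        tripled = mk.half_sd_mid([-12, -6, 0, 6, 12], IMPROVEMENT).value
        assert tripled == pytest.approx(3 * base)

    def test_smallness_error(self):
        with pytest.raises(mk.GroupTooSmallError):
            mk.half_sd_mid([1.0], IMPROVEMENT)


class TestMdc:
    def test_printed_formula(self):
        est = mk.mdc_mid(10.0, 0.96)
        assert est.sem == pytest.approx(2.0)
        assert abs(est.value) == pytest.approx(1.96 * np.sqrt(2) * 2.0)

    def test_perfect_reliability_gives_zero(self):
        assert mk.mdc_mid(10.0, 1.0).value == 0.0

    def test_zero_reliability(self):
        assert abs(mk.mdc_mid(10.0, 0.0).value) == pytest.approx(27.7186, abs=5e-4)

    def test_monotone_in_sd_and_icc(self):
        values = [abs(mk.mdc_mid(sd, 0.9).value) for sd in (5.0, 10.0, 20.0)]
        assert values == sorted(values)
        values = [abs(mk.mdc_mid(10.0, icc).value) for icc in (0.5, 0.8, 0.95)]
        assert values == sorted(values, reverse=True)

    def test_icc_out_of_range(self):
        with pytest.raises(mk.ConfigError):
            mk.mdc_mid(10.0, 1.2)


class TestChangeDifference:
    def test_hand_computed_group_means(self):
        changes = [10, 12, 8, 7, 9, 8]
        labels = [IMPROVED] * 3 + [STABLE] * 3
        est = mk.change_difference_mid(changes, labels, IMPROVEMENT)
        assert est.value == pytest.approx(2.0)
        assert (est.n_improved, est.n_stable, est.n_worsened) == (3, 3, 0)

    def test_worsening_contrast(self):
        changes = [-6, -5, -4, 0, 1, -1]
        labels = [WORSENED] * 3 + [STABLE] * 3
        est = mk.change_difference_mid(changes, labels, WORSENING)
        assert est.value == pytest.approx(-5.0)

    def test_identical_groups_give_zero(self):
        changes = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        labels = [IMPROVED] * 3 + [STABLE] * 3
        assert mk.change_difference_mid(changes, labels, IMPROVEMENT).value == 0.0

    def test_survival_contrast_and_not_defined_improvement(self):
        changes = [-5.0, -3.0, 1.0, 2.0, 0.0]
        labels = ["non_survivor"] * 2 + ["survivor"] * 3
        est = mk.change_difference_mid(changes, labels, WORSENING)
        assert est.value == pytest.approx(-4.0 - 1.0)
        with pytest.raises(mk.NotDefinedError):
            mk.change_difference_mid(changes, labels, IMPROVEMENT)

    def test_singleton_group_errors(self):
        with pytest.raises(mk.GroupTooSmallError):
            mk.change_difference_mid(
                [1.0, 2.0, 3.0], [IMPROVED, STABLE, STABLE], IMPROVEMENT
            )


class TestGlmRegression:
    def test_toy_fit_matches_group_means(self):
        changes = [10, 12, 8, 7, 9, 8, -1, 1]
        labels = [IMPROVED] * 3 + [STABLE] * 3 + [WORSENED] * 2
        fit = mk.glm_regression_mid(changes, labels)
        assert fit.intercept == pytest.approx(8.0)
        assert fit.beta_better == pytest.approx(2.0)
        assert fit.beta_worse == pytest.approx(-8.0)

    def test_all_stable_refuses(self):
        with pytest.raises(mk.GroupTooSmallError):
            mk.glm_regression_mid([1.0, 2.0, 3.0], [STABLE] * 3)

    def test_survival_fit(self):
        changes = [-5.0, -3.0, 1.0, 2.0, 0.0]
        labels = ["non_survivor"] * 2 + ["survivor"] * 3
        fit = mk.glm_regression_mid(changes, labels)
        assert fit.beta_better is None
        assert fit.beta_worse == pytest.approx(-5.0)
        assert fit.intercept == pytest.approx(1.0)

    def test_identity_with_change_difference_random_data(self):
        """Dummy-coded least squares reproduces group-mean contrasts exactly."""
        rng = np.random.default_rng(0)
        for _ in range(30):
            n = int(rng.integers(30, 300))
            labels = rng.choice([IMPROVED, STABLE, WORSENED], size=n)
            while min((labels == g).sum() for g in (IMPROVED, STABLE, WORSENED)) < 2:
                labels = rng.choice([IMPROVED, STABLE, WORSENED], size=n)
            changes = rng.normal(rng.normal(0, 10), rng.uniform(1, 40), size=n)
            fit = mk.glm_regression_mid(changes, labels)
            cd_imp = mk.change_difference_mid(changes, labels, IMPROVEMENT).value
            cd_wor = mk.change_difference_mid(changes, labels, WORSENING).value
            assert fit.beta_better == pytest.approx(cd_imp, abs=1e-8)
            assert fit.beta_worse == pytest.approx(cd_wor, abs=1e-8)
            # and both agree with the brute-force oracle
            assert cd_imp == pytest.approx(
                group_mean_contrast_oracle(changes, labels, IMPROVED, STABLE), abs=1e-10
            )


class TestSemFloor:
    def make(self, value, direction=IMPROVEMENT, method=CHANGE_DIFFERENCE):
        return mk.MIDEstimate(
            metric="m", anchor="a", method=method, direction=direction,
            value=value, sem=np.nan,
        )

    def test_below_floor_is_raised_to_sem(self):
        out = mk.apply_sem_floor(self.make(1.2), 2.0)
        assert out.value == pytest.approx(2.0)
        assert out.floored

    def test_sign_preserved(self):
        out = mk.apply_sem_floor(self.make(-1.2), 2.0)
        assert out.value == pytest.approx(-2.0)
        assert out.floored

    def test_above_floor_unchanged(self):
        out = mk.apply_sem_floor(self.make(5.0), 2.0)
        assert out.value == 5.0 and not out.floored

    def test_exactly_at_sem_not_floored(self):
        out = mk.apply_sem_floor(self.make(2.0), 2.0)
        assert out.value == 2.0 and not out.floored

    def test_zero_value_takes_direction_convention_sign(self):
        out = mk.apply_sem_floor(self.make(0.0, WORSENING), 2.0, direction_of_benefit=-1)
        assert out.value == pytest.approx(2.0)  # worsening of a volume: positive

    def test_distribution_based_rejected(self):
        with pytest.raises(mk.MidkitError):
            mk.apply_sem_floor(self.make(1.0, method="half_sd"), 2.0)


class TestSem:
    def test_formula(self):
        assert mk.standard_error_of_measurement(10.0, 0.96) == pytest.approx(2.0)

    def test_invalid_icc(self):
        with pytest.raises(mk.ConfigError):
            mk.standard_error_of_measurement(10.0, -0.1)
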