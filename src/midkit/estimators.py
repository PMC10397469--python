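"""The four MID estimators and the SEM floor rule.

Distribution-based
------------------
``half_sd``
    0.5 x the sample sd of change scores within the improved (for
    improvement) or worsened (for worsening) patient group.
``mdc``
    Minimal detectable change, ``1.96 * sqrt(2) * sem``, with
    ``sem = sd_change * sqrt(1 - ICC)``: the smallest change
    distinguishable from measurement error at 95% confidence.

Anchor-based
------------
``change_difference``
    Mean change in the improved (or worsened) group minus mean change in
    the stable group; the stable group's change adjusts for drift.
``glm_regression``
    Identity-link Gaussian regression of the change score on patient
    status dummies with *stable* as the reference level, so the
    coefficients are the incremental change when status moves to better
    or worse relative to stable.  With this coding the coefficients
    coincide algebraically with the change-difference contrasts; the
    identity is asserted in the test suite rather than hidden.

Anchor-based estimates smaller in magnitude than the standard error of
measurement are indistinguishable from measurement error, and are floored
at the SEM (:func:`apply_sem_floor`).

Sign conventions: distribution-based estimates are magnitudes signed by
each metric's direction of benefit (improvement MIDs carry the beneficial
sign, worsening MIDs the opposite); anchor-based estimates keep the
empirical sign of the group contrast.  Sample standard deviations use the
n-1 denominator throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .definitions import (
    ABSOLUTE,
    IMPROVED,
    IMPROVEMENT,
    NON_SURVIVOR,
    STABLE,
    SURVIVOR,
    WORSENED,
    WORSENING,
)
from .exceptions import ConfigError, GroupTooSmallError, MidkitError, NotDefinedError

HALF_SD = "half_sd"
MDC = "mdc"
CHANGE_DIFFERENCE = "change_difference"
GLM_REGRESSION = "glm_regression"

METHOD_ORDER = (HALF_SD, MDC, CHANGE_DIFFERENCE, GLM_REGRESSION)
DISTRIBUTION_METHODS = frozenset({HALF_SD, MDC})
ANCHOR_METHODS = frozenset({CHANGE_DIFFERENCE, GLM_REGRESSION})

#: contrast group and reference group per direction, threshold anchors
_THRESHOLD_CONTRASTS = {IMPROVEMENT: (IMPROVED, STABLE), WORSENING: (WORSENED, STABLE)}
#: mortality anchor: worsening only, non-survivors vs survivors
_SURVIVAL_CONTRASTS = {WORSENING: (NON_SURVIVOR, SURVIVOR)}


@dataclass(frozen=True)
class MIDEstimate:
    """One estimator's MID for one (metric, anchor, direction) cell."""

    metric: str
    anchor: str
    method: str
    direction: str
    value: float
    sem: float
    scale: str = ABSOLUTE
    units: str = ""
    floored: bool = False
    #: the estimate before any SEM flooring (provenance; equals ``value``
    #: for estimates the floor never touched)
    value_unfloored: float = float("nan")
    n_improved: int = 0
    n_stable: int = 0
    n_worsened: int = 0


def standard_error_of_measurement(sd_change: float, icc: float) -> float:
    """SEM = sd of change scores x sqrt(1 - reliability coefficient)."""
    if not 0.0 <= icc <= 1.0:
        raise ConfigError(f"icc must lie in [0, 1], got {icc}")
    if sd_change < 0:
        raise ValueError(f"sd_change must be non-negative, got {sd_change}")
    return float(sd_change * np.sqrt(1.0 - icc))


def _direction_sign(direction: str, direction_of_benefit: int) -> int:
    if direction == IMPROVEMENT:
        return direction_of_benefit
    if direction == WORSENING:
        return -direction_of_benefit
    raise ConfigError(f"unknown direction {direction!r}")


def _group_counts(labels: pd.Series) -> dict[str, int]:
    counts = labels.value_counts()
    return {
        "n_improved": int(counts.get(IMPROVED, 0)),
        "n_stable": int(counts.get(STABLE, 0) + counts.get(SURVIVOR, 0)),
        "n_worsened": int(counts.get(WORSENED, 0) + counts.get(NON_SURVIVOR, 0)),
    }


def half_sd_mid(
    group_changes,
    direction: str,
    metric: str = "metric",
    anchor: str = "",
    direction_of_benefit: int = 1,
    sem: float = float("nan"),
    scale: str = ABSOLUTE,
    units: str = "",
) -> MIDEstimate:
    """0.5 x sample sd of the change scores within one anchor group."""
    x = np.asarray(group_changes, dtype=float)
    if x.size < 2:
        raise GroupTooSmallError(
            f"half_sd {metric}/{anchor}/{direction}: group has {x.size} patients (< 2)"
        )
    magnitude = 0.5 * x.std(ddof=1)
    sign = _direction_sign(direction, direction_of_benefit)
    return MIDEstimate(
        metric=metric,
        anchor=anchor,
        method=HALF_SD,
        direction=direction,
        value=float(sign * magnitude),
        sem=sem,
        scale=scale,
        units=units,
    )


def mdc_mid(
    sd_change: float,
    icc: float,
    direction: str = IMPROVEMENT,
    metric: str = "metric",
    anchor: str = "",
    direction_of_benefit: int = 1,
    scale: str = ABSOLUTE,
    units: str = "",
) -> MIDEstimate:
    """Minimal detectable change: MDC = 1.96 x sqrt(2) x SEM."""
    sem = standard_error_of_measurement(sd_change, icc)
    magnitude = 1.96 * np.sqrt(2.0) * sem
    sign = _direction_sign(direction, direction_of_benefit)
    return MIDEstimate(
        metric=metric,
        anchor=anchor,
        method=MDC,
        direction=direction,
        value=float(sign * magnitude),
        sem=sem,
        scale=scale,
        units=units,
    )


def _contrast_groups(labels: pd.Series, direction: str) -> tuple[str, str]:
    present = set(labels.unique())
    if present <= {SURVIVOR, NON_SURVIVOR}:
        contrasts = _SURVIVAL_CONTRASTS
        if direction == IMPROVEMENT:
            raise NotDefinedError(
                "improvement MIDs are not defined for the survival anchor: "
                "there is no 'improved' mortality group"
            )
    else:
        contrasts = _THRESHOLD_CONTRASTS
    return contrasts[direction]


def change_difference_mid(
    changes,
    labels,
    direction: str,
    metric: str = "metric",
    anchor: str = "",
    sem: float = float("nan"),
    scale: str = ABSOLUTE,
    units: str = "",
) -> MIDEstimate:
    """Mean change in the contrast group minus mean change in the reference group."""
    changes = pd.Series(np.asarray(changes, dtype=float))
    labels = pd.Series(np.asarray(labels, dtype=object))
    if len(changes) != len(labels):
        raise ValueError("changes and labels must have equal length")
    contrast, reference = _contrast_groups(labels, direction)
    groups = {}
    for group in (contrast, reference):
        values = changes[labels.values == group]
        if len(values) < 2:
            raise GroupTooSmallError(
                f"change_difference {metric}/{anchor}/{direction}: "
                f"{group} group has {len(values)} patients (< 2)"
            )
        groups[group] = values
    value = float(groups[contrast].mean() - groups[reference].mean())
    return MIDEstimate(
        metric=metric,
        anchor=anchor,
        method=CHANGE_DIFFERENCE,
        direction=direction,
        value=value,
        sem=sem,
        scale=scale,
        units=units,
        **_group_counts(labels),
    )


@dataclass(frozen=True)
class GLMRegressionFit:
    """Dummy-coded regression fit of change scores on anchor status.

    ``intercept`` is the stable (reference) group's mean change;
    ``beta_better`` / ``beta_worse`` are the incremental changes for the
    improved and worsened groups (``beta_better`` is None for the survival
    anchor, which has no improved group).
    """

    intercept: float
    beta_better: float | None
    beta_worse: float
    estimates: dict[str, MIDEstimate]


def glm_regression_mid(
    changes,
    labels,
    metric: str = "metric",
    anchor: str = "",
    sem: float = float("nan"),
    scale: str = ABSOLUTE,
    units: str = "",
) -> GLMRegressionFit:
    """Fit change = k + beta_b * X_better + beta_w * X_worse by least squares.

    Identity-link Gaussian fit with stable (or survivor) absorbed into the
    intercept as the reference level; the printed four-term equation with a
    free intercept is rank-deficient, and reference-level coding is the
    parameterisation under which the coefficients measure the incremental
    difference vs stable patients.
    """
    changes = pd.Series(np.asarray(changes, dtype=float))
    labels = pd.Series(np.asarray(labels, dtype=object))
    if len(changes) != len(labels):
        raise ValueError("changes and labels must have equal length")
    present = set(labels.unique())
    survival = present <= {SURVIVOR, NON_SURVIVOR}
    if survival:
        levels = [NON_SURVIVOR]
        reference = SURVIVOR
    else:
        levels = [IMPROVED, WORSENED]
        reference = STABLE
    for group in levels + [reference]:
        n = int((labels.values == group).sum())
        if n < 2:
            raise GroupTooSmallError(
                f"glm_regression {metric}/{anchor}: {group} group has {n} patients (< 2)"
            )
    design = np.column_stack(
        [np.ones(len(labels))] + [(labels.values == g).astype(float) for g in levels]
    )
    fit = sm.OLS(changes.to_numpy(), design).fit()
    params = fit.params
    intercept = float(params[0])
    counts = _group_counts(labels)
    if survival:
        beta_better = None
        beta_worse = float(params[1])
        directions = {WORSENING: beta_worse}
    else:
        beta_better = float(params[1])
        beta_worse = float(params[2])
        directions = {IMPROVEMENT: beta_better, WORSENING: beta_worse}
    estimates = {
        direction: MIDEstimate(
            metric=metric,
            anchor=anchor,
            method=GLM_REGRESSION,
            direction=direction,
            value=value,
            sem=sem,
            scale=scale,
            units=units,
            **counts,
        )
        for direction, value in directions.items()
    }
    return GLMRegressionFit(
        intercept=intercept,
        beta_better=beta_better,
        beta_worse=beta_worse,
        estimates=estimates,
    )


def apply_sem_floor(
    estimate: MIDEstimate, sem: float, direction_of_benefit: int = 1
) -> MIDEstimate:
    """Floor an anchor-based MID at the standard error of measurement.

    An anchor-based estimate strictly smaller in magnitude than the SEM is
    indistinguishable from measurement error, so the SEM itself is used as
    the MID.  The sign is kept from the estimate (or, at exactly zero, set
    by the direction convention).  Applying the rule to a
    distribution-based estimate is an error: the rule exists to guard
    anchor-based contrasts.
    """
    if estimate.method not in ANCHOR_METHODS:
        raise MidkitError(
            f"SEM floor applies to anchor-based methods only, not {estimate.method!r}"
        )
    if sem < 0:
        raise ValueError(f"sem must be non-negative, got {sem}")
    if abs(estimate.value) >= sem:
        return replace(estimate, value_unfloored=estimate.value)
    if estimate.value != 0.0:
        sign = np.sign(estimate.value)
    else:
        sign = _direction_sign(estimate.direction, direction_of_benefit)
    return replace(
        estimate,
        value=float(sign * sem),
        value_unfloored=estimate.value,
        sem=sem,
        floored=True,
    )
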