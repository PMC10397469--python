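"""Paired-cohort data model: change scores and anchor classification.

A :class:`PairedCohort` wraps a patient-per-row table with
``<metric>_baseline`` / ``<metric>_followup`` columns for each metric,
``<anchor>_baseline`` / ``<anchor>_followup`` columns for each
change-threshold anchor, and a ``survived_1yr`` 0/1 flag.  All change
scores are follow-up minus baseline, everywhere; direction of benefit is
resolved through signs, never by re-subtracting the other way round.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .definitions import (
    BINARY_SURVIVAL,
    CHANGE_THRESHOLD,
    IMPROVED,
    NON_SURVIVOR,
    STABLE,
    SURVIVOR,
    WORSENED,
    AnchorDefinition,
    MetricDefinition,
)
from .exceptions import ConfigError, GroupTooSmallError

logger = logging.getLogger(__name__)


def classify_change_scores(changes: pd.Series, anchor: AnchorDefinition) -> pd.Series:
    """Label anchor change scores as improved / stable / worsened.

    With signed change ``d`` (follow-up − baseline) and beneficial sign
    ``s``, a patient improved iff ``s*d >= threshold`` and worsened iff
    ``s*d <= -threshold``; a change exactly at the threshold counts as
    changed (the threshold is itself the minimal important change).
    """
    if anchor.kind != CHANGE_THRESHOLD:
        raise ConfigError(f"anchor {anchor.name!r} is not a change_threshold anchor")
    benefit = anchor.improvement_sign * changes.astype(float)
    labels = pd.Series(STABLE, index=changes.index, dtype=object)
    labels[benefit >= anchor.threshold] = IMPROVED
    labels[benefit <= -anchor.threshold] = WORSENED
    return labels


class PairedCohort:
    """One row per patient: baseline/follow-up metric values, anchor scores,
    and a 1-year survival flag.

    Missing anchor scores are allowed; a patient contributes to an anchor's
    analysis only with both timepoints present (pairwise-complete analysis),
    and exclusions are logged and countable.
    """

    def __init__(self, data: pd.DataFrame):
        if "patient_id" not in data.columns:
            raise ConfigError("cohort table must have a 'patient_id' column")
        if data["patient_id"].duplicated().any():
            raise ConfigError("duplicate patient_id values in cohort table")
        self.data = data.reset_index(drop=True)

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def from_csv(cls, path: str | Path) -> "PairedCohort":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    # -- basic properties --------------------------------------------------

    @property
    def n_patients(self) -> int:
        return len(self.data)

    def _pair(self, name: str) -> tuple[pd.Series, pd.Series]:
        try:
            return self.data[f"{name}_baseline"], self.data[f"{name}_followup"]
        except KeyError as exc:
            raise ConfigError(f"cohort table has no baseline/followup columns for {name!r}") from exc

    def complete_mask(self, name: str) -> pd.Series:
        """Patients with both timepoints present for metric/anchor ``name``."""
        base, follow = self._pair(name)
        return base.notna() & follow.notna()

    # -- change scores -----------------------------------------------------

    def compute_changes(self, metric: MetricDefinition | str) -> pd.DataFrame:
        """Per-patient change scores for one metric.

        Returns a frame (complete pairs only, cohort order preserved) with
        columns ``patient_id``, ``absolute_change`` (follow-up − baseline),
        ``relative_change`` (absolute / baseline) and ``relative_defined``
        (False where baseline is exactly zero: the ratio is flagged NaN,
        never silently zero).
        """
        name = metric.name if isinstance(metric, MetricDefinition) else metric
        base, follow = self._pair(name)
        mask = base.notna() & follow.notna()
        n_excluded = int((~mask).sum())
        if n_excluded:
            logger.info("%s: excluded %d patients without complete pairs", name, n_excluded)
        base, follow = base[mask].astype(float), follow[mask].astype(float)
        absolute = follow - base
        defined = base != 0.0
        relative = pd.Series(np.where(defined, absolute / base.where(defined, np.nan), np.nan),
                             index=absolute.index)
        return pd.DataFrame(
            {
                "patient_id": self.data.loc[mask, "patient_id"],
                "absolute_change": absolute,
                "relative_change": relative,
                "relative_defined": defined,
            }
        )

    def anchor_changes(self, anchor: AnchorDefinition) -> pd.Series:
        """Signed anchor change (follow-up − baseline) for complete pairs."""
        if anchor.kind != CHANGE_THRESHOLD:
            raise ConfigError(f"anchor {anchor.name!r} has no continuous change score")
        base, follow = self._pair(anchor.name)
        mask = base.notna() & follow.notna()
        n_excluded = int((~mask).sum())
        if n_excluded:
            logger.info(
                "anchor %s: excluded %d patients without complete pairs", anchor.name, n_excluded
            )
        return (follow[mask] - base[mask]).astype(float)

    # -- classification ----------------------------------------------------

    def classify_by_anchor(self, anchor: AnchorDefinition) -> pd.Series:
        """Improved/stable/worsened labels for patients with complete anchor pairs."""
        return classify_change_scores(self.anchor_changes(anchor), anchor)

    def classify_by_survival(self) -> pd.Series:
        """Survivor / non-survivor labels from the 1-year flag.

        Raises :class:`GroupTooSmallError` when either group has fewer than
        two patients, since no two-group contrast is estimable downstream.
        """
        if "survived_1yr" not in self.data.columns:
            raise ConfigError("cohort table has no 'survived_1yr' column")
        flag = self.data["survived_1yr"]
        if flag.isna().any():
            raise ConfigError("survived_1yr must be recorded for every patient")
        labels = pd.Series(
            np.where(flag.astype(int) == 1, SURVIVOR, NON_SURVIVOR),
            index=self.data.index,
            dtype=object,
        )
        counts = labels.value_counts()
        for group in (SURVIVOR, NON_SURVIVOR):
            if counts.get(group, 0) < 2:
                raise GroupTooSmallError(
                    f"survival anchor: {group} group has "
                    f"{counts.get(group, 0)} patients (< 2)"
                )
        return labels

    def classify(self, anchor: AnchorDefinition) -> pd.Series:
        """Dispatch to threshold or survival classification by anchor kind."""
        if anchor.kind == BINARY_SURVIVAL:
            return self.classify_by_survival()
        return self.classify_by_anchor(anchor)
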