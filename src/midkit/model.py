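"""The MID estimation model and its results object.

:class:`MIDModel` bundles a paired cohort with metric and anchor
definitions; :meth:`MIDModel.fit` runs the correlation screen, all four
estimators per screened-in metric x anchor x direction on both the
absolute and the relative (percent-of-baseline) change scale, applies the
SEM floor to the anchor-based estimates, and returns a
:class:`MIDResults` carrying the long-format estimates table, the screen
table, and summary accessors.
"""

from __future__ import annotations

import logging
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import reporting
from .cohort import PairedCohort
from .definitions import (
    ABSOLUTE,
    BINARY_SURVIVAL,
    CHANGE_THRESHOLD,
    IMPROVEMENT,
    RELATIVE,
    WORSENING,
    AnchorDefinition,
    MetricDefinition,
    DEFAULT_ANCHORS,
    DEFAULT_METRICS,
    load_definitions,
)
from .estimators import (
    CHANGE_DIFFERENCE,
    GLM_REGRESSION,
    HALF_SD,
    IMPROVED,
    MDC,
    STABLE,
    WORSENED,
    MIDEstimate,
    apply_sem_floor,
    change_difference_mid,
    glm_regression_mid,
    half_sd_mid,
    mdc_mid,
    standard_error_of_measurement,
)
from .exceptions import MidkitError, NotDefinedError
from .screening import DEFAULT_SCREEN_THRESHOLD, correlation_screen

logger = logging.getLogger(__name__)

STATUS_OK = "ok"
STATUS_SCREENED_OUT = "screened_out"
STATUS_NOT_DEFINED = "not_defined"
STATUS_ERROR = "error"

ESTIMATE_COLUMNS = [
    "metric",
    "units",
    "anchor",
    "method",
    "direction",
    "scale",
    "value",
    "value_unfloored",
    "sem",
    "floored",
    "n",
    "n_improved",
    "n_stable",
    "n_worsened",
    "status",
    "note",
]


def _estimate_row(estimate: MIDEstimate, n: int) -> dict:
    row = asdict(estimate)
    if np.isnan(row["value_unfloored"]):
        row["value_unfloored"] = row["value"]
    row["n"] = n
    row["status"] = STATUS_OK
    row["note"] = ""
    return row


def _failure_row(
    metric: MetricDefinition,
    anchor: AnchorDefinition,
    status: str,
    note: str,
    method: str = "",
    direction: str = "",
    scale: str = "",
    units: str | None = None,
) -> dict:
    return {
        "metric": metric.name,
        "units": metric.units if units is None else units,
        "anchor": anchor.name,
        "method": method,
        "direction": direction,
        "scale": scale,
        "value": np.nan,
        "value_unfloored": np.nan,
        "sem": np.nan,
        "floored": False,
        "n": 0,
        "n_improved": 0,
        "n_stable": 0,
        "n_worsened": 0,
        "status": status,
        "note": note,
    }


class MIDModel:
    """Minimally-important-difference estimation on a paired cohort.

    Parameters
    ----------
    cohort : PairedCohort or pandas.DataFrame
        One row per patient with baseline/follow-up columns.
    metrics, anchors
        Definitions of the continuous metrics and the anchors; defaults
        are the cardiac-MRI RV metric set with emPHasis-10, ISWT and
        1-year survival anchors.
    screen_threshold : float
        Pearson |r| a metric-anchor pair must exceed to enter MID
        estimation (0.20 by default).
    scales
        Which change scales to analyse: ``absolute`` (metric units) and/or
        ``relative`` (percent of baseline).
    """

    def __init__(
        self,
        cohort: PairedCohort | pd.DataFrame,
        metrics: Sequence[MetricDefinition] = DEFAULT_METRICS,
        anchors: Sequence[AnchorDefinition] = DEFAULT_ANCHORS,
        screen_threshold: float = DEFAULT_SCREEN_THRESHOLD,
        scales: Sequence[str] = (ABSOLUTE, RELATIVE),
    ):
        if isinstance(cohort, pd.DataFrame):
            cohort = PairedCohort(cohort)
        self.cohort = cohort
        self.metrics = tuple(metrics)
        self.anchors = tuple(anchors)
        self.screen_threshold = float(screen_threshold)
        self.scales = tuple(scales)

    @classmethod
    def from_csv(
        cls,
        cohort_path: str | Path,
        config_path: str | Path | None = None,
        **kwargs,
    ) -> "MIDModel":
        cohort = PairedCohort.from_csv(cohort_path)
        if config_path is not None:
            metrics, anchors = load_definitions(config_path)
            kwargs.setdefault("metrics", metrics)
            kwargs.setdefault("anchors", anchors)
        return cls(cohort, **kwargs)

    # -- screening ---------------------------------------------------------

    def screen(self) -> pd.DataFrame:
        """Run the correlation screen for every metric x change-threshold anchor."""
        rows = []
        for metric in self.metrics:
            changes = self.cohort.compute_changes(metric).set_index("patient_id")
            for anchor in self.anchors:
                if anchor.kind != CHANGE_THRESHOLD:
                    continue
                anchor_change = self.cohort.anchor_changes(anchor)
                anchor_change.index = self.cohort.data.loc[anchor_change.index, "patient_id"]
                joined = changes.join(anchor_change.rename("anchor_change"), how="inner")
                try:
                    result = correlation_screen(
                        joined["absolute_change"],
                        joined["anchor_change"],
                        threshold=self.screen_threshold,
                        metric=metric.name,
                        anchor=anchor.name,
                    )
                    rows.append(
                        {
                            "metric": metric.name,
                            "anchor": anchor.name,
                            "n": result.n,
                            "r": result.r,
                            "passed": result.passed,
                            "note": "",
                        }
                    )
                except MidkitError as exc:
                    logger.warning("screen failed for %s x %s: %s", metric.name, anchor.name, exc)
                    rows.append(
                        {
                            "metric": metric.name,
                            "anchor": anchor.name,
                            "n": 0,
                            "r": np.nan,
                            "passed": False,
                            "note": str(exc),
                        }
                    )
        return pd.DataFrame(rows)

    # -- estimation --------------------------------------------------------

    def fit(self) -> "MIDResults":
        """Screen, estimate every cell, floor, and wrap in a results object."""
        screen = self.screen()
        passed_pairs = {
            (row.metric, row.anchor) for row in screen.itertuples() if row.passed
        }
        metrics_passing_any = {m for (m, _a) in passed_pairs}
        rows: list[dict] = []
        for metric in self.metrics:
            changes = self.cohort.compute_changes(metric).set_index("patient_id")
            for anchor in self.anchors:
                if anchor.kind == CHANGE_THRESHOLD:
                    admitted = (metric.name, anchor.name) in passed_pairs
                else:
                    # No continuous change to correlate against: the survival
                    # anchor admits metrics that passed at least one screen.
                    admitted = metric.name in metrics_passing_any
                if not admitted:
                    rows.append(
                        _failure_row(
                            metric,
                            anchor,
                            STATUS_SCREENED_OUT,
                            f"|r| <= {self.screen_threshold} for"
                            f" {metric.name} x {anchor.name}"
                            if anchor.kind == CHANGE_THRESHOLD
                            else f"{metric.name} passed no anchor screen",
                        )
                    )
                    continue
                rows.extend(self._estimate_cell(metric, anchor, changes))
        estimates = pd.DataFrame(rows, columns=ESTIMATE_COLUMNS)
        return MIDResults(self, screen, estimates)

    def _estimate_cell(
        self, metric: MetricDefinition, anchor: AnchorDefinition, changes: pd.DataFrame
    ) -> list[dict]:
        try:
            labels = self.cohort.classify(anchor)
        except MidkitError as exc:
            return [_failure_row(metric, anchor, STATUS_ERROR, str(exc))]
        if anchor.kind == BINARY_SURVIVAL:
            labels.index = self.cohort.data["patient_id"]
        else:
            labels.index = self.cohort.data.loc[labels.index, "patient_id"]
        joined = changes.join(labels.rename("label"), how="inner")
        rows: list[dict] = []
        for scale in self.scales:
            rows.extend(self._estimate_scale(metric, anchor, joined, scale))
        return rows

    def _estimate_scale(
        self,
        metric: MetricDefinition,
        anchor: AnchorDefinition,
        joined: pd.DataFrame,
        scale: str,
    ) -> list[dict]:
        units = metric.units if scale == ABSOLUTE else "% of baseline"
        if scale == ABSOLUTE:
            data = joined
            values = data["absolute_change"]
        else:
            data = joined[joined["relative_defined"]]
            dropped = len(joined) - len(data)
            if dropped:
                logger.info(
                    "%s x %s: %d patients with zero baseline excluded from the relative scale",
                    metric.name,
                    anchor.name,
                    dropped,
                )
            values = 100.0 * data["relative_change"]
        labels = data["label"]
        n = len(data)
        if n < 3:
            return [
                _failure_row(
                    metric, anchor, STATUS_ERROR,
                    f"only {n} analysable patients on the {scale} scale",
                    scale=scale, units=units,
                )
            ]
        sd_change = float(values.std(ddof=1))
        sem = standard_error_of_measurement(sd_change, metric.icc)
        shared = dict(
            metric=metric.name,
            anchor=anchor.name,
            scale=scale,
            units=units,
        )
        rows: list[dict] = []

        def attempt(method: str, direction: str, fn) -> None:
            try:
                rows.append(_estimate_row(fn(), n))
            except NotDefinedError as exc:
                rows.append(
                    _failure_row(
                        metric, anchor, STATUS_NOT_DEFINED, str(exc),
                        method=method, direction=direction, scale=scale, units=units,
                    )
                )
            except MidkitError as exc:
                logger.warning(
                    "%s %s/%s/%s (%s): %s", method, metric.name, anchor.name,
                    direction, scale, exc,
                )
                rows.append(
                    _failure_row(
                        metric, anchor, STATUS_ERROR, str(exc),
                        method=method, direction=direction, scale=scale, units=units,
                    )
                )

        group_for = {IMPROVEMENT: IMPROVED, WORSENING: WORSENED}
        survival = anchor.kind == BINARY_SURVIVAL
        for direction in (IMPROVEMENT, WORSENING):
            if survival and direction == IMPROVEMENT:
                rows.append(
                    _failure_row(
                        metric, anchor, STATUS_NOT_DEFINED,
                        "no 'improved' mortality group exists",
                        method=HALF_SD, direction=direction, scale=scale, units=units,
                    )
                )
            else:
                group = labels == ("non_survivor" if survival else group_for[direction])
                attempt(
                    HALF_SD,
                    direction,
                    lambda d=direction, g=group: half_sd_mid(
                        values[g], d, sem=sem,
                        direction_of_benefit=metric.direction_of_benefit, **shared,
                    ),
                )
            # MDC depends only on the anchored sample's change sd, so it is
            # reported for both directions (signed by convention).
            attempt(
                MDC,
                direction,
                lambda d=direction: mdc_mid(
                    sd_change, metric.icc, d,
                    direction_of_benefit=metric.direction_of_benefit, **shared,
                ),
            )
            attempt(
                CHANGE_DIFFERENCE,
                direction,
                lambda d=direction: apply_sem_floor(
                    change_difference_mid(values, labels, d, sem=sem, **shared),
                    sem,
                    metric.direction_of_benefit,
                ),
            )

        def glm_rows() -> None:
            try:
                fit = glm_regression_mid(values, labels, sem=sem, **shared)
            except MidkitError as exc:
                for direction in (IMPROVEMENT, WORSENING):
                    rows.append(
                        _failure_row(
                            metric, anchor, STATUS_ERROR, str(exc),
                            method=GLM_REGRESSION, direction=direction,
                            scale=scale, units=units,
                        )
                    )
                return
            for direction in (IMPROVEMENT, WORSENING):
                if direction in fit.estimates:
                    floored = apply_sem_floor(
                        fit.estimates[direction], sem, metric.direction_of_benefit
                    )
                    rows.append(_estimate_row(floored, n))
                else:
                    rows.append(
                        _failure_row(
                            metric, anchor, STATUS_NOT_DEFINED,
                            "no 'improved' mortality group exists",
                            method=GLM_REGRESSION, direction=direction,
                            scale=scale, units=units,
                        )
                    )

        glm_rows()
        return rows


class MIDResults:
    """Results of :meth:`MIDModel.fit`.

    Attributes
    ----------
    screen : pandas.DataFrame
        Per metric x anchor correlation-screen table (metric, anchor, n, r, passed).
    estimates : pandas.DataFrame
        Long-format table with one row per metric x anchor x method x
        direction x scale, including screened-out / not-defined / error rows.
    """

    def __init__(self, model: MIDModel, screen: pd.DataFrame, estimates: pd.DataFrame):
        self.model = model
        self.screen = screen
        self.estimates = estimates
        self._summaries: pd.DataFrame | None = None

    @property
    def summaries(self) -> pd.DataFrame:
        """Mean and range of method-level MID means per metric/direction/scale."""
        if self._summaries is None:
            self._summaries = reporting.summarize(self.estimates)
        return self._summaries

    def heatmap_table(self, direction: str, scale: str = ABSOLUTE) -> pd.DataFrame:
        return reporting.render_heatmap_table(self.estimates, direction, scale)

    def plot_heatmap(self, direction: str, scale: str = ABSOLUTE, ax=None):
        return reporting.plot_heatmap(self.estimates, direction, scale, ax=ax)

    def summary(self) -> str:
        """Human-readable report: screen decisions and headline MIDs."""
        lines = [
            "Minimally important difference estimation",
            "=" * 57,
            f"Patients: {self.model.cohort.n_patients}    "
            f"Metrics: {', '.join(m.name for m in self.model.metrics)}",
            f"Anchors: {', '.join(a.name for a in self.model.anchors)}    "
            f"Screen threshold: |r| > {self.model.screen_threshold:g}",
            "",
            "Correlation screen",
            "-" * 57,
            self.screen.to_string(index=False, float_format=lambda v: f"{v:.3f}"),
            "",
        ]
        for scale in self.model.scales:
            block = self.summaries[self.summaries["scale"] == scale]
            if block.empty:
                continue
            lines += [
                f"MID summaries ({scale} scale"
                + (", % of baseline)" if scale == RELATIVE else ")"),
                "-" * 57,
                block[
                    ["metric", "units", "direction", "mean_mid", "min_mid", "max_mid"]
                ].to_string(index=False, float_format=lambda v: f"{v:.2f}"),
                "",
            ]
        return "\n".join(lines)

    def save(
        self,
        mids_path: str | Path,
        summary_path: str | Path | None = None,
        heatmap_path: str | Path | None = None,
    ) -> None:
        """Write the estimates table (and optionally summary/heatmap CSVs)."""
        self.estimates.to_csv(mids_path, index=False)
        if summary_path is not None:
            self.summaries.to_csv(summary_path, index=False)
        if heatmap_path is not None:
            tables = []
            for direction in (IMPROVEMENT, WORSENING):
                table = self.heatmap_table(direction).reset_index()
                table.insert(0, "direction", direction)
                tables.append(table)
            pd.concat(tables, ignore_index=True).to_csv(heatmap_path, index=False)


def estimate_all(
    cohort: PairedCohort | pd.DataFrame,
    metrics: Sequence[MetricDefinition] = DEFAULT_METRICS,
    anchors: Sequence[AnchorDefinition] = DEFAULT_ANCHORS,
    screen_threshold: float = DEFAULT_SCREEN_THRESHOLD,
    scales: Sequence[str] = (ABSOLUTE, RELATIVE),
) -> MIDResults:
    """Functional one-call front door: build a :class:`MIDModel` and fit it."""
    return MIDModel(
        cohort, metrics=metrics, anchors=anchors,
        screen_threshold=screen_threshold, scales=scales,
    ).fit()
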