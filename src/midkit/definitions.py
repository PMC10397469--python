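"""Metric and anchor definitions.

A *metric* is a continuous outcome measured at baseline and follow-up
(e.g. RV ejection fraction in %, RV volumes in mL).  Its
``direction_of_benefit`` states which sign of change is an improvement
(+1 for RVEF, where an increase is good; -1 for RV volumes, where a
decrease is good), and ``icc`` is its test-retest reliability used for the
standard error of measurement.

An *anchor* is an external criterion of patient change used to classify
patients as improved / stable / worsened (a quality-of-life score or a
walk test with a published minimal-change threshold) or as survivor /
non-survivor (a binary 1-year vital-status flag).
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass
from pathlib import Path

from .exceptions import ConfigError

CHANGE_THRESHOLD = "change_threshold"
BINARY_SURVIVAL = "binary_survival"

IMPROVED = "improved"
STABLE = "stable"
WORSENED = "worsened"
SURVIVOR = "survivor"
NON_SURVIVOR = "non_survivor"

IMPROVEMENT = "improvement"
WORSENING = "worsening"

ABSOLUTE = "absolute"
RELATIVE = "relative"


@dataclass(frozen=True)
class MetricDefinition:
    """A continuous outcome metric.

    Parameters
    ----------
    name : str
        Column prefix in cohort tables (``<name>_baseline``, ``<name>_followup``).
    units : str
        Measurement units, echoed in every output row (no conversion is done).
    direction_of_benefit : int
        +1 if an increase is an improvement, -1 if a decrease is.
    icc : float
        Test-retest reliability (consistency intraclass correlation) in [0, 1].
    """

    name: str
    units: str
    direction_of_benefit: int
    icc: float

    def __post_init__(self) -> None:
        if self.direction_of_benefit not in (-1, 1):
            raise ConfigError(
                f"metric {self.name!r}: direction_of_benefit must be +1 or -1, "
                f"got {self.direction_of_benefit!r}"
            )
        if not 0.0 <= self.icc <= 1.0:
            raise ConfigError(f"metric {self.name!r}: icc must lie in [0, 1], got {self.icc}")


@dataclass(frozen=True)
class AnchorDefinition:
    """An external criterion of patient change.

    ``change_threshold`` anchors classify patients by whether the follow-up
    minus baseline anchor score crosses ``threshold`` in the beneficial
    (``improvement_sign``) or harmful direction.  ``binary_survival`` anchors
    split the cohort into survivors and non-survivors of the year after the
    follow-up assessment.
    """

    name: str
    kind: str
    threshold: float | None = None
    improvement_sign: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in (CHANGE_THRESHOLD, BINARY_SURVIVAL):
            raise ConfigError(f"anchor {self.name!r}: unknown kind {self.kind!r}")
        if self.kind == CHANGE_THRESHOLD:
            if self.threshold is None or not self.threshold > 0:
                raise ConfigError(
                    f"anchor {self.name!r}: change_threshold anchors need threshold > 0"
                )
            if self.improvement_sign not in (-1, 1):
                raise ConfigError(
                    f"anchor {self.name!r}: improvement_sign must be +1 or -1"
                )
        else:
            if self.threshold is not None:
                raise ConfigError(
                    f"anchor {self.name!r}: threshold is undefined for binary_survival"
                )


# Default cardiac-MRI metric set.  ICCs are package defaults representing
# scan-rescan reliability of automated volumetric CMR analysis.
DEFAULT_METRICS: tuple[MetricDefinition, ...] = (
    MetricDefinition("rvef", "%", +1, 0.96),
    MetricDefinition("rvedv", "mL", -1, 0.98),
    MetricDefinition("rvesv", "mL", -1, 0.97),
    MetricDefinition("rvsv", "mL", +1, 0.90),
)

# emPHasis-10: 0-50 points, lower is better, 6-point minimal change.
EMPHASIS10 = AnchorDefinition("e10", CHANGE_THRESHOLD, threshold=6.0, improvement_sign=-1)
# Incremental shuttle walk test: metres walked, higher is better, 47.5 m minimal change.
ISWT = AnchorDefinition("iswt", CHANGE_THRESHOLD, threshold=47.5, improvement_sign=+1)
# One-year vital status after the follow-up assessment.
SURVIVAL = AnchorDefinition("survival", BINARY_SURVIVAL)

DEFAULT_ANCHORS: tuple[AnchorDefinition, ...] = (EMPHASIS10, ISWT, SURVIVAL)


def load_definitions(
    path: str | Path,
) -> tuple[tuple[MetricDefinition, ...], tuple[AnchorDefinition, ...]]:
    """Read metric and anchor definitions from a TOML file.

    Expected layout::

        [metrics.rvef]
        units = "%"
        direction_of_benefit = 1
        icc = 0.96

        [anchors.e10]
        kind = "change_threshold"
        threshold = 6.0
        improvement_sign = -1

        [anchors.survival]
        kind = "binary_survival"

    Missing ``[anchors]`` falls back to the default anchor set.
    """
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    if "metrics" not in raw or not raw["metrics"]:
        raise ConfigError(f"{path}: no [metrics.*] tables found")
    metrics = tuple(
        MetricDefinition(
            name=name,
            units=spec.get("units", ""),
            direction_of_benefit=int(spec["direction_of_benefit"]),
            icc=float(spec["icc"]),
        )
        for name, spec in raw["metrics"].items()
    )
    if "anchors" in raw and raw["anchors"]:
        anchors = tuple(
            AnchorDefinition(
                name=name,
                kind=spec["kind"],
                threshold=spec.get("threshold"),
                improvement_sign=spec.get("improvement_sign"),
            )
            for name, spec in raw["anchors"].items()
        )
    else:
        anchors = DEFAULT_ANCHORS
    return metrics, anchors
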