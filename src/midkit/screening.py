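"""Correlation screening of metric-anchor pairs.

A metric is admitted to anchor-based MID estimation only if its change
scores are at least weakly correlated with the anchor's change scores
(|r| > 0.20 by default).  The screen is on the magnitude of Pearson's r:
a negative correlation (e.g. RV volumes falling as quality of life
improves on a lower-is-better scale) is as informative as a positive one.

Pearson's r is invariant to affine rescaling of either series, so the
screen is computed on raw change scores; :func:`normalize_to_six_units`
(the z-score mapping of both series onto a common 6-unit span used for
reporting) provably cannot alter any screening decision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import DegenerateDataError, GroupTooSmallError

DEFAULT_SCREEN_THRESHOLD = 0.20


@dataclass(frozen=True)
class ScreenResult:
    metric: str
    anchor: str
    r: float
    n: int
    passed: bool
    threshold: float = DEFAULT_SCREEN_THRESHOLD


def normalize_to_six_units(values, span: float = 6.0, name: str = "series") -> np.ndarray:
    """Map a change-score series onto a common span via z-score normalisation.

    The series is z-scored (mean 0) and linearly rescaled so its observed
    range covers exactly ``span`` units (six by default, the width of the
    quality-of-life anchor's minimal important change).  Being an affine
    map, it preserves every Pearson correlation computed on the output.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise GroupTooSmallError(f"{name}: need at least 3 values, got {x.size}")
    sd = x.std(ddof=1)
    if sd == 0:
        raise DegenerateDataError(f"{name}: zero variance, cannot normalise")
    z = (x - x.mean()) / sd
    return z * (span / (z.max() - z.min()))


def correlation_screen(
    metric_changes,
    anchor_changes,
    threshold: float = DEFAULT_SCREEN_THRESHOLD,
    metric: str = "metric",
    anchor: str = "anchor",
) -> ScreenResult:
    """Pearson-correlation screen on pairwise-complete change scores.

    Pairs with a missing value on either side are dropped; the pair passes
    iff ``|r| > threshold``.
    """
    x = np.asarray(metric_changes, dtype=float)
    y = np.asarray(anchor_changes, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise GroupTooSmallError(
            f"screen {metric} x {anchor}: only {x.size} complete pairs (< 3)"
        )
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError(f"screen {metric} x {anchor}: constant series")
    r = float(stats.pearsonr(x, y).statistic)
    return ScreenResult(
        metric=metric,
        anchor=anchor,
        r=r,
        n=int(x.size),
        passed=bool(abs(r) > threshold),
        threshold=threshold,
    )
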