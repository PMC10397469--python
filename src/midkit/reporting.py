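"""Aggregation of per-method MIDs into headline summaries.

The headline number for a metric and direction is the mean of the
method-level means together with their min-max range: each method's
estimates are first averaged over anchors, then averaged across methods.
Both the per-method means and the final mean are emitted so either
aggregation reading is recoverable from the output.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .estimators import METHOD_ORDER
from .exceptions import MidkitError

logger = logging.getLogger(__name__)

STATUS_OK = "ok"


def _ok(mids: pd.DataFrame) -> pd.DataFrame:
    if "status" in mids.columns:
        return mids[mids["status"] == STATUS_OK]
    return mids


def method_level_means(mids: pd.DataFrame) -> pd.DataFrame:
    """Mean MID per (metric, direction, scale, method), averaged over anchors."""
    ok = _ok(mids)
    if ok.empty:
        raise MidkitError("no usable MID estimates to aggregate")
    grouped = (
        ok.groupby(["metric", "units", "direction", "scale", "method"], sort=False)
        .agg(value=("value", "mean"), anchors=("anchor", lambda a: ",".join(sorted(set(a)))))
        .reset_index()
    )
    order = {m: i for i, m in enumerate(METHOD_ORDER)}
    return grouped.sort_values(
        ["metric", "direction", "scale", "method"],
        key=lambda col: col.map(order) if col.name == "method" else col,
        kind="stable",
    ).reset_index(drop=True)


def summarize(mids: pd.DataFrame) -> pd.DataFrame:
    """Mean and range of method-level means per (metric, direction, scale).

    Rows in the input that are screened out or failed are ignored; cells
    with no usable estimate are omitted (with a log entry), never emitted
    as NaN rows.
    """
    per_method = method_level_means(mids)
    rows = []
    for (metric, units, direction, scale), cell in per_method.groupby(
        ["metric", "units", "direction", "scale"], sort=False
    ):
        values = cell["value"].to_numpy(dtype=float)
        rows.append(
            {
                "metric": metric,
                "units": units,
                "direction": direction,
                "scale": scale,
                "mean_mid": float(values.mean()),
                "min_mid": float(values.min()),
                "max_mid": float(values.max()),
                "methods_included": ",".join(cell["method"]),
                "anchors_included": ",".join(
                    sorted(set(a for sub in cell["anchors"] for a in sub.split(",")))
                ),
                **{f"mid_{m}": float(v) for m, v in zip(cell["method"], values)},
            }
        )
    if not rows:
        logger.warning("summarize: no cells to report")
    summary = pd.DataFrame(rows)
    return summary


def render_heatmap_table(
    mids: pd.DataFrame, direction: str, scale: str = "absolute"
) -> pd.DataFrame:
    """Methods x metrics matrix of mean MIDs with average row and column.

    Row order is fixed (half_sd, mdc, change_difference, glm_regression,
    then the across-method average); column order follows first appearance
    of each metric, with the across-metric average last.
    """
    per_method = method_level_means(mids)
    cell = per_method[(per_method["direction"] == direction) & (per_method["scale"] == scale)]
    if cell.empty:
        raise MidkitError(f"no estimates for direction={direction!r}, scale={scale!r}")
    matrix = cell.pivot_table(index="method", columns="metric", values="value", sort=False)
    # column order: first appearance in the input table, not alphabetical
    column_order = [m for m in dict.fromkeys(_ok(mids)["metric"]) if m in matrix.columns]
    matrix = matrix.reindex(
        index=[m for m in METHOD_ORDER if m in matrix.index],
        columns=column_order,
    )
    matrix["average"] = matrix.mean(axis=1)
    matrix.loc["average"] = matrix.mean(axis=0)
    matrix.index.name = "method"
    matrix.columns.name = None
    return matrix


def plot_heatmap(
    mids: pd.DataFrame, direction: str, scale: str = "absolute", ax=None
):
    """Plain matplotlib rendering of :func:`render_heatmap_table`."""
    import matplotlib.pyplot as plt

    table = render_heatmap_table(mids, direction, scale)
    if ax is None:
        _, ax = plt.subplots(figsize=(1.2 * table.shape[1] + 2, 0.7 * table.shape[0] + 1.5))
    image = ax.imshow(table.to_numpy(), cmap="coolwarm", aspect="auto")
    ax.set_xticks(np.arange(table.shape[1]), labels=table.columns)
    ax.set_yticks(np.arange(table.shape[0]), labels=table.index)
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            ax.text(j, i, f"{table.iat[i, j]:.1f}", ha="center", va="center", fontsize=8)
    ax.set_title(f"Mean MID, {direction} ({scale})")
    ax.figure.colorbar(image, ax=ax, shrink=0.8)
    return ax
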