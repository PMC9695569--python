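"""Paired-half discrepancy statistics.

The study's headline quantity: for each metric, the absolute difference
between the light-exposed and the covered half of the same radiograph,
averaged (mean and sample SD) over the repeats of one condition.  The
absolute value is taken per repeat *before* averaging, which matters
once noise makes the signed difference fluctuate.

Metrics that are undefined on a given image (NaN, e.g. SNR on a
noise-free render) propagate as missing values and are excluded from
aggregation; a condition needs at least two defined repeats.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientDataError
from .metrics import METRIC_NAMES

__all__ = ["DiscrepancyRecord", "half_discrepancy", "aggregate_condition",
           "repeat_discrepancies", "aggregate_discrepancies"]

log = logging.getLogger(__name__)

CONDITION_KEYS = ["system", "exposure_time_s", "light_duration_s"]


@dataclass(frozen=True)
class DiscrepancyRecord:
    """Per-condition summary of |exposed - non-exposed| for one metric."""

    system: str
    exposure_time_s: float
    light_duration_s: float
    metric: str
    mean_abs_diff: float
    sd_abs_diff: float
    n_repeats: int


def half_discrepancy(exposed: float, non_exposed: float) -> float:
    """|exposed - non_exposed|; NaN if either half's metric is undefined."""
    if math.isnan(exposed) or math.isnan(non_exposed):
        return math.nan
    return abs(exposed - non_exposed)


def aggregate_condition(per_repeat) -> tuple[float, float, int]:
    """Mean and sample SD of the defined per-repeat discrepancies.

    Returns ``(mean, sd, n_defined)``; raises
    :class:`InsufficientDataError` with fewer than two defined values.
    """
    values = np.asarray([v for v in per_repeat if not math.isnan(v)],
                        dtype=np.float64)
    if values.size < 2:
        raise InsufficientDataError(
            f"need >= 2 defined repeats, got {values.size}"
        )
    return float(values.mean()), float(values.std(ddof=1)), int(values.size)


def repeat_discrepancies(metrics: pd.DataFrame) -> pd.DataFrame:
    """Per-repeat discrepancies from the long metrics table.

    Parameters
    ----------
    metrics
        Long-format table with columns ``system, exposure_time_s,
        light_duration_s, repeat_index, half, metric, value`` (one row
        per image x half x metric).

    Returns
    -------
    Long table with one row per image x metric and a ``discrepancy``
    column; undefined metrics yield NaN.
    """
    wide = metrics.pivot_table(
        index=CONDITION_KEYS + ["repeat_index", "metric"],
        columns="half", values="value", aggfunc="first", dropna=False,
    ).reset_index()
    wide["discrepancy"] = [
        half_discrepancy(e, n)
        for e, n in zip(wide["exposed"], wide["non_exposed"])
    ]
    return wide.drop(columns=["exposed", "non_exposed"])


def aggregate_discrepancies(per_repeat: pd.DataFrame,
                            strict: bool = False) -> pd.DataFrame:
    """Condition-level discrepancy table (one row per condition x metric).

    Conditions with fewer than two defined repeats are reported with
    NaN mean/SD and a warning unless ``strict`` is set, in which case
    they raise.
    """
    rows = []
    grouped = per_repeat.groupby(CONDITION_KEYS + ["metric"], sort=True)
    for (system, exposure, light, metric), grp in grouped:
        try:
            mean, sd, n = aggregate_condition(grp["discrepancy"])
        except InsufficientDataError:
            if strict:
                raise
            log.warning(
                "discrepancy undefined for %s / %.2g s / %g s light / %s: "
                "fewer than 2 defined repeats", system, exposure, light, metric,
            )
            mean, sd, n = math.nan, math.nan, 0
        rows.append({
            "system": system,
            "exposure_time_s": exposure,
            "light_duration_s": light,
            "metric": metric,
            "mean_abs_diff": mean,
            "sd_abs_diff": sd,
            "n_repeats": n,
        })
    out = pd.DataFrame(rows)
    order = {m: i for i, m in enumerate(METRIC_NAMES)}
    out["_m"] = out["metric"].map(order)
    out = (out.sort_values(CONDITION_KEYS + ["_m"])
              .drop(columns="_m").reset_index(drop=True))
    return out
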