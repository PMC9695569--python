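"""Variance-stabilising transform, two-way ANOVA, Tukey HSD, and
compact letter displays for the discrepancy analysis.

The per-repeat discrepancy values of one system and one metric form a
balanced two-factor layout (light duration x X-ray exposure time, ten
replicates per cell).  They are Box-Cox transformed at a fixed power
(0.5 for brightness on both systems; 0.5 / 0.35 for contrast on the
wide- and narrow-range systems respectively), fitted with the classical
fixed-effects two-way ANOVA with interaction, and summarised with Tukey
pairwise comparisons sliced two ways: light durations within each
exposure time (uppercase letters) and exposure times within each light
duration (lowercase letters), both using the pooled residual variance
of the full two-way model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import boxcox as _sc_boxcox
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .errors import LayoutError

__all__ = [
    "BoxCoxSpec",
    "TukeyComparison",
    "boxcox",
    "two_way_anova",
    "tukey_hsd",
    "letter_display",
    "study_table",
    "format_p",
]


@dataclass(frozen=True)
class BoxCoxSpec:
    """Box-Cox power transform with an optional pre-shift.

    ``y = ((x + shift)**lam - 1) / lam`` for ``lam != 0`` and
    ``log(x + shift)`` at ``lam == 0``; strictly increasing in ``x``.
    """

    lam: float
    shift: float = 0.0


def boxcox(x, spec: BoxCoxSpec):
    """Apply the Box-Cox transform; domain error if x + shift <= 0."""
    arr = np.asarray(x, dtype=np.float64) + spec.shift
    if np.any(arr <= 0):
        raise ValueError("Box-Cox input must be positive after shift")
    out = _sc_boxcox(arr, spec.lam)
    return float(out) if np.ndim(x) == 0 else out


def _check_balanced(df: pd.DataFrame, response: str,
                    factor_a: str, factor_b: str) -> None:
    counts = df.groupby([factor_a, factor_b], sort=False)[response].count()
    n_a = df[factor_a].nunique()
    n_b = df[factor_b].nunique()
    if len(counts) != n_a * n_b:
        raise LayoutError("incomplete layout: empty factor cells")
    if counts.nunique() != 1:
        raise LayoutError("unbalanced layout: unequal cell counts")
    if counts.iloc[0] < 2:
        raise LayoutError("at least 2 replicates per cell required")


def two_way_anova(df: pd.DataFrame, response: str,
                  factor_a: str, factor_b: str) -> pd.DataFrame:
    """Balanced fixed-effects two-way ANOVA with interaction.

    Returns a table indexed by ``factor_a``, ``factor_b``,
    ``"{factor_a}:{factor_b}"`` and ``"residual"`` with columns
    ``sum_sq, df, mean_sq, F, p``.  The layout must be complete and
    balanced with at least two replicates per cell.
    """
    _check_balanced(df, response, factor_a, factor_b)
    data = df[[response, factor_a, factor_b]].rename(
        columns={response: "y", factor_a: "A", factor_b: "B"}
    )
    fit = smf.ols("y ~ C(A) * C(B)", data=data).fit()
    table = sm.stats.anova_lm(fit, typ=2)

    index_map = {
        "C(A)": factor_a,
        "C(B)": factor_b,
        "C(A):C(B)": f"{factor_a}:{factor_b}",
        "Residual": "residual",
    }
    out = table.rename(index=index_map)
    out = out.rename(columns={"PR(>F)": "p"})
    out["mean_sq"] = out["sum_sq"] / out["df"]
    out = out[["sum_sq", "df", "mean_sq", "F", "p"]]
    return out.loc[[factor_a, factor_b, f"{factor_a}:{factor_b}", "residual"]]


@dataclass(frozen=True)
class TukeyComparison:
    """One Tukey HSD pairwise comparison on the analysis scale."""

    level_a: object
    level_b: object
    mean_diff: float
    q: float
    p: float
    significant: bool


def tukey_hsd(means: Mapping, ms_residual: float, df_residual: float,
              n_per_group: int, alpha: float = 0.05) -> list[TukeyComparison]:
    """All-pairs Tukey HSD given group means and a pooled error variance.

    ``q = |m_i - m_j| / sqrt(MS_res / n)``; the adjusted p-value comes
    from the studentized range distribution with ``k`` groups and
    ``df_residual`` error degrees of freedom.  Using an externally
    pooled mean square lets slices of a larger model share one error
    estimate.
    """
    if df_residual < 1:
        raise ValueError("df_residual must be >= 1")
    if ms_residual < 0 or n_per_group < 1:
        raise ValueError("invalid error variance or group size")
    levels = list(means.keys())
    k = len(levels)
    se = math.sqrt(ms_residual / n_per_group)
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = levels[i], levels[j]
            diff = means[b] - means[a]
            if se == 0:
                q = math.inf if diff != 0 else 0.0
                p = 0.0 if diff != 0 else 1.0
            else:
                q = abs(diff) / se
                p = float(sps.studentized_range.sf(q, k, df_residual))
                p = min(max(p, 0.0), 1.0)
            out.append(TukeyComparison(
                level_a=a, level_b=b, mean_diff=diff, q=q, p=p,
                significant=p <= alpha,
            ))
    return out


def letter_display(comparisons: Sequence[TukeyComparison],
                   means: Mapping,
                   level_order: Sequence | None = None,
                   letters: str = "ABCDEFGHIJKLMNOPQRSTUVWXYZ") -> dict:
    """Compact letter display by insert-and-absorb.

    Levels sharing at least one letter are exactly the non-significant
    pairs.  Letters are assigned in ascending order of the level means
    (the convention of the study tables, where 'A' marks the no-light
    control with the smallest discrepancy); ties break by
    ``level_order`` (defaults to mapping order of ``means``).
    """
    if level_order is None:
        level_order = list(means.keys())
    rank = {lv: i for i, lv in enumerate(level_order)}
    ordered = sorted(means.keys(), key=lambda lv: (means[lv], rank[lv]))

    sig_pairs = [frozenset((c.level_a, c.level_b))
                 for c in comparisons if c.significant]
    seen = {frozenset((c.level_a, c.level_b)) for c in comparisons}
    expected = {frozenset((a, b)) for i, a in enumerate(ordered)
                for b in ordered[i + 1:]}
    if seen < expected:
        raise ValueError("comparisons must cover all level pairs")

    columns: list[set] = [set(ordered)]
    for pair in sig_pairs:
        a, b = sorted(pair, key=lambda lv: (means[lv], rank[lv]))
        for col in [c for c in columns if a in c and b in c]:
            columns.remove(col)
            columns.extend([col - {a}, col - {b}])
        # absorb: drop columns contained in another
        columns = [c for c in columns
                   if not any(c < d for d in columns) ]
        # drop duplicates while preserving order
        uniq: list[set] = []
        for c in columns:
            if c not in uniq:
                uniq.append(c)
        columns = uniq

    # stable letter order: by first (lowest-mean) member, then size
    def col_key(col: set):
        idx = sorted(ordered.index(lv) for lv in col)
        return (idx[0], idx)

    columns.sort(key=col_key)
    if len(columns) > len(letters):
        raise ValueError("more letter groups than available letters")
    out = {lv: "" for lv in ordered}
    for letter, col in zip(letters, columns):
        for lv in ordered:
            if lv in col:
                out[lv] += letter
    return out


def format_p(p: float, floor: float = 1e-4) -> str:
    """Table-footnote style p-value: values below 1e-4 print as
    ``<0.0001``."""
    if math.isnan(p):
        return "nan"
    if p < floor:
        return "<0.0001"
    return f"{p:.4f}"


def study_table(per_repeat: pd.DataFrame, system: str, metric: str,
                spec: BoxCoxSpec, alpha: float = 0.05,
                light_col: str = "light_duration_s",
                exposure_col: str = "exposure_time_s"):
    """One study-style discrepancy table plus its ANOVA.

    Rows are X-ray exposure times, columns are light durations; each
    cell carries the raw-scale mean and SD over repeats plus a
    significance code: an uppercase letter family comparing light
    durations within the row and a lowercase family comparing exposure
    times within the column.  Both letter families derive from Tukey
    tests on the Box-Cox scale using the pooled residual of the full
    two-way model.

    Returns ``(table, anova)`` data frames.
    """
    sub = per_repeat[(per_repeat["system"] == system)
                     & (per_repeat["metric"] == metric)].copy()
    if sub.empty:
        raise ValueError(f"no rows for system={system!r}, metric={metric!r}")
    sub["transformed"] = boxcox(sub["discrepancy"].to_numpy(), spec)

    anova = two_way_anova(sub, "transformed", light_col, exposure_col)
    ms_res = float(anova.loc["residual", "mean_sq"])
    df_res = float(anova.loc["residual", "df"])

    lights = sorted(sub[light_col].unique())
    exposures = sorted(sub[exposure_col].unique())
    n_rep = sub.groupby([light_col, exposure_col])["transformed"].count().iloc[0]

    upper: dict = {}
    for e in exposures:
        rows = sub[sub[exposure_col] == e]
        means_t = {l: rows.loc[rows[light_col] == l, "transformed"].mean()
                   for l in lights}
        comps = tukey_hsd(means_t, ms_res, df_res, int(n_rep), alpha)
        upper[e] = letter_display(comps, means_t, level_order=lights)

    lower: dict = {}
    for l in lights:
        cols = sub[sub[light_col] == l]
        means_t = {e: cols.loc[cols[exposure_col] == e, "transformed"].mean()
                   for e in exposures}
        comps = tukey_hsd(means_t, ms_res, df_res, int(n_rep), alpha)
        lower[l] = letter_display(
            comps, means_t, level_order=exposures,
            letters="abcdefghijklmnopqrstuvwxyz",
        )

    records = []
    for e in exposures:
        row: dict = {"exposure_time_s": e}
        for l in lights:
            cell = sub[(sub[exposure_col] == e) & (sub[light_col] == l)]
            row[f"mean_{l:g}s"] = cell["discrepancy"].mean()
            row[f"sd_{l:g}s"] = cell["discrepancy"].std(ddof=1)
            row[f"sig_{l:g}s"] = upper[e][l] + lower[l][e]
        records.append(row)
    table = pd.DataFrame(records)
    return table, anova
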