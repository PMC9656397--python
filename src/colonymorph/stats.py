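"""Variance analysis of colony and cell descriptors.

Covers the three statistical views the morphometric study design calls for:

* time-binned dynamics summaries (mean +/- SEM per line and time bin, with
  the late 72-120 h observations pooled into one bin);
* normality-gated two-group comparisons (Welch t-test when both samples
  pass a Shapiro-Wilk gate, Mann-Whitney otherwise);
* two-way line x phenotype ANOVA with Type II sums of squares, reporting
  the interaction term.

The per-line phenotype screen applies the two-group comparison to every
descriptor within the 24-48 h growth window, where phenotypes are scored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .morphometry import CELL_PARAMETERS, COLONY_PARAMETERS

logger = logging.getLogger(__name__)

#: time bins used by all dynamics summaries: 24 h, 48 h, and 72-120 h pooled
TIME_BINS = ("24", "48", "72-120")


class InsufficientDataError(ValueError):
    """Raised when a test is requested on fewer than 3 observations."""


@dataclass
class StatTestResult:
    """Outcome of one hypothesis test."""

    test_name: str  # "t", "mann_whitney" or "anova_interaction"
    statistic: float
    p_value: float
    groups: tuple = ()
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return bool(self.p_value < self.alpha)


def time_bin(time_h: float) -> str:
    """Assign an observation time to its analysis bin."""
    if time_h < 36.0:
        return "24"
    if time_h < 60.0:
        return "48"
    return "72-120"


def _parameters_for(unit: str) -> list[str]:
    return COLONY_PARAMETERS if unit == "colony" else CELL_PARAMETERS


def dynamics_table(records: pd.DataFrame, unit: str = "colony") -> pd.DataFrame:
    """Mean +/- SEM of every descriptor per (line, time bin).

    Late time points (72, 96, 120 h) are pooled into a single bin.  Empty
    (line, bin) combinations are omitted and logged.
    """
    if "time_h" not in records.columns:
        raise ValueError("records must carry a time_h column")
    sub = records[records["unit"] == unit].copy()
    sub["time_bin"] = sub["time_h"].map(time_bin)
    rows = []
    for line, df_line in sub.groupby("line", sort=True):
        seen = set(df_line["time_bin"])
        for missing in set(TIME_BINS) - seen:
            logger.info("dynamics: line %s has no records in bin %s",
                        line, missing)
        for b, df_bin in df_line.groupby("time_bin"):
            for param in _parameters_for(unit):
                vals = df_bin[param].dropna().to_numpy()
                if vals.size == 0:
                    continue
                sem = (vals.std(ddof=1) / np.sqrt(vals.size)
                       if vals.size > 1 else 0.0)
                rows.append({
                    "line": line, "time_bin": b, "parameter": param,
                    "n": vals.size, "mean": vals.mean(), "sem": sem,
                })
    out = pd.DataFrame(rows, columns=["line", "time_bin", "parameter",
                                      "n", "mean", "sem"])
    order = {b: i for i, b in enumerate(TIME_BINS)}
    return out.sort_values(
        ["line", "parameter", "time_bin"],
        key=lambda s: s.map(order) if s.name == "time_bin" else s,
    ).reset_index(drop=True)


def compare_groups(
    x: Sequence[float],
    y: Sequence[float],
    alpha: float = 0.05,
    normality_alpha: float = 0.05,
    groups: tuple = (),
) -> StatTestResult:
    """Two-group location comparison with a normality gate.

    Both samples are screened with the Shapiro-Wilk test; when both are
    compatible with normality the groups are compared with Welch's unequal-
    variance t-test, otherwise with the Mann-Whitney U test.  A sample with
    zero spread never passes the gate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size < 3:
        raise InsufficientDataError(
            f"need >= 3 observations per group, got {x.size} and {y.size}")

    def _normal(v: np.ndarray) -> bool:
        if np.ptp(v) == 0.0:
            return False
        return sps.shapiro(v).pvalue >= normality_alpha

    if _normal(x) and _normal(y):
        res = sps.ttest_ind(x, y, equal_var=False)
        return StatTestResult("t", float(res.statistic), float(res.pvalue),
                              groups, alpha)
    if np.ptp(x) == 0.0 and np.ptp(y) == 0.0 and x[0] == y[0]:
        # both samples are the same constant: no evidence of any difference
        return StatTestResult("mann_whitney", x.size * y.size / 2.0, 1.0,
                              groups, alpha)
    res = sps.mannwhitneyu(x, y, alternative="two-sided")
    return StatTestResult("mann_whitney", float(res.statistic),
                          float(res.pvalue), groups, alpha)


def two_way_anova(
    records: pd.DataFrame,
    response: str,
    factors: tuple[str, str] = ("line", "phenotype"),
    alpha: float = 0.05,
) -> StatTestResult:
    """Interaction term of a two-way ANOVA (Type II sums of squares).

    Type II is appropriate for the unbalanced group sizes typical of colony
    collections.  Requires at least two levels per factor and at least two
    observations in every cell of the design.
    """
    a, b = factors
    df = records[[a, b, response]].dropna()
    for f in factors:
        if df[f].nunique() < 2:
            raise ValueError(f"factor {f!r} needs >= 2 levels")
    counts = df.groupby([a, b], observed=True).size()
    full = pd.MultiIndex.from_product(
        [df[a].unique(), df[b].unique()], names=[a, b])
    counts = counts.reindex(full, fill_value=0)
    bad = counts[counts < 2]
    if len(bad):
        cell = bad.index[0]
        raise ValueError(
            f"design cell {a}={cell[0]!r}, {b}={cell[1]!r} has "
            f"{int(bad.iloc[0])} observation(s); >= 2 required")
    data = df.rename(columns={response: "_y"})
    model = smf.ols(f"_y ~ C({a}) * C({b})", data=data).fit()
    table = sm.stats.anova_lm(model, typ=2)
    row = table.loc[f"C({a}):C({b})"]
    return StatTestResult("anova_interaction", float(row["F"]),
                          float(row["PR(>F)"]), (a, b), alpha)


def phenotype_screen(
    records: pd.DataFrame,
    unit: str = "colony",
    time_window: tuple[float, float] = (24.0, 48.0),
    alpha: float = 0.05,
    holm: bool = False,
) -> pd.DataFrame:
    """Good-vs-bad comparison of every descriptor, per line.

    Restricted to the growth window in which phenotypes are scored
    (24-48 h by default).  Returns one row per (line, parameter) with the
    chosen test, statistic, p-value and significance flag.  ``holm=True``
    applies a Holm correction across the descriptors within each line
    (off by default: each descriptor is reported at its own alpha).
    """
    sub = records[(records["unit"] == unit)
                  & records["time_h"].between(*time_window)]
    rows = []
    for line, df_line in sub.groupby("line", sort=True):
        good = df_line[df_line["phenotype"] == "good"]
        bad = df_line[df_line["phenotype"] == "bad"]
        if good.empty or bad.empty:
            raise ValueError(f"line {line!r} lacks one of the phenotypes")
        for param in _parameters_for(unit):
            res = compare_groups(good[param].dropna(), bad[param].dropna(),
                                 alpha=alpha, groups=(line, param))
            rows.append({
                "line": line, "parameter": param, "test": res.test_name,
                "statistic": res.statistic, "p_value": res.p_value,
                "significant": res.significant,
            })
    out = pd.DataFrame(rows)
    if holm and len(out):
        from statsmodels.stats.multitest import multipletests

        for line in out["line"].unique():
            m = out["line"] == line
            rej, p_adj, *_ = multipletests(out.loc[m, "p_value"],
                                           alpha=alpha, method="holm")
            out.loc[m, "p_value"] = p_adj
            out.loc[m, "significant"] = rej
    return out
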