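"""Relative gene expression from qPCR Ct panels (2^-ddCt).

Quantification follows the classical comparative-Ct method with the
amplification efficiency fixed at 2.  Technical replicates are averaged
first; the biological replicate is the unit of inference:

* per biological replicate, dCt = mean Ct(target) - mean Ct(reference gene)
  and the relative quantity is 2^-dCt;
* the fold change of a group is the mean relative quantity of its
  biological replicates divided by the mean over the reference group's
  replicates (so the reference group's pooled fold change is exactly 1);
* the SEM is taken over biological replicates on the normalized scale, and
  each gene/group is tested against the reference group with the
  normality-gated two-sample comparison from :mod:`colonymorph.stats`.

A reference-gene stability screen ranks housekeeping candidates by the
standard deviation of their per-sample mean Ct (lower = more stable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import compare_groups
from .synth import CtPanel

STAR_THRESHOLDS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))

GROUP_FACTORS = ("line", "clonality", "phenotype")


def stars(p_value: float) -> str:
    """Significance stars: * p<0.05, ** p<0.01, *** p<0.001, **** p<0.0001."""
    for threshold, symbol in STAR_THRESHOLDS:
        if p_value < threshold:
            return symbol
    return "ns"


def reference_stability(panel: CtPanel, candidates: list[str]) -> pd.DataFrame:
    """Rank candidate reference genes by Ct stability across samples.

    The stability score is the SD of the per-sample mean Ct (technical
    replicates averaged); the lowest score ranks first.  Every candidate
    must be measured in every sample.
    """
    sample_cols = ["line", "clonality", "phenotype", "bio_rep"]
    all_samples = set(map(tuple,
                          panel.data[sample_cols].drop_duplicates()
                          .itertuples(index=False)))
    rows = []
    for gene in candidates:
        sub = panel.data[panel.data["gene"] == gene]
        have = set(map(tuple, sub[sample_cols].drop_duplicates()
                       .itertuples(index=False)))
        missing = all_samples - have
        if missing:
            raise ValueError(
                f"candidate {gene!r} not measured in sample {sorted(missing)[0]}")
        per_sample = sub.groupby(sample_cols)["ct"].mean()
        rows.append({"gene": gene,
                     "stability_sd": float(per_sample.std(ddof=1))})
    out = pd.DataFrame(rows).sort_values(
        ["stability_sd", "gene"], kind="stable").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def _relative_quantities(panel: CtPanel, grouping: str) -> pd.DataFrame:
    """Per (gene, group, bio_rep) relative quantity 2^-dCt."""
    sample_cols = ["line", "clonality", "phenotype", "bio_rep"]
    tech_mean = (panel.data.groupby(["gene"] + sample_cols, sort=True)["ct"]
                 .mean().reset_index())
    ref = (tech_mean[tech_mean["gene"] == panel.reference_gene]
           .drop(columns="gene").rename(columns={"ct": "ref_ct"}))
    merged = tech_mean[tech_mean["gene"] != panel.reference_gene].merge(
        ref, on=sample_cols, how="left")
    if merged["ref_ct"].isna().any():
        raise ValueError("reference gene missing for some samples")
    merged["rq"] = 2.0 ** -(merged["ct"] - merged["ref_ct"])
    merged["group"] = merged[grouping]
    return merged


def relative_expression(
    panel: CtPanel,
    grouping: str,
    reference_group: str,
    within: str | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fold changes of every target gene per group versus a reference group.

    ``grouping`` is one of line / clonality / phenotype; ``within``
    optionally stratifies the comparison by another factor (e.g. clonal vs
    nonclonal within each line).  Returns one row per (gene, [stratum,]
    group) with fold_change, sem, p_value and stars; the reference group's
    own fold change is exactly 1 by construction.
    """
    if grouping not in GROUP_FACTORS:
        raise ValueError(f"grouping must be one of {GROUP_FACTORS}")
    merged = _relative_quantities(panel, grouping)
    if reference_group not in set(merged["group"]):
        raise ValueError(f"reference group {reference_group!r} not in panel")
    strata = [None] if within is None else sorted(merged[within].unique())
    rows = []
    for stratum in strata:
        part = merged if stratum is None else merged[merged[within] == stratum]
        for gene, df_gene in part.groupby("gene", sort=True):
            ref_rq = df_gene.loc[df_gene["group"] == reference_group, "rq"]
            if ref_rq.empty:
                raise ValueError(
                    f"reference group {reference_group!r} missing for "
                    f"gene {gene!r}" + (f" in {within}={stratum!r}" if stratum else ""))
            ref_mean = float(ref_rq.mean())
            for group, df_grp in df_gene.groupby("group", sort=True):
                norm = df_grp["rq"].to_numpy() / ref_mean
                fold = float(norm.mean())
                sem = (float(norm.std(ddof=1)) / np.sqrt(norm.size)
                       if norm.size > 1 else 0.0)
                if group == reference_group:
                    p = 1.0
                else:
                    p = compare_groups(df_grp["rq"], ref_rq, alpha=alpha).p_value
                row = {"gene": gene, "group": group, "n_bio": int(norm.size),
                       "fold_change": fold, "sem": sem, "p_value": p,
                       "stars": stars(p) if group != reference_group else "ns"}
                if within is not None:
                    row[within] = stratum
                rows.append(row)
    return pd.DataFrame(rows)


def marker_screen(results: dict[str, pd.DataFrame],
                  alpha: float = 0.05) -> pd.DataFrame:
    """Summarize expression direction and significance per gene x grouping.

    ``results`` maps a grouping name to a table from
    :func:`relative_expression`.  Non-reference groups are classified as
    "over" (fold > 1), "under" (fold < 1) or "none" (fold = 1), with the
    significance flag carried along — the machine-readable analog of
    narrating which markers respond to which grouping.
    """
    rows = []
    for grouping, table in results.items():
        if table.empty:
            continue
        for _, r in table.iterrows():
            if r["fold_change"] == 1.0 and r["p_value"] == 1.0:
                continue  # reference group rows
            if r["fold_change"] > 1.0:
                direction = "over"
            elif r["fold_change"] < 1.0:
                direction = "under"
            else:
                direction = "none"
            row = {"grouping": grouping, "gene": r["gene"],
                   "group": r["group"], "direction": direction,
                   "significant": bool(r["p_value"] < alpha),
                   "fold_change": r["fold_change"]}
            for extra in ("line", "clonality"):
                if extra in table.columns and extra != "group":
                    row[extra] = r.get(extra)
            rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# model / results facade
# --------------------------------------------------------------------------

class RelativeExpressionModel:
    """Comparative-Ct analysis of one panel, statsmodels-style.

    ``fit()`` screens the housekeeping candidates (when present), computes
    fold changes versus the reference group and returns a results object
    with the tables and a text summary.
    """

    def __init__(self, panel: CtPanel, grouping: str, reference_group: str,
                 within: str | None = None,
                 housekeeping_candidates: list[str] | None = None):
        self.panel = panel
        self.grouping = grouping
        self.reference_group = reference_group
        self.within = within
        self.housekeeping_candidates = housekeeping_candidates

    def fit(self, alpha: float = 0.05) -> "RelativeExpressionResults":
        stability = None
        if self.housekeeping_candidates:
            stability = reference_stability(self.panel,
                                            self.housekeeping_candidates)
        table = relative_expression(self.panel, self.grouping,
                                    self.reference_group, self.within, alpha)
        screen = marker_screen({self.grouping: table}, alpha)
        return RelativeExpressionResults(self, table, screen, stability)


@dataclass
class RelativeExpressionResults:
    model: RelativeExpressionModel
    table: pd.DataFrame
    screen: pd.DataFrame
    stability: pd.DataFrame | None = None

    def summary(self) -> str:
        out = [
            "Relative expression (2^-ddCt)",
            "=" * 30,
            f"grouping: {self.model.grouping}   reference group: "
            f"{self.model.reference_group}   reference gene: "
            f"{self.model.panel.reference_gene}",
        ]
        if self.stability is not None:
            out += ["", "reference-gene stability (SD of sample-mean Ct):",
                    self.stability.to_string(index=False)]
        show = self.table.copy()
        show["fold_change"] = show["fold_change"].map("{:.3f}".format)
        show["sem"] = show["sem"].map("{:.3f}".format)
        show["p_value"] = show["p_value"].map("{:.3g}".format)
        out += ["", show.to_string(index=False)]
        return "\n".join(out)
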