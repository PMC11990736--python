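"""Post-classification phenotype comparison across trajectory groups.

Once subjects are assigned to trajectory groups, consumption (or any side
channel such as body weight, food or water intake) is summarized as group
mean +/- SEM over 5-day bins, compared by a group x time factorial ANOVA on
subject-level bin means with Tukey HSD contrasts among groups within each
bin, and each bin is labeled with a phase describing which groups are
separable there. A group x regimen cross-tabulation describes how the
assignment distributes over experimental regimens.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.formula.api import ols
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .simulate import bin_average

__all__ = [
    "ComparisonResult",
    "summarize_groups",
    "two_way_anova_tukey",
    "label_phases",
    "regimen_crosstab",
    "plot_group_trajectories",
]


@dataclass
class ComparisonResult:
    anova: pd.DataFrame           # F and p for group, time, interaction
    tukey: pd.DataFrame           # per-bin pairwise group contrasts, adjusted p
    phases: pd.DataFrame          # per-bin phase label
    binned: pd.DataFrame          # subject-level bin means the tests ran on
    alpha: float = 0.05


def _binned_subject_table(data: pd.DataFrame, assignments: pd.Series, bin_width: int) -> pd.DataFrame:
    binned = bin_average(data, bin_width)
    assignments = pd.Series(assignments)
    assignments.index.name = "subject_id"
    missing = set(binned["subject_id"]) - set(assignments.index)
    if missing:
        raise ValueError(f"subjects without a group assignment: {sorted(missing)[:5]}")
    out = binned.merge(assignments.rename("group"), left_on="subject_id", right_index=True)
    return out[["subject_id", "group", "bin", "value"]]


def summarize_groups(data: pd.DataFrame, assignments: pd.Series, bin_width: int = 5) -> pd.DataFrame:
    """Group mean +/- SEM per 5-day bin, computed over subject-level bin means.

    SEM = sd/sqrt(n) with n the subjects contributing to the bin; a group
    with a single subject in a bin gets a missing SEM, never a fabricated 0.
    """
    table = _binned_subject_table(data, assignments, bin_width)
    out = (
        table.groupby(["group", "bin"])["value"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
        .reset_index()
    )
    out["sem"] = out["sd"] / np.sqrt(out["n"])
    out.loc[out["n"] < 2, ["sd", "sem"]] = np.nan
    return out[["group", "bin", "mean", "sem", "n"]]


def two_way_anova_tukey(data: pd.DataFrame, assignments: pd.Series, bin_width: int = 5,
                        alpha: float = 0.05) -> ComparisonResult:
    """Group x time factorial ANOVA with per-bin Tukey HSD group contrasts.

    The observational unit is the subject-level bin mean. The ANOVA tests the
    group and time main effects and their interaction; Tukey HSD is run among
    groups separately within each bin, mirroring per-timepoint significance
    marks on longitudinal summary figures.
    """
    table = _binned_subject_table(data, assignments, bin_width)
    groups = sorted(table["group"].unique())
    bins = sorted(table["bin"].unique())
    if len(groups) < 2 or len(bins) < 2:
        raise ValueError("need at least two groups and two bins for a two-way ANOVA")
    counts = table.groupby(["group", "bin"]).size()
    full = pd.MultiIndex.from_product([groups, bins], names=["group", "bin"])
    empty = full.difference(counts.index)
    if len(empty):
        raise ValueError(f"empty (group, bin) cell(s): {list(empty[:5])}")

    model = ols("value ~ C(group) * C(bin)", data=table).fit()
    anova = sm.stats.anova_lm(model, typ=2).rename_axis("term").reset_index()
    anova["term"] = anova["term"].map(
        {"C(group)": "group", "C(bin)": "time", "C(group):C(bin)": "group:time",
         "Residual": "residual"})

    rows = []
    for b in bins:
        sub = table[table["bin"] == b]
        res = pairwise_tukeyhsd(sub["value"].to_numpy(), sub["group"].to_numpy(), alpha=alpha)
        frame = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
        for _, r in frame.iterrows():
            rows.append({"bin": b, "group_a": r["group1"], "group_b": r["group2"],
                         "meandiff": float(r["meandiff"]), "p_adj": float(r["p-adj"]),
                         "significant": bool(r["reject"])})
    tukey = pd.DataFrame(rows)
    group_means = table.groupby(["group", "bin"])["value"].mean()
    if len(groups) >= 3:
        phases = label_phases(tukey, group_means)
    else:
        phases = pd.DataFrame(columns=["bin", "phase"])
    return ComparisonResult(anova=anova, tukey=tukey, phases=phases, binned=table, alpha=alpha)


def label_phases(tukey: pd.DataFrame, group_bin_means: pd.Series) -> pd.DataFrame:
    """Label each bin by which groups are separable there.

    With the groups ranked low/mid/high by their bin means:
    ``early``      low and mid indistinguishable, both below the top group;
    ``transition`` all three pairwise distinct;
    ``end``        mid and high indistinguishable, both above the lowest;
    anything else is ``other``. Needs at least three groups.
    """
    groups = sorted({*tukey["group_a"], *tukey["group_b"]})
    if len(groups) < 3:
        raise ValueError("phase labeling needs at least three groups")
    rows = []
    for b, sub in tukey.groupby("bin"):
        means = group_bin_means.xs(b, level="bin")
        low, mid, high = list(means.sort_values().index)[:3]

        def distinct(a, c):
            m = sub[((sub["group_a"] == a) & (sub["group_b"] == c))
                    | ((sub["group_a"] == c) & (sub["group_b"] == a))]
            return bool(m["significant"].iloc[0]) if len(m) else False

        lm, lh, mh = distinct(low, mid), distinct(low, high), distinct(mid, high)
        if not lm and lh and mh:
            label = "early"
        elif lm and lh and mh:
            label = "transition"
        elif lm and lh and not mh:
            label = "end"
        else:
            label = "other"
        rows.append({"bin": b, "phase": label})
    return pd.DataFrame(rows)


def plot_group_trajectories(summary: pd.DataFrame, path=None, ylabel="consumption (g/kg/day)",
                            bin_width: int = 5):
    """Plot group mean +/- SEM over bins from a ``summarize_groups`` table.

    Writes to ``path`` when given (format inferred from the extension) and
    returns the matplotlib figure.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for group, sub in summary.groupby("group"):
        days = sub["bin"] * bin_width - bin_width / 2
        ax.errorbar(days, sub["mean"], yerr=sub["sem"], marker="o", capsize=3,
                    label=f"group {group}")
    ax.set_xlabel("study day (bin midpoint)")
    ax.set_ylabel(ylabel)
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
    return fig


def regimen_crosstab(assignments: pd.Series, regimens: pd.Series) -> pd.DataFrame:
    """Group x regimen contingency counts (descriptive; no test attached)."""
    assignments = pd.Series(assignments)
    regimens = pd.Series(regimens)
    missing = set(assignments.index) - set(regimens.index)
    if missing:
        raise ValueError(f"subjects without a regimen label: {sorted(missing)[:5]}")
    aligned = regimens.reindex(assignments.index)
    out = pd.crosstab(assignments, aligned)
    out.index.name = "group"
    out.columns.name = "regimen"
    return out
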