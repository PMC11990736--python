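"""Group-wise phenotype comparison: binned summaries, ANOVA/Tukey, phases, crosstab."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from gbtm.compare import (
    label_phases,
    regimen_crosstab,
    summarize_groups,
    two_way_anova_tukey,
)
from gbtm.datasets import reference_assignments, reference_regimens


def make_table(groups, n_per_group, bins, rng, shift=None):
    """Subject x day table with one observation per (subject, day in bin)."""
    rows = []
    sid = 0
    for g_idx, g in enumerate(groups):
        for _ in range(n_per_group):
            sid += 1
            for b in bins:
                for d in range((b - 1) * 5 + 1, b * 5 + 1):
                    mu = 0.0 if shift is None else shift[g_idx][b - 1]
                    rows.append({"subject_id": sid, "group": g, "day": d,
                                 "value": mu + rng.standard_normal()})
    return pd.DataFrame(rows)


class TestSummarizeGroups:
    def test_constant_values_have_zero_sem(self):
        data = pd.DataFrame({"subject_id": np.repeat([1, 2, 3], 5),
                             "day": np.tile(range(1, 6), 3), "value": 2.0})
        assignments = pd.Series([1, 1, 1], index=[1, 2, 3])
        out = summarize_groups(data, assignments)
        assert (out["mean"] == 2.0).all() and (out["sem"] == 0.0).all()

    def test_two_subject_sem(self):
        data = pd.DataFrame({"subject_id": [1, 2], "day": [1, 1], "value": [1.0, 3.0]})
        out = summarize_groups(data, pd.Series([1, 1], index=[1, 2]))
        assert out.loc[0, "mean"] == 2.0 and out.loc[0, "sem"] == 1.0

    def test_singleton_group_sem_missing(self):
        data = pd.DataFrame({"subject_id": [1, 2], "day": [1, 1], "value": [1.0, 3.0]})
        out = summarize_groups(data, pd.Series([1, 2], index=[1, 2]))
        assert out["sem"].isna().all() and (out["n"] == 1).all()

    def test_default_cohort_group_sizes(self, default_cohort):
        assignments = default_cohort.groupby("subject_id")["latent_group"].first()
        out = summarize_groups(default_cohort, assignments)
        sizes = out.groupby("group")["n"].max()
        assert sizes.to_dict() == {1: 4, 2: 26, 3: 5}

    def test_unassigned_subject_rejected(self):
        data = pd.DataFrame({"subject_id": [1, 2], "day": [1, 1], "value": [1.0, 3.0]})
        with pytest.raises(ValueError, match="assignment"):
            summarize_groups(data, pd.Series([1], index=[1]))


class TestAnovaTukey:
    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(0)
        data = make_table([1, 2], 8, [1, 2, 3], rng)
        res = two_way_anova_tukey(data.drop(columns=["group"]),
                                  data.groupby("subject_id")["group"].first())
        assert (res.tukey["p_adj"] > 0.05).all()
        assert res.tukey["p_adj"].ge(0.0).all()

    def test_separated_groups_flagged_every_bin(self):
        rng = np.random.default_rng(1)
        shift = [[0.0] * 3, [5.0] * 3]
        data = make_table([1, 2], 8, [1, 2, 3], rng, shift=shift)
        res = two_way_anova_tukey(data.drop(columns=["group"]),
                                  data.groupby("subject_id")["group"].first())
        assert res.tukey["significant"].all()
        anova_p = res.anova.set_index("term")["PR(>F)"]
        assert anova_p["group"] < 1e-6

    def test_empty_cell_named(self):
        rng = np.random.default_rng(2)
        data = make_table([1, 2], 3, [1, 2], rng)
        drop = (data["group"] == 2) & (data["day"] > 5)
        data = data[~drop]
        with pytest.raises(ValueError, match="cell"):
            two_way_anova_tukey(data.drop(columns=["group"]),
                                data.groupby("subject_id")["group"].first())

    def test_null_interaction_pvalues_uniform(self):
        """Under exchangeable groups the interaction p-value is uniform;
        KS test over 200 simulated datasets must not reject at 0.01."""
        rng = np.random.default_rng(3)
        pvals = []
        for _ in range(200):
            data = make_table([1, 2, 3], 4, [1, 2], rng)
            res = two_way_anova_tukey(data.drop(columns=["group"]),
                                      data.groupby("subject_id")["group"].first())
            pvals.append(res.anova.set_index("term").loc["group:time", "PR(>F)"])
        assert kstest(pvals, "uniform").pvalue > 0.01


class TestPhases:
    def _tukey_frame(self, sig):
        rows = []
        for (a, b), s in sig.items():
            rows.append({"bin": 1, "group_a": a, "group_b": b, "meandiff": 0.0,
                         "p_adj": 0.01 if s else 0.9, "significant": s})
        return pd.DataFrame(rows)

    def _means(self, m):
        return pd.Series(m, index=pd.MultiIndex.from_product(
            [[1, 2, 3], [1]], names=["group", "bin"]))

    @pytest.mark.parametrize(
        "sig, expected",
        [
            ({(1, 2): False, (1, 3): True, (2, 3): True}, "early"),
            ({(1, 2): True, (1, 3): True, (2, 3): True}, "transition"),
            ({(1, 2): True, (1, 3): True, (2, 3): False}, "end"),
            ({(1, 2): False, (1, 3): False, (2, 3): False}, "other"),
        ],
    )
    def test_pattern_labels(self, sig, expected):
        # group means ranked 1 < 2 < 3 in the bin
        phases = label_phases(self._tukey_frame(sig), self._means([0.5, 1.0, 5.0]))
        assert phases.loc[0, "phase"] == expected

    def test_end_pattern_uses_value_ranks_not_labels(self):
        # the low-consumption group is group 2; groups 1 and 3 converge high
        sig = {(1, 2): True, (1, 3): False, (2, 3): True}
        phases = label_phases(self._tukey_frame(sig), self._means([5.0, 1.0, 5.5]))
        assert phases.loc[0, "phase"] == "end"

    def test_needs_three_groups(self):
        frame = self._tukey_frame({(1, 2): True})
        with pytest.raises(ValueError, match="three groups"):
            label_phases(frame, self._means([1.0, 2.0, 3.0]))

    def test_default_cohort_progression(self, default_cohort):
        """Latent groups of the default cohort separate early -> transition -> end."""
        assignments = default_cohort.groupby("subject_id")["latent_group"].first()
        res = two_way_anova_tukey(default_cohort, assignments)
        phases = res.phases.set_index("bin")["phase"]
        assert phases.iloc[0] in ("early", "other")
        assert "early" in set(phases.values)
        assert phases.iloc[-1] in ("end", "other")
        # the late-drinker rise produces a fully separated window somewhere
        order = {"early": 0, "transition": 1, "end": 2}
        known = [order[p] for p in phases if p in order]
        assert known == sorted(known)


class TestRegimenCrosstab:
    def test_reference_assignment_counts(self):
        """The published classification splits the late drinkers 2/2 and the
        early drinkers 3/2 across the 5% and 10% regimens."""
        table = regimen_crosstab(reference_assignments(), reference_regimens())
        assert table.loc[1].to_dict() == {"5pct": 2, "10pct": 2}
        assert table.loc[3].to_dict() == {"5pct": 3, "10pct": 2}
        assert table.loc[2].sum() == 26

    def test_row_sums_match_group_sizes(self):
        table = regimen_crosstab(reference_assignments(), reference_regimens())
        assert table.sum(axis=1).to_dict() == {1: 4, 2: 26, 3: 5}
        assert table.to_numpy().sum() == 35

    def test_single_regimen_single_column(self):
        assignments = pd.Series([1, 1, 2], index=[1, 2, 3])
        regimens = pd.Series(["5pct"] * 3, index=[1, 2, 3])
        table = regimen_crosstab(assignments, regimens)
        assert list(table.columns) == ["5pct"] and table["5pct"].sum() == 3

    def test_missing_regimen_rejected(self):
        with pytest.raises(ValueError, match="regimen"):
            regimen_crosstab(pd.Series([1], index=[1]), pd.Series([], dtype=object))


class TestPlot:
    def test_plot_writes_figure(self, default_cohort, tmp_path):
        from gbtm.compare import plot_group_trajectories
        assignments = default_cohort.groupby("subject_id")["latent_group"].first()
        summary = summarize_groups(default_cohort, assignments)
        out = tmp_path / "trajectories.png"
        fig = plot_group_trajectories(summary, out)
        assert out.exists() and out.stat().st_size > 0
        assert len(fig.axes[0].lines) >= 3
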