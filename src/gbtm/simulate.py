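"""Synthetic two-bottle-choice cohorts with latent trajectory-group structure.

Emulates a 35-mouse voluntary alcohol consumption study: three latent groups
(late drinkers, non-drinkers, early drinkers) with quadratic mean curves over
study days, censored-normal noise (consumption cannot go below 0 g/kg/day),
daily observations on days 6-57 and a handful of missing cells, plus a
5%-vs-10% alcohol-solution regimen label carried as metadata. The default
parameters are the fitted values of the reference cohort, so downstream
estimation, selection and comparison stages can be exercised end to end
without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .likelihood import design_matrix

__all__ = [
    "StudyDesign",
    "GeneratingModel",
    "default_design",
    "default_generating_model",
    "generate_cohort",
    "bin_average",
    "generate_covariate_channels",
]

# Fitted three-group quadratic model of the reference cohort: coefficients are
# (intercept, linear, quadratic) in g/kg/day over raw study day.
REFERENCE_COEFFICIENTS = (
    (1.39009, -0.05619, 0.00262),   # group 1: late drinkers  (n = 4)
    (1.61339, -0.061, 0.00109),     # group 2: non-drinkers   (n = 26)
    (2.4755, 0.19721, -0.00225),    # group 3: early drinkers (n = 5)
)
REFERENCE_SIGMA = 1.60771
REFERENCE_GROUP_SIZES = (4, 26, 5)

# Subject numbers of the reference cohort's late- and early-drinker groups;
# used so the default cohort reproduces the published regimen cross-tab.
REFERENCE_GROUP1_SUBJECTS = (1, 18, 29, 31)
REFERENCE_GROUP3_SUBJECTS = (7, 13, 14, 24, 30)


def _default_regimen_rule(subject_id: int) -> str:
    """Subjects 1-18 received the 5% solution regimen, 19-35 the 10% regimen."""
    return "5pct" if subject_id <= 18 else "10pct"


@dataclass
class StudyDesign:
    """Observation schedule and latent-group layout of a simulated cohort."""

    n_subjects: int = 35
    group_sizes: tuple[int, ...] = REFERENCE_GROUP_SIZES
    observation_days: tuple[int, ...] = tuple(range(6, 58))
    n_missing: int = 15
    regimen_rule: object = _default_regimen_rule
    group_assignment: tuple[int, ...] | None = None  # 1-based latent group per subject
    seed: int = 0

    def __post_init__(self):
        self.group_sizes = tuple(int(g) for g in self.group_sizes)
        self.observation_days = tuple(int(d) for d in self.observation_days)
        if sum(self.group_sizes) != self.n_subjects:
            raise ValueError(
                f"group_sizes sum to {sum(self.group_sizes)}, expected n_subjects={self.n_subjects}"
            )
        if any(g < 1 for g in self.group_sizes):
            raise ValueError("every latent group must have at least one subject")
        days = np.asarray(self.observation_days)
        if len(days) == 0 or np.any(np.diff(days) <= 0) or days[0] < 1:
            raise ValueError("observation_days must be strictly increasing integers >= 1")
        if not 0 <= self.n_missing < self.n_subjects * len(days):
            raise ValueError(
                f"n_missing={self.n_missing} must be < n_subjects x n_days "
                f"= {self.n_subjects * len(days)}"
            )
        if self.group_assignment is not None:
            ga = tuple(int(g) for g in self.group_assignment)
            if len(ga) != self.n_subjects:
                raise ValueError("group_assignment must give one latent group per subject")
            counts = [ga.count(j + 1) for j in range(len(self.group_sizes))]
            if counts != list(self.group_sizes):
                raise ValueError(
                    f"group_assignment counts {counts} disagree with group_sizes {list(self.group_sizes)}"
                )
            self.group_assignment = ga

    @property
    def n_groups(self) -> int:
        return len(self.group_sizes)

    def resolve_assignment(self, rng: np.random.Generator) -> np.ndarray:
        """Latent group label (1-based) for subjects 1..n, fixed or seeded shuffle."""
        if self.group_assignment is not None:
            return np.asarray(self.group_assignment, dtype=int)
        labels = np.repeat(np.arange(1, self.n_groups + 1), self.group_sizes)
        return rng.permutation(labels)


@dataclass
class GeneratingModel:
    """Ground-truth censored-normal trajectory mixture used for simulation."""

    coefficients: tuple = REFERENCE_COEFFICIENTS
    sigma: float = REFERENCE_SIGMA
    lower_bound: float = 0.0
    upper_bound: float = np.inf

    def __post_init__(self):
        self.coefficients = tuple(np.asarray(b, dtype=float) for b in self.coefficients)
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        if not self.lower_bound < self.upper_bound:
            raise ValueError("lower_bound must be strictly below upper_bound")

    @property
    def n_groups(self) -> int:
        return len(self.coefficients)

    def mean_curve(self, group: int, days) -> np.ndarray:
        """Latent mean of 1-based group over an array of study days."""
        beta = self.coefficients[group - 1]
        return design_matrix(days, len(beta) - 1) @ beta


def default_design(seed: int = 0) -> StudyDesign:
    """The reference study layout: 35 subjects, groups 4/26/5 on the published
    subject numbers, daily observations on days 6-57, 15 missing cells."""
    assignment = [2] * 35
    for s in REFERENCE_GROUP1_SUBJECTS:
        assignment[s - 1] = 1
    for s in REFERENCE_GROUP3_SUBJECTS:
        assignment[s - 1] = 3
    return StudyDesign(group_assignment=tuple(assignment), seed=seed)


def default_generating_model() -> GeneratingModel:
    return GeneratingModel()


def scenario(name: str, seed: int = 0) -> tuple[StudyDesign, GeneratingModel]:
    """Named generating scenarios for selection-procedure studies.

    ``reference``   three groups with the fitted parameters (the default);
    ``homogeneous`` a single group on the non-drinker curve (k = 1 truth);
    ``two_group``   non-drinkers vs early drinkers only (k = 2 truth).
    All share the reference schedule (35 subjects, days 6-57, 15 missing
    cells) and sigma so that only the latent group structure differs.
    """
    if name == "reference":
        return default_design(seed=seed), default_generating_model()
    if name == "homogeneous":
        design = StudyDesign(group_sizes=(35,), seed=seed)
        model = GeneratingModel(coefficients=(REFERENCE_COEFFICIENTS[1],))
        return design, model
    if name == "two_group":
        design = StudyDesign(group_sizes=(26, 9), seed=seed)
        model = GeneratingModel(coefficients=(REFERENCE_COEFFICIENTS[1],
                                              REFERENCE_COEFFICIENTS[2]))
        return design, model
    raise ValueError(f"unknown scenario '{name}'")


def generate_cohort(design: StudyDesign, model: GeneratingModel, seed: int | None = None) -> pd.DataFrame:
    """Simulate a long-format cohort table.

    One row per retained (subject, day): latent normal draw around the
    subject's group curve, clipped to the censoring bounds; exactly
    ``design.n_missing`` cells are removed uniformly at random. Deterministic
    given the seed (``design.seed`` unless overridden).

    Columns: subject_id, latent_group, day, value, regimen. The latent_group
    column is ground truth for recovery tests only; estimation never reads it.
    """
    if model.n_groups != design.n_groups:
        raise ValueError(
            f"model has {model.n_groups} groups but design specifies {design.n_groups}"
        )
    rng = np.random.default_rng(design.seed if seed is None else seed)
    groups = design.resolve_assignment(rng)
    days = np.asarray(design.observation_days, dtype=int)
    n, t = design.n_subjects, len(days)

    mu = np.vstack([model.mean_curve(g, days.astype(float)) for g in groups])  # (n, t)
    latent = mu + model.sigma * rng.standard_normal((n, t))
    values = np.clip(latent, model.lower_bound, model.upper_bound)

    keep = np.ones(n * t, dtype=bool)
    if design.n_missing:
        keep[rng.choice(n * t, size=design.n_missing, replace=False)] = False

    subject_ids = np.repeat(np.arange(1, n + 1), t)
    table = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "latent_group": np.repeat(groups, t),
            "day": np.tile(days, n),
            "value": values.ravel(),
            "regimen": [design.regimen_rule(int(s)) for s in subject_ids],
        }
    )
    return table.loc[keep].reset_index(drop=True)


def bin_average(data: pd.DataFrame, bin_width_days: int = 5) -> pd.DataFrame:
    """Per-subject means over consecutive non-overlapping day bins.

    Bins are anchored at day 1 (bin b covers days 1+(b-1)*w .. b*w); the mean
    is over the non-missing days in the bin, and empty bins are absent.
    """
    if bin_width_days < 1:
        raise ValueError(f"bin_width_days must be >= 1, got {bin_width_days}")
    if len(data) == 0:
        return pd.DataFrame(columns=["subject_id", "bin", "value"])
    out = data.copy()
    out["bin"] = (out["day"].astype(int) - 1) // bin_width_days + 1
    keys = ["subject_id", "bin"]
    carried = [c for c in ("latent_group", "regimen") if c in out.columns]
    agg = {"value": "mean", **{c: "first" for c in carried}}
    return out.groupby(keys, as_index=False).agg(agg)


def generate_covariate_channels(
    design: StudyDesign,
    channel_group_means: dict | None = None,
    channel_sds: dict | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate side channels (body weight, food, water intake) per subject/day.

    ``channel_group_means`` maps channel name to one value per latent group —
    either a scalar (flat over the study) or an array over observation days.
    Defaults emulate the reference phenotypes: body-weight growth and food
    intake indistinguishable across groups, water intake lower for the
    early-drinker group. Values are group mean plus Gaussian noise,
    deterministic given the seed.
    """
    if channel_group_means is None:
        days = np.asarray(design.observation_days, dtype=float)
        growth = 14.0 + 0.38 * days  # g, ~16 g at 4 weeks to ~36 g at 11 weeks
        k = design.n_groups
        channel_group_means = {
            "body_weight": [growth] * k,
            "food": [5.0] * k,                       # g/day, flat and equal
            "water": [150.0] * (k - 1) + [110.0],    # mL/kg/day; last group drinks less water
        }
    if channel_sds is None:
        channel_sds = {"body_weight": 1.5, "food": 0.6, "water": 18.0}

    rng = np.random.default_rng(design.seed if seed is None else seed)
    groups = design.resolve_assignment(rng)
    days = np.asarray(design.observation_days, dtype=int)
    n, t = design.n_subjects, len(days)
    frames = []
    for channel, means in channel_group_means.items():
        sd = float(channel_sds.get(channel, 0.0))
        mu = np.vstack([np.broadcast_to(np.asarray(means[g - 1], dtype=float), (t,)) for g in groups])
        values = mu + sd * rng.standard_normal((n, t))
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": np.repeat(np.arange(1, n + 1), t),
                    "latent_group": np.repeat(groups, t),
                    "day": np.tile(days, n),
                    "channel": channel,
                    "value": values.ravel(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
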