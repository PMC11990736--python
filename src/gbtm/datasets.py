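"""Reference worked example: the published three-group classification of a
35-mouse voluntary alcohol consumption cohort.

The raw consumption data of that cohort were not released; what is available
is its fitted three-group quadratic model (the generating defaults of
:mod:`gbtm.simulate`), the per-mouse posterior probability matrix, and the
resulting group assignment. These are bundled here as a worked example for
the classification and cross-tabulation operations and for documentation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "reference_posterior_matrix",
    "reference_assignments",
    "reference_regimens",
]

# (mouse number, P(group 1), P(group 2), P(group 3)); groups are late
# drinkers, non-drinkers, early drinkers. Every entry is within 0.001 of 0
# or 1 except mouse 29's split between groups 1 and 2.
_REFERENCE_BPP = [
    (1, 1.0, 0.0, 0.0),
    (2, 0.0, 1.0, 0.0),
    (3, 0.0, 1.0, 0.0),
    (4, 0.0, 1.0, 0.0),
    (5, 0.0, 1.0, 0.0),
    (6, 0.0, 1.0, 0.0),
    (7, 0.0, 0.0, 1.0),
    (8, 0.0, 1.0, 0.0),
    (9, 0.0, 1.0, 0.0),
    (10, 0.0, 1.0, 0.0),
    (11, 0.0, 1.0, 0.0),
    (12, 0.0, 1.0, 0.0),
    (13, 0.0, 0.0, 1.0),
    (14, 0.0, 0.0, 1.0),
    (15, 0.0, 1.0, 0.0),
    (16, 0.0, 1.0, 0.0),
    (17, 0.0, 1.0, 0.0),
    (18, 1.0, 0.0, 0.0),
    (19, 0.0, 1.0, 0.0),
    (20, 0.0, 1.0, 0.0),
    (21, 0.0, 1.0, 0.0),
    (22, 0.0, 1.0, 0.0),
    (23, 0.0, 1.0, 0.0),
    (24, 0.0, 0.0, 1.0),
    (25, 0.0, 1.0, 0.0),
    (26, 0.0, 1.0, 0.0),
    (27, 0.0, 1.0, 0.0),
    (28, 0.0, 1.0, 0.0),
    (29, 0.999473, 0.000527, 0.0),
    (30, 0.0, 0.0, 1.0),
    (31, 1.0, 0.0, 0.0),
    (32, 0.0, 1.0, 0.0),
    (33, 0.0, 1.0, 0.0),
    (34, 0.0, 1.0, 0.0),
    (35, 0.0, 1.0, 0.0),
]


def reference_posterior_matrix() -> pd.DataFrame:
    """Per-mouse posterior membership probabilities of the reference cohort."""
    frame = pd.DataFrame(_REFERENCE_BPP, columns=["subject_id", "group_1", "group_2", "group_3"])
    return frame.set_index("subject_id")


def reference_assignments() -> pd.Series:
    """Published hard group assignment (argmax of the posterior matrix)."""
    probs = reference_posterior_matrix()
    return pd.Series(np.argmax(probs.to_numpy(), axis=1) + 1, index=probs.index, name="group")


def reference_regimens() -> pd.Series:
    """Regimen labels by the study numbering rule: mice 1-18 got the 5%
    alcohol solution, mice 19-35 the 10% solution."""
    ids = pd.Index(range(1, 36), name="subject_id")
    return pd.Series(["5pct" if i <= 18 else "10pct" for i in ids], index=ids, name="regimen")
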