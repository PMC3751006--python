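"""Shared helpers for the test suite."""

import numpy as np

from prediasim.decision_tree import CohortAssignments


def igt_cohort(n, receives=False):
    """A cohort of baseline-IGT subjects, optionally all intervening."""
    return CohortAssignments(
        state=np.full(n, "igt", dtype="<U8"),
        diagnosed=np.full(n, True),
        receives_intervention=np.full(n, receives),
        screened=np.full(n, True),
        screening_cost=np.full(n, 3.0),
    )
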