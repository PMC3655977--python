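"""Empirical tail probabilities for Monte Carlo nulls.

P_upper and P_lower are the fractions of null replicates with statistic
greater-or-equal / less-or-equal than the observed value.  Ties count in
both tails, so with no invalid replicates ``p_upper + p_lower >= 1``.
Comparisons are exact floating-point comparisons: the statistics served
here are ratios of small-integer arithmetic where exact ties are
meaningful; callers needing tolerance must round explicitly.
"""

from __future__ import annotations

import numpy as np


def empirical_p_values(
    observed: float,
    nulls: np.ndarray | list[float],
    *,
    add_pseudocount: bool = False,
) -> tuple[float, float]:
    """Return (p_upper, p_lower) over the valid (finite) null values.

    NaN/inf entries (replicates whose statistic was undefined) are excluded
    from both fractions.  ``add_pseudocount=True`` applies the (r+1)/(R+1)
    correction as a sensitivity option; the default is the plain fraction.
    """
    nulls = np.asarray(nulls, dtype=float)
    valid = nulls[np.isfinite(nulls)]
    if valid.size == 0:
        raise ValueError("empirical_p_values: no valid null replicates")
    ge = int(np.count_nonzero(valid >= observed))
    le = int(np.count_nonzero(valid <= observed))
    if add_pseudocount:
        return (ge + 1) / (valid.size + 1), (le + 1) / (valid.size + 1)
    return ge / valid.size, le / valid.size


def count_invalid(nulls: np.ndarray | list[float]) -> int:
    nulls = np.asarray(nulls, dtype=float)
    return int(nulls.size - np.count_nonzero(np.isfinite(nulls)))
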