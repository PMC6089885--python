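"""Group-comparison statistics for per-monomer transport metrics.

Per-monomer permeation counts are small samples and far from normal, so
groups are compared with the two-sided Mann-Whitney U test: exact
p-values (full enumeration of rank assignments) for small tie-free
samples, a tie-corrected normal approximation with continuity correction
otherwise.  Summaries are arithmetic mean ± sample standard deviation
(n−1 denominator).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .errors import InputError, ParameterError

#: largest tie-free sample sizes for which the exact null is enumerated
EXACT_LIMIT = 12


@dataclass(frozen=True)
class GroupComparison:
    U: float  # min(U1, U2) convention
    p_two_sided: float
    method: str  # "exact" or "normal_approx"
    n1: int
    n2: int


def mann_whitney_u(
    sample1: Sequence[float],
    sample2: Sequence[float],
    method: str = "auto",
) -> GroupComparison:
    """Two-sided Mann-Whitney U test.

    ``U`` is reported as min(U1, U2) where U1 counts pairs in which
    sample1 exceeds sample2 (ties count 1/2).  ``method='auto'`` uses the
    exact distribution when both samples have at most 12 observations and
    there are no ties, otherwise the normal approximation with
    tie-corrected variance and continuity correction.
    """
    x = np.asarray(sample1, dtype=float)
    y = np.asarray(sample2, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InputError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    has_ties = len(np.unique(np.concatenate([x, y]))) < n1 + n2

    if method == "auto":
        use_exact = n1 <= EXACT_LIMIT and n2 <= EXACT_LIMIT and not has_ties
    elif method == "exact":
        if has_ties:
            raise ParameterError("exact method requires tie-free data")
        use_exact = True
    elif method == "normal_approx":
        use_exact = False
    else:
        raise ParameterError(f"unknown method {method!r}")

    # U1 via rank sums (midranks for ties)
    ranks = sps.rankdata(np.concatenate([x, y]))
    R1 = ranks[:n1].sum()
    U1 = R1 - n1 * (n1 + 1) / 2.0
    U2 = n1 * n2 - U1
    U = min(U1, U2)

    if use_exact:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        p = float(res.pvalue)
        return GroupComparison(U=float(U), p_two_sided=p, method="exact", n1=n1, n2=n2)

    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:  # all observations identical
        return GroupComparison(U=float(U), p_two_sided=1.0, method="normal_approx", n1=n1, n2=n2)
    z = (abs(U1 - mu) - 0.5) / np.sqrt(var)  # continuity correction
    z = max(z, 0.0)
    p = float(min(1.0, 2.0 * sps.norm.sf(z)))
    return GroupComparison(U=float(U), p_two_sided=p, method="normal_approx", n1=n1, n2=n2)


def summarize_group(values: Sequence[float]) -> Tuple[float, float]:
    """(mean, sample SD) of a group of per-monomer values; SD = 0 for n = 1."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise InputError("cannot summarize an empty group")
    sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
    return float(v.mean()), sd
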