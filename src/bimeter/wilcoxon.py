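"""One-sample Wilcoxon signed-rank test with an exact small-sample p-value.

V is the sum of the ranks (midranks under ties) of the absolute values that
carry a positive sign; under the null of symmetry about zero every one of the
2^n sign patterns is equally likely.  For small n the two-sided p-value is
computed from the exact null distribution of V (built by polynomial
convolution over the doubled ranks, which keeps midranks integral); larger
samples fall back on the normal approximation with tie correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.stats import norm, rankdata


class WilcoxonMethod(str, Enum):
    EXACT = "exact"
    NORMAL_APPROX = "normal_approx"


@dataclass(frozen=True)
class WilcoxonResult:
    n: int
    statistic: float  # V, sum of positive signed ranks
    p_value: float
    method: WilcoxonMethod


def signed_rank_null_counts(ranks: np.ndarray) -> np.ndarray:
    """Exact null distribution of 2V over all 2^n sign patterns.

    ``counts[k]`` is the number of sign patterns whose doubled statistic
    equals ``k`` (ranks are doubled so midranks like 1.5 stay integral).
    """
    doubled = np.round(2 * np.asarray(ranks, dtype=float)).astype(int)
    counts = np.zeros(doubled.sum() + 1, dtype=float)
    counts[0] = 1.0
    for r in doubled:
        counts[r:] += counts[: counts.size - r].copy()
    return counts


def wilcoxon_one_sample(values, exact_max_n: int = 20) -> WilcoxonResult:
    """Two-sided one-sample Wilcoxon signed-rank test against zero.

    Exact zeros are dropped (signed-rank convention); an all-zero sample
    carries no information and raises ``ValueError``.
    """
    values = np.asarray(values, dtype=float)
    values = values[values != 0.0]
    n = values.size
    if n == 0:
        raise ValueError("all values are zero: no information about the sign")
    ranks = rankdata(np.abs(values))
    v = float(ranks[values > 0].sum())
    total = float(ranks.sum())  # n(n+1)/2 absent ties; ties preserve the sum

    if n <= exact_max_n:
        counts = signed_rank_null_counts(ranks)
        v2 = int(round(2 * v))
        hi = max(v2, int(round(2 * total)) - v2)
        p = (counts[hi:].sum() + counts[: int(round(2 * total)) - hi + 1].sum()) / 2.0**n
        return WilcoxonResult(n, v, min(1.0, float(p)), WilcoxonMethod.EXACT)

    mean = total / 2.0
    var = float(np.sum(ranks**2)) / 4.0  # midrank form; equals n(n+1)(2n+1)/24 untied
    z = (v - mean) / np.sqrt(var)
    p = 2.0 * norm.sf(abs(z))
    return WilcoxonResult(n, v, min(1.0, float(p)), WilcoxonMethod.NORMAL_APPROX)
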