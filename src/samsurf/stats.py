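"""Group comparison statistics: two-sided Mann–Whitney–Wilcoxon with Bonferroni.

The exact null distribution is used for small samples (combined n ≤ 12
without ties), the tie-corrected normal approximation otherwise.
Adjusted p-values are annotated with the conventional star ladder.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

#: star annotation ladder: (upper bound, label); boundaries inclusive
_STAR_TABLE = [
    (1.00e-04, "****"),
    (1.00e-03, "***"),
    (1.00e-02, "**"),
    (5.00e-02, "*"),
    (1.00e00, "ns"),
]


@dataclass
class TestResult:
    statistic: float  # rank-sum U
    p_raw: float
    p_adjusted: float  # Bonferroni, capped at 1
    annotation: str
    n_a: int
    n_b: int


def mww_test(group_a, group_b, n_comparisons: int = 1) -> TestResult:
    """Two-sided Mann–Whitney–Wilcoxon U test with Bonferroni correction."""
    a = np.asarray(group_a, dtype=float).ravel()
    b = np.asarray(group_b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if (a.size + b.size <= 12 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    p_adj = min(1.0, float(res.pvalue) * n_comparisons)
    return TestResult(
        statistic=float(res.statistic),
        p_raw=float(res.pvalue),
        p_adjusted=p_adj,
        annotation=annotate_p(p_adj),
        n_a=int(a.size),
        n_b=int(b.size),
    )


def annotate_p(p: float) -> str:
    """Star annotation: ****: p ≤ 1e-4 … *: p ≤ 5e-2, else ns (bounds inclusive)."""
    if not 0 <= p <= 1:
        raise ValueError(f"p must be in [0, 1], got {p}")
    for bound, label in _STAR_TABLE:
        if p <= bound:
            return label
    return "ns"  # unreachable; p <= 1 always matches
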