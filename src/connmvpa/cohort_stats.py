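"""Group-comparison statistics from published summary data.

Demographic/neuropsychological tables usually print only mean +/- SD per
group and 2x2 counts for categorical variables; these helpers recompute
the two-sample t (Welch, unpooled — with equal group sizes the standard
error coincides with the pooled form) and the uncorrected Pearson
chi-square directly from those summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class GroupSummary:
    variable: str
    mean1: float
    sd1: float
    n1: int
    mean2: float
    sd2: float
    n2: int

    def __post_init__(self) -> None:
        if self.sd1 < 0 or self.sd2 < 0:
            raise ValueError("standard deviations must be nonnegative")
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("each group needs n >= 2")


def welch_t_from_summary(m1: float, s1: float, n1: int,
                         m2: float, s2: float, n2: int) -> tuple[float, float, float]:
    """Welch two-sample t, Welch–Satterthwaite df, two-sided p from summaries."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if s1 < 0 or s2 < 0:
        raise ValueError("standard deviations must be nonnegative")
    v1, v2 = s1 ** 2 / n1, s2 ** 2 / n2
    if v1 + v2 == 0:
        raise ValueError("zero variance in both groups")
    t = (m1 - m2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def chi_square_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Uncorrected Pearson chi-square for a 2x2 table [[a, b], [c, d]]."""
    counts = (a, b, c, d)
    if any(x < 0 for x in counts):
        raise ValueError("counts must be nonnegative")
    n = sum(counts)
    if n == 0:
        raise ValueError("empty table")
    margins = (a + b, c + d, a + c, b + d)
    if any(m == 0 for m in margins):
        raise ValueError("chi-square undefined: zero row or column margin")
    chi2 = n * (a * d - b * c) ** 2 / (margins[0] * margins[1] * margins[2] * margins[3])
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


def summary_table_report(summaries: list[GroupSummary]) -> pd.DataFrame:
    """t/df/p per row of a summary table (continuous variables only)."""
    rows = []
    for s in summaries:
        t, df, p = welch_t_from_summary(s.mean1, s.sd1, s.n1, s.mean2, s.sd2, s.n2)
        rows.append({"variable": s.variable, "t": t, "df": df, "p": p})
    return pd.DataFrame(rows, columns=["variable", "t", "df", "p"])
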