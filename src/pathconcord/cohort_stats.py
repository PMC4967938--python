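"""Species-group hypothesis tests on the pairwise comparison matrix.

Whether concordance differs between human-human, mouse-mouse and human-mouse
pairs is tested with a Kruskal-Wallis rank test (tie-corrected) followed by
Dunn's pairwise z-tests on mean ranks with Bonferroni correction over the
three group pairs. Species-related counts of significantly concordant pairs
are compared with the two-sample test for equality of proportions with
continuity correction (the R ``prop.test`` form: a Yates-corrected 2x2
chi-squared whose correction is capped so equal proportions give statistic
0).

Pairwise values that share a dataset are not independent; as is conventional
for this descriptive use, that dependence is ignored here and noted as a
caveat in reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["GroupTestResult", "kruskal_wallis_dunn", "proportions_test"]


@dataclass
class GroupTestResult:
    """Kruskal-Wallis H with Dunn post-hoc z-tests per group pair."""

    h_stat: float
    h_df: int
    h_p: float
    dunn: pd.DataFrame = field(repr=False)  # group1, group2, z, p_raw, p_bonferroni


def kruskal_wallis_dunn(values, groups) -> GroupTestResult:
    """Kruskal-Wallis across groups, then Dunn's test with Bonferroni.

    ``values`` are the per-pair statistics (e.g. mean predictive values),
    ``groups`` the parallel group labels. Every group needs >= 2 values.
    Dunn's z for groups i, j compares mean ranks:

        z = (R̄_i - R̄_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j))

    with the tie correction T = Σ(t³ - t) / (12(N - 1)). Two-sided normal
    p-values are Bonferroni-multiplied by the number of group pairs, capped
    at 1.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must have equal length")
    names = sorted(pd.unique(groups).tolist())
    if len(names) < 2:
        raise ValueError("need >= 2 groups")
    by_group = {g: values[groups == g] for g in names}
    for g, v in by_group.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has {len(v)} values; need >= 2")

    if np.ptp(values) == 0:
        # all observations identical: no rank information
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*[by_group[g] for g in names])
    n_total = len(values)

    ranks = stats.rankdata(values)  # midranks for ties
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    mean_rank = {g: ranks[groups == g].mean() for g in names}
    n_pairs = len(names) * (len(names) - 1) // 2
    rows = []
    for i, g1 in enumerate(names):
        for g2 in names[i + 1:]:
            se = np.sqrt(var_base * (1 / len(by_group[g1]) + 1 / len(by_group[g2])))
            z = (mean_rank[g1] - mean_rank[g2]) / se if se > 0 else 0.0
            p_raw = 2.0 * stats.norm.sf(abs(z))
            rows.append(dict(group1=g1, group2=g2, z=float(z),
                             p_raw=float(p_raw),
                             p_bonferroni=min(1.0, float(p_raw) * n_pairs)))
    return GroupTestResult(h_stat=float(h), h_df=len(names) - 1, h_p=float(p),
                           dunn=pd.DataFrame(rows))


def proportions_test(k1: int, n1: int, k2: int, n2: int):
    """Two-sample equality of proportions with continuity correction.

    ``(k1, n1)`` and ``(k2, n2)`` are successes/trials per group. Performed
    as the chi-squared test on the 2x2 table with Yates correction capped at
    |O - E| (so identical proportions give statistic 0 and p = 1), matching
    R's ``prop.test``. Returns ``(statistic, p)`` with df = 1, two-sided.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n < 1:
            raise ValueError("each group needs >= 1 trial")
        if not 0 <= k <= n:
            raise ValueError("need 0 <= successes <= trials")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    if 0 in table.sum(axis=0):
        # a zero column (all successes or all failures): proportions equal
        return 0.0, 1.0
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    # Yates: shrink |O - E| by 0.5 but never past zero
    diff = np.maximum(np.abs(table - expected) - 0.5, 0.0)
    stat = float(np.sum(diff**2 / expected))
    return stat, float(stats.chi2.sf(stat, df=1))
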