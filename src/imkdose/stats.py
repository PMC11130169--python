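"""Significance tests used to flag group differences.

Focus counts are compared with Scheffé's simultaneous criterion on top of
the one-way ANOVA framework — appropriate for post-hoc all-pairs
comparison, and conservative by construction (its p-value is never
smaller than the unadjusted pairwise F test's).  Clonogenic survival uses
a two-sided paired t-test.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["scheffe_test", "paired_t_test"]


def scheffe_test(groups: dict | list, alpha_flags=(0.05, 0.01)) -> pd.DataFrame:
    """All pairwise comparisons with Scheffé's simultaneous criterion.

    ``groups`` is a dict name -> observations (or a list, named 0..k-1).
    For the pair (i, j) the contrast statistic is

        F_ij = (m_i - m_j)² / (MSW (1/n_i + 1/n_j)),

    compared against (k-1)·F_{k-1, N-k}: the reported p-value is
    P[F_{k-1, N-k} ≥ F_ij/(k-1)].  Returns a frame with columns
    group_a, group_b, mean_diff, F, p, flag (''/'*'/'**').
    """
    if not isinstance(groups, dict):
        groups = {i: g for i, g in enumerate(groups)}
    names = list(groups)
    arrays = [np.asarray(groups[n], dtype=float) for n in names]
    k = len(arrays)
    if k < 2:
        raise ValueError("need at least 2 groups")
    ns = np.array([len(a) for a in arrays])
    if np.any(ns < 2):
        raise ValueError("each group needs at least 2 observations")
    N = int(ns.sum())
    means = np.array([a.mean() for a in arrays])
    ssw = float(sum(((a - a.mean()) ** 2).sum() for a in arrays))
    df_w = N - k
    msw = ssw / df_w
    if msw == 0.0:
        raise ValueError("zero within-group variance: Scheffé test undefined")
    rows = []
    for i, j in itertools.combinations(range(k), 2):
        diff = means[i] - means[j]
        F = diff**2 / (msw * (1.0 / ns[i] + 1.0 / ns[j]))
        p = float(sps.f.sf(F / (k - 1), k - 1, df_w))
        flag = "**" if p < alpha_flags[1] else ("*" if p < alpha_flags[0] else "")
        rows.append((names[i], names[j], diff, F, p, flag))
    return pd.DataFrame(rows, columns=["group_a", "group_b", "mean_diff", "F", "p", "flag"])


def paired_t_test(sf_pairs) -> tuple[float, float]:
    """Two-sided paired t-test on (x, y) pairs; returns (t, p).

    Exactly zero-variance differences (all pairs shifted by the identical
    amount, including identical pairs) make the statistic undefined and
    raise rather than returning a misleading p-value.
    """
    pairs = np.asarray(sf_pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or pairs.shape[0] < 2:
        raise ValueError("need at least 2 (x, y) pairs")
    d = pairs[:, 0] - pairs[:, 1]
    if np.var(d, ddof=1) == 0.0:
        raise ValueError("zero-variance differences: paired t-test undefined")
    t, p = sps.ttest_rel(pairs[:, 0], pairs[:, 1])
    return float(t), float(p)
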