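"""Replicated-block Friedman tests for condition comparisons.

The study design is 4 violinists (blocks) x 6 takes (replicates) x 2
conditions.  Within each block all reps*k values are jointly ranked
(mid-ranks for ties) and the condition rank sums are referred to a
chi-square statistic that generalizes the classical Friedman test to
replicated blocks:

    chi2 = (k - 1) * sum_j D_j^2 / (k * sum_b V_b)

where ``D_j`` is the deviation of condition j's rank sum from its null
expectation and ``V_b = r (m - r) v_b / (m - 1)`` is the
sampling-without-replacement variance of a sum of ``r`` ranks drawn from
the ``m = r*k`` ranks of block b (``v_b`` is the empirical population
variance of the block's mid-ranks, which is the tie correction).  For
one replicate this reduces exactly to the classical Friedman formula
``12 n / (k (k+1)) * sum_j (Rbar_j - (k+1)/2)^2``.

No multiple-comparison correction is applied across measures; reports
state this in their header.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist
from scipy.stats import rankdata


@dataclass(frozen=True)
class TestResult:
    chi2: float
    df: int
    p: float
    tie_corrected: bool = True


def _validate_matrix(data: np.ndarray) -> np.ndarray:
    data = np.asarray(data, dtype=float)
    if data.ndim == 2:  # classical layout: blocks x k, one replicate
        data = data[:, None, :]
    if data.ndim != 3:
        raise ValueError("data must have shape (blocks, reps, k)")
    if np.isnan(data).any():
        raise ValueError("incomplete design: missing cells")
    if data.shape[2] < 2:
        raise ValueError("need at least two conditions")
    return data


def friedman_replicated(data: np.ndarray) -> TestResult:
    """Friedman test on a complete (blocks, reps, k) matrix.

    All-tied data yield chi2 = 0 and p = 1.
    """
    data = _validate_matrix(data)
    n_blocks, reps, k = data.shape
    m = reps * k
    D = np.zeros(k)
    total_var = 0.0
    for b in range(n_blocks):
        ranks = rankdata(data[b].ravel()).reshape(reps, k)
        col_sums = ranks.sum(axis=0)
        D += col_sums - reps * (m + 1) / 2.0
        v_b = np.var(ranks)  # population variance of mid-ranks (tie-corrected)
        total_var += reps * (m - reps) * v_b / (m - 1)
    if total_var <= 0:
        return TestResult(chi2=0.0, df=k - 1, p=1.0)
    chi2 = (k - 1) * float(D @ D) / (k * total_var)
    p = float(chi2_dist.sf(chi2, k - 1))
    return TestResult(chi2=chi2, df=k - 1, p=max(p, np.finfo(float).tiny))


def friedman_permutation_p(
    data: np.ndarray, n_perm: int = 10000, seed: int = 0
) -> float:
    """Within-block permutation oracle for the replicated Friedman test.

    Condition labels are shuffled within each block.  Because ranking is
    invariant under within-block permutation, the permutation
    distribution is generated directly on each block's fixed mid-ranks
    (the variance term of the statistic is permutation-invariant), which
    lets all draws be vectorized.  The statistic is discrete, so the
    returned value is the add-one *mid*-p (ties at the observed value
    counted half), the unbiased comparator for a continuous reference
    distribution such as the chi-square approximation.
    """
    data = _validate_matrix(data)
    n_blocks, reps, k = data.shape
    m = reps * k
    ranks = np.stack([rankdata(data[b].ravel()) for b in range(n_blocks)])
    expect = reps * (m + 1) / 2.0
    total_var = sum(
        reps * (m - reps) * np.var(ranks[b]) / (m - 1) for b in range(n_blocks)
    )
    if total_var <= 0:
        return 1.0
    D_obs = np.zeros(k)
    for b in range(n_blocks):
        D_obs += ranks[b].reshape(reps, k).sum(axis=0) - expect
    obs = (k - 1) * float(D_obs @ D_obs) / (k * total_var)
    rng = np.random.default_rng(seed)
    D = np.zeros((n_perm, k))
    for b in range(n_blocks):
        idx = rng.random((n_perm, m)).argsort(axis=1)
        D += ranks[b][idx].reshape(n_perm, reps, k).sum(axis=1) - expect
    stats = (k - 1) * np.einsum("ij,ij->i", D, D) / (k * total_var)
    greater = int(np.sum(stats > obs + 1e-9))
    equal = int(np.sum(np.abs(stats - obs) <= 1e-9))
    return (greater + 0.5 * equal + 0.5) / (n_perm + 1)


def compare_conditions(
    table: pd.DataFrame,
    conditions: list[str] | None = None,
    group_col: str | None = None,
) -> pd.DataFrame:
    """Friedman comparison of conditions for every measure in a tidy table.

    ``table`` columns: violinist (block), take (replicate), condition,
    measure, value.  The design must be complete: every block x replicate
    x condition cell present exactly once per measure.  ``group_col``
    optionally stratifies the comparison (e.g. by conductor).

    Returns one row per measure (and group) with per-condition mean/sd
    across takes x violinists, the chi-square statistic and p-value.
    """
    required = {"violinist", "take", "condition", "measure", "value"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"table lacks columns: {sorted(missing)}")
    conditions = conditions or sorted(table["condition"].unique())
    k = len(conditions)
    groups = [None] if group_col is None else sorted(table[group_col].unique())
    rows = []
    for grp in groups:
        sub = table if grp is None else table[table[group_col] == grp]
        for measure, mdf in sub.groupby("measure", sort=True):
            dup = mdf.duplicated(subset=["violinist", "take", "condition"])
            if dup.any():
                raise ValueError(f"duplicated design cells for measure {measure!r}")
            pivot = mdf.pivot_table(
                index=["violinist", "take"], columns="condition", values="value"
            )
            if pivot.isna().any().any() or set(conditions) - set(pivot.columns):
                raise ValueError(f"incomplete design for measure {measure!r}")
            blocks = sorted(mdf["violinist"].unique())
            reps = sorted(mdf["take"].unique())
            data = np.empty((len(blocks), len(reps), k))
            for bi, b in enumerate(blocks):
                for ri, r in enumerate(reps):
                    for ci, c in enumerate(conditions):
                        data[bi, ri, ci] = pivot.loc[(b, r), c]
            res = friedman_replicated(data)
            row = {"measure": measure, "chi2": res.chi2, "df": res.df, "p": res.p}
            if grp is not None:
                row[group_col] = grp
            for c in conditions:
                row[f"mean_{c}"] = float(pivot[c].mean())
                row[f"sd_{c}"] = float(pivot[c].std(ddof=1))
            rows.append(row)
    return pd.DataFrame(rows)
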