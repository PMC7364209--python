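"""Hypothesis tests and multiple-testing correction.

Rank tests (Mann-Whitney U, Kruskal-Wallis, Wilcoxon signed-rank) follow the
classical definitions with explicit exact/asymptotic branch points; PERMANOVA
is a seeded label-permutation test of Anderson's pseudo-F computed directly
from a distance matrix.  Benjamini-Hochberg adjusted p-values are reported as
q-values throughout the pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from skbio import DistanceMatrix
from statsmodels.stats.multitest import multipletests

from .data_model import ValidationError


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    n_per_group: tuple
    alternative: str = "two-sided"

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError(f"p-value out of range: {self.p_value}")


def _has_ties(*arrays) -> bool:
    pooled = np.concatenate([np.asarray(a, dtype=float) for a in arrays])
    return len(np.unique(pooled)) < len(pooled)


def mann_whitney_u(x, y, alternative: str = "two-sided") -> TestResult:
    """Mann-Whitney U test.

    Exact enumeration of the U null when both groups have n <= 8 and there are
    no ties; otherwise the tie-corrected normal approximation with continuity
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("mann_whitney_u requires non-empty groups")
    exact = x.size <= 8 and y.size <= 8 and not _has_ties(x, y)
    method = "exact" if exact else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=alternative, method=method,
                           use_continuity=True)
    return TestResult(float(res.statistic), float(min(res.pvalue, 1.0)),
                      f"mann-whitney-u ({method})", (x.size, y.size), alternative)


def kruskal_wallis(*groups) -> TestResult:
    """Kruskal-Wallis H with tie correction and chi-square p on k-1 df.

    All-identical data is a degenerate but valid input: H = 0, p = 1.
    """
    if len(groups) < 2:
        raise ValueError("kruskal_wallis requires >= 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("kruskal_wallis requires non-empty groups")
    ns = tuple(a.size for a in arrays)
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return TestResult(0.0, 1.0, "kruskal-wallis", ns)
    H, p = sps.kruskal(*arrays)
    return TestResult(float(H), float(min(p, 1.0)), "kruskal-wallis", ns)


def wilcoxon_signed_rank(d, alternative: str = "two-sided") -> TestResult:
    """Wilcoxon signed-rank test on differences ``d``.

    Zero differences are dropped (Wilcoxon's original treatment) and n reduced
    accordingly; if everything is zero the test is vacuous (p = 1).  The exact
    null is used for n <= 15 without ties in |d|, the normal approximation
    with tie correction otherwise.
    """
    d = np.asarray(d, dtype=float)
    n_in = d.size
    d = d[d != 0]
    if d.size == 0:
        return TestResult(0.0, 1.0, "wilcoxon-signed-rank (degenerate)",
                          (n_in,), alternative)
    exact = d.size <= 15 and not _has_ties(np.abs(d))
    method = "exact" if exact else "approx"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # scipy warns on tiny n with approx
        res = sps.wilcoxon(d, alternative=alternative, zero_method="wilcox",
                           mode=method, correction=True)
    return TestResult(float(res.statistic), float(min(res.pvalue, 1.0)),
                      f"wilcoxon-signed-rank ({method})", (int(d.size),),
                      alternative)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def _pseudo_f(d2: np.ndarray, group_indices: list[np.ndarray]) -> float:
    """Anderson's pseudo-F from squared distances and group index arrays."""
    n = d2.shape[0]
    k = len(group_indices)
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for idx in group_indices:
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub.sum() / (2.0 * idx.size)
    ss_among = ss_total - ss_within
    denom = ss_within / (n - k)
    if denom <= 0:
        return np.inf if ss_among > 0 else 0.0
    return (ss_among / (k - 1)) / denom


def permanova(dm: DistanceMatrix, grouping, n_permutations: int = 999,
              seed: int | None = None) -> TestResult:
    """One-way PERMANOVA on a distance matrix.

    ``grouping`` maps (or aligns positionally with) the matrix ids to group
    labels.  The p-value uses the standard permutation convention
    ``(1 + #{F_perm >= F_obs}) / (1 + n_permutations)`` and never returns 0.
    """
    ids = list(dm.ids)
    if isinstance(grouping, (pd.Series, dict)):
        series = pd.Series(grouping)
        missing = [s for s in ids if s not in series.index]
        if missing:
            raise ValidationError(f"grouping missing samples: {missing}")
        labels = np.asarray(series.loc[ids])
    else:
        labels = np.asarray(list(grouping))
        if labels.size != len(ids):
            raise ValidationError("grouping length does not match distance matrix")
    uniq, inv = np.unique(labels, return_inverse=True)
    k = uniq.size
    n = len(ids)
    if k < 2:
        raise ValueError("permanova requires >= 2 groups")
    sizes = np.bincount(inv)
    if (sizes == 1).any():
        warnings.warn("permanova: group(s) of size 1 present", stacklevel=2)
    if n - k <= 0:
        raise ValueError("permanova: zero within-group degrees of freedom")

    d2 = np.asarray(dm.data, dtype=float) ** 2
    groups = [np.flatnonzero(inv == g) for g in range(k)]
    f_obs = _pseudo_f(d2, groups)

    rng = np.random.default_rng(seed)
    hits = 0
    perm = np.arange(n)
    for _ in range(n_permutations):
        rng.shuffle(perm)
        perm_groups = [perm[idx] for idx in groups]
        if _pseudo_f(d2, perm_groups) >= f_obs - 1e-12:
            hits += 1
    p = (1.0 + hits) / (1.0 + n_permutations)
    return TestResult(float(f_obs), p, "permanova", tuple(int(s) for s in sizes))


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------

def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Input order is preserved; values are capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def test_table(results: list[tuple[str, TestResult]], seed=None) -> pd.DataFrame:
    """Assemble named test results into a TSV-ready table with q-values."""
    rows = []
    for name, res in results:
        rows.append({"comparison": name, "statistic": res.statistic,
                     "p_value": res.p_value,
                     "n_per_group": ",".join(str(n) for n in res.n_per_group),
                     "method": res.method, "alternative": res.alternative,
                     "seed": seed})
    df = pd.DataFrame(rows)
    if len(df):
        df.insert(3, "q_value", bh_adjust(df["p_value"].to_numpy()))
    return df
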