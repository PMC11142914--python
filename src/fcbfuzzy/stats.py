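"""Rank-based statistics on FCB scores.

All score distributions here are treated non-parametrically: species
rankings with midranks for ties, Kendall tau-b correlations among the three
indices, Kruskal-Wallis with Dunn's post-hoc comparisons across taxa, and a
permutation test comparing the extreme (top-/bottom-k) species against the
full set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import InputError, UndefinedCorrelationError

_SCORE_COLS = {
    "F": "f_score",
    "C": "c_score",
    "B": "b_score",
    "mean": "mean_score",
}


def rank_species(scores, ascending: bool = False) -> np.ndarray:
    """Descending ranks (best score = rank 1); ties get midranks."""
    s = pd.Series(np.asarray(scores, dtype=float))
    return s.rank(ascending=ascending, method="average").to_numpy()


def rank_table(scores: pd.DataFrame) -> pd.DataFrame:
    """Per-index and overall (mean-score) ranks for every species."""
    out = scores[["species_id", "taxon"]].copy()
    for key, col in _SCORE_COLS.items():
        out[f"rank_{key}"] = rank_species(scores[col])
    return out


@dataclass(frozen=True)
class CorrelationResult:
    pair: tuple[str, str]
    tau: float
    p_value: float
    n: int
    method: str


def kendall_tau(x, y, pair: tuple[str, str] = ("x", "y")) -> CorrelationResult:
    """Kendall tau-b with tie correction.

    The p-value uses the exact null distribution for small samples where
    available (scipy provides it for untied data with n <= 33) and the
    normal approximation with tie correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("x and y must be equal-length 1-d vectors")
    n = x.size
    if n < 3:
        raise InputError(f"need at least 3 observations, got {n}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise UndefinedCorrelationError(
            "Kendall tau is undefined for a constant vector"
        )
    has_ties = (np.unique(x).size < n) or (np.unique(y).size < n)
    if n <= 10 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.kendalltau(x, y, method=method)
    return CorrelationResult(
        pair=pair, tau=float(res.statistic), p_value=float(res.pvalue),
        n=n, method=method,
    )


def index_correlations(scores: pd.DataFrame) -> pd.DataFrame:
    """Kendall correlations among the F, C, B score columns."""
    rows = []
    for a, b in (("F", "C"), ("F", "B"), ("C", "B")):
        r = kendall_tau(
            scores[_SCORE_COLS[a]], scores[_SCORE_COLS[b]], pair=(a, b)
        )
        rows.append(
            {
                "pair": f"{a}-{b}", "tau": r.tau, "p_value": r.p_value,
                "n": r.n, "method": r.method,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class GroupComparison:
    h_statistic: float
    p_value: float
    groups: tuple[str, ...]
    dunn: pd.DataFrame  # group_1, group_2, z, p_unadjusted, p_adjusted


def _dunn_posthoc(values, labels, groups, p_adjust):
    """Dunn's pairwise z tests on the pooled ranks, with tie correction."""
    values = np.asarray(values, dtype=float)
    n = values.size
    ranks = sps.rankdata(values)
    # tie correction term of the rank variance
    _, counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (n - 1))
    var_base = n * (n + 1) / 12.0 - tie_term
    mean_rank = {g: ranks[labels == g].mean() for g in groups}
    size = {g: int((labels == g).sum()) for g in groups}
    rows = []
    for i, g1 in enumerate(groups):
        for g2 in groups[i + 1:]:
            se = np.sqrt(var_base * (1.0 / size[g1] + 1.0 / size[g2]))
            z = (mean_rank[g1] - mean_rank[g2]) / se if se > 0 else 0.0
            p = 2.0 * sps.norm.sf(abs(z))
            rows.append({"group_1": g1, "group_2": g2, "z": z, "p_unadjusted": p})
    dunn = pd.DataFrame(rows)
    if p_adjust == "none":
        dunn["p_adjusted"] = dunn["p_unadjusted"]
    else:
        method = {"holm": "holm", "bonferroni": "bonferroni", "bh": "fdr_bh"}[
            p_adjust
        ]
        dunn["p_adjusted"] = multipletests(
            dunn["p_unadjusted"].to_numpy(), method=method
        )[1]
    return dunn


def group_compare(
    scores, labels, p_adjust: str = "holm"
) -> GroupComparison:
    """Kruskal-Wallis across groups, with Dunn's pairwise post-hoc tests.

    Identical values everywhere are degenerate; by convention that returns
    H = 0, p = 1 (no evidence of any difference).
    """
    if p_adjust not in ("none", "holm", "bonferroni", "bh"):
        raise InputError(f"unknown p_adjust {p_adjust!r}")
    values = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if values.shape != labels.shape:
        raise InputError("scores and labels must have equal length")
    groups = tuple(sorted(pd.unique(labels)))
    if len(groups) < 2:
        raise InputError("need at least two groups")
    samples = [values[labels == g] for g in groups]
    for g, s in zip(groups, samples):
        if s.size < 2:
            raise InputError(f"group {g!r} has fewer than 2 members")
    if np.all(values == values[0]):
        dunn = _dunn_posthoc(values, labels, groups, p_adjust)
        return GroupComparison(0.0, 1.0, groups, dunn)
    h, p = sps.kruskal(*samples)
    dunn = _dunn_posthoc(values, labels, groups, p_adjust)
    return GroupComparison(float(h), float(p), groups, dunn)


@dataclass(frozen=True)
class ExtremeSubsetResult:
    statistic: float  # mean(extreme k) - mean(all)
    p_value: float
    k: int
    tail: str
    n_perm: int


def extreme_subset_test(
    scores,
    k: int = 10,
    tail: str = "top",
    n_perm: int = 10000,
    seed: int | None = None,
) -> ExtremeSubsetResult:
    """Permutation test: are the k most extreme species unusual in mean?

    The statistic is mean(top-k or bottom-k scores) - mean(all scores); the
    null distribution is built from random k-subsets, and the p-value is
    one-sided in the direction of the selected tail (greater for "top",
    less for "bottom").  Because the subset is selected *by* score, a small
    p mostly quantifies the selection effect and the spread of the scores.
    """
    values = np.asarray(scores, dtype=float)
    n = values.size
    if not 1 <= k < n:
        raise InputError(f"k must lie in [1, n-1] = [1, {n - 1}], got {k}")
    if tail not in ("top", "bottom"):
        raise InputError(f"tail must be 'top' or 'bottom', got {tail!r}")
    order = np.sort(values)
    subset = order[-k:] if tail == "top" else order[:k]
    stat = float(subset.mean() - values.mean())
    rng = np.random.default_rng(seed)
    perm = np.empty(n_perm)
    for i in range(n_perm):
        perm[i] = rng.choice(values, size=k, replace=False).mean() - values.mean()
    if tail == "top":
        more_extreme = np.sum(perm >= stat)
    else:
        more_extreme = np.sum(perm <= stat)
    p = float((1 + more_extreme) / (1 + n_perm))
    return ExtremeSubsetResult(stat, p, k, tail, n_perm)
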