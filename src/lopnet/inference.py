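"""Group inference: node-wise contrasts, FDR conjunction, permutation null.

Node-wise paired t-tests compare centrality between two conditions at every
edge density; Benjamini-Hochberg FDR correction (q = 0.05) is applied within
each density, and only nodes significant with a consistent direction at
every density survive the conjunction - a deliberately conservative guard
against effects that appear at isolated thresholds only.

The centrality-memory link is a Pearson correlation between per-participant
mean centrality change (averaged over a node set and all densities) and
source-memory performance.  Its specificity is assessed with an exhaustive
subset permutation: the same correlation is recomputed for every possible
same-size subset of the remaining nodes, and the empirical p is the
fraction of subsets with a correlation at least as large (one-sided, no
smoothing; a +1-smoothed p is reported alongside).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ConjunctionSet",
    "PermutationNull",
    "paired_node_tests",
    "fdr_correct",
    "conjunction",
    "centrality_change",
    "memory_correlation",
    "count_subsets",
    "exhaustive_permutation",
]


@dataclass
class ConjunctionSet:
    """Nodes significant with consistent direction at every density."""

    nodes: list
    directions: dict            # node -> +1 / -1
    measure: str = ""
    contrast: str = ""

    @property
    def increased(self) -> list:
        return [n for n in self.nodes if self.directions[n] > 0]

    @property
    def decreased(self) -> list:
        return [n for n in self.nodes if self.directions[n] < 0]


@dataclass
class PermutationNull:
    """Exhaustive subset permutation null for the centrality-memory r."""

    k: int
    pool: list
    r_null: np.ndarray
    r_observed: float
    count_ge: int
    empirical_p: float
    empirical_p_smoothed: float

    @property
    def n_subsets(self) -> int:
        return len(self.r_null)


def _pivot(table: pd.DataFrame, measure: str, condition: str) -> pd.DataFrame:
    sub = table[(table["measure"] == measure) & (table["condition"] == condition)]
    return sub.pivot_table(
        index="participant", columns=["density", "node"], values="value"
    )


def paired_node_tests(
    table: pd.DataFrame,
    condition_a: str,
    condition_b: str,
    measure: str = "closeness",
) -> pd.DataFrame:
    """Per-node, per-density paired t-tests on centrality (A - B).

    Every participant must contribute both conditions at every density.
    Returns a frame with columns ``density, node, t, p, direction,
    zero_variance``; zero-variance difference vectors are flagged (t is NaN,
    p set to 1 so they can never be declared significant).
    """
    a = _pivot(table, measure, condition_a)
    b = _pivot(table, measure, condition_b)
    if a.shape != b.shape or a.isna().any().any() or b.isna().any().any():
        raise ValueError("every participant needs both conditions at every density")
    b = b.reindex(index=a.index, columns=a.columns)
    diff = a.to_numpy() - b.to_numpy()
    n = diff.shape[0]
    mean = diff.mean(axis=0)
    sd = diff.std(axis=0, ddof=1)
    zero_var = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    p = 2 * stats.t.sf(np.abs(t), n - 1)
    # zero-variance differences: identical conditions give t=0/p=1; a
    # nonzero constant difference has no finite t - both are flagged so
    # downstream correction can treat them explicitly
    t[zero_var & (mean == 0)] = 0.0
    t[zero_var & (mean != 0)] = np.nan
    p[zero_var] = 1.0
    out = pd.DataFrame(
        {
            "density": [c[0] for c in a.columns],
            "node": [c[1] for c in a.columns],
            "t": t,
            "p": p,
            "direction": np.sign(mean).astype(int),
            "zero_variance": zero_var,
        }
    )
    out["measure"] = measure
    return out


def fdr_correct(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up significance mask at level ``q``."""
    p = np.asarray(p_values, dtype=float)
    mask = np.zeros(len(p), dtype=bool)
    valid = np.isfinite(p)
    if valid.any():
        mask[valid] = multipletests(p[valid], alpha=q, method="fdr_bh")[0]
    return mask


def conjunction(
    test_results: pd.DataFrame, q: float = 0.05, measure: str = "", contrast: str = ""
) -> ConjunctionSet:
    """Nodes FDR-significant with consistent direction at every density.

    ``test_results`` is the output of :func:`paired_node_tests` over all
    densities; BH correction is applied within each density.
    """
    frames = []
    for d, sub in test_results.groupby("density"):
        sub = sub.copy()
        sub["significant"] = fdr_correct(sub["p"].to_numpy(), q)
        frames.append(sub)
    res = pd.concat(frames)
    n_densities = res["density"].nunique()
    nodes, directions = [], {}
    for node, sub in res.groupby("node"):
        if len(sub) == n_densities and sub["significant"].all():
            dirs = set(sub["direction"])
            if len(dirs) == 1 and 0 not in dirs:
                nodes.append(node)
                directions[node] = int(dirs.pop())
    return ConjunctionSet(nodes=nodes, directions=directions,
                          measure=measure, contrast=contrast)


def centrality_change(
    table: pd.DataFrame,
    nodes,
    condition_a: str,
    condition_b: str,
    measure: str = "closeness",
) -> pd.Series:
    """Per-participant mean centrality change over a node set.

    The mean over the given nodes and all densities of
    (centrality in A - centrality in B); index is the participant id.
    """
    nodes = list(nodes)
    if not nodes:
        raise ValueError("empty node set")
    a = _pivot(table, measure, condition_a)
    b = _pivot(table, measure, condition_b)
    cols = [c for c in a.columns if c[1] in set(nodes)]
    if not cols:
        raise ValueError("requested nodes absent from the table")
    d = (a[cols] - b[cols]).mean(axis=1)
    d.name = "centrality_change"
    return d


def memory_correlation(change: pd.Series, scores: pd.Series) -> dict:
    """Pearson correlation of centrality change with memory performance."""
    merged = pd.concat([change, scores], axis=1, join="inner").dropna()
    if len(merged) < 3:
        raise ValueError("need at least 3 participants")
    x, y = merged.iloc[:, 0].to_numpy(float), merged.iloc[:, 1].to_numpy(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant input")
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "p": float(p), "n": len(merged)}


def count_subsets(pool: int, k: int) -> int:
    """Exact number of k-subsets of a pool (binomial coefficient)."""
    if pool < 0 or k < 0 or k > pool:
        raise ValueError("require 0 <= k <= pool")
    return math.comb(pool, k)


def _change_matrix(table, nodes, condition_a, condition_b, measure):
    """participants x nodes matrix of density-averaged centrality change."""
    a = _pivot(table, measure, condition_a)
    b = _pivot(table, measure, condition_b)
    diff = a - b
    per_node = diff.T.groupby(level="node").mean().T  # average over densities
    return per_node[list(nodes)]


def exhaustive_permutation(
    table: pd.DataFrame,
    all_nodes,
    observed_set,
    scores: pd.Series,
    k: int | None = None,
    condition_a: str = "remembered",
    condition_b: str = "forgotten",
    measure: str = "closeness",
    max_subsets: int = 2_000_000,
) -> PermutationNull:
    """Exhaustive node-subset permutation null for the memory correlation.

    For every k-subset of the candidate pool (all nodes minus the observed
    set), the centrality-change/memory correlation is recomputed; the
    observed r comes from the observed set itself.  ``count_ge`` counts null
    subsets with r at least as large (one-sided), and
    ``empirical_p = count_ge / C(pool, k)``.

    Raises if the enumeration would exceed ``max_subsets``; such problems
    need a sampled (Monte Carlo) permutation scheme instead, which this
    exhaustive routine deliberately does not silently fall back to.
    """
    observed_set = list(observed_set)
    k = len(observed_set) if k is None else k
    pool = [n for n in all_nodes if n not in set(observed_set)]
    if k > len(pool):
        raise ValueError("subset size exceeds the candidate pool")
    n_subsets = count_subsets(len(pool), k)
    if n_subsets > max_subsets:
        raise ValueError(
            f"{n_subsets} subsets exceed the cap of {max_subsets}; use a sampled "
            "permutation scheme for pools this large"
        )

    r_observed = memory_correlation(
        centrality_change(table, observed_set, condition_a, condition_b, measure),
        scores,
    )["r"]

    X = _change_matrix(table, pool, condition_a, condition_b, measure)
    s = scores.reindex(X.index).to_numpy(float)
    if np.any(~np.isfinite(s)):
        raise ValueError("scores missing for some participants in the table")
    Xc = X.to_numpy(float)
    Xc = Xc - Xc.mean(axis=0)
    sc = s - s.mean()
    a_vec = Xc.T @ sc                   # per-node covariance numerators
    G = Xc.T @ Xc                       # node Gram matrix
    s_norm = np.linalg.norm(sc)

    idx = np.array(list(combinations(range(len(pool)), k)), dtype=np.int32)
    num = a_vec[idx].sum(axis=1)
    denom_sq = np.zeros(len(idx))
    for i in range(k):
        for j in range(k):
            denom_sq += G[idx[:, i], idx[:, j]]
    with np.errstate(divide="ignore", invalid="ignore"):
        r_null = num / (np.sqrt(denom_sq) * s_norm)
    r_null = np.nan_to_num(r_null, nan=0.0)
    count_ge = int(np.sum(r_null >= r_observed))
    return PermutationNull(
        k=k,
        pool=pool,
        r_null=r_null,
        r_observed=float(r_observed),
        count_ge=count_ge,
        empirical_p=count_ge / n_subsets,
        empirical_p_smoothed=(count_ge + 1) / (n_subsets + 1),
    )
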