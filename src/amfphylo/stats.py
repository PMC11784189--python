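"""Bray–Curtis dissimilarity and one-way ANOSIM.

ANOSIM (analysis of similarities) is a rank-based permutation test of whether
between-group dissimilarities exceed within-group dissimilarities:

    R = (r̄_B − r̄_W) / (M / 2),   M = n(n−1)/2

with r̄_B, r̄_W the mean ranks of between- and within-group distances (ties
receive average ranks).  R lies in [−1, 1]; the null distribution is built by
permuting group labels, and the one-sided p-value uses the add-one rule

    p = (1 + #{permuted R ≥ observed R}) / (1 + n_permutations)

so p can never be 0.  Small designs can be tested exactly by enumerating all
distinct relabelings (``method="exhaustive"``).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform
from scipy.stats import rankdata
from skbio import DistanceMatrix


@dataclass(frozen=True)
class AnosimResult:
    R: float
    p_value: float
    n_permutations: int
    seed: int | None
    group_sizes: tuple[int, ...]
    method: str = "monte-carlo"


def bray_curtis(ab: pd.DataFrame) -> DistanceMatrix:
    """Pairwise Bray–Curtis dissimilarity between sample rows.

    d(x, y) = Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ); a pair of all-zero rows is an error
    (the dissimilarity is undefined there).
    """
    x = np.asarray(ab.values, dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if (x < 0).any():
        raise ValueError("negative abundance values")
    diff = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2)
    total = (x[:, None, :] + x[None, :, :]).sum(axis=2)
    zero_pairs = (total == 0) & ~np.eye(x.shape[0], dtype=bool)
    if zero_pairs.any():
        i, j = map(int, np.argwhere(zero_pairs)[0])
        raise ValueError(
            f"Bray–Curtis undefined for all-zero sample pair "
            f"({ab.index[i]!r}, {ab.index[j]!r})"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(total > 0, diff / np.where(total == 0, 1, total), 0.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, ids=[str(s) for s in ab.index])


def _r_statistic(ranks: np.ndarray, within: np.ndarray) -> float:
    m = ranks.size
    rw = ranks[within].mean()
    rb = ranks[~within].mean()
    return (rb - rw) / (m / 2.0)


def _within_mask(labels: np.ndarray) -> np.ndarray:
    n = labels.size
    same = labels[:, None] == labels[None, :]
    iu = np.triu_indices(n, k=1)
    return same[iu]


def _distinct_relabelings(labels: np.ndarray):
    """All distinct assignments of the label multiset to positions."""
    n = labels.size
    uniq, counts = np.unique(labels, return_counts=True)
    # assign positions to groups: choose positions for each label in turn
    def rec(positions: list[int], remaining: list[tuple[str, int]]):
        if not remaining:
            yield ()
            return
        label, k = remaining[0]
        for combo in itertools.combinations(positions, k):
            rest = [p for p in positions if p not in combo]
            for tail in rec(rest, remaining[1:]):
                yield tuple((p, label) for p in combo) + tail

    for pairs in rec(list(range(n)), list(zip(uniq, counts))):
        arr = np.empty(n, dtype=labels.dtype)
        for p, lab in pairs:
            arr[p] = lab
        yield arr


def anosim(
    dm: DistanceMatrix,
    groups: list[str] | np.ndarray,
    n_permutations: int = 9999,
    seed: int | None = None,
    method: str = "monte-carlo",
) -> AnosimResult:
    """One-way ANOSIM on a distance matrix with per-sample group labels.

    ``method="monte-carlo"`` samples ``n_permutations`` uniform label
    permutations with the given seed; ``method="exhaustive"`` enumerates all
    distinct relabelings (p = #{R_perm >= R_obs} / N, identity included).
    When the Monte-Carlo budget covers every distinct relabeling
    (n_permutations >= N - 1), the test is computed exactly instead of
    sampled, so small designs always get the exact p-value.
    Requires >= 2 groups, each of size >= 2.
    """
    labels = np.asarray([str(g) for g in groups])
    if labels.size != len(dm.ids):
        raise ValueError("one group label per sample required")
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValueError("need at least 2 groups")
    if (counts < 2).any():
        small = [str(u) for u, c in zip(uniq, counts) if c < 2]
        raise ValueError(f"groups of size 1 not allowed: {small}")
    if method not in ("monte-carlo", "exhaustive"):
        raise ValueError("method must be 'monte-carlo' or 'exhaustive'")
    if method == "monte-carlo" and n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")

    condensed = squareform(np.asarray(dm.data), checks=False)
    ranks = rankdata(condensed)  # average ranks on ties
    r_obs = _r_statistic(ranks, _within_mask(labels))

    if method == "exhaustive":
        n_total = 0
        n_ge = 0
        for perm in _distinct_relabelings(labels):
            n_total += 1
            if _r_statistic(ranks, _within_mask(perm)) >= r_obs - 1e-12:
                n_ge += 1
        p = n_ge / n_total
        return AnosimResult(
            R=float(r_obs),
            p_value=float(p),
            n_permutations=n_total,
            seed=None,
            group_sizes=tuple(int(c) for c in counts),
            method="exhaustive",
        )

    n_total = n_distinct_relabelings(list(labels))
    if n_permutations >= n_total - 1:
        # budget covers every distinct relabeling: compute the exact test
        n_ge = sum(
            1
            for perm in _distinct_relabelings(labels)
            if not np.array_equal(perm, labels)
            and _r_statistic(ranks, _within_mask(perm)) >= r_obs - 1e-12
        )
        p = (1 + n_ge) / n_total
        return AnosimResult(
            R=float(r_obs),
            p_value=float(p),
            n_permutations=n_total - 1,
            seed=seed,
            group_sizes=tuple(int(c) for c in counts),
            method="monte-carlo",
        )
    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        if _r_statistic(ranks, _within_mask(perm)) >= r_obs - 1e-12:
            n_ge += 1
    p = (1 + n_ge) / (1 + n_permutations)
    return AnosimResult(
        R=float(r_obs),
        p_value=float(p),
        n_permutations=int(n_permutations),
        seed=seed,
        group_sizes=tuple(int(c) for c in counts),
        method="monte-carlo",
    )


def pairwise_anosim(
    ab: pd.DataFrame,
    metas_by_sample: dict[str, str],
    n_permutations: int = 9999,
    seed: int | None = None,
) -> dict[tuple[str, str], AnosimResult]:
    """ANOSIM for every pair of group labels; raw p-values, no correction.

    Multiple-testing correction across pairs is deliberately left to the
    caller.
    """
    labels = {s: metas_by_sample[str(s)] for s in ab.index}
    groups = sorted(set(labels.values()))
    results: dict[tuple[str, str], AnosimResult] = {}
    for i, ga in enumerate(groups):
        for gb in groups[i + 1 :]:
            samples = [s for s in ab.index if labels[s] in (ga, gb)]
            sub = ab.loc[samples]
            dm = bray_curtis(sub)
            results[(ga, gb)] = anosim(
                dm,
                [labels[s] for s in samples],
                n_permutations=n_permutations,
                seed=seed,
            )
    return results


def n_distinct_relabelings(groups: list[str]) -> int:
    """Multinomial count of distinct label arrangements."""
    labels = np.asarray([str(g) for g in groups])
    _, counts = np.unique(labels, return_counts=True)
    n = math.factorial(labels.size)
    for c in counts:
        n //= math.factorial(int(c))
    return n
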