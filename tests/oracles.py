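"""Independent brute-force oracles used to validate the library algorithms.

Everything here is deliberately naive — exhaustive clade enumeration, direct
per-column scans, double-loop rank computation — and shares no code with the
implementations under test.
"""

from __future__ import annotations

import numpy as np
from skbio import TreeNode


def all_clades(tree: TreeNode) -> list[frozenset[str]]:
    """Tip sets of every node in a rooted tree (tips included)."""
    clades = []
    for node in tree.traverse(include_self=True):
        clades.append(frozenset(t.name for t in node.tips(include_self=True)))
    return clades


def oracle_is_monophyletic(tree: TreeNode, tipset: set[str]) -> bool:
    return frozenset(tipset) in all_clades(tree)


def _oracle_consensus(lineages: list[tuple[str, str, str, str]]) -> tuple[str, str]:
    """lineages as (order, family, genus, species); species may be ''."""
    species = {l[3] for l in lineages if l[3]}
    genera = {l[2] for l in lineages}
    if len(species) == 1 and len(genera) == 1:
        return "species", next(iter(species))
    if len(genera) == 1:
        return "genus", next(iter(genera))
    families = {l[1] for l in lineages}
    if len(families) == 1:
        return "family", next(iter(families))
    orders = {l[0] for l in lineages}
    if len(orders) == 1:
        return "order", next(iter(orders))
    return "unclassified", "unknown"


def oracle_assign(
    tree: TreeNode,
    lineage_of: dict[str, tuple[str, str, str, str]],
    min_support: float | None = None,
) -> dict[str, tuple[str, str]]:
    """Enumerate every clade, filter, pick the smallest housing clade per query."""
    nodes = list(tree.traverse(include_self=True))
    out: dict[str, tuple[str, str]] = {}
    queries = [t.name for t in tree.tips() if t.name not in lineage_of]
    for q in queries:
        candidates = []
        for node in nodes:
            tips = {t.name for t in node.tips(include_self=True)}
            refs = sorted(tips & set(lineage_of))
            if q in tips and refs:
                sup = getattr(node, "support", None)
                if min_support is not None and sup is not None and sup < min_support:
                    continue
                candidates.append((len(tips), refs))
        if not candidates:
            out[q] = ("unclassified", "unknown")
            continue
        _, refs = min(candidates, key=lambda c: c[0])
        out[q] = _oracle_consensus([lineage_of[r] for r in refs])
    return out


def oracle_novel_clades(
    tree: TreeNode, ref_ids: set[str], min_size: int = 2
) -> set[frozenset[str]]:
    """Maximal query-only clades: query-only, big enough, parent not query-only."""
    result = set()
    for node in tree.traverse(include_self=False):
        tips = {t.name for t in node.tips(include_self=True)}
        if tips & ref_ids or len(tips) < min_size:
            continue
        parent_tips = {t.name for t in node.parent.tips(include_self=True)}
        if not parent_tips & ref_ids:
            continue  # nested inside a larger query-only clade
        result.add(frozenset(tips))
    return result


def oracle_gap_trim(rows: list[str], threshold: float) -> list[int]:
    """Column indices KEPT under the gap-stringency rule, by direct scan."""
    n_rows = len(rows)
    kept = []
    for c in range(len(rows[0])):
        gaps = sum(1 for r in rows if r[c] == "-")
        frac = gaps / n_rows
        if (threshold > 0 and frac < threshold) or (threshold == 0 and gaps == 0):
            kept.append(c)
    return kept


def oracle_low_count(totals: dict[str, int], max_total: int = 2) -> set[str]:
    """ASVs a direct total-count scan flags for removal."""
    return {a for a, t in totals.items() if t <= max_total}


def _avg_ranks(values: list[float]) -> list[float]:
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def oracle_anosim_r(d: np.ndarray, labels: list[str]) -> float:
    """ANOSIM R by explicit double loops and hand-rolled average ranks."""
    n = len(labels)
    pairs, values = [], []
    for i in range(n):
        for j in range(i + 1, n):
            pairs.append((i, j))
            values.append(float(d[i, j]))
    ranks = _avg_ranks(values)
    within = [ranks[k] for k, (i, j) in enumerate(pairs) if labels[i] == labels[j]]
    between = [ranks[k] for k, (i, j) in enumerate(pairs) if labels[i] != labels[j]]
    m = len(pairs)
    return (sum(between) / len(between) - sum(within) / len(within)) / (m / 2.0)


def oracle_exhaustive_anosim_p(d: np.ndarray, labels: list[str]) -> float:
    """Exact one-sided p by enumerating all distinct relabelings."""
    from itertools import permutations

    r_obs = oracle_anosim_r(d, labels)
    seen = set()
    n_ge = 0
    for perm in permutations(labels):
        if perm in seen:
            continue
        seen.add(perm)
        if oracle_anosim_r(d, list(perm)) >= r_obs - 1e-12:
            n_ge += 1
    return n_ge / len(seen)


def random_rooted_tree(
    rng: np.random.Generator, tip_names: list[str], with_lengths: bool = True
) -> TreeNode:
    """Random binary rooted tree by sequential random joins."""
    nodes = [TreeNode(name=n) for n in tip_names]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b, a = nodes.pop(j), nodes.pop(i)
        parent = TreeNode()
        if with_lengths:
            a.length = float(rng.uniform(0.01, 0.2))
            b.length = float(rng.uniform(0.01, 0.2))
        parent.append(a)
        parent.append(b)
        nodes.append(parent)
    return nodes[0]
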