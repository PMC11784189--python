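"""Tree I/O and rooted-tree algorithms.

Trees are represented as :class:`skbio.TreeNode` objects.  Internal-node
newick labels are interpreted as bootstrap support values (stored on
``node.support``); values parsed in [0, 1] are auto-scaled to the [0, 100]
convention with a warning, since newick dialects differ.

Maximum-likelihood inference is out of scope — trees are either consumed
(newick with branch lengths and supports) or built with the neighbor-joining
fallback from Jukes–Cantor distances, which is adequate for the low-divergence
desk-scale alignments the simulator produces.
"""

from __future__ import annotations

import io
import logging
import math
from pathlib import Path

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .msa import GAP, Msa

logger = logging.getLogger(__name__)

#: JC distance assigned to saturated pairs (p >= 3/4), substitutions/site.
JC_CEILING = 5.0


# ---------------------------------------------------------------------------
# newick I/O


def parse_newick(text: str) -> TreeNode:
    """Parse newick text; numeric internal labels become support values."""
    tree = TreeNode.read(io.StringIO(text))
    tips = [t.name for t in tree.tips()]
    dupes = {n for n in tips if tips.count(n) > 1}
    if dupes:
        raise ValueError(f"duplicate tip labels: {sorted(dupes)}")
    tree.assign_supports()
    supports = [
        n.support
        for n in tree.non_tips(include_self=True)
        if getattr(n, "support", None) is not None
    ]
    if supports and all(0 <= s <= 1 for s in supports) and any(0 < s < 1 for s in supports):
        logger.warning("support values look fractional; rescaling to [0, 100]")
        for n in tree.non_tips(include_self=True):
            if getattr(n, "support", None) is not None:
                n.support = n.support * 100.0
    return tree


def write_newick(tree: TreeNode, path: str | Path | None = None) -> str:
    """Serialize a tree to newick, writing supports as internal-node labels."""
    clone = tree.copy()
    for n in clone.non_tips(include_self=True):
        sup = getattr(n, "support", None)
        if sup is not None:
            n.name = f"{sup:g}"
    buf = io.StringIO()
    clone.write(buf)
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


def read_newick(path: str | Path) -> TreeNode:
    return parse_newick(Path(path).read_text(encoding="utf-8"))


# ---------------------------------------------------------------------------
# distances


def jc_distance(msa: Msa, ceiling: float = JC_CEILING) -> DistanceMatrix:
    """Jukes–Cantor distances between all rows of a (gapped) alignment.

    d = -(3/4) ln(1 - (4/3) p), with p the mismatch proportion over columns
    where both rows carry residues.  Saturated pairs (p >= 3/4) receive
    ``ceiling`` with a warning; pairs with no overlapping residue columns are
    an error.
    """
    n = msa.n_rows
    if n < 2:
        raise ValueError("need at least 2 rows")
    chars = msa.chars
    residue = chars != GAP
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = residue[i] & residue[j]
            m = int(both.sum())
            if m == 0:
                raise ValueError(
                    f"no overlapping residue columns between "
                    f"{msa.row_ids[i]!r} and {msa.row_ids[j]!r}"
                )
            p = float((chars[i, both] != chars[j, both]).mean())
            if p >= 0.75:
                logger.warning(
                    "saturated pair (%s, %s): p=%.3f >= 0.75, distance set to %g",
                    msa.row_ids[i], msa.row_ids[j], p, ceiling,
                )
                dij = ceiling
            else:
                dij = -0.75 * math.log(1.0 - (4.0 / 3.0) * p)
            d[i, j] = d[j, i] = dij
    return DistanceMatrix(d, ids=list(msa.row_ids))


# ---------------------------------------------------------------------------
# neighbor joining

# Hand-rolled rather than delegated so that Q-matrix ties break on the
# lexicographically smallest id pair — a reproducibility guarantee the tests
# rely on; skbio's NJ serves as the independent cross-check in the suite.


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Neighbor joining; returns an unrooted tree (trifurcating root).

    On additive matrices the generating topology is recovered exactly.
    Negative branch-length estimates are clamped to zero.
    """
    ids = list(dm.ids)
    if len(ids) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = {i: {j: float(dm[i, j]) for j in ids if j != i} for i in ids}
    nodes: dict[str, TreeNode] = {i: TreeNode(name=i) for i in ids}
    active = sorted(ids)

    while len(active) > 3:
        n = len(active)
        r = {i: sum(d[i][j] for j in active if j != i) for i in active}
        best_pair, best_q = None, math.inf
        for a in range(len(active)):
            for b in range(a + 1, len(active)):
                i, j = active[a], active[b]
                q = (n - 2) * d[i][j] - r[i] - r[j]
                if q < best_q - 1e-12 or (
                    abs(q - best_q) <= 1e-12 and (i, j) < best_pair
                ):
                    best_q, best_pair = q, (i, j)
        i, j = best_pair
        li = 0.5 * d[i][j] + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = d[i][j] - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = TreeNode()
        nodes[i].length, nodes[j].length = li, lj
        parent.append(nodes[i])
        parent.append(nodes[j])
        new_id = min(i, j)  # representative id keeps tie-breaks deterministic
        d_new = {
            k: 0.5 * (d[i][k] + d[j][k] - d[i][j]) for k in active if k not in (i, j)
        }
        for k in list(d_new):
            d[k].pop(i, None)
            d[k].pop(j, None)
            d[k][new_id] = d_new[k]
        d.pop(i), d.pop(j)
        d[new_id] = d_new
        nodes.pop(i), nodes.pop(j)
        nodes[new_id] = parent
        active = sorted(set(active) - {i, j} | {new_id})

    a, b, c = active
    la = 0.5 * (d[a][b] + d[a][c] - d[b][c])
    lb = 0.5 * (d[a][b] + d[b][c] - d[a][c])
    lc = 0.5 * (d[a][c] + d[b][c] - d[a][b])
    root = TreeNode()
    for node_id, length in ((a, la), (b, lb), (c, lc)):
        nodes[node_id].length = max(length, 0.0)
        root.append(nodes[node_id])
    return root


# ---------------------------------------------------------------------------
# rooting and clade queries


def root_on_outgroup(tree: TreeNode, outgroup_ids: set[str] | list[str]) -> TreeNode:
    """Root on the edge separating the outgroup from the ingroup.

    If the outgroup is not a connected cluster in the unrooted tree, a warning
    is issued and the root is placed on the edge above the outgroup's smallest
    enclosing clade.  The returned root carries ``outgroup_ids``.
    """
    outgroup = set(outgroup_ids)
    tips = {t.name for t in tree.tips()}
    unknown = outgroup - tips
    if unknown:
        raise ValueError(f"outgroup ids not in tree: {sorted(unknown)}")
    if not outgroup or outgroup == tips:
        raise ValueError("outgroup must be a non-empty proper subset of tips")
    try:
        rooted = tree.root_by_outgroup(sorted(outgroup))
    except Exception:
        # non-monophyletic outgroup: root above its smallest enclosing clade
        logger.warning(
            "outgroup is not a connected cluster; rooting on its smallest "
            "enclosing edge"
        )
        work = tree.copy()
        mrca_node = work.lca(sorted(outgroup))
        if mrca_node.is_root():
            # enclosing clade is the whole tree under the current (arbitrary)
            # rooting; re-root at a non-outgroup tip first
            other = sorted(tips - outgroup)[0]
            work = work.root_at(
                next(t for t in work.tips() if t.name == other).parent
            )
            mrca_node = work.lca(sorted(outgroup))
        rooted = work.root_at(mrca_node, above=True, reset=True)
    rooted.outgroup_ids = frozenset(outgroup)
    return rooted


def mrca(tree: TreeNode, tipset: set[str] | list[str]) -> TreeNode:
    """Most recent common ancestor of a set of tips in a rooted tree."""
    tipset = set(tipset)
    if not tipset:
        raise ValueError("tipset is empty")
    tips = {t.name for t in tree.tips()}
    unknown = tipset - tips
    if unknown:
        raise ValueError(f"unknown tip ids: {sorted(unknown)}")
    if len(tipset) == 1:
        return next(t for t in tree.tips() if t.name in tipset)
    return tree.lca(sorted(tipset))


def is_monophyletic(tree: TreeNode, tipset: set[str] | list[str]) -> bool:
    """True iff the MRCA's descendant tips equal the tipset exactly."""
    tipset = set(tipset)
    node = mrca(tree, tipset)
    return {t.name for t in node.tips(include_self=True)} == tipset


def long_branch_tips(
    tree: TreeNode, factor: float = 5.0, scope: str = "tips"
) -> list:
    """Flag unusually long terminal (or clade-root) branches.

    A branch is flagged when its length exceeds ``factor`` times the median
    tip branch length.  ``scope="tips"`` returns flagged tip ids;
    ``scope="clades"`` returns tuples of descendant tip ids for flagged
    internal edges.  All-zero branch lengths yield an empty result with a
    warning.
    """
    if scope not in ("tips", "clades"):
        raise ValueError("scope must be 'tips' or 'clades'")
    tip_lengths = [(t.name, t.length or 0.0) for t in tree.tips()]
    med = float(np.median([l for _, l in tip_lengths]))
    if med == 0.0 and all(l == 0.0 for _, l in tip_lengths):
        logger.warning("all tip branch lengths are zero; nothing to flag")
        return []
    threshold = factor * med
    if scope == "tips":
        return [name for name, l in tip_lengths if l > threshold]
    flagged = []
    for node in tree.non_tips():
        if (node.length or 0.0) > threshold:
            flagged.append(tuple(sorted(t.name for t in node.tips())))
    return flagged


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial unrooted splits, each as the smaller-side tip set."""
    all_tips = frozenset(t.name for t in tree.tips())
    splits: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(all_tips) - 1:
            other = all_tips - side
            splits.add(min(side, other, key=lambda s: (len(s), sorted(s))))
    return splits


def same_topology(a: TreeNode, b: TreeNode) -> bool:
    """Unrooted topological equality: same tips and same split sets."""
    if {t.name for t in a.tips()} != {t.name for t in b.tips()}:
        return False
    return bipartitions(a) == bipartitions(b)


def write_distance_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    """Square distance matrix as TSV with header row and column."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t" + "\t".join(dm.ids) + "\n")
        for i in dm.ids:
            fh.write(i + "\t" + "\t".join(f"{dm[i, j]:.10g}" for j in dm.ids) + "\n")


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(df.values, ids=[str(i) for i in df.index])
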