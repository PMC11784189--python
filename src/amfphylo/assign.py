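"""Monophyly-based taxonomy assignment of query ASVs.

Each query tip is annotated from the smallest monophyletic group that houses
it together with curated reference sequences: walking rootward from the tip,
the first ancestor whose descendants include at least one reference (and, if
a support threshold is given, whose support clears it) is the *housing
clade*.  The assigned taxon is the deepest rank at which all reference
lineages in the housing clade agree (species > genus > family > order);
order-level disagreement yields ``unclassified`` / ``"unknown"``.

Query-only clades of configurable minimum size are reported as putative novel
lineages, and each assignment carries diagnostics for long terminal branches
and clade-exclusive alignment insertions — the two signatures that flag
divergent or poorly aligned ASV groups in AMF 18S phylogenies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import pandas as pd
from skbio import TreeNode

from .msa import Msa, clade_exclusive_columns
from .refset import ReferenceRecord
from .tree import long_branch_tips

logger = logging.getLogger(__name__)

RANKS = ("species", "genus", "family", "order")


@dataclass(frozen=True)
class Assignment:
    """Taxonomic call and diagnostics for one query ASV."""

    asv_id: str
    rank: str  # species | genus | family | order | unclassified
    taxon: str  # name, or "unknown" when unclassified
    housing_clade_support: float | None = None
    novel_clade_id: str | None = None
    long_branch: bool = False
    exclusive_insertion_cols: int = 0


@dataclass(frozen=True)
class NovelClade:
    """A maximal query-only clade."""

    clade_id: str
    member_ids: tuple[str, ...]
    support: float | None


def _support_ok(node: TreeNode, min_support: float | None) -> bool:
    # nodes without a support value (root, tips) cannot be evaluated and pass
    if min_support is None:
        return True
    sup = getattr(node, "support", None)
    return sup is None or sup >= min_support


def _consensus(refs: list[ReferenceRecord]) -> tuple[str, str]:
    """Deepest unanimous rank over reference lineages -> (rank, taxon)."""
    species = {r.species for r in refs if r.species}
    if len(species) == 1 and all(
        not r.species or r.species == next(iter(species)) for r in refs
    ):
        # references identified only to genus contribute no species evidence,
        # but must not contradict at genus level for the species call to hold
        sp = next(iter(species))
        genus = sp.split()[0]
        if all(r.genus == genus for r in refs):
            return "species", sp
    for rank, attr in (("genus", "genus"), ("family", "family"), ("order", "order_")):
        values = {getattr(r, attr) for r in refs}
        if len(values) == 1:
            return rank, next(iter(values))
    return "unclassified", "unknown"


def assign_taxonomy(
    tree: TreeNode,
    references: list[ReferenceRecord],
    min_support: float | None = None,
) -> list[Assignment]:
    """Assign taxonomy to every query tip of a rooted tree.

    Tips whose labels appear in the reference taxonomy are references; all
    other tips are queries.  Deterministic given the tree and taxonomy:
    results are sorted by asv_id.
    """
    ref_by_id = {r.seq_id: r for r in references}
    tip_nodes = list(tree.tips())
    ref_tips = {t.name for t in tip_nodes if t.name in ref_by_id}
    if not ref_tips:
        raise ValueError("no reference tips in tree")
    query_tips = [t for t in tip_nodes if t.name not in ref_by_id]

    # per-node reference descendants, computed once bottom-up
    ref_desc: dict[int, list[str]] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            ref_desc[id(node)] = [node.name] if node.name in ref_by_id else []
        else:
            acc: list[str] = []
            for ch in node.children:
                acc.extend(ref_desc[id(ch)])
            ref_desc[id(node)] = acc

    out = []
    for q in query_tips:
        node = q.parent
        housing = None
        while node is not None:
            if ref_desc[id(node)] and _support_ok(node, min_support):
                housing = node
                break
            node = node.parent
        if housing is None:
            out.append(Assignment(asv_id=q.name, rank="unclassified", taxon="unknown"))
            continue
        refs = [ref_by_id[i] for i in sorted(set(ref_desc[id(housing)]))]
        rank, taxon = _consensus(refs)
        out.append(
            Assignment(
                asv_id=q.name,
                rank=rank,
                taxon=taxon,
                housing_clade_support=getattr(housing, "support", None),
            )
        )
    return sorted(out, key=lambda a: a.asv_id)


def detect_novel_clades(
    tree: TreeNode,
    reference_ids: set[str],
    min_novel_size: int = 2,
    min_support: float | None = None,
) -> list[NovelClade]:
    """Maximal query-only clades of size >= min_novel_size, root-to-tip order."""
    clades: list[NovelClade] = []

    def _visit(node: TreeNode) -> None:
        tips = [t.name for t in node.tips(include_self=True)]
        if all(t not in reference_ids for t in tips):
            if len(tips) >= min_novel_size and _support_ok(node, min_support):
                clades.append(
                    NovelClade(
                        clade_id=f"novel_{len(clades) + 1}",
                        member_ids=tuple(sorted(tips)),
                        support=getattr(node, "support", None),
                    )
                )
                return  # maximal: do not report nested query-only clades
            if len(tips) >= min_novel_size:
                pass  # unsupported: children may still qualify
        for ch in node.children:
            _visit(ch)

    # preorder from root, but the root itself can never be query-only when
    # references are present
    for ch in tree.children:
        _visit(ch)
    return clades


def apply_novel_clades(
    assignments: list[Assignment], clades: list[NovelClade]
) -> list[Assignment]:
    """Attach novel_clade_id to the member assignments."""
    clade_of = {m: c.clade_id for c in clades for m in c.member_ids}
    return [
        replace(a, novel_clade_id=clade_of[a.asv_id]) if a.asv_id in clade_of else a
        for a in assignments
    ]


def annotate_diagnostics(
    assignments: list[Assignment],
    tree: TreeNode,
    msa: Msa,
    factor: float = 5.0,
    f_in: float = 0.5,
) -> list[Assignment]:
    """Enrich assignments with long-branch and exclusive-insertion diagnostics.

    Long branches are flagged per tip; exclusive insertion columns are counted
    per novel clade (the clade's private columns in the alignment) and written
    onto every member.
    """
    tree_tips = {t.name for t in tree.tips()}
    msa_rows = set(msa.row_ids)
    if not tree_tips <= msa_rows:
        diff = sorted(tree_tips ^ msa_rows)
        raise ValueError(f"tree/alignment tip mismatch (symmetric difference): {diff}")
    flagged = set(long_branch_tips(tree, factor=factor, scope="tips"))
    insertion_count: dict[str, int] = {}
    clades: dict[str, list[str]] = {}
    for a in assignments:
        if a.novel_clade_id:
            clades.setdefault(a.novel_clade_id, []).append(a.asv_id)
    for clade_id, members in clades.items():
        cols = clade_exclusive_columns(msa, set(members), f_in=f_in)
        for m in members:
            insertion_count[m] = len(cols)
    return [
        replace(
            a,
            long_branch=a.asv_id in flagged,
            exclusive_insertion_cols=insertion_count.get(a.asv_id, 0),
        )
        for a in assignments
    ]


def filter_off_target(
    assignments: list[Assignment],
    tree: TreeNode,
    outgroup_ids: set[str] | None = None,
) -> tuple[list[Assignment], list[Assignment]]:
    """Split assignments into (kept, removed) on outgroup-side placement.

    Queries placed inside a root-child subtree that contains outgroup tips,
    or attached directly to the root, are off-target (non-Glomeromycotan in
    the study's terms) and removed.
    """
    if outgroup_ids is None:
        outgroup_ids = set(getattr(tree, "outgroup_ids", ()) or ())
    off_subtrees = []
    root_children = list(tree.children)
    for ch in root_children:
        tips = {t.name for t in ch.tips(include_self=True)}
        if tips & set(outgroup_ids):
            off_subtrees.append(tips)
    off_tips: set[str] = set().union(*off_subtrees) if off_subtrees else set()
    direct = {ch.name for ch in root_children if ch.is_tip()}
    kept, removed = [], []
    for a in assignments:
        if a.asv_id in off_tips or a.asv_id in direct:
            removed.append(a)
        else:
            kept.append(a)
    if removed:
        logger.info(
            "removed %d off-target queries: %s",
            len(removed), [a.asv_id for a in removed],
        )
    return kept, removed


def annotate_queries(
    tree: TreeNode,
    references: list[ReferenceRecord],
    msa: Msa | None = None,
    min_support: float | None = None,
    min_novel_size: int = 2,
    factor: float = 5.0,
    f_in: float = 0.5,
) -> list[Assignment]:
    """Full annotation: assign, detect novel clades, attach diagnostics."""
    assignments = assign_taxonomy(tree, references, min_support=min_support)
    ref_ids = {r.seq_id for r in references}
    clades = detect_novel_clades(
        tree, ref_ids, min_novel_size=min_novel_size, min_support=min_support
    )
    assignments = apply_novel_clades(assignments, clades)
    if msa is not None:
        assignments = annotate_diagnostics(
            assignments, tree, msa, factor=factor, f_in=f_in
        )
    return assignments


def write_assignments(assignments: list[Assignment], path: str | Path) -> None:
    rows = [
        {
            "asv_id": a.asv_id,
            "rank": a.rank,
            "taxon": a.taxon,
            "housing_clade_support": (
                "" if a.housing_clade_support is None else f"{a.housing_clade_support:g}"
            ),
            "novel_clade_id": a.novel_clade_id or "",
            "long_branch": str(a.long_branch).lower(),
            "exclusive_insertion_cols": a.exclusive_insertion_cols,
        }
        for a in assignments
    ]
    pd.DataFrame(
        rows,
        columns=[
            "asv_id", "rank", "taxon", "housing_clade_support",
            "novel_clade_id", "long_branch", "exclusive_insertion_cols",
        ],
    ).to_csv(path, sep="\t", index=False)


def read_assignments(path: str | Path) -> list[Assignment]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        out.append(
            Assignment(
                asv_id=row.asv_id,
                rank=row.rank,
                taxon=row.taxon,
                housing_clade_support=(
                    float(row.housing_clade_support) if row.housing_clade_support else None
                ),
                novel_clade_id=row.novel_clade_id or None,
                long_branch=row.long_branch == "true",
                exclusive_insertion_cols=int(row.exclusive_insertion_cols),
            )
        )
    return out
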