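"""Synthetic AMF amplicon datasets with full ground truth.

The generator emulates the statistical structure of a rootstock x treatment
AMF community study: a curated two-set 18S reference world (species tree with
genus/family/order structure and a basal *Paraglomus* outgroup), intragenomic
rRNA variants (each species represented by up to dozens of ASVs), ~800 bp
AML1/AML2 amplicons, a genotype x treatment x replicate design at 10,000
reads per sample, and planted treatment effects: taxon dropout, enrichment of
a distantly related clade, a query-only novel lineage carrying a
clade-exclusive insertion, and off-target (outgroup-side) sequences.

Sequences evolve under a Jukes–Cantor-like substitution process (uniform
alternative bases) with rare geometric-length indels.  Every alignment column
carries a float key assigned at creation, so the *true* multiple alignment of
any set of simulated sequences is available exactly, without an external
aligner.  Primer-binding sites are held invariant so the amplicon window stays
locatable.

All randomness flows from a single ``numpy.random.default_rng(cfg.seed)``
stream consumed in a fixed order; a fixed seed reproduces every output file
byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from .community import SampleMeta, write_counts, write_metadata
from .msa import AML1, AML2, Msa, _revcomp
from .refset import ReferenceRecord, write_queries, write_references
from .refset import QueryRecord
from .tree import write_newick

logger = logging.getLogger(__name__)

BASES = np.array(list("ACGT"), dtype="U1")


@dataclass(frozen=True)
class Effect:
    """A planted treatment effect on the community composition.

    kind: "dropout" (taxon mass set to 0) or "enrich" (mass multiplied).
    taxon: a species or genus name from the simulated world.
    treatment: treatment in which the effect applies.
    genotypes: restrict to these genotypes (None = all).
    """

    kind: str
    taxon: str
    treatment: str
    factor: float = 1.0
    genotypes: tuple[str, ...] | None = None


@dataclass(frozen=True)
class SimConfig:
    """Study-calibrated simulation settings.

    Defaults mirror the study design: ~800 bp AML1/2 amplicons, 10,000 reads
    per sample, 4 rootstock genotypes x {PP, C, CM1x} x 5 replicates, species
    represented by 1–30 intragenomic variants, and a curated reference world
    of 24 genera / 91 species / 174 accessions split into two sets (set B
    with 28 accessions).
    """

    seed: int = 0
    n_genera: int = 24
    n_species: int = 91
    n_reference_accessions: int = 174
    set_b_size: int = 28
    genera_per_family: int = 3
    families_per_order: int = 2
    amplicon_len: int = 800
    flank_len: int = 25
    variants_min: int = 1
    variants_max: int = 30
    variant_divergence: float = 0.005
    accession_divergence: float = 0.002
    indel_rate: float = 0.0005
    genotypes: tuple[str, ...] = ("G.890", "G.935", "M.7", "M.26")
    treatments: tuple[str, ...] = ("PP", "C", "CM1x")
    replicates: int = 5
    reads_per_sample: int = 10_000
    n_community_genera: int = 4
    n_community_species: int = 12
    replicate_concentration: float = 200.0
    n_off_target: int = 3
    off_target_fraction: float = 0.01
    novel_insertion_len: int = 12
    novel_extra_divergence: float = 0.15
    novel_variants_min: int = 4  # the unknown lineage spans several ASVs
    effects: tuple[Effect, ...] | None = None  # None = study-default effects

    def __post_init__(self) -> None:
        for rate in (self.variant_divergence, self.indel_rate, self.accession_divergence):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        if self.replicates < 2:
            raise ValueError("need >= 2 replicates per group (ANOSIM requirement)")
        if self.variants_min < 1 or self.variants_max < self.variants_min:
            raise ValueError("invalid variants range")
        if self.n_species < self.n_genera:
            raise ValueError("need at least one species per genus")
        if self.n_reference_accessions < self.n_species:
            raise ValueError("need at least one accession per species")


# ---------------------------------------------------------------------------
# sequence evolution with tracked alignment columns


@dataclass
class EvoSeq:
    """A sequence whose residues carry persistent alignment-column keys."""

    keys: np.ndarray  # float64, strictly increasing
    bases: np.ndarray  # U1
    conserved: np.ndarray  # bool; True = immune to substitution/indel

    def copy(self) -> "EvoSeq":
        return EvoSeq(self.keys.copy(), self.bases.copy(), self.conserved.copy())

    def __len__(self) -> int:
        return self.keys.size

    def ungapped(self) -> str:
        return "".join(self.bases)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(BASES, size=n))


def make_root_seq(cfg: SimConfig, rng: np.random.Generator) -> EvoSeq:
    """Flank + AML1 + core + revcomp(AML2) + flank, primers conserved."""
    rc2 = _revcomp(AML2)
    core_len = cfg.amplicon_len - len(AML1) - len(rc2)
    parts = [
        (_random_seq(rng, cfg.flank_len), False),
        (AML1, True),
        (_random_seq(rng, core_len), False),
        (rc2, True),
        (_random_seq(rng, cfg.flank_len), False),
    ]
    seq = "".join(p for p, _ in parts)
    conserved = np.concatenate(
        [np.full(len(p), flag, dtype=bool) for p, flag in parts]
    )
    return EvoSeq(
        keys=np.arange(len(seq), dtype=float),
        bases=np.array(list(seq), dtype="U1"),
        conserved=conserved,
    )


def evolve(
    seq: EvoSeq,
    branch_length: float,
    rng: np.random.Generator,
    indel_rate: float = 0.0,
    mean_indel_len: float = 3.0,
) -> EvoSeq:
    """Evolve a sequence along a branch (substitutions/site) with rare indels.

    Substitutions are Poisson(branch_length x L) uniform base changes;
    indel events are Poisson(indel_rate x L), each a geometric-length
    insertion or deletion.  Conserved (primer) positions are immune, and
    insertions never split a conserved run.
    """
    out = seq.copy()
    L = len(out)
    n_sub = rng.poisson(branch_length * L)
    if n_sub:
        eligible = np.flatnonzero(~out.conserved)
        if eligible.size:
            pos = rng.choice(eligible, size=n_sub)
            for p in pos:
                alt = BASES[BASES != out.bases[p]]
                out.bases[p] = rng.choice(alt)
    n_indel = rng.poisson(indel_rate * L)
    for _ in range(n_indel):
        length = int(rng.geometric(1.0 / mean_indel_len))
        if rng.random() < 0.5 and len(out) > length:  # deletion
            eligible = np.flatnonzero(~out.conserved)
            if not eligible.size:
                continue
            start_i = int(rng.choice(eligible))
            # delete contiguous non-conserved positions, stopping at primers
            idx = []
            i = start_i
            while i < len(out) and len(idx) < length and not out.conserved[i]:
                idx.append(i)
                i += 1
            keep = np.ones(len(out), dtype=bool)
            keep[idx] = False
            out = EvoSeq(out.keys[keep], out.bases[keep], out.conserved[keep])
        else:  # insertion
            slot = int(rng.integers(0, len(out) + 1))
            left_cons = out.conserved[slot - 1] if slot > 0 else False
            right_cons = out.conserved[slot] if slot < len(out) else False
            if left_cons and right_cons:
                continue  # would split a primer
            lo = out.keys[slot - 1] if slot > 0 else out.keys[0] - 1.0
            hi = out.keys[slot] if slot < len(out) else out.keys[-1] + 1.0
            new_keys = np.sort(rng.uniform(lo, hi, size=length))
            new_bases = rng.choice(BASES, size=length)
            out = EvoSeq(
                np.concatenate([out.keys[:slot], new_keys, out.keys[slot:]]),
                np.concatenate([out.bases[:slot], new_bases, out.bases[slot:]]),
                np.concatenate(
                    [out.conserved[:slot], np.zeros(length, dtype=bool), out.conserved[slot:]]
                ),
            )
    return out


def insert_block(seq: EvoSeq, length: int, rng: np.random.Generator) -> EvoSeq:
    """Plant a contiguous insertion of ``length`` columns at a random core slot."""
    out = seq.copy()
    eligible = [
        s
        for s in range(1, len(out))
        if not (out.conserved[s - 1] or out.conserved[s])
    ]
    slot = int(rng.choice(eligible))
    lo, hi = out.keys[slot - 1], out.keys[slot]
    new_keys = np.sort(rng.uniform(lo, hi, size=length))
    return EvoSeq(
        np.concatenate([out.keys[:slot], new_keys, out.keys[slot:]]),
        np.concatenate([out.bases[:slot], rng.choice(BASES, size=length), out.bases[slot:]]),
        np.concatenate(
            [out.conserved[:slot], np.zeros(length, dtype=bool), out.conserved[slot:]]
        ),
    )


def true_alignment(seqs: dict[str, EvoSeq]) -> Msa:
    """Exact multiple alignment of tracked sequences via their column keys."""
    all_keys = np.unique(np.concatenate([s.keys for s in seqs.values()]))
    rows = []
    for s in seqs.values():
        row = np.full(all_keys.size, "-", dtype="U1")
        row[np.searchsorted(all_keys, s.keys)] = s.bases
        rows.append("".join(row))
    return Msa(list(seqs.keys()), rows)


def amplicon_of(seq: EvoSeq) -> EvoSeq:
    """Trim to the amplicon: from the first to the last conserved column."""
    cons = np.flatnonzero(seq.conserved)
    lo, hi = cons[0], cons[-1] + 1
    return EvoSeq(seq.keys[lo:hi], seq.bases[lo:hi], seq.conserved[lo:hi])


# ---------------------------------------------------------------------------
# reference world


@dataclass
class Species:
    species_id: str
    name: str  # binomial, begins with genus
    genus: str
    family: str
    order: str
    seq: EvoSeq = None  # type: ignore[assignment]
    is_outgroup: bool = False
    is_novel: bool = False


@dataclass
class ReferenceWorld:
    """Species tree, sequences, accessions and taxonomy of the simulated clade."""

    cfg: SimConfig
    species: dict[str, Species]
    species_tree: TreeNode  # tips = species ids; outgroup basal
    accessions: list[ReferenceRecord]
    accession_seqs: dict[str, EvoSeq]
    accession_species: dict[str, str]  # accession id -> species id
    outgroup_species_ids: tuple[str, ...]
    novel_species_id: str
    community_species_ids: tuple[str, ...]


def _partition(total: int, parts: int) -> list[int]:
    base, extra = divmod(total, parts)
    return [base + (1 if i < extra else 0) for i in range(parts)]


def _join_random(
    nodes: list[TreeNode], rng: np.random.Generator, lo: float, hi: float
) -> TreeNode:
    """Randomly join subtrees pairwise into one binary tree."""
    nodes = list(nodes)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[j], nodes[i]  # pop higher index first
        nodes.pop(j), nodes.pop(i)
        parent = TreeNode()
        a.length = float(rng.uniform(lo, hi))
        b.length = float(rng.uniform(lo, hi))
        parent.append(a)
        parent.append(b)
        nodes.append(parent)
    return nodes[0]


def simulate_reference_world(cfg: SimConfig) -> ReferenceWorld:
    """Build the curated reference world: taxonomy, species tree, sequences.

    Taxonomy follows tree structure by construction (genera, families and
    orders are monophyletic), so recovery of the planted species labels by
    monophyly-based assignment is well defined.
    """
    rng = np.random.default_rng(cfg.seed)

    # taxonomy scaffold; the basal Paraglomus outgroup counts among the
    # curated genera/species, as in the study's reference sets
    n_og_species = 2
    genus_sizes = _partition(cfg.n_species - n_og_species, cfg.n_genera - 1)
    species: dict[str, Species] = {}
    genus_of_family: dict[str, list[str]] = {}
    family_of_order: dict[str, list[str]] = {}
    for g in range(cfg.n_genera - 1):
        fam = g // cfg.genera_per_family
        order = fam // cfg.families_per_order
        genus = f"Genus{g + 1:02d}"
        family = f"Family{fam + 1:02d}"
        order_name = f"Order{order + 1:02d}"
        genus_of_family.setdefault(family, []).append(genus)
        if family not in family_of_order.setdefault(order_name, []):
            family_of_order[order_name].append(family)
        for s in range(genus_sizes[g]):
            sid = f"sp_{g + 1:02d}_{s + 1:02d}"
            species[sid] = Species(
                species_id=sid,
                name=f"{genus} simulans{s + 1:02d}",
                genus=genus,
                family=family,
                order=order_name,
            )

    # outgroup: basal Paraglomus pair
    for i, epithet in enumerate(("occultum", "laccatum")):
        sid = f"sp_og_{i + 1:02d}"
        species[sid] = Species(
            species_id=sid,
            name=f"Paraglomus {epithet}",
            genus="Paraglomus",
            family="Paraglomeraceae",
            order="Paraglomerales",
            is_outgroup=True,
        )
    outgroup_ids = ("sp_og_01", "sp_og_02")

    # species tree respecting the taxonomy
    genus_trees: dict[str, TreeNode] = {}
    for genus in sorted({sp.genus for sp in species.values() if not sp.is_outgroup}):
        tips = [
            TreeNode(name=sid)
            for sid, sp in sorted(species.items())
            if sp.genus == genus
        ]
        genus_trees[genus] = (
            tips[0] if len(tips) == 1 else _join_random(tips, rng, 0.005, 0.02)
        )
    family_trees = {
        fam: _join_random([genus_trees[g] for g in genera], rng, 0.02, 0.05)
        for fam, genera in sorted(genus_of_family.items())
    }
    order_trees = {
        order: _join_random([family_trees[f] for f in fams], rng, 0.03, 0.06)
        for order, fams in sorted(family_of_order.items())
    }
    ingroup = _join_random(list(order_trees.values()), rng, 0.04, 0.08)

    # planted novel lineage: an undescribed, query-only species branching at
    # family depth inside the ingroup, with extra divergence
    novel_id = "sp_novel_01"
    species[novel_id] = Species(
        species_id=novel_id,
        name="unknown sp01",
        genus="unknown",
        family="unknown",
        order="unknown",
        is_novel=True,
    )
    attach = ingroup.children[0]
    novel_tip = TreeNode(name=novel_id, length=float(cfg.novel_extra_divergence))
    new_inner = TreeNode(length=attach.length / 2.0)
    attach.parent.append(new_inner)
    attach.parent.remove(attach)
    attach.length = attach.length / 2.0
    new_inner.append(attach)
    new_inner.append(novel_tip)

    og_a = TreeNode(name=outgroup_ids[0], length=0.02)
    og_b = TreeNode(name=outgroup_ids[1], length=0.02)
    og = TreeNode(length=0.20)
    og.append(og_a)
    og.append(og_b)
    root = TreeNode()
    ingroup.length = 0.05
    root.append(ingroup)
    root.append(og)

    # evolve sequences down the species tree
    root_seq = make_root_seq(cfg, rng)
    seq_at: dict[int, EvoSeq] = {id(root): root_seq}
    for node in root.preorder(include_self=False):
        parent_seq = seq_at[id(node.parent)]
        child_seq = evolve(
            parent_seq, node.length or 0.0, rng, indel_rate=cfg.indel_rate
        )
        if node.is_tip() and node.name == novel_id:
            child_seq = insert_block(child_seq, cfg.novel_insertion_len, rng)
        seq_at[id(node)] = child_seq
        if node.is_tip():
            species[node.name].seq = child_seq

    # reference accessions: every described species gets >= 1, extras cycle
    described = [
        sid for sid, sp in sorted(species.items()) if not sp.is_novel
    ]
    n_extra = cfg.n_reference_accessions - len(described)
    alloc = {sid: 1 for sid in described}
    for i in range(max(n_extra, 0)):
        alloc[described[i % len(described)]] += 1
    accessions: list[ReferenceRecord] = []
    accession_seqs: dict[str, EvoSeq] = {}
    accession_species: dict[str, str] = {}
    k = 0
    for sid in described:
        sp = species[sid]
        for _ in range(alloc[sid]):
            k += 1
            acc_id = f"REF{k:04d}"
            acc_seq = evolve(sp.seq, cfg.accession_divergence, rng, indel_rate=0.0)
            accession_seqs[acc_id] = acc_seq
            accession_species[acc_id] = sid
            accessions.append(
                ReferenceRecord(
                    seq_id=acc_id,
                    sequence=acc_seq.ungapped(),
                    order_=sp.order,
                    family=sp.family,
                    genus=sp.genus,
                    species=sp.name,
                    is_type_culture=bool(k % 8 == 0),
                    source_set="set_A",
                )
            )
    # last set_b_size accessions form reference set B (a smaller second study)
    if cfg.set_b_size:
        accessions = [
            dataclasses.replace(r, source_set="set_B")
            if i >= len(accessions) - cfg.set_b_size
            else r
            for i, r in enumerate(accessions)
        ]

    # community species pool: a handful of genera, plus the novel lineage
    ingroup_genera = sorted(
        {sp.genus for sp in species.values() if not (sp.is_outgroup or sp.is_novel)}
    )
    pool_genera = list(
        rng.choice(ingroup_genera, size=cfg.n_community_genera, replace=False)
    )
    candidates = [
        sid
        for sid, sp in sorted(species.items())
        if sp.genus in pool_genera and not sp.is_novel
    ]
    n_pick = min(cfg.n_community_species - 1, len(candidates))
    pool = sorted(rng.choice(candidates, size=n_pick, replace=False))
    pool.append(novel_id)

    return ReferenceWorld(
        cfg=cfg,
        species=species,
        species_tree=root,
        accessions=accessions,
        accession_seqs=accession_seqs,
        accession_species=accession_species,
        outgroup_species_ids=outgroup_ids,
        novel_species_id=novel_id,
        community_species_ids=tuple(pool),
    )


def simulate_intragenomic_variants(
    species_seq: EvoSeq, cfg: SimConfig, rng: np.random.Generator
) -> list[EvoSeq]:
    """Intragenomic rRNA variants of one species (1 to dozens of copies)."""
    n = int(rng.integers(cfg.variants_min, cfg.variants_max + 1))
    return [
        evolve(species_seq, cfg.variant_divergence, rng, indel_rate=cfg.indel_rate)
        for _ in range(n)
    ]


# ---------------------------------------------------------------------------
# communities


@dataclass
class GroundTruth:
    """Planted truth: variant->species map, compositions, effect manifest."""

    asv_species: dict[str, str]  # ASV id -> species id or "off_target"
    sample_composition: dict[str, dict[str, float]]  # sample -> species -> mass
    effects: tuple[Effect, ...]
    novel_species_id: str
    novel_asv_ids: tuple[str, ...]
    off_target_asv_ids: tuple[str, ...]


@dataclass
class CommunityData:
    counts: pd.DataFrame  # samples x ASVs
    metas: list[SampleMeta]
    queries: list[QueryRecord]
    query_seqs: dict[str, EvoSeq]  # amplicon-trimmed tracked sequences
    tree: TreeNode  # true tree over accessions + observed ASVs
    truth: GroundTruth


def default_effects(world: ReferenceWorld) -> tuple[Effect, ...]:
    """Study-default planted effects, resolved to concrete simulated taxa.

    In the inoculated treatment (CM1x) the dominant pool genus drops out of
    the last genotype and a distantly related pool genus is enriched fivefold
    everywhere — mirroring the dropout of resident taxa and the stimulation
    of a distant clade under inoculation.
    """
    pool = [world.species[s] for s in world.community_species_ids if s != world.novel_species_id]
    genera = sorted({sp.genus for sp in pool})
    drop_genus = genera[0]
    enrich_genus = genera[-1] if len(genera) > 1 else genera[0]
    return (
        Effect(
            kind="dropout",
            taxon=drop_genus,
            treatment="CM1x",
            genotypes=(world.cfg.genotypes[-1],),
        ),
        Effect(kind="enrich", taxon=enrich_genus, treatment="CM1x", factor=5.0),
    )


def _effect_applies(e: Effect, sp: Species, genotype: str, treatment: str) -> bool:
    if e.treatment != treatment:
        return False
    if e.genotypes is not None and genotype not in e.genotypes:
        return False
    return e.taxon in (sp.genus, sp.name, sp.species_id)


def simulate_communities(cfg: SimConfig, world: ReferenceWorld) -> CommunityData:
    """Generate the count table, metadata, queries, true tree and ground truth."""
    rng = np.random.default_rng(cfg.seed + 1)
    effects = cfg.effects if cfg.effects is not None else default_effects(world)
    for e in effects:
        known = {sp.genus for sp in world.species.values()} | {
            sp.name for sp in world.species.values()
        } | set(world.species)
        if e.taxon not in known:
            raise ValueError(f"effect references unknown taxon {e.taxon!r}")

    pool = list(world.community_species_ids)

    # intragenomic variants per pool species -> ASVs
    asv_species: dict[str, str] = {}
    asv_seqs: dict[str, EvoSeq] = {}
    variants_of: dict[str, list[str]] = {}
    k = 0
    for sid in pool:
        sp_cfg = cfg
        if sid == world.novel_species_id:
            sp_cfg = dataclasses.replace(
                cfg, variants_min=max(cfg.variants_min, cfg.novel_variants_min)
            )
        var_seqs = simulate_intragenomic_variants(world.species[sid].seq, sp_cfg, rng)
        ids = []
        for vs in var_seqs:
            k += 1
            aid = f"ASV{k}"
            asv_species[aid] = sid
            asv_seqs[aid] = vs
            ids.append(aid)
        variants_of[sid] = ids
    # off-target sequences from beyond the outgroup split
    og_anc = world.species[world.outgroup_species_ids[0]].seq
    off_ids = []
    for _ in range(cfg.n_off_target):
        k += 1
        aid = f"ASV{k}"
        asv_species[aid] = "off_target"
        asv_seqs[aid] = evolve(og_anc, 0.10, rng, indel_rate=cfg.indel_rate)
        off_ids.append(aid)

    # per-species variant weights (intragenomic copy-number profile)
    variant_weights = {
        sid: rng.dirichlet(np.ones(len(variants_of[sid]))) for sid in pool
    }

    # genotype base compositions over the pool
    base = {g: rng.dirichlet(np.full(len(pool), 0.8)) for g in cfg.genotypes}

    samples: list[str] = []
    metas: list[SampleMeta] = []
    rows: list[np.ndarray] = []
    composition: dict[str, dict[str, float]] = {}
    asv_ids = sorted(asv_species, key=lambda a: int(a[3:]))
    col_index = {a: i for i, a in enumerate(asv_ids)}
    off_mass = cfg.off_target_fraction / max(cfg.n_off_target, 1)

    for genotype in cfg.genotypes:
        for treatment in cfg.treatments:
            for rep in range(1, cfg.replicates + 1):
                sample = f"{genotype}.{treatment}.r{rep}"
                samples.append(sample)
                metas.append(SampleMeta(sample, genotype, treatment, rep))
                alpha = base[genotype] * cfg.replicate_concentration
                mass = rng.dirichlet(alpha)
                for i, sid in enumerate(pool):
                    sp = world.species[sid]
                    for e in effects:
                        if _effect_applies(e, sp, genotype, treatment):
                            mass[i] = 0.0 if e.kind == "dropout" else mass[i] * e.factor
                mass = mass / mass.sum()
                composition[sample] = {sid: float(m) for sid, m in zip(pool, mass)}
                full_mass = np.concatenate(
                    [mass * (1.0 - cfg.off_target_fraction),
                     np.full(cfg.n_off_target, off_mass)]
                )
                sp_counts = rng.multinomial(cfg.reads_per_sample, full_mass)
                row = np.zeros(len(asv_ids), dtype=int)
                for i, sid in enumerate(pool):
                    if sp_counts[i] == 0:
                        continue
                    v_counts = rng.multinomial(sp_counts[i], variant_weights[sid])
                    for aid, c in zip(variants_of[sid], v_counts):
                        row[col_index[aid]] += c
                for j, aid in enumerate(off_ids):
                    row[col_index[aid]] += sp_counts[len(pool) + j]
                rows.append(row)

    counts = pd.DataFrame(rows, index=samples, columns=asv_ids)
    observed = [a for a in asv_ids if counts[a].sum() > 0]
    counts = counts[observed]

    # true tree: graft observed variants and accessions onto the species tree
    tree = world.species_tree.copy()
    obs_of: dict[str, list[str]] = {}
    for aid in observed:
        sid = asv_species[aid]
        obs_of.setdefault(sid, []).append(aid)
    acc_of: dict[str, list[str]] = {}
    for acc, sid in world.accession_species.items():
        acc_of.setdefault(sid, []).append(acc)
    for tip in list(tree.tips()):
        sid = tip.name
        children = []
        for acc in sorted(acc_of.get(sid, [])):
            children.append(TreeNode(name=acc, length=cfg.accession_divergence))
        for aid in obs_of.get(sid, []):
            children.append(TreeNode(name=aid, length=cfg.variant_divergence))
        if not children:
            tip.parent.remove(tip)
            continue
        if len(children) == 1:
            tip.name = children[0].name
            continue
        tip.name = None
        for ch in children:
            tip.append(ch)
    # off-target ASVs attach on the outgroup side of the root
    og_node = None
    for ch in tree.children:
        tips_here = {t.name for t in ch.tips(include_self=True)}
        if tips_here & set(
            a for sid in world.outgroup_species_ids for a in acc_of.get(sid, [])
        ):
            og_node = ch
    for aid in off_ids:
        if aid in observed:
            og_node.append(TreeNode(name=aid, length=0.10))
    tree.prune()

    query_seqs = {aid: amplicon_of(asv_seqs[aid]) for aid in observed}
    queries = [QueryRecord(aid, query_seqs[aid].ungapped()) for aid in observed]

    truth = GroundTruth(
        asv_species={a: asv_species[a] for a in observed},
        sample_composition=composition,
        effects=tuple(effects),
        novel_species_id=world.novel_species_id,
        novel_asv_ids=tuple(
            a for a in observed if asv_species[a] == world.novel_species_id
        ),
        off_target_asv_ids=tuple(a for a in off_ids if a in observed),
    )
    logger.info(
        "simulated %d samples, %d observed ASVs (%d novel, %d off-target)",
        len(samples), len(observed), len(truth.novel_asv_ids), len(truth.off_target_asv_ids),
    )
    return CommunityData(
        counts=counts,
        metas=metas,
        queries=queries,
        query_seqs=query_seqs,
        tree=tree,
        truth=truth,
    )


def simulate_dataset(cfg: SimConfig) -> tuple[ReferenceWorld, CommunityData]:
    world = simulate_reference_world(cfg)
    return world, simulate_communities(cfg, world)


# ---------------------------------------------------------------------------
# emission


def dataset_alignment(world: ReferenceWorld, comm: CommunityData) -> Msa:
    """True gapped alignment over all reference accessions + observed ASVs."""
    seqs: dict[str, EvoSeq] = {}
    for acc, s in world.accession_seqs.items():
        seqs[acc] = s
    for aid, s in comm.query_seqs.items():
        seqs[aid] = s
    return true_alignment(seqs)


def emit_dataset(
    world: ReferenceWorld, comm: CommunityData, outdir: str | Path
) -> dict[str, Path]:
    """Write every artifact of a simulated dataset; all plain-text formats."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "reference_fasta_a": out / "reference_set_a.fasta",
        "reference_taxonomy_a": out / "reference_taxonomy_a.tsv",
        "reference_fasta_b": out / "reference_set_b.fasta",
        "reference_taxonomy_b": out / "reference_taxonomy_b.tsv",
        "queries": out / "queries.fasta",
        "alignment": out / "alignment.fasta",
        "tree": out / "tree.nwk",
        "counts": out / "counts.tsv",
        "metadata": out / "metadata.tsv",
        "manifest": out / "ground_truth.json",
    }
    set_a = [r for r in world.accessions if r.source_set == "set_A"]
    set_b = [r for r in world.accessions if r.source_set == "set_B"]
    write_references(set_a, paths["reference_taxonomy_a"], paths["reference_fasta_a"])
    write_references(set_b, paths["reference_taxonomy_b"], paths["reference_fasta_b"])
    write_queries(comm.queries, paths["queries"])
    dataset_alignment(world, comm).to_fasta(paths["alignment"])
    write_newick(comm.tree, paths["tree"])
    write_counts(comm.counts, paths["counts"])
    write_metadata(comm.metas, paths["metadata"])
    manifest = {
        "seed": world.cfg.seed,
        "asv_species": comm.truth.asv_species,
        "novel_species_id": comm.truth.novel_species_id,
        "novel_asv_ids": list(comm.truth.novel_asv_ids),
        "off_target_asv_ids": list(comm.truth.off_target_asv_ids),
        "outgroup_accessions": sorted(
            a
            for a, sid in world.accession_species.items()
            if sid in world.outgroup_species_ids
        ),
        "species_names": {
            sid: world.species[sid].name for sid in comm.truth.asv_species.values()
            if sid != "off_target"
        },
        "effects": [dataclasses.asdict(e) for e in comm.truth.effects],
        "sample_composition": comm.truth.sample_composition,
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return paths


def file_checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
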