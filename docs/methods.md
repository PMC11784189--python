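# Methods

This note documents the models, algorithmic choices and limitations behind
`amfphylo`. It covers what each component assumes, which parameters matter,
and what the synthetic-data experiments do and do not demonstrate.

## Monophyly-based taxonomy assignment

Given a rooted tree whose tips are either curated reference sequences (with
an order/family/genus/species lineage) or query ASVs, each query is
annotated from its **housing clade**: walking rootward from the query tip,
the first ancestor whose descendant tips include at least one reference.
Because every clade containing a given tip is one of its ancestors, this is
exactly the *smallest* monophyletic group housing the query together with
references. The assigned taxon is the deepest rank at which the housed
reference lineages are unanimous, in the order species > genus > family >
order; disagreement at order level yields `unclassified` / `"unknown"`.
The procedure is deterministic given the tree text and taxonomy table, and
the test suite holds it equal to a brute-force clade-enumeration oracle on
hundreds of random instances.

Decisions taken where the behaviour was genuinely open:

- **Support thresholding** (`min_support`, default off): when set, ancestors
  whose bootstrap support falls below the threshold are skipped during the
  rootward walk. Nodes that carry no support value (the root; trees without
  supports) cannot be evaluated and are treated as passing — a threshold
  should restrict to *well-supported* clades, not silently discard trees
  that lack annotations.
- **Genus-only references**: a reference with an empty species field is
  evidence at genus rank and above. At species rank it is missing data, not
  disagreement: a species call requires at least one species-bearing
  reference, unanimity among the species-bearing ones, and genus-level
  consistency of all housed references.
- **Queries basal to every reference clade** (housing clade = root with
  order-level disagreement, e.g. ingroup vs outgroup references) are
  reported `unclassified` rather than being forced into a rank.
- **Novel clades** are maximal query-only clades with at least
  `min_novel_size = 2` members. A single divergent ASV is not called a
  novel lineage — one sequence cannot distinguish a novel taxon from a
  chimeric or otherwise aberrant read.

Diagnostics attach two signatures of problematic placements: terminal
branches longer than `factor` (default 5) times the median tip branch
length, and clade-exclusive insertion columns — alignment columns where at
least `f_in = 0.5` of the clade's rows carry a residue while every row
outside carries a gap. Together these identify divergent groups whose long
branches are explained by unaligned private regions rather than elevated
substitution rates.

## Alignment operations

Alignments are consumed, not computed (the generator emits exact true
alignments; real data would come from an external aligner). Columns are
0-based and windows half-open. The amplicon window is located by Hamming
matching of the forward primer and the reverse complement of the reverse
primer (AML1/AML2 by default, up to `max_mismatches = 2`, IUPAC-aware) on
each ungapped row, mapping per-row offsets through the row's gap pattern,
and taking the median start/end columns over matching rows (at least half
the rows must match). Indels within the primer site are not modelled —
primer-binding regions are conserved almost by definition, which is also
why the window includes the binding sites themselves.

Gap-stringency trimming removes a column when its gap fraction is
**at least** the threshold; at threshold 0 any column containing a gap is
removed. This reading makes the 0 % case the exact limit of the 90/50/10 %
series and guarantees that removal sets are nested across decreasing
thresholds (a property test asserts this on random alignments). Gap
fractions count all rows, references and queries alike. Rows left without
residues by a trim are dropped with a warning.

## Tree algorithms

Trees are `skbio.TreeNode` objects; numeric internal-node labels parse as
bootstrap supports, and values in [0, 1] are rescaled to [0, 100] with a
warning since newick dialects differ. Multifurcations are accepted;
monophyly is defined on the polytomy as-is.

The fallback tree builder is neighbor joining on Jukes–Cantor distances:
`d = −(3/4)·ln(1 − (4/3)p)` with `p` the mismatch proportion over columns
where both rows carry residues; saturated pairs (`p ≥ 0.75`) receive a
ceiling of 5.0 substitutions/site with a warning, and pairs with no
overlapping residue columns are an error. NJ is implemented directly so
that Q-matrix ties break on the lexicographically smallest id pair —
reproducibility over elegance; merged nodes inherit the smaller child id
for tie purposes, and negative branch-length estimates are clamped to zero.
The suite cross-checks topologies against scikit-bio's NJ and verifies
≥ 95 % topology recovery on 100 seeded 8-taxon, ~850 bp simulations.
This fallback targets desk-scale trees; real studies should supply a
maximum-likelihood tree.

Outgroup rooting places the root on the edge separating the outgroup
(*Paraglomus*, the most basal glomeromycotan branch, in the intended use)
from the ingroup. A non-monophyletic outgroup triggers a warning and
rooting above its smallest enclosing clade — which is also what makes
off-target query sequences land on the outgroup side, where
`filter_off_target` removes them (together with queries attached directly
to the root).

## Community profiling

Counts are samples × ASVs integer tables. Singleton/doubleton removal uses
**dataset-wide** totals (≤ `max_total = 2`), interpreting the pre-analysis
edit as a single global pass. All filtering happens on counts before
normalization, so relative abundance is computed exactly once; relative
abundance rows, replicate means (unweighted, so deeper-sequenced replicates
do not dominate) and clade-aggregated rows all sum to 1 within 1e-9, which
the acceptance suite asserts across a full pipeline run. Clade labels are
the assigned taxon, or the novel-clade id for members of query-only clades.
The qPCR conversion is the product `fungal_dna × glomero_fraction`,
returning pg AMF DNA per reaction.

## ANOSIM

One-way ANOSIM ranks all `M = n(n−1)/2` pairwise distances (average ranks
on ties) and computes `R = (r̄_B − r̄_W)/(M/2)`. The test is one-sided
(large R = separation). Monte-Carlo p-values use the add-one rule
`p = (1 + #{R_perm ≥ R_obs})/(1 + n_permutations)`, so `p ≥ 1/(1+n)` and
p = 0 is impossible. When the permutation budget covers every distinct
relabeling (`n_permutations ≥ N − 1`), the implementation enumerates them
instead of sampling, making small-design p-values exact and reproducible
independent of the seed; the exhaustive mode is validated against an
independent enumeration oracle. Pairwise group comparisons report raw
p-values — multiple-testing correction is deliberately left to the caller,
who knows the family of hypotheses being tested.

Type-I error is verified empirically: on 2,000 null datasets (iid random
distances, two groups of five) the rejection rate at α = 0.05 falls in
[0.03, 0.07].

## The synthetic-data generator

The generator is first-class, tested code; its defaults *are* the study
conditions the pipeline targets:

| parameter | default | rationale |
| --- | --- | --- |
| amplicon length | 800 bp | AML1/2 amplicon size |
| reads per sample | 10,000 | sequencing depth per sample |
| design | 4 genotypes × {PP, C, CM1x} × 5 replicates | rootstock × treatment × replicate layout |
| reference world | 174 accessions, 91 species, 24 genera; set B = 28 | the two curated reference sets, including the basal *Paraglomus* pair |
| intragenomic variants | 1–30 per species, divergence 0.005 subs/site | "dozens of sequence variants" per spore; ≥ 99 % mean pairwise identity |
| indel rate | 5e-4 per site per branch, geometric length (mean 3) | rare alignment gaps |
| novel lineage | ≥ 4 variants, +0.15 subs/site, 12-column private insertion | the multi-ASV unknown clade with clade-exclusive nucleotides |
| off-target sequences | 3, ~1 % of reads | non-target amplification removed by placement |
| replicate concentration | Dirichlet × 200 | biological replicate variation around the genotype base |

Sequences evolve by Poisson substitutions (uniform alternative base — the
same JC model the distance assumes, keeping the NJ-recovery property
honest) and tracked indels: every column carries a float key assigned at
creation, so the *true* multiple alignment of any tip set is reconstructed
exactly without an external aligner. Primer sites are immune to mutation.
Taxonomy is monophyletic on the species tree by construction, which is what
makes "the true species label" well defined for recovery scoring.
Communities are genotype-specific Dirichlet base compositions with
per-sample Dirichlet jitter, planted dropout/enrichment effects applied per
treatment, and multinomial read allocation to species and then to variants
(per-species variant weights drawn once). Every sample totals exactly
`reads_per_sample`. All randomness flows from one
`numpy.random.default_rng(seed)` stream consumed in a fixed order, so a
fixed seed reproduces every output file byte for byte.

The novel lineage is given at least 4 intragenomic variants: a planted
"unknown clade" is only meaningful as a clade, and the community structure
being emulated is a multi-ASV monophyletic group of unknown taxonomy.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: sequencing error, chimeras and denoising
artifacts (the pipeline starts at ASVs); alignment error (true alignments
are emitted; real MAFFT alignments misalign divergent regions, which is
precisely why the long-branch/insertion diagnostics exist); rate
heterogeneity, base-composition bias and non-JC substitution processes;
ecological covariance between taxa beyond the Dirichlet draw; and
reference taxonomies that are *not* monophyletic on the true tree, which in
real data is a genuine failure mode of any monophyly-based annotation.

## Problem sizes used in the checks

The acceptance experiments run at desk scale by design: oracle comparisons
use 500 random instances (trees ≤ 25 tips, alignments ≤ 20 × 50), ANOSIM
calibration uses 2,000 null datasets of 10 samples, recovery uses 50
simulated replicates of the full default design (~60 samples, ~150–200
ASVs each), and trimming stability uses 12-taxon NJ trees. These sizes make
every check exhaustive or near-exhaustive where it matters (oracle
equality is exact, not statistical) while keeping a full run in tens of
seconds.

## Known limitations

- The annotation walk uses the first reference-containing ancestor; it does
  not weigh branch lengths or likelihoods (no evolutionary placement).
- Novel-clade naming is positional (`novel_1`, `novel_2`, … in root-to-tip
  order), not stable across trees.
- The NJ fallback is quadratic-memory and cubic-time; it is a testing
  convenience, not a phylogenetics engine.
- `filter_off_target` trusts the rooting: with a wrongly specified outgroup
  the kept/removed split is wrong in the corresponding way.
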