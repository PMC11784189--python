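"""ASV count-table processing and community profiling.

Count tables are pandas DataFrames with samples as rows and ASVs as columns
(nonnegative integers).  The profiling chain mirrors the standard AMF
amplicon workflow: drop singleton/doubleton ASVs (dataset-wide total <= 2),
drop off-target ASVs flagged by phylogenetic placement, convert to per-sample
relative abundance, average biological replicates per (genotype, treatment)
group, and aggregate to clade level for stacked-bar / heatmap style summaries.

All abundance rows sum to 1 within 1e-9; filtering happens on counts, before
normalization, so there is never a double normalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .assign import Assignment

logger = logging.getLogger(__name__)

GENOTYPES = ("G.890", "G.935", "M.7", "M.26", "CM", "SOIL")
TREATMENTS = ("PP", "C", "CM1x")


@dataclass(frozen=True)
class SampleMeta:
    """Experimental-design coordinates of one sample."""

    sample_id: str
    genotype: str
    treatment: str
    replicate: int


@dataclass(frozen=True)
class QpcrQuantity:
    """Total fungal DNA (qPCR) and the Glomeromycota read fraction."""

    sample_id: str
    fungal_dna: float  # pg per reaction
    glomero_fraction: float

    def __post_init__(self) -> None:
        if self.fungal_dna < 0:
            raise ValueError(f"{self.sample_id}: negative fungal DNA quantity")
        if not 0.0 <= self.glomero_fraction <= 1.0:
            raise ValueError(f"{self.sample_id}: glomero_fraction outside [0, 1]")


def validate_counts(table: pd.DataFrame) -> pd.DataFrame:
    if (table.values < 0).any():
        raise ValueError("count table contains negative entries")
    if table.index.has_duplicates or table.columns.has_duplicates:
        raise ValueError("duplicate sample or ASV ids in count table")
    return table


def load_counts(path: str | Path) -> pd.DataFrame:
    """Samples-as-rows x ASVs-as-columns TSV with header on both axes."""
    return validate_counts(pd.read_csv(path, sep="\t", index_col=0))


def write_counts(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t")


def load_metadata(path: str | Path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    needed = {"sample_id", "genotype", "treatment", "replicate"}
    if not needed <= set(df.columns):
        raise ValueError(f"metadata missing columns {sorted(needed - set(df.columns))}")
    metas = [
        SampleMeta(r.sample_id, r.genotype, r.treatment, int(r.replicate))
        for r in df.itertuples(index=False)
    ]
    keys = [(m.genotype, m.treatment, m.replicate) for m in metas]
    if len(set(keys)) != len(keys):
        raise ValueError("(genotype, treatment, replicate) combinations are not unique")
    return metas


def write_metadata(metas: list[SampleMeta], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": m.sample_id,
                "genotype": m.genotype,
                "treatment": m.treatment,
                "replicate": m.replicate,
            }
            for m in metas
        ]
    ).to_csv(path, sep="\t", index=False)


def filter_low_count(
    table: pd.DataFrame, max_total: int = 2
) -> tuple[pd.DataFrame, list[str]]:
    """Remove ASVs with dataset-wide total <= max_total (singletons/doubletons)."""
    validate_counts(table)
    totals = table.sum(axis=0)
    removed = [str(a) for a in table.columns[totals <= max_total]]
    kept = table.loc[:, totals > max_total]
    if removed:
        logger.info("filter_low_count removed %d ASVs (total <= %d)", len(removed), max_total)
    return kept, removed


def drop_asvs(table: pd.DataFrame, ids: list[str]) -> pd.DataFrame:
    """Drop ASV columns by id; samples whose total becomes 0 are dropped."""
    unknown = sorted(set(ids) - set(table.columns))
    if unknown:
        raise ValueError(f"unknown ASV ids: {unknown}")
    out = table.drop(columns=list(ids))
    if out.shape[1] == 0:
        raise ValueError("no ASVs remain")
    empty = out.index[out.sum(axis=1) == 0]
    if len(empty):
        logger.warning("dropping zero-total samples: %s", list(empty))
        out = out.drop(index=empty)
    return out


def relative_abundance(table: pd.DataFrame) -> pd.DataFrame:
    """Per-sample relative abundance; zero-total samples dropped with a warning."""
    validate_counts(table)
    totals = table.sum(axis=1)
    empty = table.index[totals == 0]
    if len(empty):
        logger.warning("dropping zero-total samples: %s", list(empty))
        table = table.drop(index=empty)
        totals = totals.drop(index=empty)
    return table.div(totals, axis=0)


def replicate_mean(ab: pd.DataFrame, metas: list[SampleMeta]) -> pd.DataFrame:
    """Unweighted mean abundance per (genotype, treatment) group.

    Returned frame is indexed by a (genotype, treatment) MultiIndex; groups
    with no samples in ``ab`` are absent.  Every sample in ``ab`` must have
    metadata.
    """
    meta_by_id = {m.sample_id: m for m in metas}
    missing = sorted(set(ab.index) - set(meta_by_id))
    if missing:
        raise ValueError(f"samples without metadata: {missing}")
    keys = pd.MultiIndex.from_tuples(
        [(meta_by_id[s].genotype, meta_by_id[s].treatment) for s in ab.index],
        names=["genotype", "treatment"],
    )
    grouped = ab.set_axis(keys).groupby(level=["genotype", "treatment"], sort=True).mean()
    return grouped


def aggregate_by_clade(
    ab: pd.DataFrame, assignments: list[Assignment]
) -> pd.DataFrame:
    """Sum member-ASV abundances per clade label.

    The clade label of an ASV is its novel-clade id when present, otherwise
    its assigned taxon.  Every ASV column must have an assignment.
    """
    label_of = {
        a.asv_id: (a.novel_clade_id if a.novel_clade_id else a.taxon)
        for a in assignments
    }
    missing = sorted(set(map(str, ab.columns)) - set(label_of))
    if missing:
        raise ValueError(f"unassigned ASVs: {missing}")
    labels = [label_of[str(c)] for c in ab.columns]
    return ab.T.groupby(pd.Index(labels, name="clade")).sum().T


def absolute_amf(q: QpcrQuantity) -> float:
    """AMF DNA per reaction (pg): total fungal DNA x Glomeromycota fraction."""
    return q.fungal_dna * q.glomero_fraction


def load_qpcr(path: str | Path) -> list[QpcrQuantity]:
    df = pd.read_csv(path, sep="\t")
    return [
        QpcrQuantity(str(r.sample_id), float(r.fungal_dna_pg), float(r.glomero_fraction))
        for r in df.itertuples(index=False)
    ]


def heatmap_table(group_means: pd.DataFrame) -> pd.DataFrame:
    """ASVs-as-rows x groups-as-columns layout for heatmap export."""
    out = group_means.T
    out.columns = [f"{g}.{t}" for g, t in out.columns]
    return out
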