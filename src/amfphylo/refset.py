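"""Curated 18S reference sets and query ASV sequences.

Phylogenetic taxonomy assignment of Glomeromycota amplicons leans on a small
number of well-curated reference sequences from identified AMF cultures, each
carrying a four-rank lineage (order / family / genus / species).  This module
reads, validates, merges and writes those reference sets, plus the query ASV
sequences produced by amplicon denoising.

The taxonomy table is a 6-column, tab-delimited, UTF-8 file with a header row:

    seq_id  order  family  genus  species  is_type_culture

An empty ``species`` field means the accession is identified only to genus;
downstream assignment then uses it as genus-level evidence only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

IUPAC_DNA = frozenset("ACGTRYSWKMBDHVN")

TAXONOMY_COLUMNS = ["seq_id", "order", "family", "genus", "species", "is_type_culture"]

_TRUTHY = {"true", "1", "yes", "y", "t"}
_FALSY = {"false", "0", "no", "n", "f", ""}


@dataclass(frozen=True)
class ReferenceRecord:
    """One curated 18S reference sequence with its lineage."""

    seq_id: str
    sequence: str
    order_: str
    family: str
    genus: str
    species: str = ""  # empty = identified only to genus
    is_type_culture: bool = False
    source_set: str = "set_A"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"reference {self.seq_id!r}: empty sequence")
        bad = set(self.sequence) - IUPAC_DNA
        if bad:
            raise ValueError(
                f"reference {self.seq_id!r}: non-IUPAC characters {sorted(bad)!r}"
            )
        if self.species and not self.species.startswith(self.genus):
            raise ValueError(
                f"reference {self.seq_id!r}: species {self.species!r} does not "
                f"begin with genus {self.genus!r}"
            )

    @property
    def lineage(self) -> tuple[str, str, str, str]:
        """(order, family, genus, species); species may be ''."""
        return (self.order_, self.family, self.genus, self.species)


@dataclass(frozen=True)
class QueryRecord:
    """One query ASV sequence."""

    asv_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"query {self.asv_id!r}: empty sequence")


def _normalize_seq(raw: str, seq_id: str) -> str:
    """Upcase, map U->T, and validate IUPAC DNA codes."""
    seq = str(raw).upper().replace("U", "T")
    bad = set(seq) - IUPAC_DNA
    if bad:
        raise ValueError(f"sequence {seq_id!r}: non-IUPAC characters {sorted(bad)!r}")
    return seq


def _parse_bool(value: object, seq_id: str) -> bool:
    text = str(value).strip().lower()
    if text in _TRUTHY:
        return True
    if text in _FALSY:
        return False
    raise ValueError(f"taxonomy row {seq_id!r}: unparseable is_type_culture {value!r}")


def load_references(
    taxonomy_path: str | Path,
    fasta_path: str | Path,
    source_set: str = "set_A",
) -> list[ReferenceRecord]:
    """Load a reference set from a FASTA file plus its taxonomy table.

    Every FASTA id must appear in the taxonomy table and vice versa.  Records
    duplicated on ``seq_id`` with identical fields are deduplicated; records
    duplicated with conflicting fields are an error.
    """
    tax = pd.read_csv(taxonomy_path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = set(TAXONOMY_COLUMNS) - set(tax.columns)
    if missing_cols:
        raise ValueError(f"taxonomy table missing columns {sorted(missing_cols)}")

    seqs: dict[str, str] = {}
    order: list[str] = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        seq = _normalize_seq(str(rec.seq), rec.id)
        if rec.id in seqs:
            if seqs[rec.id] != seq:
                raise ValueError(f"duplicate FASTA id {rec.id!r} with differing sequences")
            continue
        seqs[rec.id] = seq
        order.append(rec.id)

    tax_ids = set(tax["seq_id"])
    fasta_only = sorted(set(seqs) - tax_ids)
    if fasta_only:
        raise ValueError(f"FASTA ids missing from taxonomy table: {fasta_only}")
    tax_only = sorted(tax_ids - set(seqs))
    if tax_only:
        raise ValueError(f"taxonomy ids missing from FASTA: {tax_only}")

    by_id: dict[str, ReferenceRecord] = {}
    for row in tax.itertuples(index=False):
        rec = ReferenceRecord(
            seq_id=row.seq_id,
            sequence=seqs[row.seq_id],
            order_=row.order,
            family=row.family,
            genus=row.genus,
            species=row.species,
            is_type_culture=_parse_bool(row.is_type_culture, row.seq_id),
            source_set=source_set,
        )
        prev = by_id.get(row.seq_id)
        if prev is not None:
            if prev != rec:
                raise ValueError(
                    f"duplicate taxonomy rows for {row.seq_id!r} with conflicting "
                    f"fields: {prev.lineage} vs {rec.lineage}"
                )
            continue
        by_id[row.seq_id] = rec

    records = [by_id[i] for i in order]
    if not records:
        logger.warning("reference set %s is empty", fasta_path)
    n_species = len({r.species for r in records if r.species})
    n_genera = len({r.genus for r in records})
    logger.info(
        "loaded %d reference records (%d species, %d genera) from %s",
        len(records), n_species, n_genera, fasta_path,
    )
    return records


def merge_reference_sets(
    set_a: list[ReferenceRecord], set_b: list[ReferenceRecord]
) -> list[ReferenceRecord]:
    """Union of two internally deduplicated reference sets, keyed on seq_id.

    A seq_id shared between the sets must carry the same sequence and lineage;
    conflicting duplicates raise with both lineages listed.  ``source_set`` of
    the first occurrence wins; record order is set_a followed by novel set_b.
    """
    merged: dict[str, ReferenceRecord] = {}
    out: list[ReferenceRecord] = []
    for rec in list(set_a) + list(set_b):
        prev = merged.get(rec.seq_id)
        if prev is None:
            merged[rec.seq_id] = rec
            out.append(rec)
            continue
        if prev.lineage != rec.lineage or prev.sequence != rec.sequence:
            raise ValueError(
                f"lineage conflict for {rec.seq_id!r}: {prev.lineage} vs {rec.lineage}"
            )
    return out


def load_queries(fasta_path: str | Path) -> list[QueryRecord]:
    """Load query ASVs from FASTA, preserving file order; duplicate ids error."""
    seen: set[str] = set()
    out: list[QueryRecord] = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate asv_id {rec.id!r} in {fasta_path}")
        seen.add(rec.id)
        out.append(QueryRecord(asv_id=rec.id, sequence=_normalize_seq(str(rec.seq), rec.id)))
    return out


def write_references(
    records: list[ReferenceRecord],
    taxonomy_path: str | Path,
    fasta_path: str | Path,
) -> None:
    """Write a reference set back out as FASTA + taxonomy TSV."""
    rows = [
        {
            "seq_id": r.seq_id,
            "order": r.order_,
            "family": r.family,
            "genus": r.genus,
            "species": r.species,
            "is_type_culture": str(r.is_type_culture).lower(),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=TAXONOMY_COLUMNS).to_csv(taxonomy_path, sep="\t", index=False)
    SeqIO.write(
        (SeqRecord(Seq(r.sequence), id=r.seq_id, description="") for r in records),
        str(fasta_path),
        "fasta",
    )


def write_queries(records: list[QueryRecord], fasta_path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(r.sequence), id=r.asv_id, description="") for r in records),
        str(fasta_path),
        "fasta",
    )
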