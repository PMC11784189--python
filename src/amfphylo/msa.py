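"""Multiple-sequence-alignment operations for amplicon trimming.

The pipeline consumes an externally computed gapped alignment of reference
and ASV sequences and operates on its columns: trimming to the AML1/AML2
amplicon window, removing columns by gap-fraction stringency, and locating
insertion columns private to a clade (the signature of the divergent,
long-branch ASV groups seen in AMF 18S data).

Columns are 0-based; windows are half-open ``[start, end)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

GAP = "-"

# IUPAC code -> set of bases it can stand for (used for primer matching)
_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

#: Glomeromycota-specific 18S primers (Lee et al. AML1/AML2), written 5'->3'.
AML1 = "ATCAACTTTCGATGGTAGGATAGA"
AML2 = "GAACCCAAACACTTTGGTTTCC"


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse primer pair, both written 5'->3'."""

    forward: str = AML1
    reverse: str = AML2
    max_mismatches: int = 2

    def __post_init__(self) -> None:
        if not self.forward or not self.reverse:
            raise ValueError("both primers must be non-empty")
        if self.max_mismatches < 0 or self.max_mismatches >= min(
            len(self.forward), len(self.reverse)
        ):
            raise ValueError("max_mismatches must be in [0, min(primer lengths))")


class Msa:
    """A gapped DNA alignment: ordered unique row ids over equal-length rows."""

    def __init__(self, row_ids: list[str], rows: list[str]):
        if len(row_ids) != len(rows):
            raise ValueError("row_ids and rows length mismatch")
        if len(set(row_ids)) != len(row_ids):
            raise ValueError("row ids are not unique")
        if not rows:
            raise ValueError("alignment has no rows")
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            raise ValueError(f"rows have unequal lengths {sorted(lengths)}")
        self.row_ids = list(row_ids)
        self.chars = np.array([list(r.upper()) for r in rows], dtype="U1")
        for rid, row in zip(self.row_ids, self.chars):
            if np.all(row == GAP):
                raise ValueError(f"row {rid!r} is all-gap")
        self._index = {rid: i for i, rid in enumerate(self.row_ids)}

    @property
    def n_rows(self) -> int:
        return self.chars.shape[0]

    @property
    def n_cols(self) -> int:
        return self.chars.shape[1]

    def row(self, row_id: str) -> str:
        return "".join(self.chars[self._index[row_id]])

    def ungapped(self, row_id: str) -> str:
        r = self.chars[self._index[row_id]]
        return "".join(r[r != GAP])

    def subset_rows(self, row_ids: list[str]) -> "Msa":
        return Msa(list(row_ids), [self.row(r) for r in row_ids])

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, Msa)
            and self.row_ids == other.row_ids
            and bool(np.array_equal(self.chars, other.chars))
        )

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Msa":
        ids, rows = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            ids.append(rec.id)
            rows.append(str(rec.seq))
        return cls(ids, rows)

    def to_fasta(self, path: str | Path) -> None:
        SeqIO.write(
            (
                SeqRecord(Seq("".join(row)), id=rid, description="")
                for rid, row in zip(self.row_ids, self.chars)
            ),
            str(path),
            "fasta",
        )


def column_gap_fraction(msa: Msa) -> np.ndarray:
    """Per-column fraction of rows that carry a gap; length n_cols."""
    return (msa.chars == GAP).mean(axis=0)


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _iupac_mismatches(window: np.ndarray, primer: np.ndarray) -> int:
    """Mismatch count treating IUPAC ambiguity as compatible when overlapping."""
    n = 0
    for w, p in zip(window, primer):
        if not (set(_IUPAC.get(w, "")) & set(_IUPAC.get(p, ""))):
            n += 1
    return n


def _scan_primer(seq: str, primer: str, max_mm: int, rightmost: bool) -> int | None:
    """Offset of the best primer match (<= max_mm mismatches), or None.

    Ties on mismatch count resolve to the leftmost (or rightmost) offset.
    """
    L, k = len(seq), len(primer)
    if L < k:
        return None
    s = np.array(list(seq), dtype="U1")
    p = np.array(list(primer), dtype="U1")
    windows = np.lib.stride_tricks.sliding_window_view(s, k)
    ambiguous = ~np.isin(s, np.array(list("ACGT-"), dtype="U1")).all() or not set(
        primer
    ) <= set("ACGT")
    if ambiguous:
        mism = np.array([_iupac_mismatches(w, p) for w in windows])
    else:
        mism = (windows != p).sum(axis=1)
    best = int(mism.min())
    if best > max_mm:
        return None
    hits = np.flatnonzero(mism == best)
    return int(hits[-1] if rightmost else hits[0])


def locate_primer_window(
    msa: Msa, primers: PrimerPair | None = None, min_row_fraction: float = 0.5
) -> tuple[int, int]:
    """Locate the amplicon window (inclusive of both primer-binding sites).

    For each row, the forward primer and the reverse complement of the reverse
    primer are searched on the ungapped sequence (Hamming matching, up to
    ``primers.max_mismatches`` mismatches); per-row start/end offsets are then
    mapped through that row's gap pattern to alignment columns, and the
    consensus window is the median of the per-row column coordinates over
    matching rows.  Returns a half-open column interval.

    Raises if fewer than ``min_row_fraction`` of rows match both primers.
    """
    if primers is None:
        primers = PrimerPair()
    rc_rev = _revcomp(primers.reverse)
    starts, ends = [], []
    for i, rid in enumerate(msa.row_ids):
        row = msa.chars[i]
        residue_cols = np.flatnonzero(row != GAP)
        seq = "".join(row[residue_cols])
        f_off = _scan_primer(seq, primers.forward, primers.max_mismatches, rightmost=False)
        r_off = _scan_primer(seq, rc_rev, primers.max_mismatches, rightmost=True)
        if f_off is None or r_off is None:
            continue
        r_last = r_off + len(rc_rev) - 1
        if r_last <= f_off:
            continue
        starts.append(int(residue_cols[f_off]))
        ends.append(int(residue_cols[r_last]))
    if len(starts) < min_row_fraction * msa.n_rows or not starts:
        raise ValueError(
            "primer region not localizable: "
            f"{len(starts)}/{msa.n_rows} rows match both primers"
        )
    col_start = int(np.median(starts))
    col_end = int(np.median(ends)) + 1
    logger.info(
        "primer window located at columns [%d, %d) from %d/%d matching rows",
        col_start, col_end, len(starts), msa.n_rows,
    )
    return (col_start, col_end)


def trim_to_window(msa: Msa, window: tuple[int, int]) -> Msa:
    """Restrict the alignment to a half-open column window.

    Rows that become all-gap inside the window are dropped with a warning.
    """
    col_start, col_end = window
    if not (0 <= col_start < col_end <= msa.n_cols):
        raise ValueError(f"invalid window {window} for alignment with {msa.n_cols} columns")
    sub = msa.chars[:, col_start:col_end]
    keep = ~np.all(sub == GAP, axis=1)
    dropped = [rid for rid, k in zip(msa.row_ids, keep) if not k]
    if dropped:
        logger.warning("trim_to_window dropped all-gap rows: %s", dropped)
    if not keep.any():
        raise ValueError("window leaves no non-empty rows")
    ids = [rid for rid, k in zip(msa.row_ids, keep) if k]
    return Msa(ids, ["".join(r) for r in sub[keep]])


def gap_trim(msa: Msa, max_gap_fraction: float) -> tuple[Msa, dict[int, int]]:
    """Remove columns by gap-fraction stringency.

    A column is removed when its gap fraction is >= ``max_gap_fraction``; at
    stringency 0 every column containing any gap is removed.  Returns the
    trimmed alignment and an old->new column-index map for retained columns.
    Removal sets are nested across decreasing thresholds.
    """
    if not 0.0 <= max_gap_fraction <= 1.0:
        raise ValueError("max_gap_fraction must be in [0, 1]")
    frac = column_gap_fraction(msa)
    if max_gap_fraction > 0:
        keep = frac < max_gap_fraction
    else:
        keep = frac == 0.0
    if not keep.any():
        raise ValueError("alignment fully trimmed")
    kept_cols = np.flatnonzero(keep)
    col_map = {int(old): new for new, old in enumerate(kept_cols)}
    sub = msa.chars[:, kept_cols]
    keep_rows = ~np.all(sub == GAP, axis=1)
    dropped = [rid for rid, k in zip(msa.row_ids, keep_rows) if not k]
    if dropped:
        logger.warning("gap_trim dropped rows left all-gap: %s", dropped)
    if not keep_rows.any():
        raise ValueError("alignment fully trimmed")
    ids = [rid for rid, k in zip(msa.row_ids, keep_rows) if k]
    return Msa(ids, ["".join(r) for r in sub[keep_rows]]), col_map


def clade_exclusive_columns(
    msa: Msa, clade_ids: set[str] | list[str], f_in: float = 0.5
) -> list[int]:
    """Columns with residues private to a clade.

    Reports columns where at least ``f_in`` of clade rows carry a residue and
    every row outside the clade carries a gap — the alignment signature of
    clade-exclusive insertions that inflate branch lengths.
    """
    clade = set(clade_ids)
    unknown = clade - set(msa.row_ids)
    if unknown:
        raise ValueError(f"clade ids not in alignment: {sorted(unknown)}")
    if not clade or clade == set(msa.row_ids):
        raise ValueError("clade_ids must be a non-empty proper subset of rows")
    mask = np.array([rid in clade for rid in msa.row_ids])
    in_res = (msa.chars[mask] != GAP).mean(axis=0) >= f_in
    out_gap = np.all(msa.chars[~mask] == GAP, axis=0)
    return [int(c) for c in np.flatnonzero(in_res & out_gap)]


def write_trim_report(
    msa: Msa, col_map: dict[int, int], path: str | Path
) -> None:
    """TSV report of per-column gap fraction and kept/removed status."""
    frac = column_gap_fraction(msa)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("column\tgap_fraction\tstatus\tnew_column\n")
        for c in range(msa.n_cols):
            if c in col_map:
                fh.write(f"{c}\t{frac[c]:.6g}\tkept\t{col_map[c]}\n")
            else:
                fh.write(f"{c}\t{frac[c]:.6g}\tremoved\t\n")
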