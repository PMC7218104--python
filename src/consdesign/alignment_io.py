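"""Reading, validating and curating aligned protein FASTA.

An alignment here is a rectangular block of gapped amino-acid sequences with
one row flagged as the *query* — the protein whose positions anchor all
downstream reporting (mutation labels like ``A240G`` refer to the 1-based
index in the query's ungapped sequence).

Curation mirrors the standard manual clean-up applied to BLAST/database
retrievals before consensus analysis: drop sequences with non-informative
annotation keywords ("hypothetical", "predicted", "putative"), drop fragments
and oversized outliers by ungapped-length window relative to the query, and
drop exact duplicates.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
GAP: str = "-"
UNKNOWN: str = "X"
ALPHABET: frozenset[str] = frozenset(AMINO_ACIDS) | {GAP, UNKNOWN}

DEFAULT_KEYWORDS: tuple[str, ...] = ("hypothetical", "predicted", "putative")


class AlignmentError(ValueError):
    """Raised for malformed or inconsistent alignment input."""


@dataclass(frozen=True)
class AlignedSequence:
    """One row of an alignment.

    ``residues`` is the gapped string, uppercased, over the 20 amino acids
    plus ``X`` (ambiguous) and ``-`` (gap).
    """

    seq_id: str
    header: str
    residues: str

    @property
    def ungapped(self) -> str:
        return self.residues.replace(GAP, "")

    @property
    def ungapped_length(self) -> int:
        return len(self.ungapped)


@dataclass
class Alignment:
    """A rectangular protein alignment with an optional flagged query row."""

    sequences: list[AlignedSequence]
    query_id: str | None = None

    def __post_init__(self) -> None:
        if not self.sequences:
            raise AlignmentError("alignment contains no sequences")
        n_cols = len(self.sequences[0].residues)
        seen: set[str] = set()
        for rec in self.sequences:
            if len(rec.residues) != n_cols:
                raise AlignmentError(
                    f"ragged alignment: sequence {rec.seq_id!r} has length "
                    f"{len(rec.residues)}, expected {n_cols}"
                )
            if rec.seq_id in seen:
                raise AlignmentError(f"duplicate sequence id {rec.seq_id!r}")
            seen.add(rec.seq_id)
        if self.query_id is not None and self.query_id not in seen:
            raise AlignmentError(f"query id {self.query_id!r} not found in alignment")

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    @property
    def n_columns(self) -> int:
        return len(self.sequences[0].residues)

    @property
    def query(self) -> AlignedSequence:
        if self.query_id is None:
            raise AlignmentError("alignment has no query flagged")
        for rec in self.sequences:
            if rec.seq_id == self.query_id:
                return rec
        raise AlignmentError(f"query id {self.query_id!r} not found")  # pragma: no cover

    def column(self, col: int) -> str:
        """Residues of column ``col`` (0-based), in sequence order."""
        if not 0 <= col < self.n_columns:
            raise IndexError(f"column {col} out of range 0..{self.n_columns - 1}")
        return "".join(rec.residues[col] for rec in self.sequences)


@dataclass
class CurationReport:
    n_input: int = 0
    n_removed_keyword: int = 0
    n_removed_length: int = 0
    n_removed_duplicate: int = 0
    n_retained: int = 0
    removed_ids: list[tuple[str, str]] = field(default_factory=list)

    def reconciles(self) -> bool:
        return self.n_input == (
            self.n_retained
            + self.n_removed_keyword
            + self.n_removed_length
            + self.n_removed_duplicate
        )


@dataclass(frozen=True)
class QueryMap:
    """Mapping between alignment columns and 1-based ungapped query positions.

    ``column_to_query[i]`` is the query position held by column ``i``, or
    ``None`` where the query row carries a gap.
    """

    column_to_query: tuple[int | None, ...]
    query_length: int

    def position_to_column(self, position: int) -> int:
        """Column index (0-based) holding query position ``position`` (1-based)."""
        col = self._inverse.get(position)
        if col is None:
            raise KeyError(f"query position {position} out of range 1..{self.query_length}")
        return col

    @property
    def _inverse(self) -> dict[int, int]:
        inv = getattr(self, "_inv_cache", None)
        if inv is None:
            inv = {p: c for c, p in enumerate(self.column_to_query) if p is not None}
            object.__setattr__(self, "_inv_cache", inv)
        return inv


def _normalize(raw: str, seq_id: str) -> str:
    s = raw.upper().replace(".", GAP)
    for pos, ch in enumerate(s):
        if ch not in ALPHABET:
            raise AlignmentError(
                f"sequence {seq_id!r} has unknown residue character {ch!r} "
                f"at column {pos + 1}"
            )
    return s


def read_alignment(path: str | Path | io.TextIOBase, query_id: str | None = None) -> Alignment:
    """Read an aligned FASTA file into an :class:`Alignment`.

    Residues are uppercased and ``.`` gaps normalized to ``-``. Ragged rows,
    unknown characters, and a missing ``query_id`` are hard errors.
    """
    handle = path if isinstance(path, io.TextIOBase) else open(path)
    try:
        records = list(SeqIO.parse(handle, "fasta"))
    finally:
        if handle is not path:
            handle.close()
    if not records:
        raise AlignmentError(f"no FASTA records found in {path}")
    sequences = [
        AlignedSequence(
            seq_id=rec.id,
            header=rec.description,
            residues=_normalize(str(rec.seq), rec.id),
        )
        for rec in records
    ]
    return Alignment(sequences=sequences, query_id=query_id)


def write_alignment(alignment: Alignment, path: str | Path, wrap: int = 60) -> None:
    """Write an alignment as aligned FASTA (60-column wrapping by default)."""
    records = [
        SeqRecord(Seq(rec.residues), id=rec.seq_id, description=rec.header)
        for rec in alignment.sequences
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(records)


def curate(
    alignment: Alignment,
    keywords: Iterable[str] = DEFAULT_KEYWORDS,
    min_len_frac: float = 0.8,
    max_len_frac: float = 1.2,
) -> tuple[Alignment, CurationReport]:
    """Remove keyword-flagged, length-outlier and duplicate sequences.

    Filters are applied in order (keyword, length window, duplicate) and a
    sequence is counted under the first filter that removes it. Lengths are
    ungapped lengths compared against ``[min_len_frac, max_len_frac]`` times
    the query's ungapped length; duplicates are later sequences whose ungapped
    string equals that of an earlier *retained* sequence. The query row is
    never removed.
    """
    if not (0 < min_len_frac <= 1 <= max_len_frac):
        raise ValueError(
            f"length window must satisfy 0 < min_len_frac <= 1 <= max_len_frac, "
            f"got ({min_len_frac}, {max_len_frac})"
        )
    query = alignment.query  # raises if no query flagged
    qlen = query.ungapped_length
    lo, hi = min_len_frac * qlen, max_len_frac * qlen
    kw = [k.lower() for k in keywords]

    report = CurationReport(n_input=alignment.n_sequences)
    kept: list[AlignedSequence] = []
    seen_ungapped: set[str] = set()
    for rec in alignment.sequences:
        if rec.seq_id == alignment.query_id:
            kept.append(rec)
            seen_ungapped.add(rec.ungapped)
            continue
        header = rec.header.lower()
        if any(k in header for k in kw):
            report.n_removed_keyword += 1
            report.removed_ids.append((rec.seq_id, "keyword"))
            continue
        if not lo <= rec.ungapped_length <= hi:
            report.n_removed_length += 1
            report.removed_ids.append((rec.seq_id, "length"))
            continue
        if rec.ungapped in seen_ungapped:
            report.n_removed_duplicate += 1
            report.removed_ids.append((rec.seq_id, "duplicate"))
            continue
        kept.append(rec)
        seen_ungapped.add(rec.ungapped)
    report.n_retained = len(kept)
    if len(kept) < 2:
        raise AlignmentError("curation removed every non-query sequence")
    assert report.reconciles()
    return Alignment(sequences=kept, query_id=alignment.query_id), report


def build_query_map(alignment: Alignment) -> QueryMap:
    """Map alignment columns to 1-based ungapped query positions."""
    qrow = alignment.query.residues
    mapping: list[int | None] = []
    pos = 0
    for ch in qrow:
        if ch == GAP:
            mapping.append(None)
        else:
            pos += 1
            mapping.append(pos)
    if pos == 0:
        raise AlignmentError("query row is entirely gaps")
    return QueryMap(column_to_query=tuple(mapping), query_length=pos)


def write_curation_report(report: CurationReport, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("metric\tvalue\n")
        fh.write(f"n_input\t{report.n_input}\n")
        fh.write(f"n_removed_keyword\t{report.n_removed_keyword}\n")
        fh.write(f"n_removed_length\t{report.n_removed_length}\n")
        fh.write(f"n_removed_duplicate\t{report.n_removed_duplicate}\n")
        fh.write(f"n_retained\t{report.n_retained}\n")
        for seq_id, reason in report.removed_ids:
            fh.write(f"removed\t{seq_id}:{reason}\n")
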