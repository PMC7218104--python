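"""Per-column conservation: residue profiles, consensus calls, relative entropy.

Relative entropy (RE) of a column is the Kullback–Leibler divergence of the
column's amino-acid frequency distribution ``p`` from a background ``q``:

    RE = sum_a p(a) * ln(p(a) / q(a))        [nats]

Against the default uniform background (q = 1/20) a fully conserved column
scores ln(20) ≈ 3.0 nats and a column matching the background scores 0, so
RE directly ranks columns by conservation. Gaps and ambiguous 'X' residues
carry no consensus information and are excluded from the categorical
distribution; they only contribute to the column's gap fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alignment_io import AMINO_ACIDS, GAP, UNKNOWN, Alignment, QueryMap

AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
MAX_RE_UNIFORM: float = math.log(20.0)


@dataclass(frozen=True)
class BackgroundDistribution:
    """Amino-acid background probabilities q(a), ordered as ``AMINO_ACIDS``."""

    probabilities: tuple[float, ...]

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.shape != (20,):
            raise ValueError("background must give one probability per amino acid")
        if not np.all(p > 0):
            raise ValueError("background probabilities must be strictly positive")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"background probabilities sum to {p.sum()}, not 1")

    @classmethod
    def uniform(cls) -> "BackgroundDistribution":
        return cls(probabilities=tuple([1.0 / 20] * 20))

    @classmethod
    def from_alignment(cls, alignment: Alignment) -> "BackgroundDistribution":
        """Empirical background from all non-gap, non-'X' residues of an alignment.

        A pseudo-observation of each amino acid keeps probabilities strictly
        positive in small alignments.
        """
        counts = np.ones(20)
        for rec in alignment.sequences:
            for ch in rec.residues:
                idx = AA_INDEX.get(ch)
                if idx is not None:
                    counts[idx] += 1
        return cls(probabilities=tuple(counts / counts.sum()))

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.probabilities, dtype=float)


@dataclass
class ColumnProfile:
    """Residue statistics for one alignment column.

    ``query_position`` is the 1-based ungapped query position held by this
    column, or ``None`` where the query row is gapped. ``relative_entropy``
    is ``nan`` for columns with no countable residues (all gap/'X').
    """

    column_index: int
    query_position: int | None
    counts: np.ndarray
    frequencies: np.ndarray
    gap_fraction: float
    consensus_residue: str | None
    consensus_tied: bool
    relative_entropy: float

    @property
    def defined(self) -> bool:
        return self.consensus_residue is not None


def _column_counts(column: str) -> tuple[np.ndarray, int]:
    counts = np.zeros(20)
    n_uncounted = 0
    for ch in column:
        idx = AA_INDEX.get(ch)
        if idx is None:  # gap or 'X'
            n_uncounted += 1
        else:
            counts[idx] += 1
    return counts, n_uncounted


def relative_entropy(frequencies: np.ndarray, background: BackgroundDistribution) -> float:
    """KL divergence (nats) of ``frequencies`` from the background, 0·ln(0/q) = 0."""
    p = np.asarray(frequencies, dtype=float)
    q = background.array
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] / q[nz])))


def column_profile(
    alignment: Alignment,
    col: int,
    background: BackgroundDistribution | None = None,
    query_map: QueryMap | None = None,
    pseudocount: float = 0.0,
) -> ColumnProfile:
    """Profile one column: frequencies, gap fraction, consensus, RE.

    ``pseudocount`` adds a Laplace count alpha to every amino acid before
    normalizing (default 0: raw frequencies). Consensus ties are broken
    alphabetically by one-letter code and flagged.
    """
    background = background or BackgroundDistribution.uniform()
    column = alignment.column(col)
    counts, n_uncounted = _column_counts(column)
    gap_fraction = n_uncounted / len(column)
    query_position = query_map.column_to_query[col] if query_map is not None else None

    total = counts.sum()
    if total == 0:
        return ColumnProfile(
            column_index=col,
            query_position=query_position,
            counts=counts,
            frequencies=np.zeros(20),
            gap_fraction=gap_fraction,
            consensus_residue=None,
            consensus_tied=False,
            relative_entropy=float("nan"),
        )
    smoothed = counts + pseudocount
    frequencies = smoothed / smoothed.sum()
    best = int(np.argmax(counts))  # np.argmax takes the first maximum: alphabetical
    tied = int(np.sum(counts == counts[best])) > 1
    return ColumnProfile(
        column_index=col,
        query_position=query_position,
        counts=counts,
        frequencies=frequencies,
        gap_fraction=gap_fraction,
        consensus_residue=AMINO_ACIDS[best],
        consensus_tied=tied,
        relative_entropy=relative_entropy(frequencies, background),
    )


def profile_alignment(
    alignment: Alignment,
    background: BackgroundDistribution | None = None,
    query_map: QueryMap | None = None,
    pseudocount: float = 0.0,
) -> list[ColumnProfile]:
    """Profiles for every column of the alignment."""
    background = background or BackgroundDistribution.uniform()
    return [
        column_profile(alignment, c, background, query_map, pseudocount)
        for c in range(alignment.n_columns)
    ]


def consensus_sequence(profiles: list[ColumnProfile], query_map: QueryMap) -> str:
    """Query-indexed consensus string (one residue per ungapped query position).

    Columns where the query is gapped are skipped; columns with no countable
    residues emit 'X'.
    """
    out = [UNKNOWN] * query_map.query_length
    for prof in profiles:
        pos = query_map.column_to_query[prof.column_index]
        if pos is None:
            continue
        out[pos - 1] = prof.consensus_residue if prof.defined else UNKNOWN
    return "".join(out)


def mean_re(profiles: list[ColumnProfile], max_gap_fraction: float = 0.5) -> float:
    """Arithmetic mean RE over columns with defined RE and gap fraction below cutoff."""
    values = [
        p.relative_entropy
        for p in profiles
        if p.gap_fraction <= max_gap_fraction and not math.isnan(p.relative_entropy)
    ]
    if not values:
        raise ValueError(
            f"no column is eligible for mean RE at max_gap_fraction={max_gap_fraction}"
        )
    return float(np.mean(values))


def write_profile_table(profiles: list[ColumnProfile], path: str | Path) -> None:
    """TSV: column, query position, gap fraction, consensus, RE, top-3 residues."""
    with open(path, "w") as fh:
        fh.write(
            "column\tquery_position\tgap_fraction\tconsensus\ttied\t"
            "relative_entropy\ttop3\n"
        )
        for p in profiles:
            if p.defined:
                order = np.argsort(-p.frequencies, kind="stable")[:3]
                top3 = ",".join(
                    f"{AMINO_ACIDS[i]}:{p.frequencies[i]:.3f}"
                    for i in order
                    if p.frequencies[i] > 0
                )
                re_str = f"{p.relative_entropy:.4f}"
                cons = p.consensus_residue
            else:
                top3, re_str, cons = "", "NA", "NA"
            qpos = p.query_position if p.query_position is not None else "gap"
            fh.write(
                f"{p.column_index}\t{qpos}\t{p.gap_fraction:.4f}\t{cons}\t"
                f"{int(p.consensus_tied)}\t{re_str}\t{top3}\n"
            )
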