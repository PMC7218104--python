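"""Pairwise mutual information between alignment columns, with shuffle-noise
correction.

Mutual information (MI) between columns i and j,

    MI = sum_{a,b} p(a,b) * ln( p(a,b) / (p(a) p(b)) )     [nats]

flags co-evolving position pairs whose substitution may need compensation.
Finite alignments inflate MI even between independent columns, so a noise
floor is estimated by shuffling each column independently across sequences
(which destroys inter-column coupling while preserving every column's
residue composition and gap count) and averaging the MI of the shuffled
alignments over replicates. The corrected score is the raw MI minus this
noise, clipped at zero.

Marginals are always recomputed on the jointly non-gap rows of a pair, and
pairs with too few such rows are marked ineligible (NaN) rather than
reported as unreliable numbers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment_io import Alignment
from .conservation import AA_INDEX, ColumnProfile
from .alignment_io import QueryMap

#: integer code used for gaps and 'X' (anything that is not a countable residue)
GAP_CODE: int = 20

DEFAULT_MIN_PAIR_COVERAGE: int = 20
DEFAULT_N_REPLICATES: int = 20


def encode_alignment(alignment: Alignment) -> np.ndarray:
    """(n_sequences, n_columns) uint8 matrix; amino acids 0..19, gap/'X' 20."""
    lut = np.full(128, GAP_CODE, dtype=np.uint8)
    for aa, idx in AA_INDEX.items():
        lut[ord(aa)] = idx
    rows = [
        lut[np.frombuffer(rec.residues.encode("ascii"), dtype=np.uint8)]
        for rec in alignment.sequences
    ]
    return np.vstack(rows)


def _mi_from_codes(ci: np.ndarray, cj: np.ndarray, min_pair_coverage: int) -> float:
    """Raw MI (nats) of two code vectors over their jointly non-gap rows."""
    mask = (ci < GAP_CODE) & (cj < GAP_CODE)
    n = int(mask.sum())
    if n < min_pair_coverage:
        return float("nan")
    joint = np.bincount(ci[mask].astype(np.intp) * 20 + cj[mask], minlength=400)
    jm = joint.reshape(20, 20)
    row = jm.sum(axis=1)
    colsum = jm.sum(axis=0)
    nz = joint > 0
    c = joint[nz].astype(float)
    outer = (row[:, None] * colsum[None, :]).ravel()[nz]
    # MI = (1/n) * sum c * ln(c * n / outer)
    return float(np.sum(c * np.log(c * n / outer)) / n)


def pairwise_mi(
    alignment_or_codes: Alignment | np.ndarray,
    col_i: int,
    col_j: int,
    min_pair_coverage: int = DEFAULT_MIN_PAIR_COVERAGE,
) -> float:
    """Raw MI between two columns; NaN if joint coverage is insufficient."""
    if col_i == col_j:
        raise ValueError("pairwise MI requires two distinct columns")
    codes = (
        alignment_or_codes
        if isinstance(alignment_or_codes, np.ndarray)
        else encode_alignment(alignment_or_codes)
    )
    return _mi_from_codes(codes[:, col_i], codes[:, col_j], min_pair_coverage)


def mi_matrix(codes: np.ndarray, min_pair_coverage: int = DEFAULT_MIN_PAIR_COVERAGE) -> np.ndarray:
    """Symmetric raw-MI matrix over all column pairs (diagonal NaN)."""
    n_cols = codes.shape[1]
    out = np.full((n_cols, n_cols), np.nan)
    cols = [np.ascontiguousarray(codes[:, c]) for c in range(n_cols)]
    for i in range(n_cols):
        for j in range(i + 1, n_cols):
            v = _mi_from_codes(cols[i], cols[j], min_pair_coverage)
            out[i, j] = v
            out[j, i] = v
    return out


def shuffle_columns(codes: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Independently permute each column across sequences (gaps shuffled too)."""
    shuffled = codes.copy()
    n_rows = codes.shape[0]
    for c in range(codes.shape[1]):
        shuffled[:, c] = shuffled[rng.permutation(n_rows), c]
    return shuffled


def shuffle_noise(
    alignment_or_codes: Alignment | np.ndarray,
    n_replicates: int = DEFAULT_N_REPLICATES,
    seed: int | None = None,
    min_pair_coverage: int = DEFAULT_MIN_PAIR_COVERAGE,
) -> np.ndarray:
    """Mean raw-MI matrix of ``n_replicates`` column-shuffled alignments.

    Deterministic for a given ``seed``. Entries where a replicate was
    ineligible are averaged over the remaining replicates.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    codes = (
        alignment_or_codes
        if isinstance(alignment_or_codes, np.ndarray)
        else encode_alignment(alignment_or_codes)
    )
    rng = np.random.default_rng(seed)
    acc = np.zeros((codes.shape[1], codes.shape[1]))
    cnt = np.zeros_like(acc)
    for _ in range(n_replicates):
        rep = mi_matrix(shuffle_columns(codes, rng), min_pair_coverage)
        ok = ~np.isnan(rep)
        acc[ok] += rep[ok]
        cnt[ok] += 1
    with np.errstate(invalid="ignore"):
        noise = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    np.fill_diagonal(noise, np.nan)
    return noise


@dataclass
class CouplingResult:
    """Raw, noise and corrected MI matrices for one alignment."""

    mi_raw: np.ndarray
    mi_noise: np.ndarray
    mi_corrected: np.ndarray
    n_replicates: int
    seed: int | None


@dataclass(frozen=True)
class PositionMIScore:
    """Per-query-position MI score: max corrected MI against any eligible partner."""

    query_position: int
    mi_score: float
    partner_column: int | None
    partner_position: int | None


def compute_coupling(
    alignment: Alignment,
    n_replicates: int = DEFAULT_N_REPLICATES,
    seed: int | None = None,
    min_pair_coverage: int = DEFAULT_MIN_PAIR_COVERAGE,
) -> CouplingResult:
    """Raw MI, shuffle noise and clipped corrected MI for all column pairs."""
    codes = encode_alignment(alignment)
    raw = mi_matrix(codes, min_pair_coverage)
    noise = shuffle_noise(codes, n_replicates, seed, min_pair_coverage)
    corrected = np.clip(raw - noise, 0.0, None)
    return CouplingResult(
        mi_raw=raw,
        mi_noise=noise,
        mi_corrected=corrected,
        n_replicates=n_replicates,
        seed=seed,
    )


def eligible_columns(
    profiles: list[ColumnProfile], max_gap_fraction: float = 0.5
) -> set[int]:
    """Columns with enough residue occupancy to enter MI scoring."""
    return {
        p.column_index
        for p in profiles
        if p.defined and p.gap_fraction <= max_gap_fraction
    }


def position_mi_scores(
    coupling: CouplingResult,
    query_map: QueryMap,
    eligible: set[int],
    aggregation: str = "max",
) -> list[PositionMIScore]:
    """One MI score per query position.

    ``max`` aggregation (default) reports the strongest corrected coupling of
    the position's column to any other eligible column — the conservative
    reading of "this position is not strongly coupled to anything". ``mean``
    averages over eligible partners instead. Positions with no eligible
    partner score 0.
    """
    if aggregation not in ("max", "mean"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    corrected = coupling.mi_corrected
    scores: list[PositionMIScore] = []
    elig = sorted(eligible)
    for col, pos in enumerate(query_map.column_to_query):
        if pos is None or col not in eligible:
            continue
        partners = [c for c in elig if c != col and not np.isnan(corrected[col, c])]
        if not partners:
            scores.append(PositionMIScore(pos, 0.0, None, None))
            continue
        vals = corrected[col, partners]
        if aggregation == "max":
            k = int(np.argmax(vals))
            partner = partners[k]
            scores.append(
                PositionMIScore(
                    query_position=pos,
                    mi_score=float(vals[k]),
                    partner_column=partner,
                    partner_position=query_map.column_to_query[partner],
                )
            )
        else:
            scores.append(PositionMIScore(pos, float(np.mean(vals)), None, None))
    return scores


def write_mi_matrix(coupling: CouplingResult, query_map: QueryMap, path) -> None:
    """Upper-triangle corrected-MI table in query numbering (TSV)."""
    with open(path, "w") as fh:
        fh.write("position_i\tposition_j\tmi_raw\tmi_noise\tmi_corrected\n")
        n = coupling.mi_corrected.shape[0]
        for i in range(n):
            pi = query_map.column_to_query[i]
            if pi is None:
                continue
            for j in range(i + 1, n):
                pj = query_map.column_to_query[j]
                if pj is None or np.isnan(coupling.mi_raw[i, j]):
                    continue
                fh.write(
                    f"{pi}\t{pj}\t{coupling.mi_raw[i, j]:.6f}\t"
                    f"{coupling.mi_noise[i, j]:.6f}\t{coupling.mi_corrected[i, j]:.6f}\n"
                )


def write_position_scores(scores: list[PositionMIScore], path) -> None:
    with open(path, "w") as fh:
        fh.write("query_position\tmi_score\tpartner_position\n")
        for s in scores:
            partner = s.partner_position if s.partner_position is not None else "NA"
            fh.write(f"{s.query_position}\t{s.mi_score:.6f}\t{partner}\n")
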