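"""Candidate consensus mutations and the RE/MI selection funnel.

The method: compare each alignment's consensus sequence against the query
protein, record every position where a consensus residue differs from the
query as a *potential* consensus mutation, then keep only substitutions that

  * have relative entropy above that alignment's mean RE in every alignment
    (well-conserved, not just noise),
  * call the same non-query consensus residue in every alignment,
  * are not nearly invariant (RE <= re_cap; a position conserved at ~2.4+
    nats disagrees with the query for reasons unlikely to be neutral), and
  * are not strongly coupled to another position (MI score <= mi_max;
    covarying positions may need compensating changes).

Both thresholds are inclusive. Selected mutations are finally compared
against an ancestral sequence to tag consensus/ancestral agreement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .alignment_io import GAP, QueryMap
from .conservation import ColumnProfile
from .covariation import PositionMIScore

DEFAULT_MI_MAX: float = 0.6
DEFAULT_RE_CAP: float = 2.4


@dataclass
class SelectionConfig:
    """Thresholds of the selection funnel (both inclusive)."""

    mi_max: float = DEFAULT_MI_MAX
    re_cap: float = DEFAULT_RE_CAP
    require_all_msas: bool = True
    max_gap_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.mi_max <= 0:
            raise ValueError(f"mi_max must be positive, got {self.mi_max}")
        if self.re_cap <= 0:
            raise ValueError(f"re_cap must be positive, got {self.re_cap}")


@dataclass
class CandidateMutation:
    query_position: int
    wild_residue: str
    consensus_residue: str
    re_values: list[float] = field(default_factory=list)
    per_msa_consensus: list[str | None] = field(default_factory=list)
    in_all_msas: bool = False
    mi_score: float = float("nan")
    re_preselected: bool = False
    mi_pass: bool = False
    re_cap_pass: bool = False
    selected: bool = False
    ancestral_residue: str | None = None
    consensus_ancestral: bool | None = None

    @property
    def label(self) -> str:
        return f"{self.wild_residue}{self.query_position}{self.consensus_residue}"


def call_candidates(
    profiles_per_msa: list[list[ColumnProfile]],
    query_maps: list[QueryMap],
    query_sequence: str,
    max_gap_fraction: float = 0.5,
) -> list[CandidateMutation]:
    """One candidate per query position where any alignment's consensus differs
    from the query residue.

    The query's ungapped sequence must be identical across alignments (they
    are alignments of the same protein). A column is only allowed to call a
    candidate if it passes the gap-occupancy cutoff. The candidate's single
    ``consensus_residue`` is the most common differing consensus across the
    alignments (first alignment wins ties); ``in_all_msas`` is true only when
    every alignment calls the same non-query consensus at the position.
    """
    if not profiles_per_msa:
        raise ValueError("at least one alignment is required")
    for qmap in query_maps:
        if qmap.query_length != len(query_sequence):
            raise ValueError(
                "query sequence disagrees across alignments: length "
                f"{qmap.query_length} vs {len(query_sequence)}"
            )

    n_msa = len(profiles_per_msa)
    by_position: list[list[ColumnProfile | None]] = [
        [None] * n_msa for _ in range(len(query_sequence))
    ]
    for m, (profiles, qmap) in enumerate(zip(profiles_per_msa, query_maps)):
        for prof in profiles:
            pos = qmap.column_to_query[prof.column_index]
            if pos is not None:
                by_position[pos - 1][m] = prof

    candidates: list[CandidateMutation] = []
    for pos0, row in enumerate(by_position):
        wild = query_sequence[pos0]
        if wild == GAP:
            continue
        cons: list[str | None] = []
        res: list[float] = []
        for prof in row:
            if prof is None or not prof.defined or prof.gap_fraction > max_gap_fraction:
                cons.append(None)
                res.append(float("nan"))
            else:
                cons.append(prof.consensus_residue)
                res.append(prof.relative_entropy)
        differing = [c for c in cons if c is not None and c != wild]
        if not differing:
            continue
        # most common differing consensus; ties resolved by alignment order
        counts: dict[str, int] = {}
        for c in differing:
            counts[c] = counts.get(c, 0) + 1
        consensus = max(counts, key=lambda c: (counts[c], -differing.index(c)))
        in_all = all(c is not None and c != wild for c in cons) and len(set(differing)) == 1
        candidates.append(
            CandidateMutation(
                query_position=pos0 + 1,
                wild_residue=wild,
                consensus_residue=consensus,
                re_values=res,
                per_msa_consensus=cons,
                in_all_msas=in_all,
            )
        )
    return candidates


def select(
    candidates: list[CandidateMutation],
    per_msa_mean_re: list[float],
    mi_scores: list[PositionMIScore],
    config: SelectionConfig | None = None,
) -> list[CandidateMutation]:
    """Fill selection flags in place and return the candidate list.

    ``re_preselected``: RE strictly above the mean RE of the same alignment,
    in every alignment. ``mi_pass``: MI score <= mi_max (positions without a
    score are treated as uncoupled, score 0). ``re_cap_pass``: RE <= re_cap
    in every alignment. ``selected`` is the conjunction, optionally requiring
    the same consensus in every alignment.
    """
    config = config or SelectionConfig()
    score_by_pos = {s.query_position: s.mi_score for s in mi_scores}
    for cand in candidates:
        res = cand.re_values
        if len(res) != len(per_msa_mean_re):
            raise ValueError("per-MSA RE values and means have different lengths")
        cand.re_preselected = all(
            not math.isnan(r) and r > m for r, m in zip(res, per_msa_mean_re)
        )
        cand.mi_score = score_by_pos.get(cand.query_position, 0.0)
        cand.mi_pass = cand.mi_score <= config.mi_max
        cand.re_cap_pass = all(not math.isnan(r) and r <= config.re_cap for r in res)
        cand.selected = (
            cand.re_preselected
            and cand.mi_pass
            and cand.re_cap_pass
            and (cand.in_all_msas or not config.require_all_msas)
        )
    return candidates


def tag_ancestral(
    candidates: list[CandidateMutation], ancestral_sequence: str
) -> list[CandidateMutation]:
    """Tag each candidate with the ancestral residue at its query position.

    ``ancestral_sequence`` is an ungapped sequence in query coordinates
    (position k of the query corresponds to character k). Positions outside
    the ancestral sequence, or holding a gap/'X', leave the tag undefined.
    """
    for cand in candidates:
        idx = cand.query_position - 1
        if 0 <= idx < len(ancestral_sequence):
            anc = ancestral_sequence[idx].upper()
            if anc in (GAP, "X"):
                cand.ancestral_residue = None
                cand.consensus_ancestral = None
            else:
                cand.ancestral_residue = anc
                cand.consensus_ancestral = cand.consensus_residue == anc
        else:
            cand.ancestral_residue = None
            cand.consensus_ancestral = None
    return candidates


@dataclass(frozen=True)
class FunnelSummary:
    n_potential: int
    n_preselected: int
    n_selected: int
    n_consensus_ancestral: int
    n_ancestral_known: int


def funnel_summary(candidates: list[CandidateMutation]) -> FunnelSummary:
    selected = [c for c in candidates if c.selected]
    tagged = [c for c in selected if c.consensus_ancestral is not None]
    return FunnelSummary(
        n_potential=len(candidates),
        n_preselected=sum(
            1 for c in candidates if c.re_preselected and c.in_all_msas
        ),
        n_selected=len(selected),
        n_consensus_ancestral=sum(1 for c in tagged if c.consensus_ancestral),
        n_ancestral_known=len(tagged),
    )


def design_report(candidates: list[CandidateMutation]) -> pd.DataFrame:
    """Candidate table sorted by query position, one row per candidate."""
    rows = []
    for c in sorted(candidates, key=lambda c: c.query_position):
        row = {
            "mutation": c.label,
            "position": c.query_position,
            "wild": c.wild_residue,
            "consensus": c.consensus_residue,
            "mi": round(c.mi_score, 4) if not math.isnan(c.mi_score) else float("nan"),
            "in_all_msas": c.in_all_msas,
            "re_preselected": c.re_preselected,
            "mi_pass": c.mi_pass,
            "re_cap_pass": c.re_cap_pass,
            "selected": c.selected,
            "ancestor": c.ancestral_residue if c.ancestral_residue else "NA",
            "consensus_ancestral": (
                "NA" if c.consensus_ancestral is None else bool(c.consensus_ancestral)
            ),
        }
        for m, r in enumerate(c.re_values, start=1):
            row[f"re_msa{m}"] = round(r, 4) if not math.isnan(r) else float("nan")
        row["re_max"] = round(max(c.re_values), 4) if c.re_values else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def write_design_report(candidates: list[CandidateMutation], path: str | Path) -> None:
    """TSV report with a funnel-count summary in leading comment lines."""
    summary = funnel_summary(candidates)
    df = design_report(candidates)
    with open(path, "w") as fh:
        fh.write(
            f"# funnel: potential={summary.n_potential} "
            f"preselected={summary.n_preselected} selected={summary.n_selected} "
            f"consensus_ancestral={summary.n_consensus_ancestral}"
            f"/{summary.n_ancestral_known}\n"
        )
        df.to_csv(fh, sep="\t", index=False)


# --- packaged published candidate set -------------------------------------

def load_published_candidates() -> pd.DataFrame:
    """The published 20-mutation candidate set for the PM1 laccase (OB-1).

    Columns: mutation label, relative entropy (nats), MI score (nats), and
    the consensus/ancestor residue pair as printed.
    """
    ref = resources.files("consdesign.data").joinpath("pm1_laccase_candidates.tsv")
    with ref.open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def filter_published_candidates(
    table: pd.DataFrame, config: SelectionConfig | None = None
) -> pd.DataFrame:
    """Apply the MI/RE selection predicate to a published candidate table."""
    config = config or SelectionConfig()
    keep = (table["mi"] <= config.mi_max) & (table["re"] <= config.re_cap)
    return table[keep].reset_index(drop=True)
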