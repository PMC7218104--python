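"""End-to-end consensus design: alignments in, selected mutations out."""

from __future__ import annotations

from dataclasses import dataclass

from .alignment_io import Alignment, AlignmentError, QueryMap, build_query_map
from .conservation import (
    BackgroundDistribution,
    ColumnProfile,
    mean_re,
    profile_alignment,
)
from .covariation import (
    DEFAULT_MIN_PAIR_COVERAGE,
    DEFAULT_N_REPLICATES,
    CouplingResult,
    PositionMIScore,
    compute_coupling,
    eligible_columns,
    position_mi_scores,
)
from .design import (
    CandidateMutation,
    FunnelSummary,
    SelectionConfig,
    call_candidates,
    funnel_summary,
    select,
    tag_ancestral,
)


@dataclass
class DesignResult:
    candidates: list[CandidateMutation]
    summary: FunnelSummary
    per_msa_mean_re: list[float]
    profiles_per_msa: list[list[ColumnProfile]]
    query_maps: list[QueryMap]
    reference_index: int
    coupling: CouplingResult
    mi_scores: list[PositionMIScore]

    @property
    def selected(self) -> list[CandidateMutation]:
        return [c for c in self.candidates if c.selected]


def run_design(
    alignments: list[Alignment],
    seed: int,
    config: SelectionConfig | None = None,
    background: BackgroundDistribution | None = None,
    ancestral_sequence: str | None = None,
    n_replicates: int = DEFAULT_N_REPLICATES,
    min_pair_coverage: int = DEFAULT_MIN_PAIR_COVERAGE,
    reference_index: int | None = None,
    mi_aggregation: str = "max",
    pseudocount: float = 0.0,
) -> DesignResult:
    """Run the full funnel over one or more curated alignments of one query.

    MI is computed on a single designated reference alignment (by default the
    deepest one), since a coupling estimate is most reliable where the sample
    is largest. All alignments must contain the same query protein (identical
    ungapped query sequence).
    """
    if not alignments:
        raise ValueError("at least one alignment is required")
    config = config or SelectionConfig()
    background = background or BackgroundDistribution.uniform()

    query_maps = [build_query_map(a) for a in alignments]
    query_seq = alignments[0].query.ungapped
    for a in alignments[1:]:
        if a.query.ungapped != query_seq:
            raise AlignmentError(
                "query sequences differ between alignments; the alignments "
                "must all contain the same query protein"
            )

    profiles_per_msa = [
        profile_alignment(a, background, qmap, pseudocount)
        for a, qmap in zip(alignments, query_maps)
    ]
    per_msa_mean_re = [
        mean_re(profiles, config.max_gap_fraction) for profiles in profiles_per_msa
    ]

    if reference_index is None:
        reference_index = max(
            range(len(alignments)), key=lambda i: alignments[i].n_sequences
        )
    reference = alignments[reference_index]
    coupling = compute_coupling(
        reference, n_replicates=n_replicates, seed=seed,
        min_pair_coverage=min_pair_coverage,
    )
    eligible = eligible_columns(
        profiles_per_msa[reference_index], config.max_gap_fraction
    )
    mi_scores = position_mi_scores(
        coupling, query_maps[reference_index], eligible, mi_aggregation
    )

    candidates = call_candidates(
        profiles_per_msa, query_maps, query_seq, config.max_gap_fraction
    )
    select(candidates, per_msa_mean_re, mi_scores, config)
    if ancestral_sequence is not None:
        tag_ancestral(candidates, ancestral_sequence)

    return DesignResult(
        candidates=candidates,
        summary=funnel_summary(candidates),
        per_msa_mean_re=per_msa_mean_re,
        profiles_per_msa=profiles_per_msa,
        query_maps=query_maps,
        reference_index=reference_index,
        coupling=coupling,
        mi_scores=mi_scores,
    )
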