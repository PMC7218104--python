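"""Synthetic alignments and toy structures with known ground truth.

The generator draws columns independently (apart from planted covarying
pairs) from a fixed per-column residue distribution:

* ordinary columns have a random majority residue at ``baseline_conservation``
  probability with the remainder spread uniformly over a small random set of
  minority residues (real alignment columns show a handful of residues, not
  all 20); the query carries the majority residue, so ordinary columns do not
  call consensus mutations;
* planted consensus positions put ``consensus_residue`` at
  ``consensus_frequency`` in non-query rows while the query row carries a
  different ``query_residue`` — these are the true positives the selection
  funnel should recover;
* covarying pairs draw both columns from a shared two-state latent symbol
  with probability ``coupling`` (independently otherwise), planting true
  mutual information; *decoy* pairs additionally make the first column
  query-divergent, planting candidates that only the MI filter can reject.

Columns are independent across sequences — there is no phylogenetic tree, so
tree-induced correlations (which shuffle-noise correction cannot remove) are
deliberately absent. Gaps are inserted independently at ``gap_rate``, never
in the query row.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .alignment_io import AMINO_ACIDS, GAP, AlignedSequence, Alignment

#: two-state weights for covarying pairs; unequal so the consensus is unique
PAIR_STATE_WEIGHTS: tuple[float, float] = (0.6, 0.4)


@dataclass(frozen=True)
class SyntheticMSASpec:
    """Generative recipe for one alignment (or a triple sharing a query).

    Positions are 1-based query positions; the query row is ungapped, so the
    query length equals ``n_columns``.
    """

    n_sequences: int = 300
    n_columns: int = 60
    baseline_conservation: float = 0.5
    planted_consensus_positions: tuple[tuple[int, str, str, float], ...] = ()
    planted_covarying_pairs: tuple[tuple[int, int, float], ...] = ()
    planted_decoy_pairs: tuple[tuple[int, int, str, str, float], ...] = ()
    gap_rate: float = 0.02
    seed: int = 0
    query_id: str = "query"
    n_minority_residues: int = 8

    def __post_init__(self) -> None:
        if self.n_sequences < 2:
            raise ValueError("n_sequences must be >= 2 (query plus one homolog)")
        if not 0 < self.baseline_conservation < 1:
            raise ValueError("baseline_conservation must be in (0, 1)")
        if not 0 <= self.gap_rate < 1:
            raise ValueError("gap_rate must be in [0, 1)")
        used: set[int] = set()

        def claim(pos: int) -> None:
            if not 1 <= pos <= self.n_columns:
                raise ValueError(f"planted position {pos} outside 1..{self.n_columns}")
            if pos in used:
                raise ValueError(
                    f"position {pos} is planted more than once (over-constrained spec)"
                )
            used.add(pos)

        for pos, query_res, cons_res, freq in self.planted_consensus_positions:
            claim(pos)
            if not 0 < freq <= 1:
                raise ValueError(f"consensus frequency {freq} outside (0, 1]")
            if query_res == cons_res:
                raise ValueError(f"planted position {pos}: query equals consensus")
        for pos_a, pos_b, coupling in self.planted_covarying_pairs:
            claim(pos_a)
            claim(pos_b)
            if not 0 <= coupling <= 1:
                raise ValueError(f"coupling {coupling} outside [0, 1]")
        for pos_a, pos_b, _query_res, _cons_res, coupling in self.planted_decoy_pairs:
            claim(pos_a)
            claim(pos_b)
            if not 0 <= coupling <= 1:
                raise ValueError(f"coupling {coupling} outside [0, 1]")


@dataclass(frozen=True)
class GroundTruth:
    """What was planted, sufficient to score the full selection pipeline."""

    query_sequence: str
    planted_positions: tuple[int, ...]
    planted_mutations: tuple[str, ...]
    decoy_positions: tuple[int, ...]
    decoy_mutations: tuple[str, ...]
    covarying_pairs: tuple[tuple[int, int], ...]


@dataclass
class _ColumnModel:
    support: np.ndarray  # residue indices with positive probability
    probs: np.ndarray
    query_code: int


@dataclass
class _PairModel:
    col_a: int  # 0-based
    col_b: int
    states_a: np.ndarray  # residue code per latent state
    states_b: np.ndarray
    weights: np.ndarray
    coupling: float


def _build_model(
    spec: SyntheticMSASpec, rng: np.random.Generator
) -> tuple[list[_ColumnModel | None], list[_PairModel], GroundTruth]:
    aa_codes = np.arange(20)
    columns: list[_ColumnModel | None] = [None] * spec.n_columns
    pairs: list[_PairModel] = []
    idx = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

    planted_pos: list[int] = []
    planted_mut: list[str] = []
    for pos, query_res, cons_res, freq in spec.planted_consensus_positions:
        q, c = idx[query_res], idx[cons_res]
        others = rng.choice(
            np.setdiff1d(aa_codes, [q, c]), size=4, replace=False
        )
        support = np.concatenate(([c, q], others))
        probs = np.concatenate(([freq], np.full(5, (1 - freq) / 5)))
        columns[pos - 1] = _ColumnModel(support, probs, q)
        planted_pos.append(pos)
        planted_mut.append(f"{query_res}{pos}{cons_res}")

    cov_pairs: list[tuple[int, int]] = []
    for pos_a, pos_b, coupling in spec.planted_covarying_pairs:
        states_a = rng.choice(aa_codes, size=2, replace=False)
        states_b = rng.choice(aa_codes, size=2, replace=False)
        pairs.append(
            _PairModel(
                pos_a - 1, pos_b - 1, states_a, states_b,
                np.asarray(PAIR_STATE_WEIGHTS), coupling,
            )
        )
        columns[pos_a - 1] = _ColumnModel(states_a, np.asarray(PAIR_STATE_WEIGHTS), int(states_a[0]))
        columns[pos_b - 1] = _ColumnModel(states_b, np.asarray(PAIR_STATE_WEIGHTS), int(states_b[0]))
        cov_pairs.append((pos_a, pos_b))

    decoy_pos: list[int] = []
    decoy_mut: list[str] = []
    for pos_a, pos_b, query_res, cons_res, coupling in spec.planted_decoy_pairs:
        q, c = idx[query_res], idx[cons_res]
        alt = int(rng.choice(np.setdiff1d(aa_codes, [q, c])))
        states_a = np.array([c, alt])
        states_b = rng.choice(aa_codes, size=2, replace=False)
        pairs.append(
            _PairModel(
                pos_a - 1, pos_b - 1, states_a, states_b,
                np.asarray(PAIR_STATE_WEIGHTS), coupling,
            )
        )
        columns[pos_a - 1] = _ColumnModel(states_a, np.asarray(PAIR_STATE_WEIGHTS), q)
        columns[pos_b - 1] = _ColumnModel(states_b, np.asarray(PAIR_STATE_WEIGHTS), int(states_b[0]))
        decoy_pos.append(pos_a)
        decoy_mut.append(f"{query_res}{pos_a}{cons_res}")
        cov_pairs.append((pos_a, pos_b))

    n_min = spec.n_minority_residues
    for col in range(spec.n_columns):
        if columns[col] is not None:
            continue
        majority = int(rng.integers(20))
        others = rng.choice(np.setdiff1d(aa_codes, [majority]), size=n_min, replace=False)
        support = np.concatenate(([majority], others))
        probs = np.concatenate(
            ([spec.baseline_conservation],
             np.full(n_min, (1 - spec.baseline_conservation) / n_min))
        )
        columns[col] = _ColumnModel(support, probs, majority)

    query_seq = "".join(AMINO_ACIDS[m.query_code] for m in columns)  # type: ignore[union-attr]
    truth = GroundTruth(
        query_sequence=query_seq,
        planted_positions=tuple(planted_pos),
        planted_mutations=tuple(planted_mut),
        decoy_positions=tuple(decoy_pos),
        decoy_mutations=tuple(decoy_mut),
        covarying_pairs=tuple(cov_pairs),
    )
    return columns, pairs, truth


def _draw_rows(
    spec: SyntheticMSASpec,
    columns: list[_ColumnModel],
    pairs: list[_PairModel],
    n_rows: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """(n_rows, n_columns) residue-code matrix for the non-query rows."""
    codes = np.empty((n_rows, spec.n_columns), dtype=np.int64)
    paired_cols = {p.col_a for p in pairs} | {p.col_b for p in pairs}
    for col, model in enumerate(columns):
        if col in paired_cols:
            continue
        draws = rng.choice(len(model.support), size=n_rows, p=model.probs)
        codes[:, col] = model.support[draws]
    for p in pairs:
        latent = rng.choice(2, size=n_rows, p=p.weights)
        coupled = rng.random(n_rows) < p.coupling
        ind_a = rng.choice(2, size=n_rows, p=p.weights)
        ind_b = rng.choice(2, size=n_rows, p=p.weights)
        za = np.where(coupled, latent, ind_a)
        zb = np.where(coupled, latent, ind_b)
        codes[:, p.col_a] = p.states_a[za]
        codes[:, p.col_b] = p.states_b[zb]
    return codes


def _to_alignment(
    spec: SyntheticMSASpec,
    query_seq: str,
    codes: np.ndarray,
    rng: np.random.Generator,
) -> Alignment:
    gap_mask = rng.random(codes.shape) < spec.gap_rate
    sequences = [AlignedSequence(spec.query_id, spec.query_id, query_seq)]
    width = len(str(codes.shape[0]))
    for r in range(codes.shape[0]):
        chars = [AMINO_ACIDS[c] for c in codes[r]]
        for c in np.nonzero(gap_mask[r])[0]:
            chars[c] = GAP
        seq_id = f"seq{r + 1:0{width}d}"
        sequences.append(AlignedSequence(seq_id, seq_id, "".join(chars)))
    return Alignment(sequences=sequences, query_id=spec.query_id)


def generate_msa(spec: SyntheticMSASpec) -> tuple[Alignment, GroundTruth]:
    """One alignment drawn from the spec; deterministic for a given seed."""
    rng = np.random.default_rng(spec.seed)
    columns, pairs, truth = _build_model(spec, rng)
    codes = _draw_rows(spec, columns, pairs, spec.n_sequences - 1, rng)
    return _to_alignment(spec, truth.query_sequence, codes, rng), truth


def generate_msa_triple(
    spec: SyntheticMSASpec, depths: tuple[int, int, int]
) -> tuple[list[Alignment], GroundTruth]:
    """Three independent draws from the same generative profile and query row.

    ``depths`` are total sequence counts (query included) of the three
    alignments, emulating homolog sets of different database depths.
    """
    for d in depths:
        if d < 2:
            raise ValueError(f"alignment depth {d} cannot form non-query rows")
    rng = np.random.default_rng(spec.seed)
    columns, pairs, truth = _build_model(spec, rng)
    alignments = []
    for i, depth in enumerate(depths):
        sub_rng = np.random.default_rng([spec.seed, i + 1])
        codes = _draw_rows(spec, columns, pairs, depth - 1, sub_rng)
        alignments.append(_to_alignment(spec, truth.query_sequence, codes, sub_rng))
    return alignments, truth


def design_benchmark_spec(
    n_planted: int = 10,
    n_decoys: int = 3,
    n_columns: int = 60,
    n_sequences: int = 300,
    consensus_frequency: float = 0.7,
    seed: int = 0,
) -> SyntheticMSASpec:
    """Benchmark recipe for the full selection funnel.

    Plants ``n_planted`` query-divergent conserved positions (true positives)
    and ``n_decoys`` query-divergent covarying pairs with true MI above the
    selection threshold (the MI filter must reject the divergent member).
    """
    rng = np.random.default_rng(seed)
    n_special = n_planted + 2 * n_decoys
    if n_special > n_columns:
        raise ValueError("not enough columns for the requested planted content")
    positions = 1 + rng.choice(n_columns, size=n_special, replace=False)
    consensus = []
    for i in range(n_planted):
        q, c = rng.choice(20, size=2, replace=False)
        consensus.append(
            (int(positions[i]), AMINO_ACIDS[q], AMINO_ACIDS[c], consensus_frequency)
        )
    decoys = []
    for i in range(n_decoys):
        a = int(positions[n_planted + 2 * i])
        b = int(positions[n_planted + 2 * i + 1])
        q, c = rng.choice(20, size=2, replace=False)
        decoys.append((a, b, AMINO_ACIDS[q], AMINO_ACIDS[c], 1.0))
    return SyntheticMSASpec(
        n_sequences=n_sequences,
        n_columns=n_columns,
        planted_consensus_positions=tuple(consensus),
        planted_decoy_pairs=tuple(decoys),
        seed=seed,
    )


# --- toy structures -------------------------------------------------------

@dataclass(frozen=True)
class ToyStructure:
    pdb_text: str
    site_spec: dict[str, dict]


def generate_toy_structure(
    n_residues: int,
    planted_distances: list[tuple[int, str, float]],
    seed: int = 0,
    max_attempts: int = 50,
) -> ToyStructure:
    """Minimal PDB text whose named-site distances equal the planted values.

    Residues are single-CA alanines spaced far apart; each planted
    ``(residue, site, distance)`` adds one copper site atom at the requested
    distance in a random direction. Geometrically infeasible requests (a
    site atom of the same site landing closer to a constrained residue than
    that residue's own planted distance) are retried and finally rejected.
    """
    if n_residues < 1:
        raise ValueError("need at least one residue")
    for res, site, d in planted_distances:
        if not 1 <= res <= n_residues:
            raise ValueError(f"planted residue {res} outside 1..{n_residues}")
        if d < 0:
            raise ValueError(f"planted distance {d} is negative")

    rng = np.random.default_rng(seed)
    res_coords = np.zeros((n_residues, 3))
    res_coords[:, 0] = 100.0 * np.arange(n_residues)

    site_atoms: dict[str, list[np.ndarray]] = {}
    for attempt in range(max_attempts):
        site_atoms = {}
        for res, site, d in planted_distances:
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            site_atoms.setdefault(site, []).append(res_coords[res - 1] + d * direction)
        ok = True
        for res, site, d in planted_distances:
            actual = min(
                float(np.linalg.norm(res_coords[res - 1] - atom))
                for atom in site_atoms[site]
            )
            if abs(actual - d) > 1e-3:
                ok = False
                break
        if ok:
            break
    else:
        raise ValueError("planted distances are geometrically infeasible")

    n_site_atoms = sum(len(v) for v in site_atoms.values())
    n_atoms = n_residues + n_site_atoms
    arr = struc.AtomArray(n_atoms)
    arr.coord = np.zeros((n_atoms, 3), dtype=np.float32)
    site_spec: dict[str, dict] = {}
    for i in range(n_residues):
        arr.coord[i] = res_coords[i]
        arr.chain_id[i] = "A"
        arr.res_id[i] = i + 1
        arr.res_name[i] = "ALA"
        arr.atom_name[i] = "CA"
        arr.element[i] = "C"
        arr.hetero[i] = False
    k = n_residues
    next_res_id = 1000
    for site, atoms in site_atoms.items():
        ids = []
        for coord in atoms:
            arr.coord[k] = coord
            arr.chain_id[k] = "S"
            arr.res_id[k] = next_res_id
            arr.res_name[k] = "CU"
            arr.atom_name[k] = "CU"
            arr.element[k] = "CU"
            arr.hetero[k] = True
            ids.append(next_res_id)
            next_res_id += 1
            k += 1
        site_spec[site] = {"res_id": ids}
    if not planted_distances:
        site_spec["site"] = {"element": "CU"}

    pdb = PDBFile()
    pdb.set_structure(arr)
    out = io.StringIO()
    pdb.write(out)
    return ToyStructure(pdb_text=out.getvalue(), site_spec=site_spec)


def write_ground_truth(truth: GroundTruth, path) -> None:
    with open(path, "w") as fh:
        fh.write("kind\tvalue\n")
        for mut in truth.planted_mutations:
            fh.write(f"planted_mutation\t{mut}\n")
        for mut in truth.decoy_mutations:
            fh.write(f"decoy_mutation\t{mut}\n")
        for a, b in truth.covarying_pairs:
            fh.write(f"covarying_pair\t{a},{b}\n")
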