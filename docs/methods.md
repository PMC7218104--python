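# Methods

## Problem and approach

`consdesign` implements consensus design for protein stabilization: given
one or more curated multiple sequence alignments (MSAs) of homologs of a
query protein, it proposes single substitutions that move the query toward
the consensus of its family while avoiding positions whose variation is
coupled to other positions. The workflow was developed around fungal
high-redox-potential laccases (the PM1 laccase / OB-1 variant, with the
deposited structure 5ANH providing the catalytic copper geometry), but
nothing in the implementation is laccase-specific.

The pipeline is: curate each MSA → profile columns and compute relative
entropy (RE) → compute noise-corrected mutual information (MI) on a
reference MSA → call candidate mutations where the consensus differs from
the query → select candidates under RE/MI thresholds → tag agreement with an
ancestral sequence → optionally annotate structural context.

## Column conservation (RE)

For column `c` with amino-acid frequencies `p` (computed over non-gap,
non-`X` residues) and background `q`,

    RE(c) = Σ_a p(a) · ln( p(a) / q(a) )    [nats],

with `0·ln(0/q) = 0`. The default background is uniform (`q = 1/20`), under
which RE ranges from 0 (background-like column) to `ln 20 ≈ 3.0` (invariant
column); the RE cap of 2.4 nats used in selection then reads naturally as
"nearly invariant". Natural logarithms are used throughout — in bits the
same cap would sit at an unremarkable 55% of the ceiling, which is why we
consider nats the intended scale. An empirical alignment-wide background and
Laplace pseudocounts are available but off by default: RE here *ranks*
columns of a single alignment, and raw frequencies against a fixed uniform
background are the simplest reproducible choice.

Gap policy: gaps and `X` are excluded from the categorical distribution and
only contribute to a column's gap fraction. Columns with more than 50%
gap/`X` occupancy (configurable `max_gap_fraction`) are excluded from mean-RE
computation, candidate calling and MI eligibility. Consensus ties are broken
alphabetically by one-letter code and flagged, preferring determinism over
silent arbitrariness.

## Covariation (MI with shuffle noise)

For columns `i, j`, raw MI is computed from the joint residue distribution
over the *jointly* non-gap rows, with marginals recomputed on those same
rows. Pairs with fewer than 20 jointly non-gap rows (configurable) are
ineligible rather than unreliable.

Finite samples inflate MI between independent columns (the bias grows with
alphabet size and shrinks with depth), so a noise floor is estimated by
independently permuting every column across sequences — preserving each
column's residue composition and gap count exactly while destroying
inter-column coupling — and averaging the raw MI of 20 such replicates
(configurable). The corrected score is `max(0, MI_raw − MI_noise)`:
subtraction is the minimal use of a noise estimate, and the clip keeps
scores interpretable against the selection threshold. The shuffle seed is a
required, logged parameter.

Each query position receives a single MI score: the **maximum** corrected MI
between its column and any other eligible column (mean aggregation is a
config option). The selection rule "MI ≤ 0.6" is read as "this position is
not strongly coupled to *any* other position", for which max is the
conservative aggregation. MI is computed on one designated reference MSA —
by default the deepest one, where the coupling estimate is most reliable —
rather than recomputed per MSA.

No average-product correction or Potts/DCA modelling is applied; the method
deliberately uses plain MI with an explicit shuffle null.

## Selection funnel

A position is a *potential* candidate when at least one MSA's consensus
differs from the query residue there. Flags, all of which must hold for
selection:

* `re_preselected` — RE strictly above the mean RE of eligible columns of
  the *same* MSA, in every MSA (each MSA has its own depth and conservation
  scale, so each gets its own mean);
* `in_all_msas` — every MSA calls the same non-query consensus residue
  (read strictly: disagreeing consensus residues disqualify even if all
  differ from the query);
* `re_cap_pass` — RE ≤ 2.4 nats in every MSA (inclusive);
* `mi_pass` — MI score ≤ 0.6 nats (inclusive).

Both boundaries are inclusive because the published candidate table contains
selected substitutions at exactly RE = 2.40. Raising either threshold can
only grow the selected set; the test suite checks this monotonicity along
with funnel monotonicity (selected ⊆ preselected ⊆ potential).

Ancestral tagging compares each selected candidate's consensus residue with
a user-supplied ancestral sequence given in query coordinates (no tree
machinery); positions outside ancestral coverage are left untagged and
excluded from overlap counts.

## Curation

Header keywords ("hypothetical", "predicted", "putative"; case-insensitive
substring), an ungapped-length window of 0.8–1.2 × the query's ungapped
length, and exact ungapped-string duplicates (first occurrence kept, query
never removed), applied in that order with each removal counted once. The
20% length window is a conventional homolog-curation default — the published
workflow states only "too short or too large" — and both it and the
duplicate criterion (ungapped, header-blind) are explicit knobs.

## Structure annotation

Distances are minimum heavy-atom distances from any atom of the residue to
any atom of a named site; the convention is declared rather than inferred
(published tables rarely state theirs, and plausible conventions differ by
a few tenths of an Å). For multicopper oxidases the T1 copper and the
trinuclear T2/T3 cluster are resolved automatically from the copper–copper
distance pattern. Burial is classed from relative solvent accessibility:
Shrake–Rupley SASA (probe 1.4 Å, ≥ 100 sphere points per atom, 1000 by
default, via biotite) divided by the residue type's theoretical maximum ASA
(Tien et al. 2013), with < 10% buried, 10–30% partially buried, > 30%
surface. Domain and secondary-structure labels are user-supplied
annotations, not computed (no DSSP).

## Synthetic data

The generator emulates curated homolog alignments at the level the
statistics consume — per-column residue distributions — not at the level of
evolution:

* ordinary columns: a random majority residue at probability 0.5 with the
  remainder uniform over 8 random minority residues (real columns show a
  handful of residues, not all 20); the query carries the majority residue;
* planted consensus positions: consensus residue at frequency 0.7 in
  non-query rows, remainder spread over the query residue plus 4 others;
  the query carries a different residue, making these the true positives
  (expected RE ≈ 1.9 nats versus a column mean near 1.3);
* covarying pairs: two two-state columns drawn from a shared latent symbol
  with probability `coupling` (weights 0.6/0.4, so consensus calls are
  untied; at coupling 1 the true MI is ≈ 0.67 nats); decoy pairs
  additionally make one member query-divergent, planting candidates that
  pass every filter except MI;
* gaps at rate 0.02, never in the query row.

Columns are independent across sequences: there is no phylogenetic tree, so
tree-induced correlations — exactly the noise component that column
shuffling *cannot* model — are absent by construction. Passing tests
therefore demonstrate correctness of the statistics and the funnel under
columnwise-independent sampling, not robustness to phylogenetic
autocorrelation or alignment error in real homolog sets. Toy structures
place single-atom residues far apart and plant named-site atoms at exact
distances, validating geometry code without real coordinates.

## Problem sizes and tolerances

Closed-form RE/MI identities are asserted to 1e-9 (1e-12 against brute-force
oracles). The null-MI suite uses 50 alignments of 500 rows × 25 columns
(pooled corrected-MI 99th percentile < 0.05 nats); the planted-pair suite
uses the same sizes. The end-to-end suite uses 25 alignment triples of
depths 100/700/150 — matching the depth profile of the motivating laccase
study — with 10 planted positions and 3 decoys in 60 columns, requiring
exact recovery (planted minus decoys) in ≥ 95% of runs. The acceptance
script reports the same quantities at 25/25/15 trials, sizes chosen to keep
a single-CPU run in tens of seconds while leaving percentile and rate
estimates stable across seeds.

## Known limitations

* No phylogenetic down-weighting (Henikoff weights) of redundant clades;
  shuffle noise does not correct shared-ancestry MI.
* The per-position MI score's aggregation (max over partners) and the
  noise treatment (subtraction) are declared design choices; published
  spreadsheet workflows in this area rarely document either.
* Structure annotation assumes structure residue numbering matches query
  numbering; no sequence-to-structure alignment is performed.
* The curation keyword list is header-based and English-specific.
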