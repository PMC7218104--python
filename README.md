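# consdesign

Consensus design of stabilizing protein mutations from multiple sequence
alignments.

Consensus design exploits a simple observation: at many positions of a
protein family alignment, the most frequent (consensus) residue is more
stabilizing than the residue a particular family member happens to carry.
`consdesign` turns curated alignments of homologs into a ranked, filtered
list of candidate consensus mutations for a query protein, the way this is
done in enzyme-stabilization campaigns (the motivating application is a
fungal high-redox-potential laccase engineered for expression in yeast):

1. **Curate** each alignment: drop sequences with non-informative annotation
   keywords, length outliers, and duplicates.
2. **Conservation.** For each column with residue frequencies *p* and
   background *q* (uniform by default), compute the relative entropy
   RE = Σₐ p(a) ln(p(a)/q(a)) in nats (0 = background-like, ln 20 ≈ 3.0 =
   invariant) and call the consensus residue.
3. **Covariation.** For column pairs, compute mutual information
   MI = Σ p(a,b) ln(p(a,b)/(p(a)p(b))), subtract a noise floor estimated by
   shuffling columns across sequences (20 replicates), and score each
   position by its maximum corrected MI against any partner.
4. **Select.** Candidate positions are those where the consensus differs
   from the query. A candidate is selected when, in *every* alignment, its
   RE is above that alignment's mean but at most 2.4 nats (not nearly
   invariant), the same consensus residue is called, and its MI score is at
   most 0.6 nats (not coupled to another position — a substitution there
   might need compensation).
5. **Tag** selected mutations by agreement with an ancestral sequence, and
   optionally **annotate** each position on a structure: minimum heavy-atom
   distance to named sites (e.g. the T1 copper and trinuclear T2/T3 copper
   cluster of a laccase, resolved automatically) and burial class from
   Shrake–Rupley relative solvent accessibility.

A synthetic-data module generates alignments with planted ground truth
(conserved query-divergent positions, covarying pairs, MI decoys, gap noise)
so the whole funnel is testable without any downloads.

## Worked example

Simulate three alignments of depths 100/700/150 sharing one query, with 10
planted consensus mutations and 3 MI decoys, then run the funnel:

```python
from consdesign import design_benchmark_spec, generate_msa_triple, write_alignment

spec = design_benchmark_spec(n_planted=10, n_decoys=3, n_columns=60, seed=7)
msas, truth = generate_msa_triple(spec, (100, 700, 150))
for i, aln in enumerate(msas):
    write_alignment(aln, f"msa{i + 1}.fa")
print("planted:", " ".join(sorted(truth.planted_mutations)))
print("decoys :", " ".join(sorted(truth.decoy_mutations)))
```

```
planted: A12D A1D E3V K53F M16K M43Y N30H S49Y V50T W39L
decoys : A51W E56Y I44L
```

```bash
consdesign design --msa msa1.fa --msa msa2.fa --msa msa3.fa \
    --query query --seed 11 --out report.tsv
```

```
funnel: 13 potential -> 13 preselected -> 10 selected; consensus/ancestral 0/0
```

All 13 query-divergent positions are conserved enough to pass RE
preselection in all three alignments, but the three decoys covary with a
partner column (corrected MI > 0.6 nats) and are rejected by the MI filter;
the 10 selected mutations are exactly the planted ones. `report.tsv` holds
one row per candidate with per-alignment RE, MI score, every filter flag and
the ancestral tag; a first data row looks like

```
mutation  position  wild  consensus  mi      selected  re_msa1  re_msa2  re_msa3
A1D       1         A     D          0.0172  True      1.8992   1.9599   1.9432
```

i.e. substitute the query's Ala1 by the family consensus Asp, conserved at
≈ 1.9 nats in all three alignments and coupled to nothing.

The package also ships the published 20-mutation candidate table for the PM1
laccase (`consdesign.load_published_candidates()`) — RE, MI and the
consensus/ancestor residue pair per mutation — used by the test suite to pin
the selection predicate's boundary behaviour (RE = 2.40 rows are kept; 18 of
20 consensus residues match the ancestral ones).

Other subcommands: `curate`, `profile` (per-column RE table), `mi`
(corrected-MI pair table and per-position scores), `annotate` (site
distances and burial from a PDB file), `simulate`. Every run writes a
manifest (version, parameters, input digests, seed) next to its output.

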