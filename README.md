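# gapfill

Tools and an analysis pipeline for discovering, de-duplicating, validating
and characterizing **gap-closing sequences**: the DNA that de novo assemblies
place inside the N-gaps of a reference genome.

Reference assemblies such as GRCh38 still carry hundreds of runs of N marking
unresolved sequence. Given one or more long-read de novo assemblies aligned
to the reference, each gap can be interrogated: if two alignments of the same
contig flank a gap in consistent orientation, with both alignment edges
within 100 bp of the gap edges, the contig sequence between them is a
candidate gap-closing sequence; if a single alignment spans the gap, the
reference flanks are re-anchored onto the contig and the intervening contig
sequence is extracted. A zero-length fill — the donor's flanks are contiguous
— is evidence that the reference gap annotation itself is wrong (a
*discrepant* gap). Per-assembly fills are merged into a non-redundant call
set by CD-HIT-style greedy clustering (identity ≥ 0.9 over the shorter
sequence, length ratio ≥ 0.9); gaps with more than one surviving cluster are
*polymorphic*. The call set is then validated by short-read coverage
(breadth > 80% at ≥ 1× in at least one sample), tested for
population-specific presence (Fisher's exact test, p < 0.001), checked for
presence in other sequence sets (≥ 95% identity over ≥ 80% merged coverage),
and characterized by GC content and repeat-class composition.

The pipeline consumes standard formats — PAF alignments (minimap2 dialect;
a MUMmer `show-coords -T` converter is included), FASTA, SAM/BAM or per-base
depth TSVs, NCBI gap/modeled-region tables, UCSC cytoBand tables and
RepeatMasker `.out` files. Aligners and RepeatMasker themselves are never
invoked; a deterministic unique-k-mer anchor aligner is bundled so the whole
pipeline runs on synthetic data with no external downloads.

## Layout

- `src/gapfill/` — the library: `gap_catalog` (gap classification),
  `alignment_io` (PAF/coords I/O, best-chain selection, toy aligner),
  `gap_closure` (extraction rules), `clustering` (CD-HIT-style
  de-duplication), `coverage_validation`, `presence`, `characterization`,
  `synthetic_data` (seeded cohort generator with truth tables) and `study`
  (end-to-end orchestration).
- `analysis/` — numbered drivers reproducing the study on synthetic data:
  `01_simulate.py` … `06_characterize.py`, each writing tables under
  `results/`.
- `scripts/acceptance.py` — recomputes the headline quantities from scratch.
- A `gapfill` command-line tool wraps the library for shell use
  (`gapfill --help`).

## Worked example

```bash
python analysis/02_close_gaps.py --seed 1
```

prints

```
40 gaps: 26 euchromatic, 14 non-euchromatic
asm1: 30 closed, 1 discrepant, 9 open
...
total: 144 gap-closing sequences at 32 gaps (truth expects 32); 144/144 match the planted alleles exactly
```

i.e. on the seeded cohort (40 planted gaps, 5 donor assemblies) the
classifier splits the gaps into 26 euchromatic and 14 non-euchromatic, each
donor closes 27–30 gaps, one gap is consistently flagged as a reference
discrepancy, and every extracted sequence is bit-identical to the planted
allele. Continuing with `03_cluster.py` collapses the 144 fills into 42
non-redundant sequences at 32 gaps (31.2% of closed gaps polymorphic);
`04_validate_coverage.py` validates 42/42 sequences by simulated sample reads
and flags the planted population-private alleles (Fisher p < 0.001);
`05_presence.py` finds 34 sequences (12.3 kb) absent from both the reference
and the ALT set — the novel non-reference sequence of the cohort.

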