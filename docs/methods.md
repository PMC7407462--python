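# Methods

## Coordinates and formats

All internal coordinates are 0-based half-open (BED convention). Parsers for
1-based dialects convert at the boundary: the NCBI gaps table and
modeled-regions TSV (1-based inclusive), MUMmer `show-coords -T` output and
RepeatMasker `.out` rows. PAF and UCSC cytoBand tables are consumed as-is.
Written outputs convert back where the dialect requires it.

## Gap classification

A gap is euchromatic iff (a) its type is `within_scaffold` or
`between_scaffolds`; (b) it does not overlap a modeled region; (c) it lies at
least `flank_bp` (default 5 000 bp) from every modeled region and from every
gap typed telomere / heterochromatin / short_arm, with overlap counting as
distance 0; and (d) it does not overlap a cytoband stained `acen`, `gvar` or
`stalk`. The prose rule "adjacent … and positioned within the 5 kb flanking
sequences" is grammatically ambiguous about whether the 5 kb buffer applies
to modeled regions, to the special gap types, or to both; this implementation
applies it to both (the conservative reading) and exposes each buffer as a
flag (`flank_applies_to_modeled`, `flank_applies_to_special`). Distances are
measured between closest interval edges. The median gap length uses the
average-of-two-middles convention for even counts. Chromosome names present
in one annotation input but not another produce a warning, not an error.

## Alignments and chain selection

The pipeline consumes alignments; it never invokes minimap2, MUMmer or
QUAST. Best-chain selection emulates mask-level filtering with a documented
greedy rule: candidates are visited by descending match count (ties broken by
query name and start for determinism); a candidate is rejected when
previously accepted alignments of the same query cover more than
`mask_level` (default 0.9) of its query interval, or when any single accepted
alignment overlaps it by more than `mask_level` of the smaller of the two
query intervals. Equivalence with any external tool's internal chain
filtering is explicitly out of scope; the PAF records are the contract.

The bundled anchor aligner indexes k-mers (default k = 31) that occur exactly
once in each sequence, pairs unique k-mers shared between query and target,
merges collinear anchors on one diagonal separated by at most 100
anchor-free bases, and extends each merged run outwards by exact matching
into a single gapless block per record, on both strands. N never matches
anything, so blocks stop exactly at gap edges — which is what makes
bit-exact fill extraction possible on clean data. The 100 bp merge limit also
means an anchor-free stretch longer than 100 bp (an unfilled N-run, a novel
insertion) splits the chain; consequently a donor that fills a gap always
presents as two flanking blocks rather than one spanning alignment, and the
spanning extraction rule is reached only with alignments from sloppier
aligners (it is exercised in the tests with constructed spanning records).

## Fill extraction

Per gap, the flank-pair rule is tried first, then the spanning rule; at most
one fill is emitted per (gap, assembly).

Flank pair: among best-chain alignments, a left candidate ends within
100 bp before the gap start (strictly `< 100`; configurable, and up to 10 bp
of overhang into the gap is tolerated for aligners that clip inconsistently
at N boundaries — the fill boundary is then moved back by the overhang so
clean data stays exact) and a right candidate starts within 100 bp after the
gap end; both must be on the same contig, same strand, in
orientation-consistent contig order. Within a contig the pair minimizing
total edge distance wins; across contigs the pair with the largest combined
flank alignment length wins and the alternatives are recorded in the report
note. For strand +, the fill is `contig[L.query_end : R.query_start]`; for
strand − it is the reverse complement of
`contig[R.query_end : L.query_start]`; fills are always reported in
reference orientation. A negative interval is reported as a zero-length fill
with the overlap magnitude recorded.

Spanning: the N-free portions of the reference flanks (default 5 kb,
truncated at chromosome ends with a warning) are anchored onto the contig
with the toy aligner; each flank must produce exactly one alignment covering
at least 90% of the flank with its gap-adjacent edge fully aligned, else the
gap stays unresolved. The contig interval strictly between the anchors is
the fill.

Status per (gap, assembly): `closed` for a positive-length fill (fills
containing N are kept but flagged), `discrepant` for a zero-length fill or
overlapping flanks, `open` otherwise. A fill consisting entirely of N —
the donor still carries the gap as Ns — is reported `open`, not `closed`:
it is not evidence of resolved sequence. Candidate pairs with opposite
strands (a putative inverted fill) are not extracted but are noted in the
report rather than silently dropped.

## Clustering and identity

CD-HIT is emulated, not invoked: fills per gap number at most the number of
assemblies, so its word-filter heuristics are unnecessary and exact global
alignment is used instead, preserving the documented semantics —
longest-first greedy clustering, first-fit assignment in cluster-creation
order, identity defined as matching columns over the shorter sequence length
(`-c 0.9`), and the length-difference cutoff as shorter/longer length ratio
(`-s 0.9`).

Identity comes from a global affine-gap alignment (match +1, mismatch 0, gap
open −1, gap extend −0.5, end gaps penalized). Because many alignments can
share the optimal score while differing in matching columns, the reported
identity is made canonical: the dynamic program maximizes (score, matching
columns, aligned columns) lexicographically, via int64 packing of the three
additive quantities, so the value is deterministic and
implementation-independent. Sequence pairs are compared as given; a
reverse-complement retry exists as an opt-in safety net (fills are already
reference-oriented).

Cross-assembly sharing labels a fill *shared* when some fill at the same gap
from another assembly matches it at ≥ 90% identity over ≥ 90% of the shorter
length, where coverage is the fraction of the shorter sequence in aligned
columns and identity is matches over aligned columns.

## Coverage validation

Fills are emitted with up to 99 bp of N-free reference flank on each side
(one read length minus one, so a read overlapping a terminal fill base can
still map); realized pad lengths are recorded and padding bases are excluded
from every summary. Depth at a base counts primary alignments whose
reference span (including deletions, excluding soft clips) covers it; input
is SAM/BAM or a (sequence_id, pos, depth) TSV. Breadth of coverage is the
fraction of fill bases at or above a depth threshold (default 1×); a
sequence is validated iff some sample's breadth strictly exceeds 0.8
("more than 80%" read as strict).

Combined per-gap depth is `sum_i(depth_i × len_i) / max_i(len_i)` over the
gap's alleles — total aligned fill bases normalized by the longest allele.
The literal phrasing "sum of coverage depth divided by the maximum length"
is dimensionally odd (a depth divided by a length); it is available behind
`literal=True` for comparison. Depth ratios divide by each sample's
genome-wide depth; samples without a known genome depth are skipped with a
warning.

Population specificity: per sequence and per population, a one-vs-rest 2×2
table (validated × in-population) is tested with a two-sided Fisher's exact
test; p-values are Bonferroni-corrected across populations and the minimum
is reported; sequences below p = 0.001 are flagged. The chromosome-Y sex
signal is reproduced only as a breadth summary stratified by the metadata
sex field; no sex inference is performed.

## Presence

For one fill against one dataset, query intervals of all alignments are
merged; covered fraction is the union length over the fill length and
identity is Σ matches / Σ block length over the contributing alignments
(block-length weighting is this package's choice for multi-hit aggregation;
a strictest-single-hit mode is available). Presence requires identity
≥ 0.95 and coverage ≥ 0.80, both inclusive. Self-hits of a fill onto its own
source locus can be excluded by coordinate overlap. Novel non-reference
sequence is whatever is absent from both the primary reference and the ALT
dataset.

## Characterization

GC content excludes N (and any ambiguity code) from the denominator.
Reference comparison windows are drawn uniformly over the genome
(chromosomes weighted by length), N-free, with lengths resampled with
replacement from the fills' empirical length distribution, seeded. The
per-class comparison uses the two-sample KS test against the sampled
windows and a two-sided Wilcoxon rank-sum between euchromatic and
non-euchromatic fills. Repeat composition is parsed from RepeatMasker
`.out` files (class = class/family prefix before "/", unknown classes
mapped to Other); overlapping intervals of one class are merged before
fractions are computed. Enrichment per class is a two-sided Wilcoxon
rank-sum on per-sequence fractions. Repeat-masked GC removes masked bases
from numerator and denominator; fully masked sequences are dropped and
counted.

## Synthetic cohort

The generator builds, from one integer seed (NumPy PCG64; fixed iteration
order, byte-identical output per seed), a reference of 2 chromosomes
(~200 kb each) carrying 40 N-gaps of the five annotated types, annotation
fixtures (a modeled region and an acen band per chromosome, gvar/stalk bands
over the special-gap neighborhoods), 5 donor assemblies, 30 samples in three
populations, presence datasets and a truth table. Study-condition defaults:
fill lengths log-normal with median 300 bp capped at 20 kb (the scale of
closed gaps in real cohorts), a 0.33 polymorphic fraction, ~0.11 discrepant
fraction, 0.12 left unfilled, error-free 100 bp reads at 4× depth. Four
within-scaffold gaps are deliberately confounded — inside a modeled region,
3 kb from one, inside an acen band, 3 kb from a heterochromatin gap — so the
classifier's four exclusion rules each have a planted positive; the
remaining within/between gaps are placed with ≥ 7 kb clearance.

Donors are the reference with each gap's N-run replaced by the assigned
allele (nothing for discrepant gaps; the N-run kept, and the donor split
there, for unfilled gaps — as a real assembly would break). Contigs arise
from Poisson background breakpoints (rate 1/80 kb) that avoid ±400 bp around
fills meant to be recoverable; about 10% of (assembly, gap) fills are
deliberately broken mid-fill, under the constraint that every allele keeps
at least one intact carrier. Gap flanks are random background sequence and
therefore k-mer-unique genome-wide with overwhelming probability; a hard
mode reuses one shared flank across gaps to exercise ambiguous anchoring.

Fill content mixes AT-biased satellite arrays (171 bp monomer, 5% per-copy
divergence), mutated simple-repeat arrays (unit 2–6 bp) and uniform-random
sequence; tandem fills always receive two extra point substitutions so they
contain unique anchor k-mers. Minor alleles of polymorphic gaps are drawn
non-repetitive and at ≤ 0.7× the major allele's length: two independent
AT-biased repeat arrays can exceed 90% mutual identity under the
match-maximizing alignment, which would make planted sharing/clustering
truth ill-defined, whereas random-content minor alleles are provably below
both thresholds. Population-private minor alleles (about a quarter of
polymorphic gaps) are carried by every sample of one population and no
others, giving the Fisher test planted positives.

Reads are drawn uniformly (Poisson count at the target depth); in embedded
mode read starts may hang off the sequence ends and are clipped, making
expected depth uniform across the padded fill including its edges. Error
rate defaults to 0 and quality strings are constant; no realistic error
model is attempted.

What passing on this cohort does and does not show: it verifies the
machinery — coordinate arithmetic and bit-exact extraction on both strands,
rule interactions, threshold conventions, statistical behaviour under
planted effects and permutation nulls — under clean alignments with unique
flanks and error-free reads. It does not measure robustness to alignment
noise, repeat-mediated mis-anchoring at real centromeres, assembly errors or
read-mapping ambiguity, which dominate real-data difficulty.

## Problem sizes and numerical choices

The study configuration (40 gaps, 5 donors, 30 samples, ~400 kb of
reference) keeps a full pipeline run around ten seconds while every code
path still has planted positives; the statistical acceptance checks use
dedicated simulations (200 clustering instances, 1 000 Fisher permutations,
20 fills at 5 kb for depth recovery). Chain-selection and flank-pair ties
are broken by fixed lexicographic keys; all stochastic steps flow from
explicit seeds. Comparisons at thresholds follow the stated conventions:
strict `<` for the 100 bp edge distance and the 0.8 breadth cutoff,
inclusive `≥` for clustering identity/length-ratio and presence
identity/coverage.

## Known limitations

- The toy aligner requires unique exact k-mer anchors; highly diverged or
  internally exact-repetitive sequence may anchor sparsely or not at all.
  Production use should supply PAF from a real aligner.
- Pairwise identity is computed exactly (no banding); comparing two ~20 kb
  alleles costs a few seconds. Fill counts per gap are small, so this is not
  limiting at the intended scale.
- Inverted-orientation fills are detected and noted but not extracted.
- The Fisher permutation null is conservative (discrete tables), so the
  empirical false-positive rate sits below the nominal level.
- Local re-assembly of reads across gaps, ORF/CpG/gene annotation and
  liftover between reference versions are out of scope.
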