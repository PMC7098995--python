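# Methods

This note documents the models, algorithms and parameter choices behind
`puerabar`, and what the synthetic study fixtures do and do not emulate.

## Coordinate frame and diagnostic sites

All site positions are 1-based columns of the pairwise global alignment of
the two group consensus ITS2 sequences. This is the only frame a 246-bp
(*lobata*) and a 247-bp (*thomsonii*) sequence share; the alignment is 247
columns long because the single indel pads the shorter sequence. The indel
polarity — *thomsonii* carries the T at column 29, *lobata* the gap — is
implied by the 247 vs 246 bp lengths and adopted as an assumption.

`detect_variable_sites` lists every column at which the two group
consensuses differ (kind `indel` when one side is a gap, else `snp`) and
flags columns that also vary within a group. Consensus is strict per-column
majority with ties resolved to the covering IUPAC code; the two bundled
*lobata* haplotypes tie T/G at column 244, so the *lobata* consensus state
there is `K`, and agreement at diagnostic sites is evaluated by IUPAC
base-set intersection throughout.

## Subspecies calling

A query is aligned to both group consensuses. The better identity gates the
call: below 0.90 the query is not *Pueraria* at all; between 0.90 and 0.99
it is reported `ambiguous` (genus level only — the varieties exceed 0.99
mutual identity on the full amplicon while outgroups fall below it); at or
above 0.99 the observed query state at each diagnostic site votes for group
A or B with the site's reliability weight. Sites polymorphic within a group
get weight 0.25 (column 244: a *lobata* 244-G haplotype matches the
*thomsonii* state there, so a full-weight site would misclassify it); fixed
sites get weight 1.0. The call is the better-supported group; a tied vote,
or full-weight sites agreeing exclusively with *both* groups, yields
`ambiguous`.

## Alignment

Global affine-gap alignment (match +1, mismatch −1, gap open −2 for the
first gap base, extend −0.5) is delegated to Biopython's `PairwiseAligner`
with a substitution matrix over the full IUPAC alphabet: two states score
as a match when their base sets intersect, so ambiguity codes from
heterozygous trace calls align cleanly. Among co-optimal alignments the
first traceback is taken, which is deterministic for fixed inputs; in the
barcoding regime (near-identical sequences) the optimum is unique, so the
choice is immaterial.

## Distances, gap and trees

K2P distances use pairwise deletion: for each pair, columns with a gap or
ambiguity in either row are excluded, and d = −½ ln(1−2P−Q) − ¼ ln(1−2Q)
over the remaining comparable columns. Saturation (a non-positive log
argument) and empty comparable sets are errors, never silently clamped.
Distances are computed on the full aligned amplicon (ITS2 plus retained
rRNA flanks, 477 comparable sites in the fixtures) rather than trimmed
ITS2: a single transversion then gives 0.0021, the scale on which the
within-*lobata* maximum is reported. Barcoding-gap statistics cover only
the focal barcode groups; groups labelled `outgroup` or `contaminant` are
excluded by default, and singleton groups report their within-group maximum
as absent rather than zero.

Neighbor joining follows Saitou–Nei: repeatedly join the pair minimizing
Q(i,j) = (n−2)d(i,j) − r_i − r_j, with ties broken by the lexicographically
smallest pair of subtree labels (the smallest contained leaf), then solve
the final three-branch star in closed form. Negative branch lengths are
clamped to zero with the deficit moved to the sister branch so the joined
pair's path length is preserved. Bootstrap support resamples alignment
columns with replacement (a Philox counter-based generator, so replicate
column sets are a pure function of the seed), rebuilds the tree per
replicate, and annotates each internal bipartition of the point tree with
the integer percentage of replicates containing it; bipartitions absent
from the point tree are not reported.

## Sanger model and A/B/C triage

A chromatogram is a per-position table of four channel intensities;
electropherogram physics (mobility, spacing) is out of scope. Base calling
takes the strongest channel as primary and emits the two-base IUPAC code
whenever the second channel reaches `ambiguity_threshold` (default 0.25)
of the primary. Bidirectional assembly reverse-complements the reverse
call, aligns it to the forward call (overlap identity ≥ 0.8 required), and
merges columns by IUPAC set intersection (empty intersection → N; a gap in
one read defers to the other).

Triage thresholds: type A when the heterozygous fraction of called
positions is ≤ 0.5%; type B when it is ≤ 5% *and* the nested score — the
het fraction restricted to positions downstream of the known indel column —
is < 0.3; type C otherwise. The mechanistic reading: co-linear template
mixtures (substitutions only) produce isolated het peaks at the differing
sites (B), while templates of unequal length phase-shift every downstream
peak of the minor component, nesting most of the trace (C). A minor
component below ~25% of the major peak never crosses the default ambiguity
threshold, which is why modest contamination still yields clean type-A
traces — and why the generator's type-B herbal samples are 70:30 mixtures
of *lobata* with an equal-length (indel-free) *thomsonii*-like variant,
while the type-C sample is a 50:50 *lobata*:*thomsonii* mixture whose indel
nests everything downstream of column 29.

## Metabarcoding pipeline

Boundary semantics are read literally from the exclusion rules: keep reads
with length ≥ 300 and arithmetic-mean Phred ≥ 30; retain unique sequences
with count ≥ 11 ("more than 10 repetitions"), per sample. Tag matching is
exact by default (`max_mismatch 0`, configurable to 1); ambiguous or
unmatched reads go to an unassigned bin, and the partition provably
conserves reads.

ITS2 trimming uses two position-weight-matrix anchors — the last 20 bases
of the 5.8S flank and the first 20 of the 28S flank — trained from the
annotated full-amplicon references at run time (pseudocount 0.1, log-odds
against a uniform background). A window counts as an anchor at ≥ 0.6 of
the matrix's maximum score, which tolerates two point errors per anchor
while remaining unreachable by random sequence (whose expected score is
deeply negative); both strands are scanned and the best-scoring
non-overlapping pair wins, with output canonicalized to the reference
strand. Anchors-from-references replaces a full profile HMM: on reads that
actually contain the flanks the observable behaviour (exact trimming) is
identical, and the algorithm is fully specified and dependency-free.

Assignment is best-identity search of the whole reference database;
*Pueraria* hits are resolved to subspecies with the diagnostic-site caller,
other taxa are reported when identity ≥ 0.90, else `unassigned`. The
authentication report calls the dominant *Pueraria* variety per sample and
lists every other taxon at ≥ 1% of retained reads as a contaminant
(configurable; the threshold is a reporting choice, not a statistical one).

## Synthetic data: what it emulates, what it does not

The generator is a pure function of an integer seed (Philox) and emits
byte-identical files on re-runs, always alongside ground-truth records so
tests never re-derive truth from the pipeline under test.

Reference backbones are random sequences at ~55% GC — the package ships no
third-party sequence data — with the diagnostic indel and SNP states, the
insertion neighbourhood (pinned non-T so the indel column is unique), the
second *lobata* haplotype (244-G), conserved rRNA flanks (lobata amplicon
exactly 477 bases, so the single-transversion K2P equals the reported
within-group maximum under the full-amplicon convention), outgroups at ~5%
ITS2 divergence and contaminants at >15%. Outgroups and contaminants carry
third-party states at the diagnostic columns, as genuinely external taxa
would; with lobata-like states there they would sit inside the *lobata*
radiation and make the variety clades unresolvable. All divergence is
substitution-only with a single shared flank pair, which keeps the true
multiple alignment trivial (one indel column); real contaminant ITS2
differs in length and flank sequence, so the bundled alignment path is a
best case.

Reads are full amplicons with independent per-base substitution errors
(default 0.002/base), a two-state quality model (good ≈ Q35 σ3, bad ≈ Q12
σ2; 10% of reads bad, so they fail the QV filter essentially exactly), and
the 10-bp sample tag prepended. Ion-Torrent-style homopolymer indels, PCR
chimeras, primer sequences and strand mixtures are not simulated; passing
tests therefore demonstrate the pipeline's logic, not robustness to every
real-platform artefact. Panel truth follows the published study design: 30
raw materials (21 labelled Gegen, 2 of them truly Fenge; 9 labelled and
true Fenge), 10 foods (5 per variety), 12 herbal products (9 pure / 2
co-linear mixtures / 1 indel mixture), with metabarcoded reads for one
sample of each trace type (fungal contamination in all three, barley in
the type-C analog, rose in one type-B analog).

## Numerical and degenerate-input choices

* Distance errors (saturation, no comparable columns) name the offending
  pair and abort rather than returning infinities.
* NJ tie-breaks, dereplication ordering (descending count, then sequence)
  and report row order are all deterministic, so identical inputs give
  byte-identical outputs.
* −0.0 branch lengths are normalized to +0.0 before serialization.
* Identical-sequence alignments: the bootstrap runs on the degenerate star;
  supports stay within [0, 100] and unsupported bipartitions are simply not
  reported.
* Type-C traces yield no reliable barcode; the Sanger panel records such
  samples (and any per-sample error) as `failed` instead of aborting.

## Known limitations

* The published minimum between-variety distance (0.0098) is a property of
  the real deposited sequences; the synthetic fixtures give 0.0042 (two
  transitions over 477 sites between the nearest haplotypes), so only the
  existence of the barcoding gap — not that particular value — is
  reproduced here.
* The A/B/C thresholds are calibrated to the trace generator; real
  chromatograms with baseline drift or dye blobs may need different
  `ambiguity_threshold` and fraction cut-offs.
* Per-sample dereplication assumes tags identify samples uniquely; global
  (cross-sample) abundance filtering is not implemented.
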