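# Methods

## Evidence model

The pipeline consumes fragment-level chimeric evidence rather than raw
alignments.  Each record links two genomic loci and is either a chimeric
read **pair** (two sequencing ends on different genes) or a **split** read
(one read spanning the junction, with the junction bases and per-side
overhang lengths recorded).  The TSV dialect fixes fifteen columns
(`sample_id read_id kind chromA posA strandA spanA chromB posB strandB
spanB donor_pos acceptor_pos overhangA overhangB`, positions 1-based);
locus A is the upstream side of the fragment as sequenced, and a fragment
representing the antisense of the fusion transcript simply carries both
aligned strands flipped.  This keeps the caller independent of any
particular aligner while preserving exactly the two evidence classes the
method needs.

Coordinates are 0-based half-open internally; every file format keeps its
native convention (GTF 1-based inclusive, BEDPE 0-based half-open, evidence
and candidate TSVs 1-based).

## Detection

Each locus is assigned to the gene whose exon union (merged across
transcripts) overlaps the aligned span by the most nucleotides; exact ties
are discarded and counted, so one fragment can never be credited to two
genes.  Orientation follows strand concordance: the ordering in which each
locus's aligned strand reads its gene in transcription direction is the
5′→3′ call; mixed configurations are rejected and counted.  Under the
fragment-layout convention above the two orderings are mutually exclusive,
so the ambiguity branch ("both orderings consistent") is a defensive check
rather than a reachable state.

A `read_id` contributes at most once per ordered gene pair; if the same
fragment appears both as a split and a pair record, the split
representation wins (and is then still subject to the overhang rule).  A
split read counts toward split support only when both overhangs are at
least `min_overhang` (default 15 nt, matching the chimeric-segment minimum
a spliced aligner would use); an inadmissible split contributes nothing.

Support tiers (defaults): retain a pair iff

- `n_split >= 2` and `n_chimeric >= 5`, or
- `n_split == 1` and `n_chimeric >= 10`, or
- `n_split == 0` and `n_chimeric >= 20`.

The breakpoint is the modal split junction; ties are broken by the largest
total overhang, then by the smallest genomic coordinate, making the call
deterministic.

Partner homology (the criterion behind "fusions between homologous genes
are discarded") is operationalized as k-mer sharing: two genes are
homologous when the fraction of one gene's distinct 24-mers present in the
other (maximum over both directions) reaches 5 %, or when the unordered
symbol pair appears in a user paralog table.  Both parameters sit in
`FilterConfig`.  "Overlapping homologous genes" additionally requires any
genomic span intersection.  There is deliberately **no** genomic-distance
or read-through filter: genuinely proximal fusions (tandem-duplication
events between neighbouring genes) must survive detection.

## Cohort filters

`flag_improbable` uses strict inequalities: a pair present in more than
95 % of a cohort's samples is flagged, as is a pair in which *each*
partner participates in at least two distinct pairs cohort-wide and is
itself fused in more than 25 % of samples.  The promiscuity clause counts
distinct partner pairs across the cohort and sample prevalence separately,
resolving the ambiguity of "involved in >1 fusions" in favour of the
interpretation that is symmetric in samples and pairs.  Multiple
breakpoints of the same pair within one sample count once.

The panel of normals is built by running the *identical* detection
procedure (same `FilterConfig`) on each normal sample's evidence; a pair
detected in ≥5 normal samples is removed from every tumour cohort.
Normals removal and improbable-frequency flagging are applied
flag-then-remove in the pipeline; they commute whenever the removed pairs
do not alter another pair's promiscuity counts.

Recurrence pools distinct tumour samples across **all** cohorts and keeps
kinase fusions reaching `recurrence_min = 2`.  The default mode counts per
kinase across all of its partners (so a kinase fused once each to two
different partners is recurrent); `mode="pair"` counts per ordered gene
pair.  Flagged candidates are excluded from both counting and output but
are retained, with flags, in the per-sample reports for review.

## Functional annotation

The canonical transcript of a gene is the one with the longest CDS (ties:
longest exonic length, then lexicographic transcript id) — one predicted
protein per fusion without requiring a transcript-selection input.

*Junction class*: `exon_exon` when both breakpoints coincide with annotated
exon boundaries in transcription orientation, `exon_cryptic` when exactly
one does, `unresolved` otherwise or without split support.  No splice-motif
check is imposed (a cryptic junction is simply any split junction off the
annotated boundaries), but the junction dinucleotides are reported for the
reviewer.

*Fusion transcript*: exonic sequence of the 5′ canonical transcript through
the donor base, concatenated with the 3′ transcript from the acceptor base,
in transcription orientation (minus-strand pieces reverse-complemented).  A
breakpoint that is not exonic in the canonical transcript aborts annotation
for that candidate with a note, and the junction reverts to `unresolved`.

*Frame*: `promoter_fusion` when the 5′ partner contributes only
untranslated sequence and the complete downstream CDS is retained (the
promoter-swap pattern); `in_frame` when the retained 5′ coding length joins
the 3′ CDS in its annotated codon phase with no intervening stop codon
(verified by translating the constructed sequence); `no_cds` when neither
side contributes coding sequence; `out_of_frame` otherwise.  A promoter
fusion is treated as satisfying the in-frame requirement for driver calls
because the full wild-type protein is produced; the distinct label keeps
the distinction visible to the user.  When a junction is unresolved the
frame and domain fields are reported as null rather than forced into a
category.

*Kinase domain*: the registry supplies the catalytic-domain interval in
1-based amino-acid coordinates of the canonical protein (domain discovery
itself, e.g. by profile HMM search, is upstream of this package).  Only
fully retained codons count; the status is `complete`, `truncated` or
`absent` and is monotone in the breakpoint position.  Only the catalytic
domain is tested — loss of N-terminal regulatory domains of Ser/Thr
kinases is biologically interesting but is not part of the driver rule.

*Coiled-coil scan*: windows of 28 residues are scored at each of the seven
heptad registers; the window score is the geometric mean of per-position
propensities at the best register, each residue takes the maximum over
covering windows, and the score becomes a probability through the ratio of
two Gaussians (coiled-coil mean 1.63, sd 0.24; globular mean 0.77, sd
0.20) with a 30:1 globular:coiled-coil prior.  The propensity table
shipped in `kinefuse/data/coils_mtk.tsv` encodes the classic
myosin/tropomyosin/keratin-derived residue preferences of two-stranded
coiled coils; zero observed frequencies are floored at 0.01 so every
propensity is positive, and alternative tables are loadable.  Motif
intervals are maximal runs with probability ≥0.5.  Other dimerization
motifs (LisH, zinc fingers, …) come from a user-extensible interval table
and are reported when fully contained in the partner-contributed region.

*Artifacts and verdict*: `homologous_repeat` when the partners are
homologous; `trans_splice_suspect` when a partner's within-cohort
expression z-score (unbiased n−1 standard deviation, cohorts of ≥3
samples) reaches 3.0 **and** the call has no split support **and** the
junction is unresolved — the joint signature of reverse-transcriptase
template switching.  Promoter-fusion overexpression is reported as the 3′
gene's expression rank within its cohort, as corroborating evidence rather
than a gate.  The verdict is `artifact` when any artifact flag is set;
`candidate_driver` when the fusion is recurrent with a resolvable
junction, an in-frame or promoter-fusion coding sequence and a complete
kinase domain; otherwise `passenger`.

## Synthetic cohort

The generator emulates the statistical structure the filters assume, not
sequencing reads: evidence is produced at the record level with synthetic
read ids.  Genes have 2–6 exons on mixed strands with exon 1 entirely
5′ UTR, the CDS starting at the first base of exon 2 and internal coding
exons whose lengths are multiples of three — so exon-boundary junctions
are in frame by construction, frame intent is enforced by shifting the
donor off the boundary (out-of-frame, cryptic) or by choosing a deeper
acceptor exon (domain truncation), and the expected annotation of every
planted fusion is part of the ground truth.

The reference scenario (defaults of `default_scenario`) is a single
20-tumour cohort with 10 normals and 34 genes: six drivers (four in-frame,
two promoter fusions, spanning all three support tiers and 2–4 carriers
each), two out-of-frame and two domain-truncating passengers, two fusions
planted in exactly five normals, one trans-splicing artifact (22 chimeric
pairs, no split reads, 1000× partner overexpression in its first carrier)
and one homologous decoy pair built by copying a gene's sequence with 1 %
point mutations.  Background chimeras follow a per-gene-pair Poisson rate
(0.002) capped below all support tiers.  Expression values are log-normal
FPKM-like numbers.  With two carriers of equal outlier expression in a
20-sample cohort the z-score cannot exceed ~2.9, so only the inflated
carrier of the trans-splicing pair is flagged as an artifact; the second
carrier is rejected as a passenger through its unresolved junction — both
routes keep it out of the driver set.

What the generator does **not** emulate: mapping ambiguity and mappability
structure, coverage-dependent support, fragment-length distributions,
multi-transcript genes, and sequence-context artifact hotspots.  Passing
the end-to-end recovery test therefore demonstrates the correctness of the
filtering logic under its own assumptions, not performance on real
libraries.

## Determinism and problem sizes

All randomness flows through a single integer seed
(`numpy.random.default_rng`); outputs are written in sorted order with
fixed float formats and no timestamps, and the run manifest records a
SHA-256 checksum of every file, so identical seeds give byte-identical
results.  The shipped scenario sizes (20 tumours, 10 normals, 34 genes,
~400 evidence records per run) keep a full simulate-plus-pipeline cycle
under a few seconds while exercising every filter at its decision
boundary; the oracle-equivalence tests run brute-force enumerations on
instances up to 500 residues / 200 records.

## Known limitations

- Reciprocal fusions are called independently per ordered pair; no
  reciprocity evidence is combined.
- Frame prediction uses one canonical transcript per gene; isoform-specific
  frames are not explored.
- The homology criterion is sequence-identity based and will not catch
  diverged paralogs below the k-mer share threshold (the paralog table is
  the escape hatch).
- Expression-based artifact flagging needs cohorts of at least three
  samples and raw-scale values; cohorts with heavy-tailed expression may
  warrant a higher `trans_splice_z`.
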