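# Methods

## The analysis in brief

Reads that fail to align to a linear reference (or align with MAPQ < 20)
carry sequence the sampled individual possesses and the reference lacks.
The pipeline treats each donor's alignment file as the primary input,
recovers those reads, and follows assembled contigs through quality control,
cross-donor deduplication, reference placement, population-sharing analysis
and orthogonal validation. All intermediate contracts are standard formats
(SAM, FASTA/FASTQ, 12-column PAF, GFF3, BED, VCF, TSV); coordinates are
0-based half-open internally and converted at parse/write time.

## Read classification and extraction

Primary paired records are partitioned into five mutually exclusive classes:
well mapped, poorly mapped (mapped with MAPQ < 20 — the threshold is strict,
so MAPQ 20 is well mapped), unmapped pair, unmapped-with-mapped-mate and
mapped-with-unmapped-mate. Secondary and supplementary records are ignored:
the unit of extraction is the read, not the alignment. Strict extraction
emits unmapped pairs plus the unmapped halves of half-mapped pairs; loose
extraction additionally emits poorly mapped reads *and their mates*, keeping
pairs intact for assemblers. Every extracted read with a mapped mate yields
a mate anchor (chromosome, 0-based position, strand, MAPQ).

## Contig QC

Contigs under 1000 bp are discarded (999 removed, 1000 kept). The
contaminant screen consumes classifier output rather than running a
classifier: BLAST outfmt-6-style rows (qseqid sseqid pident length evalue
bitscore stitle) and two-column centrifuge-style labels, mapped to
human / non-human / unclassified through a user-supplied label→taxon table.
A contig is removed when any non-human hit qualifies; since the upstream
notion of a "high scoring match" is not quantified, the policy is explicit
and configurable — BLAST e-value ≤ 1e-5 with aligned length ≥ 100 bp, or any
centrifuge non-human label — and deliberately permissive toward removal:
human-labelled hits never rescue a contig that also has qualifying non-human
hits.

## Collapsing to super-contigs

From an all-vs-all alignment, a pair is a containment candidate when the
union of its alignment blocks, projected onto the **shorter** contig,
strictly exceeds 90 % of that contig's length. Reading "90 % of their own
length" as a condition on the absorbed (shorter) contig is a design choice:
the larger contig becomes the representative, so containment of the smaller
is the operative condition; both readings coincide when lengths differ
substantially. Multiple blocks between a pair are merged by interval union
first, so split alignments of a genuinely contained contig still collapse.

Absorption of the smaller into the larger, iterated until a full pass makes
no change, converges to the transitive closure of the candidate relation;
the implementation computes that closure directly (union-find), which makes
the fixed point trivially order-independent. Ties in length resolve to the
lexicographically smaller identifier. The occurrence of a super-contig is
the number of distinct donors among its members; occurrence ≥ 2 defines
"shared", and occurrence / cohort size is the frequency-spectrum coordinate.

## Placement

Direct placement keeps, per contig, the longest reference alignment with
block ≥ 500 bp (the boundary is accepted; where source descriptions
disagreed between "over 500 bp" and "at least 500 bp" the inclusive reading
was adopted). Additional qualifying loci are logged, not reported — one
location per contig. Mate placement groups a contig's anchors by
chromosome; the majority chromosome wins (ties leave the contig unplaced
with a conflict note), the placement point is the lower-median anchor
position (median rather than mean for robustness to stray anchors), and at
least `min_anchors` (default 2) anchors must lie within twice the placement
window (default 1 kb) of that median. The interval is
`[point − window, point + window + contig_length)` clamped at zero. When
both routes place a contig, agreement (same chromosome, midpoints within
100 kb) is reported as method `both` with the alignment interval; on
disagreement the alignment placement wins with a conflict flag, because
direct sequence evidence outranks indirect pairing evidence.

## Presence/absence LD

The binary grid has one row per donor and one column per shared super-contig
(shared-only by default, matching a grid whose width is the shared-contig
count; configurable). r² is the squared Pearson correlation of two binary
columns; columns constant across the cohort have undefined r² and are
excluded with an explicit count. The high-LD threshold r² > 0.9 is strict.
The "fraction of all pairs" denominator is the ordered-pair count M²: the
published pair total is consistent with M² (and M(M−1)) but not with
M(M−1)/2, so the ordered-pair convention is adopted and documented. Pair
distance is the distance between placement midpoints (not otherwise
defined upstream). A placed member of a high-LD pair anchors an unplaced
partner to the placed interval widened by 100 kb on each side.

## Annotation, GWAS and biobank peaks

GFF3 (1-based closed) converts to half-open intervals at parse time; overlap
requires at least one shared base. Distance from an interval to a point is
0 on containment, else the distance to the nearer of the first and last
base; all distance thresholds (0/100/1000 bp GWAS sweep, 1 Mb peak
proximity, 10 kb LD proximity) are inclusive. Peak calling keeps, per trait,
significant loci (neglog10p ≥ −log10 p-threshold, boundary included) in
descending significance order (ties: position ascending), retaining a locus
unless a previously retained peak for that trait lies on the same chromosome
within 50 kb — greedy by significance rather than left-to-right, since the
procedure selects "the highest scoring" locus of each cluster. Consequences:
no two retained peaks of a trait are within the merge window, and every
discarded significant locus is dominated by a retained peak within it.

## Validation

PAF identity is residue matches over block length (gap-compressed identity
is not used). A contig validates against a long-read assembly when its best
identity ≥ 0.9 and the union of its aligned query intervals covers ≥ 0.5 of
its length; these cutoffs are declared defaults, as the upstream
"high identity" is unquantified. Intersection validation rates divide
validated-contig intersections by evaluable intersections, with
no-long-read-data contigs excluded from the denominator and counted.
RNA-seq tallies count primary alignments only (secondary/supplementary
records would inflate counts on near-identical contigs) with strict
thresholds (> 100, > 1000). VCF comparison treats INS and BND records as
point loci matched within a 1 kb window, stratified by SVLEN.

## The synthetic cohort

The generator plants `n_insertions` random insertion sequences
(1–3 kb — above the length filter by construction) at uniform loci kept
≥ 12 kb apart and away from chromosome ends; each donor carries insertion
*m* independently with probability `f_m` (frequencies cycle through
0.5/0.25/0.1/0.75/1.0), and each carried copy receives point substitutions
at 0.002/bp, enough to exercise — but not defeat — the 90 % collapsing rule.
Alignment records are constructed from truth rather than produced by an
aligner: pairs inside an insertion become unmapped pairs, boundary-straddling
pairs become half-mapped records whose mapped mate carries its true
coordinate, 5 % of reference pairs are emitted at MAPQ 10, and contaminant
pairs are unmapped. Reads are uniform with independent substitution errors
(0.001/bp) and **no indels**, which keeps every PAF catalog exactly
computable from the known sequences. Contigs are carried copies with 600 bp
reference flanks (none for deliberately "unplaceable" insertions, including
the second member of each identical-carrier pair); contaminants are injected
as read pairs and as short (< 1 kb) contigs plus one ≥ 1 kb contig with a
planted classifier hit, exercising both removal paths. Catalogs plant gene
models over insertion points, GWAS sites at designed distances 0/100/1000 bp
from the placement interval, and summary-statistic clusters within and
beyond the 50 kb merge window.

What the generator deliberately does **not** emulate: realistic genome
composition and repeats, indel/structural sequencing errors, diploidy and
phasing, assembly fragmentation or chimerism, and aligner-specific MAPQ
behaviour. Passing tests therefore demonstrate the correctness and
calibration of the analysis logic on data satisfying its assumptions, not
robustness to assembler or aligner artifacts on real genomes.

## Problem sizes and reference study

The demonstration cohort is 20 donors, 2 × 200 kb chromosomes, 12
insertions, 3× read coverage — small enough that the full pipeline with
reads runs in seconds. The recovery study is 200 donors and 40 insertions
over 4 × 250 kb chromosomes with two identical-carrier insertion pairs,
evaluated at contig level (the studied metrics — frequency recovery,
placement recall, r² calibration — do not require reads), and completes in
well under a minute. Frequency recovery is judged within three binomial
standard deviations of the planted frequency; placement recall requires the
recovered interval within 1 kb of the true insertion point.

## Numerical and degenerate-input choices

Seeded generators derive independent per-stage streams from the single run
seed, making every output byte-identical across runs. Pearson r² is computed
in double precision and matches the explicit covariance formula to 1e-12.
Empty inputs yield empty outputs rather than errors wherever the empty case
is meaningful (no alignments → unplaced; no significant loci → no peaks);
genuinely inconsistent inputs (duplicate primary records, membership naming
unknown donors, cohort smaller than an observed occurrence) raise errors
naming the offender. Malformed classifier/summary rows are reported with
line numbers or skipped with warnings as specified per format.

## Known limitations

Collapsing uses provided all-vs-all alignments; the package does not align.
Mate placement assumes the read→contig assignment provided by the assembler
is correct. The LD grid treats presence/absence as haploid indicators —
no dosage, phasing or haplotype awareness. Pangenome placement and
Mash-style sketch collapsing are out of scope.
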