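# Methods

`orexpress` implements a repertoire-mining and expression-localization
analysis for olfactory receptor (*OR*) genes: find OR-like loci in a genome
assembly, classify each as intact / pseudogene / truncated, quantify
per-gene expression in bulk RNA-seq libraries normalized to *β-actin*,
call a locus "expressed" in a sample against a pooled criterion, and place
the intact repertoire on a rooted gene tree. Because the motivating use
case (nasal-mucosa expression in a baleen whale) requires multi-gigabase
accessions, the package ships a synthetic-data module that reproduces the
statistical structure of those inputs at desk scale; all claims verified by
the test suite are claims about that synthetic truth, as qualified below.

## Repertoire mining

The genome is translated in all six frames (standard code; stop codons are
kept as `*`, any codon containing N becomes `X`). Query OR proteins are
aligned locally against the translated frames under BLOSUM62 with affine
gaps (open 11, extend 1), and raw scores S are converted to E-values with
the Karlin–Altschul formula `E = K·m·n·exp(−λS)` using the standard gapped
BLOSUM62 parameters λ = 0.267, K = 0.041, where m is the query length and n
the total translated length searched. Hits with E ≤ 1e−5 (the conventional
cut-off for this kind of screen) are retained. These E-values are used for
thresholding and ranking; they are not bit-exact reproductions of any
external tool's statistics, which the analysis does not need.

ORs are single-exon and stop-free in frame while random DNA is stop-rich,
so by default each frame is split at stop codons and only stop-free
segments of ≥ 30 residues are aligned; after a significant hit the flanking
subject regions are searched recursively so co-linear gene copies in one
segment are all found. A `split_at_stops=False` path searches whole frames
for completeness.

Same-strand hits within 1,000 bp merge into a candidate locus (ORs are
single-exon, so the HSPs of one gene lie close; the synthetic generator
spaces genes further apart than this so one locus is one gene copy). A
locus is kept only when the top-scoring subject of its translation among
the OR queries plus a set of non-OR 7TM decoy proteins is an OR — the
in-package analog of discarding candidates whose best database hit is not
an OR — with score ties discarding, conservatively. Finally, overlapping
kept loci are resolved to the single highest-scoring locus per genomic
place: a strong gene can throw a marginal antisense shadow hit just under
the E-value cut-off, and two single-exon genes cannot occupy the same span.

## Gene models and status classification

Each kept locus is extended to a full reading frame: the nearest in-frame
ATG upstream of the leftmost hit (within the aligned query offset plus 90
bp) and the first in-frame stop codon at or beyond the merged hit interval,
bounded by 1.5× the query length; stops occurring more than 30 bp before
the end of the hit interval are premature and retained as `*` in the
conceptual translation. A missing start or stop is recorded as a boundary
note (it does not change status).

Defects:

* **premature stop** — `*` in the reconstructed translation;
* **frameshift** — the locus's supporting hits fall in more than one
  reading frame on the same strand. A 1–2 bp indel necessarily shifts the
  downstream reading frame, so the translated search reports the two gene
  fragments in different frames; this realizes "a nucleotide indel of
  length ≢ 0 (mod 3)" without a protein-to-DNA alignment.
* **missing TM block** — a semi-global query↔translation alignment (BLOSUM62,
  affine 11/1, free end gaps) shows ≥ 5 consecutive query residues deleted
  in the subject, and that deleted query span intersects a predicted
  transmembrane helix *of the query*. The criterion needs a reference
  topology and the query is the only reference available; deletions of ≥ 5
  residues confined to loops do not fire the rule and leave the gene
  intact.
* **contig gap** — an N-run of ≥ 50 bp overlaps the locus.

Status precedence: a gap-interrupted sequence is **truncated** regardless
of co-occurring defects (it cannot be confidently pseudogenized when part
of it is unsequenced); otherwise any core defect makes a **pseudogene**;
otherwise **intact**.

Transmembrane helices use the classic Kyte–Doolittle scan: per-residue
hydropathy, sliding window of 19, windows with mean > 1.6 seed a span,
overlapping seed windows merge, span ends are trimmed back to hydrophobic
(KD ≥ 1.6) residues, and spans shorter than 17 residues are dropped. The
method is deterministic and dependency-free, and is provably correct on the
synthetic templates (below), which is exactly what the truth-recovery tests
require. It is a heuristic on real proteins.

Class-2 versus non-class-2 is assigned by best global alignment score of
the coding nucleotide sequence against reference coding sequences of each
class (match +1, mismatch −1, open −4, extend −1, free end gaps), because
the two classes are defined by nucleotide sequence; the winning margin is
recorded and exact ties are flagged unclassified rather than guessed.

## Read quality trimming

Reads pass a four-stage trimmer with the parameterization LEADING 20,
TRAILING 20, SLIDINGWINDOW 4:20, MINLEN 36: optional adapter-prefix
clipping (simple mode only; palindrome adapter chemistry is out of scope),
removal of leading then trailing bases below threshold, a 5′→3′ scan of
4-base windows cutting at the start of the first window whose arithmetic
mean integer Phred score is strictly below 20 followed by re-trimming
trailing sub-threshold bases, then a length filter. Output is always a
contiguous substring of the input, so trimming is idempotent. A vectorized
batch implementation handles uniform-length libraries and is
property-tested for exact agreement with the scalar reference; edge
behaviors not pinned down by the external tool this stage emulates (e.g.
the re-trim order after a window cut) are fixed by this contract.

## Quantification and the expression criterion

Alignment-based quantification is replaced by unique-k-mer assignment,
which preserves the quantity of interest for single-exon genes: each
indexed transcript contributes its canonical (strand-symmetric) 31-mers,
k-mers occurring in more than one transcript are discarded, and a read pair
votes for the transcript owning the majority of its matched private
k-mers; mates voting for different transcripts in equal measure are
unassigned, and duplicate pairs — identical (mate-1, mate-2) sequences —
are counted once. Genes left without a single private k-mer are reported
un-quantifiable. Then

    FPKM = count · 1e9 / (gene_length · total_assigned)

with `total_assigned` the assigned, duplicate-removed fragment count of the
sample (duplicates are removed before quantification, and effective-length
corrections are not applied — transcript length equals gene length for
single-exon genes). Expression percentage is FPKM divided by the sample's
*β-actin* FPKM, × 100, so it is invariant to depth and to any uniform
rescaling of counts.

The expression criterion pools **every** non-zero intact-OR expression
percentage across **all** samples, negative controls included, and takes
the mean; a gene–sample cell is called expressed when its percentage is ≥
the criterion. Pooling cells (rather than averaging per-sample means) is
the only reading under which the published per-sample means are consistent
with the published pooled value, and the controls' non-zero cells exist and
are therefore included; a configuration switch (`include_controls_in_pool`)
exposes the alternative. The ≥ call rule is consistent with the published
borderline case. Per-sample mean ± sd (sample sd, ddof = 1; sd 0 with n = 1
flagged) of the non-zero cells is reported alongside, and intact ORs are
named OR001, OR002, … by descending FPKM in a reference sample with ties
broken by gene id.

## Gene tree

Intact OR coding sequences are aligned progressively: pairwise global
alignments (match +1, mismatch −1, gap open −4, extend −1) give a distance
matrix, UPGMA on those distances gives the guide tree, and profiles merge
along it with the same scoring (the profile–profile DP is affine-gap,
vectorized row-wise). Inputs are sorted by id first, so the alignment is
independent of input order. Distances are Jukes–Cantor,
`d = −(3/4)·ln(1 − (4/3)p)`, with p the mismatch proportion over
pairwise-ungapped columns (pairwise deletion, robust to the long indels
pseudogenes would contribute if a user includes them; the default input is
intact genes only); p ≥ 0.75 is capped at 10 substitutions/site with a
warning. Neighbor joining is canonical Saitou–Nei, with Q-ties broken by
the lexicographically smallest taxon pair and negative branch lengths
clamped to zero with the deficit moved to the sister branch. Support values
are column-bootstrap percentages over the original tree's bipartitions.
The root goes on the branch separating the non-class-2 leaves; when they
are not monophyletic the branch maximizing non-class-2 purity of one side
is used and the tree is flagged. Maximum-likelihood inference is explicitly
out of scope — the claims here concern the class-2/non-class-2 partition
and the rooting logic, not published branch lengths — and the alignment is
exported in FASTA and relaxed PHYLIP for external ML tools.

## Synthetic data: what it emulates and what it does not

The generator plants single-exon OR-like genes on random contigs, both
strands, with ≥ 1.2 kb spacing. Protein templates are built from a fixed
scaffold — Met, a polar N-terminal segment, seven 21-residue blocks of
strongly hydrophobic residues (KD ≥ 1.8) separated by polar loops (KD <
1.6), ~306 aa total — so the hydropathy detector finds exactly seven spans
by construction. The non-class-2 template carries a diagnostic loop motif
and ≥ 25% amino-acid divergence from the class-2 template (nearest-
reference class assignment is unambiguous); two decoy proteins share the
7TM scaffold but none of the template sequence. Gene copies are synonymous
variants of their class template (per-codon synonymous substitution rate
0.15, chosen so essentially every 100-bp read carries copy-private 31-mers
and the repertoire is quantifiable; proteins remain identical to the
queries). Defects are planted in the central region of the ORF (≥ 35 codons
from either end) so both flanks of a defect support their own homology
hits: one internal stop codon, one 1–2 bp indel, or an in-frame deletion of
5–7 codons wholly inside a TM span. Truncated genes carry a 50-bp N-run
(default chosen to be unambiguously longer than any homopolymer) replacing
the center of the coding span. A β-actin analog (1,128 bp), an OMP analog
(1,100 bp), ten generic highly-expressed filler transcripts (1,500 bp) and
one decoy-derived gene complete the genome.

Libraries are paired-end 2×100 bp, error-free by default (an optional
uniform substitution rate and a 3′ quality-degradation switch exist to
exercise trimming). The expected fragment count of gene g is
`FPKM_g · (len_g/1e3) · (total/1e6)`; realized counts are multinomial, with
residual probability mass emitted as intergenic background. Fragment
lengths are normal (mean 300, sd 90, clamped to [read length, gene
length]), orientation is random, and `round(duplicate_fraction · total)`
exact copies are appended after the draw. Read names encode the source gene
and duplicate status so tests can audit every assignment.

The six-library default design mirrors the study structure — one high-OR
frontoturbinal sample in which OMP also clears the criterion, one
intermediate ethmoturbinal sample whose OMP does not, one respiratory
sample, and three negative controls (olfactory bulb, two skin) with low but
non-zero OR signal; only class-2 ORs are planted as expressed. Two
deliberate departures from the published magnitudes: per-sample target
FPKMs are rescaled so the planted transcripts account for the whole library
(Σ FPKM·length = 1e9, the β-actin analog holding 25% of fragments and the
fillers the bulk), which makes the closed-form estimator an unbiased
recovery of the targets while leaving every expression percentage
untouched; and planted expression percentages are roughly an order of
magnitude above the published ones so that at the default depth of 1e5
fragments per library every non-zero gene collects on the order of a
thousand fragments (binomial noise ~3%) and duplicate removal loses only a
~2% birthday-collision tail. At published magnitudes and desk depth, OR
cells would receive single-digit fragment counts and no estimator could
recover them; the relative structure (which sample is high, which cells
clear the criterion, controls below it) is what the tests assert.

Consequences for interpretation: passing tests show the pipeline recovers
a *planted* truth whose genes are highly diverged between classes, nearly
protein-identical within class, single-exon, and adapter-free, under
error-free reads. They do not show robustness to sequencing error, intron
structure, segmental duplication, allelic variation, adapter chemistry, or
TM-detection failure on real membrane proteins.

## Numerical and design choices

* Scores and E-values are floats; determinism everywhere comes from seeded
  `numpy` generators (one seed per sample plan, derived as `seed·1009 + i`),
  canonical input sorting, and stated tie rules (best-hit ties discard;
  class ties unclassified; NJ ties lexicographic; FPKM-rank ties by id).
* The FPKM formula divides by `total_assigned`; a sample with zero assigned
  fragments is an error, not a zero.
* Saturated JC distances are capped at 10 rather than infinite so NJ stays
  finite; the cap only matters for inputs far outside the intended use.
* `k = 31` (odd, canonical) for the quantification index; `k ≥ 21` enforced.
* Pipeline exit codes: 0 success, 2 validation, 3 stage failure; every
  summary number is recomputable from the stage artifacts on disk.

## Known limitations

Heuristic segment search can in principle miss a gene fragment shorter than
the 30-residue segment floor (defects planted near ORF ends); the full
 six-frame path exists but is slower. Frameshift detection requires both
fragments to produce significant hits, which is why the generator keeps
defects central; very 3′ or 5′ indels in real data would be classified from
the remaining evidence (often as premature stops, mimicking real pipeline
behavior). Class assignment of pseudogenes follows the nearest reference
and is reported, not asserted, since a defect can erode the signal. The
expression criterion is sensitive to the set of samples pooled; both
pooling variants are exposed. The NJ tree is a distance method: branch
lengths are not ML estimates and should not be compared with published ML
trees beyond topology and rooting.
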