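# Methods

This note documents the models and conventions behind `vdjprof`: what the
simulator generates, how the annotator decides things, which defaults are
measurement thresholds taken from the source study's analysis protocol and
which are this package's own declared choices, and what the validation
experiments do and do not demonstrate.

## Germline model and anchors

A germline database holds V, D and J nucleotide references for one locus.
Functionality is decided purely by the presence of the conserved CDR3
anchors:

* **V**: an in-frame TGT/TGC codon whose start lies within the final 30 nt
  of the reference. The reading frame is frame 1 of the (de-gapped)
  reference — IMGT V references begin in frame, and the bundled synthetic
  references are constructed that way. When several in-frame cysteine
  codons fall in the window the rightmost is the anchor ("the last
  cysteine").
* **J**: a [FW]GXG tetrapeptide in any of the three reading frames; the
  5'-most hit anchors the CDR3 end, matching junction-proximal usage.

Inputs with IMGT "." gaps are de-gapped on read and the original numbering
is retained, so the FR3 span (positions 196–310, 1-based inclusive) always
refers to the gapped (IMGT unique) numbering when gaps were present and to
raw coordinates otherwise. All externally visible coordinates are 1-based
inclusive.

Database-supplied pseudogene/ORF labels are not consulted; motif presence
is the only functionality criterion. This keeps behaviour identical across
reference sets that do or do not ship such labels.

## Synthetic references

`simulate.synthetic_database` builds random references with planted
anchors: V genes of 318 nt with the cysteine codon at 307–309 (so FR3
196–310 lies inside the gene and up to 9 nt may be trimmed without
touching the anchor), D genes of 16 nt, J genes of 48 nt with [FW]GXG at
nt 16. J references are kept stop-free in the anchor frame downstream of
the anchor, as real J genes read through into the constant region;
without this, synthetic repertoires would be dominated by artifactual
stop-codon losses. Default gene counts per locus follow the functional
inventories of the rhesus loci the package targets (TRB 59 V/2 D/13 J,
TRA 31/–/55, IGH 19/10/6, IGK 83/–/4, IGL 83/–/5). These references are
synthetic stand-ins: they reproduce the *structural* features the pipeline
depends on (anchors, frames, lengths), not real allele sequences or
inter-gene similarity. Consequences for interpretation are discussed under
Limitations.

## Rearrangement model

Per clonotype the simulator draws, in a fixed RNG order (genes → trims →
insertions → frame adjustment → allele substitution → SHM → clone size):

* V/(D)/J genes by normalized usage weights (uniform by default).
* Four trim lengths (3'V, 5'D, 3'D, 5'J), geometric with mean 2 nt,
  capped so the V/J anchors survive and at least 6 nt of D remain (a D
  core below the 5-nt detection floor would be unrecoverable by any
  annotator).
* Insertion lengths, geometric with mean 4 nt; insertion bases i.i.d.
  from a per-locus bias — beta-chain pools ~31% C/28% G, heavy-chain
  pools ~27% C/39% G, light chains uniform — mirroring the C/G bias
  reported for TdT-generated N-nucleotides.
* Optionally the junction is padded to keep the CDR3 in frame
  (`frame_mode="in_frame"`), emulating the predominantly productive
  transcripts of sorted-cell mRNA libraries; the default leaves frames
  random.
* For BCR loci: heterozygous germline alleles (gene, V position,
  alternative base, allele fraction) are substituted per clonotype before
  SHM, then every position mutates independently at `shm_rate_per_nt`
  (default 6% for IGH, 4% for light chains) with optional per-position
  hotspot overrides and a configurable transition:transversion weight.
  Allele and SHM events are recorded separately in the ground truth.
* Clone sizes follow a truncated discrete power law (Zipf exponent 2 by
  default), giving the heavy-tailed rank-abundance curves seen in real
  repertoires and supplying the singletons/doubletons Chao1 needs.

### The canonical junction parse

A junction admits many physically indistinguishable parses: an inserted
nucleotide that happens to equal the adjacent germline base cannot be told
apart from an untrimmed germline base. Both the ground truth and the
annotator therefore commit to one convention — **germline absorbs
maximally**: the V extends rightward over junction bases that continue its
germline sequence, the J extends leftward likewise, and the D is the
longest contiguous exact match (≥ 5 nt) of any D reference inside the
remaining gap, ties broken toward the lexicographically smaller gene name,
then the leftmost gap offset, then the leftmost D offset. The simulator
stores both the as-drawn values (`Rearrangement.raw`, used to verify the
generative length models) and the canonical values (used as recovery
ground truth). Without a shared convention, exact junction recovery would
be capped around 90% by chance matches alone.

## Read emission

Each read copy draws a fragment length uniformly from 150–190 nt; the
template is the fragment-length 3' tail of the transcript (constant-side
sequencing of a 5'-RACE library), read 1 covers the template 5' end and
read 2 is the reverse complement of its 3' end, both 100 nt, phred+33.
The upper fragment bound sits at 190 nt so that every pair overlaps by at
least the 10-nt merge minimum; the sonication band of such libraries
extends to ~250 nt, but fragments above 190 nt cannot be merged from
2×100 reads and would only inflate the discarded fraction. This layout
reproduces the characteristic coverage gradient of short-read repertoire
data: the junction and the FR3 3' half are covered by every read while
coverage decays toward the FR3 5' end. Substitution errors (default
0.1%/nt) and N bases (0.05%) are applied per base; qualities are a flat
Q30 with errored/N bases at Q15 — only the QC thresholds downstream
depend on qualities, so no full quality model is attempted.

## Preprocessing

A pair is dropped when either mate's arithmetic mean phred score is below
15 ("average quality score" read as a phred mean) or when more than 5% of
its bases are N; both thresholds are the source protocol's. Merging scores
every overlap length from the maximum down to 10 nt, keeps candidates with
mismatch rate ≤ 10%, picks the one with the most matching bases (ties to
the longer overlap), and resolves overlap disagreements toward the
higher-quality base. The overlap/mismatch parameters are declared defaults
(the original merging tools' settings are unpublished); reads are only
100 nt, so the exhaustive search needs no seeding heuristics.

## Annotation

Alignment is local Smith-Waterman with match +1, mismatch −1, gap open
−3, gap extend −1 (Bio.Align.PairwiseAligner). A shared-k-mer prescreen
(k = 11 for V, 7 for J) restricts full alignment to the top 8 candidate
genes per segment; the unit tests verify against an independent exhaustive
DP oracle that the prescreened assignment still finds the globally best
gene and score, and `prescreen_top=None` disables it. Assignment
thresholds — V ≥ 40 aligned nt at ≥ 80% identity, J ≥ 15 nt at ≥ 80% —
are declared defaults chosen to tolerate heavy SHM while rejecting junk;
score ties go to the lexicographically smaller gene name and are flagged.

**Boundary refinement.** A raw local alignment extends past the true
germline boundary whenever a net-positive run of chance matches follows
(expected for ~1 junction in 9). The V 3' (and J 5') boundary is
therefore trimmed back: any terminal exact-match run shorter than 10
columns is discarded together with the mismatch or indel column that
precedes it, iterating until the boundary rests on a ≥ 10-column exact
run. Gap columns break runs. The refined boundaries feed the junction
decomposition and the SHM profiles; the raw alignment still provides CDR3
anchor mapping and identity.

CDR3 extraction maps the V and J anchor codons onto the read through the
alignments; the CDR3 includes both anchor codons. Productivity requires
CDR3 length divisible by 3, no stop codon in the anchor frame from the
cysteine through the end of the J alignment, and functional genes;
failure reasons are reported as `out_of_frame`, `stop_codon` or
`nonfunctional_gene`. Mixed light-chain pools are demultiplexed by
comparing the best V-alignment score against the IGK and IGL databases;
equal scores leave the read unresolved.

Clonotype-level error collapse merges a clonotype into a ≥ 100× larger
one (ratio 0.01) sharing V and J with at most 1 CDR3 substitution,
applied in one largest-first pass — a declared stand-in for the original
pipeline's unpublished correction step, exposed in config.

## Repertoire statistics and diversity

All statistics are read-weighted by default ("the sequences that aligned
best"), with a clonotype-weighted mode behind a flag; only productive
clonotypes enter the table. Frequency tables sum to 1; V−J usage
marginalizes exactly to V and J usage. The captured-pairing fraction is
observed distinct V−J pairs over n_V × n_J.

Chao1 uses the singleton/doubleton form above; when F2 = 0 the standard
bias-corrected fallback S_obs + F1(F1−1)/2 is returned and flagged.
Because published richness numbers mix nucleotide- and amino-acid-level
counts, the diversity unit is a required explicit parameter everywhere —
there is no silent default. Rarefaction subsamples reads (expanded from
clonotype counts) without replacement at depths 10%…100%, ten replicates
each, seeded and bit-reproducible.

## FR3 SHM analysis

Per V gene, reads assigned to it accumulate read-weighted coverage,
mismatch counts and observed-base composition at each FR3 position of the
V reference, restricted by default to productive sequences. Alignment
columns beyond the refined V end are excluded — they are junction bases,
and counting them would paint a false mutation stripe at the V 3' edge.
Guard bands further drop the 5 columns after each read's alignment start
and the 10 positions before its inferred V end: a local alignment must
begin and end on exact matches, so edge columns that survive are
match-conditioned while mutated edge bases are preferentially trimmed
off, and counting the survivors underestimates per-position rates near
read boundaries. The guards trade a little FR3-edge coverage for an
unconditioned estimate (recovery of a configured 6% uniform rate improves
from ≈5.5% to ≈6.0% in the validation experiment).
Amino-acid-level rates compare whole codons (frame-1 codons fully inside
FR3, fully covered by the read): a codon with any mismatching base counts
as one event, so aa-level rates exceed nt-level rates by construction.

* **Hotspots**: mutation frequency strictly > 10% at coverage ≥ 31
  (positions with ≤ 30 sequenced bases are masked and reported
  separately, the grey heatmap cells).
* **Polymorphic sites**: coverage ≥ 1000, a single non-reference base at
  40–60% of coverage (endpoints inclusive) that also accounts for ≥ 80%
  of all mismatches there. The dominance threshold makes the qualitative
  "mainly one type" criterion operational. Dominant sites at 30–40% or
  60–70% are reported in a separate *candidate* tier rather than silently
  accepted or dropped — allele-expression imbalance can push a true
  heterozygous site below the band.
* **Spectra**: relative frequencies of the 12 nucleotide substitution
  types, and of amino-acid substitution types from codon comparison (with
  a top-N view).

Reads are compared against their single best-matching reference only;
there is no iterative allele-reassignment loop as in dedicated novel-allele
inference tools — the polymorphic-site tier is a screen, not a genotyper.

## Validation experiments

`vdjprof.validation` runs the whole pipeline on ground-truthed libraries:

* **Junction recovery** — 5,000 error-free, SHM-free TRB clonotypes with
  the full 59/2/13 synthetic database: fraction of unique annotated
  sequences whose V gene, J gene, CDR3 nt and all seven junction section
  values exactly match the canonical ground truth.
* **SHM recovery** — 5,000 IGH clonotypes at 6% per-nt SHM, in-frame,
  with one V gene at half the repertoire (mirroring the dominant-gene
  usage such repertoires show), low clonal dominance (Zipf exponent 3, so
  read-weighted allele fractions track transcript shares), and a
  heterozygous allele (fraction 0.5) injected at V positions 239 and 300
  of the dominant gene. Reported: the overall FR3 mutation rate, the SHM
  rate net of detected polymorphic positions (germline polymorphism is
  not SHM — excluding it is the method's own point), detection
  sensitivity at deep positions, and the number of false calls. A site
  counts as detected when the caller surfaces it in either the
  polymorphic or the candidate tier: clone-size skew shifts read-weighted
  allele fractions, and a true 0.5 allele can land just outside the
  strict band — the situation the candidate tier exists for. The
  strict-band sensitivity is reported alongside.
* **Insertion composition round trip** — 2,500 error-free, SHM-free
  clonotypes per locus, clonotype-weighted pooling: recovered inserted-base
  frequencies versus the configured bias (~18,000 inserted bases). SHM is
  off here because junction mutations fragment the exact D match and
  relabel germline D bases as N-insertions, diluting the composition — a
  limitation of alignment-based decomposition generally.

Problem sizes were chosen so each experiment completes in a few minutes on
one CPU while leaving binomial sampling error well inside the checked
tolerances.

## Numerical and degenerate-input conventions

Zero-coverage mutation rates, empty insertion pools and empty substitution
spectra return an explicit undefined flag (None) with a logged warning
rather than NaN. Empty clonotype tables raise. Probability vectors are
validated to sum to 1 within 1e-9. All stochastic components take explicit
integer seeds; the simulator consumes independent child streams for
rearrangement generation and read emission so either stage can be
reproduced in isolation.

## Limitations

* Synthetic references are mutually random: real V genes share family
  structure and up to ~95% identity, so real-data assignment ambiguity is
  higher than these experiments show. The experiments validate the
  machinery and its conventions, not macaque-specific accuracy.
* The SHM model is position-independent (with optional hotspots); real
  SHM clusters in motif contexts, so real aa/nt rate ratios will differ
  from the binomial expectation seen here.
* 5'-RACE chemistry (poly-C tailing, biotin selection, PCR-duplicate
  families) is not modelled; the QC stage sees idealized errors.
* The paired-read layout guarantees mergeable overlaps by capping fragment
  length; the unmerged-read path is exercised by unit tests, not by the
  default simulation.
* CDR1/CDR2 mutation analysis is out of reach of this read layout by
  design, as it is for the underlying 2×100 protocol.
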