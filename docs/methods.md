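# Methods

## The measurement and its artifacts

Direct RNA sequencing reads are primed on the polyA tail and sequenced by
synthesis, so each read is reverse-complementary to its RNA fragment and
the read's 5' mapped end marks the transcript's cleavage position.  The
package therefore stores a single coordinate per read, `cleavage_pos`
(0-based, the last transcribed nucleotide; `[pos, pos+1)` in BED output),
and takes the record's strand to be the *transcript* strand.

Two artifact classes are handled at read level:

- **Leading Ts** in raw sequences come from inefficient locking of the RNA
  against the polyT primer and are trimmed (`trim_leading_t`); an all-T read
  trims to the empty string and is unusable.
- **Internal priming**: the oligo-dT primer can anneal to a genomic A-rich
  stretch, creating a false cleavage signal.  A read is discarded when the
  10 genomic nucleotides immediately 3' of its cleavage position, read on
  the transcript strand, begin with a run of ≥ 6 adenines.  The criterion
  is deliberately a *leading* run ("AAAAAGAAAA" passes, leading run 5): the
  wording that motivated it is ambiguous between "the first six" and "any
  six of ten", and the leading-run reading is both the literal one and the
  conservative one.  The window/run lengths are configurable
  (`QcThresholds`).  Windows truncated by a chromosome end count missing
  bases as non-A (conservative retention).

Mapping filters (unique, length ≥ 21 nt, score ≥ 4, boundaries inclusive)
treat the aligner score as an abstract numeric threshold.

## Site calling

Cleavage is imprecise within a few nucleotides, so read ends are clustered
single-linkage per (chromosome, strand) with a strict < 24 nt gap between
*read positions* (not running cluster centroids): this reproduces iterative
merging while being order-invariant, and is verified against a brute-force
transitive-closure oracle.  Clustering pools reads across all samples so
per-sample counts refer to one unified site registry; per-sample cluster
reports remain available by clustering one sample's reads.

The site coordinate is the read-weighted median of member positions; for an
even read count the lower of the two central values is taken, so the
representative is always an observed read position and the procedure is
deterministic on integer coordinates.

Retention keeps a site with ≥ 1 read in ≥ 2 samples or ≥ 2 reads in
total — infrequently used polyA sites are real, but single-read singletons
are not trusted.

## Annotation

Sites are classified against gene models (GTF; UTRs derived from exon/CDS
geometry) with strand-matched overlap only, since polyadenylation is
strand-specific.  Category priority is 3UTR > CODING > 5UTR within a
coding gene (applied across all of the gene's transcripts), then ncGENE,
PROMOTER (≤ 1 kb upstream), DOWNSTREAM (≤ 1 kb downstream, attributed to
the nearest upstream same-strand gene), INTERGENIC.  The priority is a
design choice: a genuine 3'-end annotation should win over an intron of an
overlapping isoform.  Positions inside a coding gene that fall in a coding
exon *or any intron of the CDS region* are CODING, because their usage
truncates the reading frame.  PROMOTER and INTERGENIC sites carry no gene
and are excluded from APA testing; DOWNSTREAM sites within 1 kb join the
upstream gene's table (they carry far more reads than other intergenic
sites and behave as unannotated distal sites).

## Differential APA

Per protein-coding gene, the samples × sites table includes a site iff its
count reaches 10% of the gene's reads in **at least one** sample (the
stricter every-sample variant is available via `require_all_samples`);
reads at excluded minor sites are dropped, not pooled, since such sites
have little impact on the mRNA pool.  Genes with < 2 included sites are
untestable.

Differential usage is tested per *pair* of samples with a two-sided Fisher
exact test on the 2 × C table.  The implementation enumerates all
first-row completions of the fixed margins (vectorized log-gamma
arithmetic), summing the null probability of tables no more probable than
the observed one with a relative tie tolerance of 1e-7; when the
enumeration grid exceeds 10⁶ cells it switches to a Monte-Carlo estimate
(10⁵ multivariate-hypergeometric draws, fixed seed `stats.MC_SEED`, so
results are reproducible).  On 2 × 2 tables the enumeration agrees with
the hypergeometric closed form to < 1e-10.

Multiple-testing correction is Benjamini–Hochberg, applied separately per
sample-pair comparison across all testable genes (the correction scheme is
a design choice; correcting jointly across the six pairs would couple the
within-group and versus-reference calls).  A gene is **significant** iff
all three tumor–tumor q-values exceed 0.1 (the tumor group is homogeneous)
and all three tumor–reference q-values are below 0.1.

## Curation

Five ordered removal rules make the post-hoc selection reproducible.  Two
operational definitions the source rules leave open are fixed as:

- **implicated sites** — the pair of sites with the largest increase and
  largest decrease in mean tumor usage share relative to the reference;
- **primarily used** — a strict plurality of the gene's included reads
  (ties do not fire a rule, conservative retention), required in ≥ 2 of 3
  tumors for the group-level rule.

Rule 3 (implicated sites < 10 reads in 2/3 tumors) fires by default only
when *both* implicated sites fail (`read_support_mode="any"` switches to
either).  Rules 1–2 use transcript-containment geometry only; no
expression deconvolution is attempted.

## miRNA target loss and qPCR arithmetic

For UTR-APA genes the truncated region is the genomic interval between the
proximal and distal cleavage positions.  A target site counts as lost when
it is present in the long isoform but not fully contained in the short
one — so a site straddling the proximal cleavage position is lost by
default (a partial seed match is non-functional); `straddle_lost=False`
switches to strict containment in the truncated region.  Expressed miRNAs
come from a plain list or from a detection matrix with a ≥ 4-of-5-samples
threshold (configurable).

qPCR triplicates collapse to a median after removing values deviating
> 2 cycles from the median (applied once, not iterated; the median always
survives).  The short/long ratio is `efficiency^(Ct_distal − Ct_proximal)`
with efficiency 2 by default (perfect doubling; the transform used for the
published per-sample ratios is not derivable from them, so only the
normalization-to-reference step is treated as exactly reproducible, and it
reproduces all nine published normalized cells to 6 significant figures).

## Synthetic data

The generator emulates the analysis' data regime, not the raw sequencing:
genes with a two-exon structure (intron, last-exon 3'UTR), 2–4 polyA sites
per gene placed in the intron, the 3'UTR, or ≤ 1 kb downstream; gene read
totals drawn negative-binomially (default mean 300 per gene per sample,
dispersion 0.1 — 3'-end counts are overdispersed); multinomial site choice
per read; discretized Gaussian cleavage jitter (sd 2 nt, truncated at
±10 nt, matching nucleotide-scale cleavage imprecision while keeping every
read inside its site's 24-nt cluster); and internal-priming decoys — a
fraction (default 5%, the order of magnitude real DRS libraries lose to
internal priming) of each gene's reads relocated to a planted 10-adenine
run ≥ 100 nt from any true site.  The genomic context around every true
site is rewritten A-free, and sites within a gene are ≥ 250 nt apart, so
filter exactness and cluster/truth correspondence can be asserted exactly
rather than statistically.  A planted APA gene uses proximal fraction 0.8
in all tumor samples against 0.2 in the reference (remainder spread evenly
over the other sites); null genes share one Dirichlet(2) usage vector
across all four samples.  Each sample's reads come from an independent
(seed, sample) random stream, so any sample regenerates byte-identically
from the manifest.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: raw nucleotide sequences and base-calling
error, alignment ambiguity and mapping bias, genuinely A-rich true 3'
ends (where the internal-priming filter must trade sensitivity for
precision), overlapping and read-through transcription, library-depth
imbalance between samples of the magnitude seen in real runs, and
biological within-group heterogeneity.  The benchmark sensitivity and
false-call numbers are properties of this generative model at its default
sizes (500 genes, ~300 reads/gene/sample), chosen so the full pipeline
runs in about a minute on one CPU.

## Numerical choices and degenerate inputs

- Fisher: zero rows or fewer than two non-empty columns give p = 1;
  all-zero columns are dropped before enumeration.
- Weighted median: lower central value on even counts.
- Plurality with ties: no curation rule fires.
- Isoform count ratio: x/0 with x > 0 is +inf; 0/0 is NaN.
- qPCR outlier removal that would empty an (even-sized) replicate set
  keeps the median and removes nothing.
- BH q-values come from `statsmodels.stats.multitest.multipletests`.

## Known limitations

- The Fisher Monte-Carlo fallback estimates p with standard error
  ≈ √(p(1−p)/10⁵); q-values near the 0.1 threshold can flip for genes
  whose tables exceed the enumeration cap.
- The curation structural rules flag geometry only; a human reviewer (or
  expression deconvolution) is still needed for genuinely ambiguous
  overlapping-transcription cases.
- The annotation categories depend on the completeness of the supplied
  GTF; unannotated 3'UTR extensions will classify as DOWNSTREAM or
  INTERGENIC.
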