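# Methods

`stemtx` reimplements the post-alignment computation of a joint long-read /
short-read stem transcriptome analysis as a tested, reusable library. The
upstream work — read processing, consensus calling, spliced alignment,
coding-potential model fitting, negative-binomial model fitting — is out of
scope; the package starts from transcript models, split alignments,
sequences, evidence tables and count matrices, and ends at classified
isoforms, typed splicing events, fusion calls, lncRNA calls, DET sets and
profile clusters.

## Coordinates and data model

All in-memory coordinates are 0-based half-open; GTF/GFF3 I/O converts to
and from the 1-based inclusive convention at exactly one site
(`stemtx.io`), which keeps off-by-one errors out of the analysis code. A
`TranscriptModel` is an ordered tuple of non-overlapping exons on one
chromosome and strand; spliced models must be stranded, while strand "."
is tolerated on single-exon models only (junction orientation is undefined
there) and is treated as a wildcard in overlap queries.

## Isoform classification

A transcript model is

* **known** when its intron chain (the ordered list of intron
  (donor, acceptor) intervals) exactly matches a reference isoform on the
  same chromosome and strand. Exactness is the default because it is
  reproducible; a per-site `junction_tolerance` (bp, default 0) is exposed
  for pipelines that collapse reads with junction fuzz. Mono-exonic models
  have empty chains, so they match by reciprocal exonic overlap
  (`mono_exon_reciprocal_overlap`, default 0.9) against mono-exonic
  reference isoforms.
* **novel isoform** when not known but exon-overlapping an annotated gene
  on the same strand. With several overlapping genes the model is assigned
  to the gene with maximal overlap bp; ties break to the lexicographically
  smaller gene id, making classification order-invariant.
* **novel locus** otherwise. "Overlap" is exonic and same-strand by
  default (`strand_aware=False` relaxes to either strand); this is the
  stricter reading of "does not overlap any annotated gene" and the one
  consistent with stranded aligners.

Merging novel models back into the reference appends novel isoforms under
their matched gene and groups novel-locus models into new genes by
single-linkage clustering of same-strand exonic overlap (union-find over
interval-tree hits). The operation is idempotent: reclassifying the merged
annotation makes every input transcript known.

## Alternative-splicing event typing

Events are defined pairwise between two isoforms of a locus and then
deduplicated by (type, coordinates), keeping the supporting isoform pairs
as provenance. The five canonical patterns:

* **IR** — an intron of one isoform fully inside an exon of the other;
* **SE** — consecutive introns (d1,a1),(d2,a2) in one isoform against the
  fused intron (d1,a2) in the other; the skipped exon is (a1,d2);
* **A5/A3** — two overlapping introns sharing exactly one boundary; the
  shared/differing boundary is interpreted as donor or acceptor in
  transcription orientation, so the same genomic configuration is A5 on
  one strand and A3 on the other. A guard requires the alternative region
  to be exonic in the shorter-intron isoform, which prevents SE and MEX
  configurations from being double-typed;
* **MEX** — two non-overlapping internal exons with shared flanking
  junctions, each present in exactly one of the two isoforms.

Splice-chain differences inside the shared genomic span that none of the
typed events explains are counted once per pair under an `other` bucket —
reported, never silently dropped. Typing is symmetric in argument order,
and two summaries are emitted (per event and per transcript carrying an
event) because both counting units are used in practice.

## Fusion detection

Alignment rows of one query are merged into loci only when their genomic
intervals overlap on the same chromosome; merging by proximity would make
the separation criterion unfalsifiable. The four criteria are then checked
strictly in order: (a) at least two loci, (b) every locus covers at least
5% of the read, (c) the union of query intervals covers at least 95%,
(d) every same-chromosome locus pair is separated by at least 10 kb
(nearest-end gap; different chromosomes satisfy (d) unconditionally). All
coverages are computed on the query axis with interval unions, so
overlapping blocks never double-count. A rejected query reports the first
violated criterion, which makes decoy-based testing per criterion
possible. Defaults: `min_locus_cov=0.05`, `min_combined_cov=0.95`,
`min_separation=10000`, `require_unique=False` for long-read loci.

Validation counts, per candidate, uniquely mapping short reads that span a
fusion junction with at least `min_overhang` (10 bp) aligned on each side,
plus uniquely mapping read pairs whose mates fall entirely on the two
sides of a junction; a candidate is validated when the total reaches
`min_support` (1).

## lncRNA filtering

The cascade keeps a transcript when (1) spliced length > `min_length`
(200 nt), (2) exon count >= `min_exons`, (3) the longest complete
ATG-initiated ORF in the three forward frames is <= `max_orf` (300 nt,
start through stop codon inclusive; codons containing ambiguity characters
never act as start or stop), and (4) the external coding-potential
predictors (CPC, CNCI, CPAT, Pfam — consumed as an evidence table, never
re-implemented) reach consensus. The default consensus is `all_noncoding`
over the available (non-missing) verdicts; missing predictors do not veto,
and a transcript with no evidence at all passes stage 4 by vacuity.
`min_exons` defaults to 1 rather than the sometimes-quoted ">2 exons"
rule: a multi-exon requirement contradicts the observation that lncRNA
sets average fewer than two exons, so the stricter rule is exposed as a
parameter instead of being the default. The ORF scan is forward-strand
only because oriented transcript sequences are assumed.

## Expression layer

**FPKM.** `fpkm[i,s] = counts[i,s] * 1e9 / (library_size[s] * length[i])`,
with library sizes supplied or defaulting to column sums. The conservation
identity (summing FPKM back against lengths and library sizes returns the
column counts) is asserted to 1e-12 in tests.

**DET calling.** Fold change is the ratio of zone-mean FPKM with a
pseudocount (0.1 FPKM, configurable) guarding zeros. P-values come from
one of three sources: a supplied external statistics table; the builtin
default `nb_wald`, a Wald test on the log ratio of normalized-count means
with variance `(1/mu + alpha)/n` per group, where `alpha` is a pooled
method-of-moments NB dispersion (median of `(var-mean)/mean^2` over all
transcript-zone cells with mean >= 5); or `welch` on log2(FPKM +
pseudocount). The default is `nb_wald` because with 2-3 replicates a
per-transcript Welch test has ~4 degrees of freedom and essentially no
power at strict FDR levels — information must be shared across transcripts,
which is exactly the assumption the count simulator satisfies. Welch is
retained for designs with many replicates. Benjamini-Hochberg adjustment
(implemented in-package as the step-up definition, cross-checked against
statsmodels in tests) is applied per contrast; a transcript is a DET when
q <= 0.01 and fold change >= 2 in either direction, and the DET set fed to
clustering is the union over all adjacent-zone contrasts.

**Profile clustering.** Zone-mean FPKM profiles are row-standardized;
profiles with zero variance are excluded with a warning since correlation
is undefined for them. On z-scored rows of dimension n, squared Euclidean
distance equals 2n(1 − Pearson r), so standard K-means (scikit-learn,
k-means++ with `n_init=50` restarts, fixed seed) minimizes
Pearson-correlation distance; the identity is asserted numerically to
1e-10. Clusters are renumbered by descending size for stable output.

**2^-ddCt.** dCt = Ct_target − Ct_reference per sample, ddCt relative to
the calibrator sample, F = 2^(−ddCt); the calibrator is exactly 1.

## Synthetic data

The generator produces every input with planted truth, all deterministic
under one seed:

* annotations with sequentially placed, never-overlapping genes (5-20 kb
  gaps, 1-10 exons of 80-300 nt, introns 80-2000 nt, ~10% mono-exonic
  single-isoform genes) whose sibling isoforms share at least one intact
  intron;
* transcript models at chosen category fractions (default .3/.5/.2). Each
  novel isoform is one AS edit of a sampled type applied to a reference
  isoform (default mix IR .6, SE .1, A3 .1, A5 .1, MEX .1, matching the
  intron-retention-dominated mixes reported for plant stems); edits that
  collide with an existing reference chain are resampled. A quarter of
  novel loci are placed antisense within a gene span to exercise the
  strand-aware boundary;
* fusion queries whose true cases satisfy all four criteria and whose
  decoys violate exactly one each (cycling a-d), plus a short-read table
  giving true fusions three junction-spanning pairs — except a
  validation-fail fraction (default 25%) with zero reads;
* sequences with controlled ORF content: planted lncRNAs are built from
  random 150-nt stretches interleaved with stop-codon blocks covering all
  three frames (bounding any ORF well under 300 nt), planted coding
  transcripts carry a 396-nt ORF where length permits and at least one
  coding verdict;
* negative-binomial counts (variance mu + alpha mu^2, default alpha 0.05,
  falling back to Poisson below 1e-8) over six zones x three replicates
  around nine planted shapes: one peak per zone plus gradual-up,
  up-plateau, down-plateau and gradual-down ramps, each with at least one
  adjacent-zone fold change >= 4 over a lognormal baseline
  (exp(N(5, 0.8)) expected fragments).

What the simulator does **not** emulate: sequencing error, chimera
artifacts from library preparation, junction wobble, positional coverage
bias, overdispersed outlier counts, or correlated gene structure.
Passing planted-truth tests therefore demonstrates that the algorithms
implement their definitions correctly on clean inputs, not that they are
robust to real-data noise — robustness knobs (junction tolerance, coverage
thresholds, consensus rules) exist but default to the strict settings.

## Problem sizes and numerical choices

The test and acceptance workloads use 150-220 simulated genes, 2000
transcript models, 1000 fusion queries, 2000-transcript count matrices and
1800 clustered profiles — sizes at which every planted-truth check runs in
seconds while still exercising all code paths at realistic multiplicity.
Ties are broken lexicographically everywhere a choice is arbitrary
(matched transcripts, gene assignment, cluster renumbering by size), files
are written in sorted order, and stage seeds are spawned from the master
seed, so whole-pipeline reruns are byte-identical.

## Known limitations

* Classification has no category for genomic-overlap-without-junction
  agreement (e.g. SQANTI-style subtypes); the three printed groups are
  deliberate scope.
* Pairwise AS typing cannot represent coordinated multi-intron events; they
  surface in the `other` bucket.
* The fusion detector treats loci as genomic alignment clusters and does
  not refine breakpoints or assign reading frames.
* The builtin DE tests assume a common dispersion across transcripts;
  strongly gene-specific dispersion calls for an external DE engine via
  the supplied-p-table path.
* The ORF scan ignores the reverse strand by design and does not model
  non-ATG starts.
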