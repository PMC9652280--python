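# Methods

## Model and assumptions

`kstrain` treats a genome as its set of canonical k-mers.  With k = 27
(the default), k-mers outside repetitive regions are effectively unique in
a mammalian-sized genome, so presence/absence of reference k-mers in a
strain's k-mer set is a proxy for local sequence identity.  The method is
reference-free on the strain side — no assembly, no alignment — and only
needs the annotated reference for coordinates and gene models.

Three inference layers sit on top of the k-mer sets:

1. **Individual membership.**  A k-mer belongs to an individual when its
   read count is ≥ T.  Sequencing errors produce a large population of
   k-mers seen once or twice; true genomic k-mers cluster around the
   sequencing coverage.  T is the valley between the two modes of the
   occurrence histogram (below).
2. **Strain membership.**  A k-mer belongs to a strain when ≥ m of its
   individuals possess it (default m = 3, a 3-of-N rule suited to panels
   of roughly 4-10 animals).  This majority rule absorbs
   individual-level dropout (a k-mer falling just under T in one animal)
   and private polymorphism.
3. **Scan semantics.**  A reference base is *present* iff at least one
   ambiguity-free k-mer window containing it is in the strain set.
   Altered base pairs are the complement; maximal altered runs are variant
   calls.  Window geometry makes signatures exact for isolated events: an
   isolated substitution removes the k windows covering it but its
   neighbours stay covered by flanking windows, leaving exactly 1 altered
   bp; a deletion of L bp leaves exactly L; an insertion leaves 0 altered
   bp but breaks exactly k−1 windows spanning the junction, which is how
   insertions are called (zero-width call at the junction, carrying the
   absent-run length).

## Threshold inference

The histogram rule: let c_peak be the location of the histogram maximum
over counts c ≥ 3 (the coverage peak; c ≥ 3 excludes the error mode).
T is the count in [2, c_peak] minimising hist(c), ties toward smaller c.
A missing count is treated as a zero-depth valley only when both immediate
neighbours are present; otherwise it is ignored — the unpopulated gap below
the coverage peak of an error-free histogram is not a valley.  A histogram
with no coverage peak (monotone decreasing, e.g. hopelessly low coverage)
falls back to T = 3 and is flagged low-confidence.  Per-sample explicit T
overrides are supported at the pipeline level for reproducing externally
fixed thresholds.

## Synthetic data: what it emulates, what it does not

The generator emulates the study design the pipeline is built for: a
random i.i.d. reference at configurable GC (default 0.41), strain genomes
derived by planted substitutions/deletions/insertions, uniform shotgun
reads at configurable coverage (defaults 30×, 150 bp — the deeper of the
two sequencing regimes the pipeline targets; 15× / 100 bp is the other),
i.i.d. substitution errors (default 0.1%, Q30-like), a toy
gene/mRNA/exon/CDS annotation, and a TSV truth table (0-based half-open
reference coordinates).

Deliberate simplifications, and hence what green tests do *not* show about
real data:

- No repeats: planted events are rejection-sampled so every reference
  window they disrupt truly disappears from the strain (no survival
  through novel junction k-mers, indel-alignment-ambiguous placements, or
  duplicated reference windows).  Real genomes have repeat-induced
  non-unique k-mers, which blur signature exactness.
- Variants are spaced ≥ 2k apart (default), so signatures never interact.
- Substitution-only, quality-independent error model; no indel errors.
  Threshold inference only cares that error k-mers are rare per k-mer, so
  error type matters little.
- Haploid individuals; within-strain polymorphism is optional
  (`private_variant_rate`) and off by default, since no published rate is
  available for the strains emulated.
- Single-end reads; the k-mer content of a paired-end library is the same.
- Read starts may overhang contig ends (the read is clipped), keeping
  k-mer coverage uniform along the whole contig; otherwise contig ends are
  systematically undercovered and produce edge artefacts no real
  chromosome-scale analysis would see.

Everything is a pure function of the config seed; identical configs give
byte-identical FASTA/FASTQ/GFF3/truth outputs.

## Problem sizes

Simulated studies use desk-scale genomes — 100 kb references with 4
individuals per strain at 30× for recovery and noise-robustness runs,
30 kb with 8 individuals for the end-to-end fixture, ≤ 5 kb for
brute-force oracle comparisons — sizes at which every stage is exercised
and exact expectations are computable.  Counting is vectorised (2-bit
codes in uint64, one numpy pass per read batch), so these runs take
seconds; the same code path scales to real read sets given memory for the
count table.

## Numerical and coordinate conventions

- Coordinates are 0-based half-open internally and in BED output; GFF3's
  1-based inclusive coordinates are converted on load.  The insertion
  junction is placed at the end of the covered span (`run_start + k − 1`);
  the true junction is only localisable to within the run.
- Windows containing non-ACGT symbols are skipped in counting, and during
  scanning count as absent; reference bases covered by *no* ambiguity-free
  window (N runs, contigs shorter than k) are reported as "unscannable"
  rather than altered, so assembly gaps do not flood the variant list.
- k must be odd (no k-mer equals its own reverse complement, so canonical
  identity is unambiguous) and ≤ 31 (codes fit in 62 bits).
- Per-Mbp rates are count / length × 10⁶; zero-length regions report 0.
- A variant call overlapping a region boundary counts once per region; a
  call overlapping two genes counts in both.  Zero-width insertion calls
  count when their junction is strictly inside the region.
- The (0,0) cell of the (i,j) summary matrix is structurally empty: k-mers
  belonging to no individual are never materialised.

## Genotyping

PCR is exact-match by default (a mismatch allowance exists but is off, as
no tolerance is published for the assay); both template orientations are
searched and the smallest product within the size limit is returned, with
equal-length products at distinct loci an explicit ambiguity error.
Digestion scans the top strand for the IUPAC site; BsaHI's GRCGYC is its
own reverse complement under IUPAC, so single-strand scanning is complete.
Band sets use gel semantics (order lost, co-migrating lengths collapse).

The bundled template builder is *synthetic*: the real PRKAG3 GenBank
record is not distributed with the package, and the published constraints
(primer pair, 545 bp product, V-allele bands 317/119/109, I-allele bands
436/109) fix the two BsaHI cut positions at 317 and 436 — the builder
fills everything else with seeded random sequence, rejection-sampled
against spurious primer sites and BsaHI sites.  The single-base edit that
ablates the internal site stands in for the V199I nucleotide change, whose
exact base is not published; the module verifies band patterns for any
user-supplied edit rather than hard-coding one.

## Design choices that were genuinely open

- **Valley-minimisation for T**: per-sample thresholds are often fixed by
  hand from the histogram without a formula; histogram-valley thresholding
  is the standard automatic choice, and the CLI accepts explicit
  per-sample overrides to reproduce externally fixed values.
- **Exon sets are unions over transcripts** (counting is per gene, not per
  transcript), and the "gene" region is the full genomic span; coding is
  first-to-last coding base.
- **Insertion calls accept any qualifying absent-run length** (not only
  k−1), since multiple nearby insertions or partially shared sequence can
  shorten a run; the run length is reported on the call.
- **Aggregation requires exactly two named strains**; the (i,j) counter
  table generalises, but every downstream contract (summary matrix,
  differential lists) is pairwise.

## Known limitations

- Presence/absence cannot reconstruct the alternate allele; calls say
  *that* and *where* the strain differs, not *what* it carries.
- Repetitive reference regions whose k-mers occur in the strain for other
  reasons are invisible (false presence); this mirrors the k-mer
  uniqueness assumption.
- Two variants closer than k interact and may merge into one altered run.
- The altered-bp count for a deletion equals its reference footprint, but
  a substitution run of L consecutive changed bases is indistinguishable
  from a length-preserving complex event with the same footprint.
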