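# Methods

## The system being modelled

MR and GR are corticosteroid receptors that bind largely the same GRE motif
sites as dimers but differ sharply in ligand affinity: MR approaches full
occupancy at low corticosterone levels, whereas GR requires the higher
levels of a stress pulse.  The analysis contrasts three conditions —
vehicle, a 20-minute CORT pulse, and pulse-plus-washout — in which this
asymmetry shows up as peak-count dynamics: both receptors bind during the
pulse, GR binding collapses after washout, MR binding is substantially
retained.

ChIP-nexus data have two structural features the pipeline exploits.  Each
read begins with a random barcode (9 nt), so a PCR duplicate is a read with
the same mapped 5′ position, strand *and* barcode — two independent
molecules crosslinked at the same position keep distinct barcodes and are
both retained.  And because λ-exonuclease digests 5′→3′ up to the
crosslinked protein, read 5′ ends pile up at strand-specific *borders*
flanking the protected region, so plus- and minus-strand stop maxima can be
paired into near-nucleotide binding-site calls.

## Simulator (the study conditions)

The generator plants `n_sites = 100` non-overlapping sites (at most one per
kb, ≥1 kb from chromosome ends) on a `200 kb` random genome with mouse-like
GC content `0.41`.  Defaults encode the experiment being emulated:

- **Occupancy** (condition → factor → binding probability at a capable
  site): CORT `1.0/1.0`, washout `0.33` (MR) / `0.023` (GR), vehicle
  `0.005` both.  Washout and vehicle values are the retention ratios the
  study design implies (roughly a third of MR sites retained, a few percent
  of GR sites, near-zero vehicle binding); CORT occupancy is saturating so
  the washout/CORT peak-count ratio directly reflects the washout
  occupancy.
- **Site classes**: a site is co-bound (capable of binding both factors)
  with probability `co_binding_fraction = 0.66`, otherwise MR-only or
  GR-only with equal probability.
- **Motifs**: `motif_fraction = 0.58` of sites get the canonical
  palindromic GRE consensus `AGAACAnnnTGTTCT` written at their midpoint
  (spacer bases random); the rest are binding sites without a recognisable
  GRE, as observed for a substantial minority of real sites.
- **Read model**: each bound site emits `reads_per_bound_site = 100`
  original molecules, split between strands; plus-strand 5′ stops sit at
  the left border and minus-strand stops at the right border (recorded at
  the exclusive-end coordinate, so `minus − plus = protected_width`),
  jittered uniformly within ±2 bp.  `protected_width = 30` bp, inside the
  10–60 bp range typical of receptor footprints.  Reads are a random
  barcode plus a 50-bp genomic insert at constant Q35.  Background reads
  are uniform at 0.5 reads/kb (IP samples); the input control is
  background-only at 5 reads/kb.  On top of the originals, 10% of the
  final stream are PCR re-emissions with identical position, strand and
  barcode.
- **Gene models** (annotation plumbing): random non-overlapping genes, one
  per ~20 kb, 1–5 kb long, random strand — sparse enough that peaks fall in
  all four gene-relative categories with an intergenic share comparable to
  real data (~30%).

Everything derives from one seed through purpose-keyed random streams, so
regenerating one sample never perturbs another and the whole pipeline is
byte-reproducible.

What the simulator does **not** model: chromatin accessibility or
mappability structure, base-composition bias, tethered (indirect) binding,
fragment-length variation, sequencing errors, or fixed barcode segments.
Passing tests therefore demonstrate the pipeline's correctness on data
satisfying its own assumptions — not performance on real libraries, where
alignment artefacts and accessibility structure dominate error budgets.

## Preprocessing

Reads are quality-trimmed on the full sequence with a 5′→3′ sliding window
(4 bases, cut at the start of the first window with mean Phred < 20),
dropped below 29 bp, capped at 59 bp (9-bp barcode + 50-bp insert), then
split into barcode and insert.  The trim-before-split order matters: the
59-bp cap includes the barcode.  On synthetic genomes the aligner is an
exact-substring search on both strands: a unique hit gets MAPQ 42,
multi-hits MAPQ 0, so the MAPQ > 20 filter (strict inequality) removes
exactly the non-unique alignments.  Externally aligned SAM/BAM is ingested
with the barcode taken from the read name after the last `:`.  For
minus-strand alignments the 5′ stop is the rightmost aligned base.
Deduplication keeps the first-encountered tag per
(chrom, strand, stop5, barcode) key — deterministic and order-stable — and
is idempotent by construction.

## Peak calling

A 100-bp window slides at a 10-bp step; the pooled-strand 5′-stop count is
tested against a Poisson null with
`λ_local = max(λ_BG, λ_100, λ_1k, λ_10k)`, each term the input-control
count in the corresponding window centred on the candidate, linearly
depth-scaled to the treatment and expressed per 100-bp window, floored at a
pseudocount of 1 (a zero-depth control without a pseudocount is an error).
Including the window-scale (100 bp) control term alongside the 1 kb/10 kb
terms makes the caller exactly null on treatment == control inputs, at the
cost of slightly conservative behaviour when the control is noisy at fine
scale.  Window p-values (exact Poisson upper tails) are converted to
Benjamini–Hochberg q-values genome-wide (`statsmodels` implementation
behind the `bh_fdr` surface); windows with q < 0.05 are merged when they
overlap.

**Summit definition.**  Raw 5′-stop density is bimodal at a binding site —
it peaks at the two exonuclease borders, not the bound midpoint — so the
summit is taken from the pileup of reads extended 50 bp (the insert length)
toward their 3′ ends, which overlap across the protected region.  The
summit is the centre of the longest maximal-pileup plateau (leftmost run on
ties).  This matches how fragment pileups behave in MACS2 and puts summits
on planted midpoints to within a few bp; a pooled-stop-maximum summit would
sit half a protected width away and systematically off-centre every
summit-anchored motif profile.  Each merged region is reported as one
100-bp peak centred on its summit (shifted inward at chromosome edges), with
the region's minimum p/q and the fold enrichment of its strongest window.

Reproducibility filtering keeps pooled-call peaks that overlap (≥1 bp)
peaks in at least `min_support = 2` individual replicates.

## Borders and pairing

Within each called peak ±100 bp, strand-specific stop-count local maxima
(≥ every count within ±3 bp, leftmost on ties, count ≥ max(5, 2× the local
mean per-position stop rate)) are detected separately per strand, then
paired greedily left-to-right: each plus border takes the nearest unused
downstream minus border at a separation within 10–100 bp (the observed
range of protected-region sizes, including the larger GR regions).
Unpairable borders are reported, not dropped silently.  On jitter-free
simulations the pairs equal the planted borders exactly; with ±2 bp stop
jitter ≥80% of pairs land within ±3 bp.

## Annotation

A peak overlapping a gene body by ≥1 bp is `within_gene` (larger overlap
wins, ties to the smaller gene id); otherwise a nearest gene edge within
5 kb (boundary **inclusive** — the open/closed convention was a free
choice) makes it `upstream_5kb`/`downstream_5kb` resolved by gene strand;
anything farther is intergenic.  The four categories partition the peak
set.  Gene-level multiplicity counts peaks per gene over the three
gene-linked categories.

## Co-binding and condition dynamics

Overlap uses the ≥1 bp direct-intersection rule on half-open intervals.
Retention ratios are `100·n/d` rounded half-up to one decimal — the same
arithmetic reproduces the printed washout percentages from the
per-condition peak counts (246/10602 → 2.3%, 4885/14638 → 33.4% ≈ 33%).

The co-positioning comparison uses each reference-factor (GR) peak that
overlaps the other factor's regions: with the reference peak's floor
midpoint as origin, every position covered by each factor's binding regions
(border pairs when available, otherwise peaks) contributes one count at its
offset, clipped to ±155 nt (the observed maximal extent, configurable).
Similarity between the two normalized offset distributions is quantified by
Jensen–Shannon divergence in nats (0 = identical, ln 2 = disjoint) plus the
per-offset Pearson correlation; the source figures show the distributions
without a metric, so the metric choice is this package's own.

## Motif scanning

Probability matrices are scored as log-odds against a uniform background at
every position on both strands; windows containing N (or lowercase when
masking is on) are skipped; a hit requires a score ≥ 0.8 of the maximal
achievable score, and a matrix with non-positive maximal score (e.g. equal
to background) can never produce hits.  The packaged GRE/GATA3/AP-1
matrices are **synthetic consensus-derived** fixtures (consensus base
probability 0.91, spacers uniform), built by `consensus_pwm`; real curated
matrices can be supplied in JASPAR text format.  Note the GRE is
palindromic, so a perfect site registers one hit per strand.  The
enrichment fraction counts peaks with ≥1 hit within ±100/±200 bp of the
summit; the frequency profile histograms hit-centre offsets from the summit
normalised per peak.

## Numerical and degenerate-input conventions

- Even-width interval midpoints use the floor convention.
- BH q-values are clipped to [0, 1]; p-values floored at 1e-300 before
  −log10 for narrowPeak output.
- Ties: summit plateau → centre (leftmost run); border local maxima →
  leftmost; duplicate retention → first in input order; annotation →
  larger overlap, then smaller gene id.
- Empty inputs return empty outputs (empty tag sets, empty peak lists,
  zero-total coverage distributions); zero-total distributions are an error
  for the similarity metric, a defined empty result for coverage itself.
- `count_ratio` rejects a zero denominator; the pipeline reports NaN for
  retention when a denominator condition produced no peaks.

## Problem sizes

The default desk-scale experiment is a 200 kb single-chromosome genome with
100 sites and ~22k reads per full run (seconds per stage); the
acceptance script adds a 40-site jitter-free border run, a 500-site motif
recovery run on 600 kb, and 200 null peak-calling runs on 20 kb.  These
sizes give binomial error bars small enough for the recovery criteria while
keeping a full verification run in well under a minute per stage.

## Known limitations

- The naive aligner is exact-match only (no mismatches or gaps); real data
  should be aligned externally and ingested via SAM/BAM.
- The peak caller has no fragment-length model-building step and no broad
  mode; peak width is fixed by design.
- Border pairing is greedy nearest-downstream; a global optimal matching
  could differ on pathological border clusters.
- Replicate handling deduplicates per replicate before pooling; the
  alternative order (pool, then dedup) would collapse identical-barcode
  coincidences across replicates and is not modelled.
- Reported fractions on real data depend on the exact motif matrices and
  aligner used; the packaged consensus matrices are for verification, not
  for reproducing database-specific percentages.
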