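# Methods

This note documents the models, statistics, and numerical choices behind
each stage of the package, what the synthetic-data generator does and does
not emulate, and the design decisions taken where the problem was
genuinely open.

## Coordinate and data conventions

All internal coordinates are 0-based half-open. GTF is written/read
1-based inclusive; SAM positions are 1-based (both standard dialects).
A splice junction is the pair (donor_end, acceptor_start): the gap
[donor_end, acceptor_start) is the intron, oriented genomically; strand
is carried separately and junction equality requires exact coordinates
and equal strand (no fuzzy matching). "Fragment" language is kept
although each fragment is represented by one single-end SAM record, so
FPKM semantics stay honest.

A record counts as uniquely mapped when it is not unmapped, secondary,
or supplementary, and either its MAPQ is at least `min_mapq` (default
20) or it carries `NH:i:1` (the simulator's explicit unique marker).
"Unique" has no universal numeric definition across aligners, so the
threshold is configurable.

## Synthetic data generator

The generator emulates the statistical structure of a two-condition
(control vs RBP-overexpression) RNA-seq experiment and an IP vs
total-lysate RIP experiment, at a scale where every expected value is
checkable:

* One random-uniform ACGT chromosome (default 2 Mb). Genes are placed in
  disjoint slots (one per gene), 5–8 exons of 150–400 bp, introns
  200–600 bp, random strand; ~80% of genes are coding, with a nominal
  CDS from mid-exon-2 to mid-penultimate-exon, clipped per transcript to
  its exons. A sizing error is raised when a slot cannot hold the
  largest possible gene, so placement never silently degrades.
* Expression: gene weight `w ~ lognormal(0, 0.5)`; library fragment
  count per gene is Poisson with rate `depth · w / Σw` (times the true
  fold change in condition B for planted fold-change genes, half up at
  `fold_change`, half down at its reciprocal). Fragment starts are
  uniform on the spliced transcript; junction-spanning fragments yield
  N-gapped CIGARs; reads carry the transcript strand (stranded-kit
  convention, switchable).
* Splicing: a planted AS gene carries two isoforms realising one of the
  ten event types (cycled, so all types appear); per-fragment isoform
  choice is Bernoulli with inclusion ratio `0.5 ∓ ratio_shift/2` per
  condition. For ES the skip isoform is deliberately left out of the
  GTF — the grammar distinguishes ES (novel skip) from CE (annotated
  cassette), so the two types need distinguishable annotation. The
  alternative splice-site offset is a fixed 60 bp.
* RIP: input fragments start uniformly within gene spans, weighted by
  the same expression weights; IP fragments get start-position weight
  `enrichment` (default 10) inside planted peak windows (default 100 bp,
  placed away from gene edges) and 1 elsewhere, so a planted window
  collects enrichment-fold the reads of a matched control window.
  Shared "artifact" peaks are enriched in IP *and* input, emulating
  expression-driven pile-ups. Half of IP-only peaks (configurable)
  carry the motif (default `GCGCG`) written into the genome at the peak
  centre — reverse-complemented on minus-strand genes so the
  transcript-strand sequence contains the motif. The paper-style assay
  does not pin fragment sizes or peak widths; both are configuration,
  not claims of fidelity.
* Everything derives from one seed through named `SeedSequence` streams;
  outputs are byte-identical across runs and platforms.

Not emulated (so passing tests say nothing about): sequencing errors,
PCR duplicates, multimapping, paired-end bookkeeping, overdispersion
beyond Poisson, positional/GC bias, overlapping genes, and real splice
site sequence signals. In particular, the DEG test is exactly calibrated
here because counts really are Poisson; on real data (overdispersed) it
would be anti-conservative, which is why the stage is swappable.

## Event grammar

Detection works per gene from the pooled observed junction set plus the
annotation. In order: (1) **IR** — an annotated transcript exon strictly
spans another transcript's intron; (2) the **skip family** — an observed
junction (D, A) bridging an annotated exon whose inclusion junctions
(D', s) and (e, A') are annotated: pure skips are **CE** when (D, A) is
itself annotated and **ES** when novel; when instead the bridging
junction takes an alternative donor (D ≠ D') or acceptor (A ≠ A') lying
on the flanking exon, the composite **A5SS&ES** / **A3SS&ES** label is
assigned, named strand-awarely; (3) **MXE** — two disjoint exons, never
co-transcribed and never joined to each other, each spliced to a common
upstream donor and common downstream acceptor; with only one shared
flank and both exons transcript-terminal the pattern is **5pMXE** /
**3pMXE** (alternative first/last exons, strand-aware); (4) **A5SS /
A3SS** — junction pairs sharing one end whose variant ends sit on
overlapping exon variants (or inside an annotated exon, covering novel
splice sites). Junctions consumed by an earlier pattern are excluded
from later ones; this ordering makes the grammar mutually exclusive on
the fixture suite. Junctions attributable to no gene are counted and
excluded. Events are reported when their defining junctions have any
observed support (configurable); one junction may participate in several
reported events, and shared counts are not deduplicated.

The model/alternative orientation convention: the model form is the
annotation's inclusion path for skips, the shorter intron for splice-site
variants, the genomically left exon for MXE-family events, and the
spliced form for IR. The AS ratio `alt/(alt+model)` is symmetric: swapping
labels maps r to 1−r and leaves |Δr| and the t-test unchanged (tested).

## Quantification and tests

* Model/alt counts are the **mean** supporting-read count over the
  form's junctions (not the sum), so multi-junction forms are not
  double-weighted and the ratio estimates the planted Bernoulli
  parameter without bias. IR retention counts are the mean over the two
  exon–intron boundaries of contiguous single-block reads overhanging
  the boundary by at least `anchor` bp (default 5); the anchor trims the
  effective window and biases IR ratios slightly toward the spliced
  form, visible but harmless at default depths. Ratios are NA below
  `min_support` (default 10) informative reads per sample.
* RASE: two-sided pooled-variance t-test on per-replicate ratios
  (>= 2 defined ratios per condition required), flagged when raw
  p <= 0.05 and |Δr| >= 0.2. A BH-adjusted column is emitted alongside
  but does not gate the flag — the headline rule uses the raw p, and
  both are reported rather than guessing a single intent.
* DEG: exact conditional rate-ratio test — given pooled counts a and b
  and summed library sizes N_a and N_b, b ~ Binomial(a+b, N_b/(N_a+N_b))
  under the null — BH-adjusted across genes; fold change from
  library-size-normalised mean counts with an additive pseudocount of
  1 fragment. Gene length for FPKM is the exon-union length
  (transcript-level ambiguity resolved conservatively; whether real
  pipelines use gene span or exon union varies, exon union chosen).
* Correlation: Pearson on the FPKM matrix; sample ordering from
  average-linkage hierarchical clustering on 1−r; zero-variance samples
  give NaN correlations and are appended unclustered.

## Peak calling

Clusters are transitive >=1-bp overlaps of read footprints (touching
reads do not merge); height is the maximum per-base depth, with the
summit recorded as the leftmost base attaining it (a cluster-read-count
scoring mode is available behind the ``statistic`` switch). The null re-places
the gene's own reads (same count, identical lengths — "similar lengths"
taken as identical) uniformly over the gene span, strand preserved,
exon structure ignored; 500 placements per gene. Empirical p uses
add-one smoothing (1 + #{null max >= h})/501, so p is never zero and
taller peaks never get larger p (tested monotone). Reads longer than the
gene span are clamped with a warning. IP and input are assessed
separately; IP peaks overlapping any significant input peak by >= 1 bp
on the same strand are removed; replicates are called independently and
the final set keeps replicate-1 peaks that overlap replicate 2. Because
the empirical null max is integer-valued, ties make the test mildly
conservative — under pure-null simulations ~4% of genes reach p < 0.05
at the nominal 5%.

## Integration

Feature classes tile each gene span with precedence
CDS > 5'UTR > 3'UTR > NC-exon > intron when transcripts disagree
(exonic always beats intronic; translated sequence wins); reads and
peaks are assigned by majority overlap on their strand, ties broken by
the same precedence. NC-exon is per-transcript (an exon of a noncoding
isoform), not per-gene.

K-mer enrichment replaces full motif discovery: z = (f_obs − mean
f_bg)/sd(f_bg), with background frequencies from repeatedly resampled
(seeded) length-matched windows drawn from gene spans outside peaks, and
the SD floored at half of one observed count to avoid division by a
degenerate background. Sequences are taken strand-aware (minus-strand
peaks reverse-complemented) from **summit-centred windows** (summit
± 75 bp, clipped to the peak): at realistic depths >= 1-bp clustering
merges most of a gene into one cluster, and a 5-mer planted once per
binding site is undetectable when diluted over kilobases, while the
binding signal by construction sits at the depth maximum. Full-interval
extraction remains available (`summit_flank=None`).

## Problem sizes and calibration checks

The standard validation configuration is 200 genes on ~2 Mb, 3+3
RNA-seq libraries of ~3×10^5 fragments, and 2 IP + 2 input libraries of
~1×10^5 fragments — large enough that every planted effect is
detectable in expectation, small enough to run in ~1–2 minutes per
experiment on one CPU. The acceptance script runs three such seeded
experiments plus one no-signal experiment; the test suite runs five.
Calibration checks compare false-positive fractions against
0.05 ± 3·sqrt(0.05·0.95/n) with n the tested units of that run. The
permutation null is additionally validated against an exhaustively
enumerable case (two 50-bp reads in a 100-bp gene: P(max depth >= 2) =
2599/2601, all 51×51 start pairs overlapping except the two at distance
exactly 50).

## Known limitations

* The event grammar anchors to annotated exon boundaries; fully novel
  exons (both splice sites unannotated) and microexons are not
  classified, and exitrons are out of scope.
* `count_fragments` requires genes to be disjoint per strand (always
  true for generated data) and leaves reads spanning gene boundaries
  unassigned rather than resolving them.
* The DEG stage tests pooled counts, not per-replicate dispersion; it is
  exact under the generator's Poisson law but not a general-purpose
  differential-expression method.
* The permutation null ignores exon structure (placement over the whole
  gene span); an exonic-placement variant would sharpen nulls for genes
  with long introns and is a natural extension.
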