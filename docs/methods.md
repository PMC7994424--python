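# Methods

## Input model and coordinates

The unit of input is a per-sample cytosine coverage file in the Bismark
coverage dialect: `chrom start end meth% meth_reads unmeth_reads` (six
columns) or the same without the percentage (five columns, counts in the
last two). Read counts are the statistical substrate; the printed
percentage is never used for computation and is only cross-checked (a
disagreement above one percentage point is logged once per file).
Internally every coordinate is 1-based and inclusive at both ends, matching
this dialect; UCSC BED inputs (0-based, half-open) are converted on read
(`start = chromStart + 1`, `end = chromEnd`; exon blocks
`(chromStart + blockStart + 1, chromStart + blockStart + blockSize)`) and
never stored raw. Sample group and replicate come from the
`<group>_<replicate>` file-name convention or from an explicit sample
sheet, which is also the only way to attach categorical covariates.

## Quality control

Two per-sample coverage rules, both strict inequalities:

* `high_quantile` (default **99.9**, percentile): sites with total coverage
  strictly above the sample's empirical percentile are dropped. This guards
  against PCR clonal reads, a library-specific artifact, which is why the
  percentile is computed per sample rather than pooled. The percentile uses
  the nearest-rank definition (k-th smallest value, k = ⌈q/100·n⌉), so an
  all-equal coverage vector loses nothing.
* `low_coveragenum` (default **10**, reads): sites with coverage strictly
  below the floor are dropped; shallow sites give unstable proportion
  estimates.

Sites are *not* required to be covered in every sample: the weighted means
tolerate missing sites naturally, and completeness is decided per
comparison (a region with zero coverage in a compared group is excluded
from that comparison and logged, never imputed).

An optional DMC pre-pass reruns the region analysis restricted to
previously significant cytosines: site-level tests → significance filter →
restriction of the count table to DMC positions, after which region means
pool DMCs only.

## Regions

From a BED12 gene set (first accession kept per gene symbol) and a merged
CpG-island track the package derives:

* **Promoter**: `[TSS − promoter_up, TSS + promoter_down − 1]` on the +
  strand, mirrored 3'→5' on the − strand; defaults **1000/1000 bp**. The
  symmetric default makes the promoter midpoint coincide with the gene
  start (+) or end (−), which is exactly the rule used to annotate a
  promoter with its gene (midpoint = ⌊(start+end)/2⌋; unmatched promoters
  are logged and left unlinked).
* **TSS**: a single base (gene start on +, gene end on −). Keeping it
  single-base makes TSS means interpretable as site-level means.
* **Exons/introns**: BED blocks and the gaps between them; ordinals are
  transcript-strand-aware (ordinal 1 = 5'-most), because "first exon" is a
  biological, not a genomic-coordinate, notion. Exons and introns partition
  the gene span exactly for canonical BED12.
* **Shores**: up to `shore_bp` (default **2000 bp**, the field-standard
  shore width) on each flank of an island, clipped at position 1, never
  overlapping any island; two shores facing each other across a short
  inter-island gap are split at the gap midpoint (the downstream island's
  shore takes the extra base when the gap length is odd — the unique
  symmetric resolution up to that one-base tie). Shores are numbered per
  chromosome in coordinate order; left/right of their island is kept as
  metadata.
* **Overlaps**: every nonempty intersection of a gene-side region (gene,
  promoter, exon, intron) with a CpG-side region (island, shore), labeled
  with both components (`Exon1-CpGi`, `Promoter-Shore3`). Gene-level
  overlaps equal the union of the per-exon/per-intron intersections with
  the same island or shore; since exons and introns tile the gene, this is
  the single interval gene ∩ island.
* **Windows**: exact tiling `[1, w], [w+1, 2w], …` per chromosome, last
  window truncated; default `windowbp` = **1,000,000**. Window density
  tables count genes/islands/shores by the window containing their midpoint.

Site-to-region containment is closed at both endpoints. A cytosine may
belong to many regions at once (exon, gene, island and their overlap).

## Testing

Weighted means pool reads: `pi = Σ meth / Σ total` over samples (and sites,
for regions). The group test is a binomial logistic regression with one
aggregated observation per sample per target and a likelihood-ratio
chi-squared statistic for the group factor (df = k − 1). The chi-squared
test is implemented as an LRT rather than a Wald test: it is stable at
boundary fits (a group with all-zero or all-one methylation has a finite
deviance by construction), and in the two-group, no-covariate case the
binomial MLE is closed-form (group-pooled proportions), making the
statistic exactly the G-statistic of the pooled 2×2 table — which the test
suite verifies against an independent contingency-table implementation to
1e-8. Covariate models are fitted by IRLS (statsmodels GLM) with the same
deviance-difference statistic; a degenerate covariate design raises an
error naming the covariate.

Multiple-testing correction is applied within each analysis family
separately (all genes; all promoters; all Exon–CpGi overlaps; …), since the
families answer different questions and have very different sizes. The
significance filter keeps `Q < 0.01` and `|diff| > 0.05` (both strict,
reading "greater/lower than" literally; `diff` is a proportion, 0.05 = 5
percentage points) and assigns hyper/hypo by the sign of group2 − group1.
With more than two groups the test uses all covered groups while `diff` is
computed for the requested pair.

Joint categorization with an expression table inner-joins filtered genes on
the gene symbol and crosses hyper/hypo with up/down (sign of logFC); genes
with logFC exactly 0 are excluded with a warning.

## Synthetic data

The generator emulates the structure the analysis assumes, so that
statistical claims about the pipeline are testable end to end:

* **Annotation**: non-overlapping genes packed into per-chromosome slots
  (2–6 exons, 4–16 kb spans), islands placed relative to gene features —
  inside promoters, straddling exon1/intron1 junctions — plus intergenic
  ones, so every overlap class is instantiated; written as standard BED.
* **Baseline methylation**: DNA methylation is locally correlated, so the
  baseline is drawn per *methylation domain* — one Beta(0.6, 0.6) draw
  (bimodal, as real methylomes are) per gene span, per island outside
  genes, and per 2 kb intergenic tile — with per-site jitter of Beta
  concentration κ = 100 around the domain mean, clipped to [0.01, 0.99]. A
  gene is one domain end to end, matching the within-region homogeneity the
  pooled binomial test assumes. Fully independent per-site baselines would
  make pooled region means differ between groups through random coverage
  weighting alone.
* **Effects**: a delta on the proportion scale added for one group inside
  selected regions; the shared baseline is squeezed so the shifted value
  stays in [0.01, 0.99] and the between-group difference is exactly delta.
* **Counts**: per sample, coverage ~ NegBin(mean 30, size 5) — realistic
  overdispersion that stresses the read weighting — and methylated reads ~
  Binomial(coverage, true pi). Zero-coverage sites are simply not written,
  as in real coverage files. Site density defaults to 1/kb genome-wide plus
  10/kb inside islands (RRBS-like enrichment).

Everything is deterministic given the seed: identical configurations yield
byte-identical files.

What the generator does **not** emulate: replicate-level biological
variation beyond binomial noise (no beta-binomial overdispersion across
samples — the analysis model has none either, so tests passing here say
nothing about robustness to it on real data), strand-specific CpG pairing,
bisulfite-conversion error, or regions that are internally heterogeneous in
truth (promoters and shores spanning domain boundaries are mildly
heterogeneous; genes are not). Calibration and FDR results on these data
therefore certify the implementation under its own model assumptions, not
performance on arbitrary real methylomes.

## Test problem sizes

The statistical tests run at sizes chosen to make their assertions
meaningful while staying quick: exact-oracle checks on 500 random weighted-
mean instances (≤10 samples × ≤20 sites, rational arithmetic) and 1,000
random 2×2 tables (1e-8 agreement); calibration and recovery on 2
chromosomes × 3 Mb (≈6,500 sites, 200 genes, 2 groups × 3 replicates), with
the null scenario checking site-level type-I error in [0.035, 0.065] at
α = 0.05 and zero gene calls, and the recovery scenario (30 genes at
delta = +0.2, coverage mean 30) requiring sensitivity ≥ 0.8 at observed
FDR ≤ 0.05. Seeds are fixed in the tests.

## Known limitations

* No beta-binomial/overdispersion correction: with real biological
  replicates the pooled binomial test is anticonservative when samples
  within a group genuinely differ; Q-values should then be read as ranking
  scores rather than calibrated error rates.
* Region heterogeneity: pooling weights sites by realized coverage, so a
  region whose sites have very different methylation can show group
  differences driven by coverage imbalance alone. The site-level analysis
  plus DMC restriction is the built-in mitigation.
* The 5-column coverage dialect is assumed to carry counts in the last two
  columns; files with other column orders need conversion.
* No isoform handling beyond the first-accession rule, no UTR/CDS
  distinction, and no enrichment-database queries or plot rendering — the
  numeric tables those would consume are all emitted.
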