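# dmrkit

Gene-based differential methylation analysis for bisulfite-sequencing data.

Most DMR callers report differentially methylated cytosines or generic
regions. `dmrkit` instead asks where methylation changes *relative to gene
architecture*: it computes methylation levels for whole genes, gene-body
features (promoters, exons, introns, TSSes — with strand-aware ordinals, so
"first exon" means the 5'-most one), CpG islands, island shores, and every
overlap between the two sides (e.g. Exon1–CpGi, Promoter–Shore), then tests
each region for a group difference and filters hyper-/hypomethylated
regions. Typical users are epigenomics groups with RRBS/WGBS case–control
designs who want gene-resolved candidates to integrate with expression data.

## Model

For one group, the methylation level of a cytosine site is the
read-weighted mean over the group's *n* samples,

    pi = ( Σᵢ MRᵢ ) / ( Σᵢ TRᵢ ),

where MRᵢ and TRᵢ are the methylated and total read counts of sample *i*.
For a region containing *m* cytosines the sums extend over sites *j*:

    pi = ( Σᵢ Σⱼ MRᵢⱼ ) / ( Σᵢ Σⱼ TRᵢⱼ ).

Reads are pooled, not averaged per site, so deeply covered sites carry more
weight. Group differences are tested with a binomial logistic regression

    ln( pi / (1 − pi) ) = u + β·Tᵢ  (+ categorical covariates),

one aggregated observation per sample, and a chi-squared likelihood-ratio
test on the group term (df = k − 1 for k groups). With two groups and no
covariates this statistic is algebraically the G-statistic of the pooled
2×2 methylated/unmethylated-by-group table. P-values are adjusted to
Q-values within each analysis family (all genes, all promoters, all
Exon–CpGi overlaps, …; methods: bonferroni, holm, hochberg, hommel, BH/fdr,
BY, none), and a region is called differentially methylated when
Q < 0.01 and |pi₂ − pi₁| > 0.05 (both strict; the difference is on the
proportion scale). Positive differences (group2 − group1) are *hyper*-,
negative ones *hypo*-methylated. See `docs/methods.md` for assumptions,
parameter choices and limitations.

## Worked example

Everything runs on synthetic data — no downloads. Simulate a two-group,
three-replicate methylome (200 genes, 30 of them with a +0.2 methylation
shift in group 2) and run the full workflow:

```sh
dmrkit --quiet simulate --outdir ex --seed 4 --affected-genes 30
dmrkit --quiet run --coverage-dir ex --refseq ex/refseq.bed \
       --cpgi ex/cpgi.bed --chrom-sizes ex/chrom.sizes --outdir ex_out
```

which prints (abridged):

```
wrote 6 coverage files, 200 genes, 134 islands to ex
CpGisland: 134 tested, 8 significant
Exon: 520 tested, 66 significant
Gene: 199 tested, 29 significant
Promoter: 179 tested, 20 significant
Site: 6535 tested, 175 significant
...
```

Per family, "tested" counts regions covered in both groups and
"significant" those passing the default filter (Q < 0.01, |diff| > 0.05,
BH). Here 29 of the 30 genes carrying a true effect are recovered. The
per-family tables land in `ex_out/`; e.g. `filtered_Gene.tsv`:

```
region_id       chrom  start  end    feature  gene   pi_1    pi_2    diff    pvalue      qvalue      direction
gene:NM_000001  chr1   12755  25472  gene     gene1  0.7397  0.9525  0.2128  3.3e-49     7.4e-48     hyper
gene:NM_000007  chr1   184492 200245 gene     gene7  0.8064  0.9853  0.1789  4.4e-69     2.2e-67     hyper
```

`pi_1`/`pi_2` are the pooled group methylation levels, `diff` their
difference (group2 − group1), and `direction` the hyper/hypo call. Sample
files are discovered by the `<group>_<replicate>.cov` naming convention; an
explicit sample sheet (`--sample-sheet`, TSV with sample_id/path/group/
replicate plus covariate columns) overrides it and enables covariates.
Subcommands `qc`, `regions`, `test`, `filter` and `density` expose single
stages; `dmrkit run --show-config` prints every default, and the library
API (`dmrkit.run_pipeline`, `dmrkit.logistic_tests`, …) mirrors the CLI.

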