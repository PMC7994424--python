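"""Shared domain types and the internal coordinate convention.

All coordinates inside the package are 1-based and inclusive at both ends,
matching the Bismark coverage dialect. BED inputs (0-based half-open) are
converted on read and never stored raw.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Tuple

#: Column schema of the long-format site table used throughout the package.
SITE_COLUMNS = ["sample_id", "chrom", "pos", "meth_reads", "unmeth_reads", "total_reads"]

#: Gene-side feature kinds that participate in overlap regions.
GENE_SIDE_KINDS = ("gene", "promoter", "exon", "intron")

#: CpG-side feature kinds that participate in overlap regions.
CPG_SIDE_KINDS = ("CpGisland", "Shore")


@dataclass(frozen=True)
class SampleSpec:
    """Identity and design information for one bisulfite library.

    ``group`` is the categorical label entering the logistic model as the
    group indicator; ``covariates`` maps covariate name to a categorical
    level shared across samples.
    """

    sample_id: str
    group: str
    replicate: int
    covariates: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValueError(f"replicate must be >= 1, got {self.replicate}")


@dataclass(frozen=True)
class GeneModel:
    """One transcription unit with its exon structure (1-based inclusive)."""

    gene_id: str
    gene_name: str
    chrom: str
    start: int
    end: int
    strand: str
    exon_intervals: Tuple[Tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")
        prev_end = None
        for (s, e) in self.exon_intervals:
            if s > e:
                raise ValueError(f"gene {self.gene_id}: exon start > end")
            if not (self.start <= s and e <= self.end):
                raise ValueError(f"gene {self.gene_id}: exon outside gene span")
            if prev_end is not None and s <= prev_end:
                raise ValueError(f"gene {self.gene_id}: exons unsorted or overlapping")
            prev_end = e


@dataclass(frozen=True)
class Region:
    """A genomic interval with a feature kind and optional gene linkage.

    ``ordinal`` numbers exons/introns along the transcript strand (1 =
    5'-most) and shores along each chromosome in coordinate order.
    For ``kind == "overlap"`` the interval is the intersection of a
    gene-side and a CpG-side component, and ``components`` carries their
    labels, e.g. ``("Exon1", "CpGi")``.
    """

    region_id: str
    chrom: str
    start: int
    end: int
    kind: str
    strand: Optional[str] = None
    ordinal: Optional[int] = None
    gene_id: Optional[str] = None
    gene_name: Optional[str] = None
    components: Optional[Tuple[str, str]] = None
    side: Optional[str] = None  # for shores: "left" | "right" of their island

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"region {self.region_id}: start > end")
        if self.ordinal is not None and self.ordinal < 1:
            raise ValueError(f"region {self.region_id}: ordinal must be >= 1")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def family(self) -> str:
        """Analysis family used for per-family multiple-testing correction."""
        if self.kind == "overlap":
            gene_part, cpg_part = self.components  # type: ignore[misc]
            return f"{_strip_ordinal(gene_part)}-{_strip_ordinal(cpg_part)}"
        return {
            "gene": "Gene",
            "promoter": "Promoter",
            "exon": "Exon",
            "intron": "Intron",
            "TSS": "TSS",
            "CpGisland": "CpGisland",
            "Shore": "Shore",
            "window": "Window",
        }[self.kind]


def _strip_ordinal(label: str) -> str:
    return label.rstrip("0123456789")


@dataclass(frozen=True)
class QcConfig:
    """Coverage-based site filter settings.

    ``high_quantile``: per-sample percentile (nearest-rank); sites with
    coverage strictly above it are dropped (PCR clonal-read guard).
    ``low_coveragenum``: sites with coverage strictly below it are dropped.
    """

    high_quantile: float = 99.9
    low_coveragenum: int = 10

    def __post_init__(self) -> None:
        if not (50 < self.high_quantile <= 100):
            raise ValueError("high_quantile must lie in (50, 100]")
        if self.low_coveragenum < 0:
            raise ValueError("low_coveragenum must be >= 0")


@dataclass(frozen=True)
class GroupMean:
    """Weighted methylation mean of one group over a site or region.

    ``pi = meth_sum / total_sum`` pools reads over samples (and sites, for
    regions) rather than averaging per-site proportions.
    """

    target_id: str
    group: str
    meth_sum: int
    total_sum: int
    pi: float
    n_sites: int
    n_samples: int


ADJUST_METHODS = ("bonferroni", "holm", "hochberg", "hommel", "BH", "fdr", "BY", "none")

ALL_FAMILIES = (
    "Site",
    "Window",
    "Gene",
    "Promoter",
    "Exon",
    "Intron",
    "TSS",
    "CpGisland",
    "Shore",
    "Gene-CpGi",
    "Gene-Shore",
    "Promoter-CpGi",
    "Promoter-Shore",
    "Exon-CpGi",
    "Exon-Shore",
    "Intron-CpGi",
    "Intron-Shore",
)


@dataclass
class RunConfig:
    """Everything the end-to-end pipeline needs.

    Numeric defaults: QC at the 99.9th coverage percentile / minimum
    coverage 10, significance at Q < 0.01 and |methylation difference| >
    0.05 (proportion scale, i.e. 5 percentage points), 1 Mb windows.
    """

    coverage_dir: Optional[str] = None
    sample_sheet: Optional[str] = None
    refseq_bed: Optional[str] = None
    cpgi_bed: Optional[str] = None
    chrom_sizes: Optional[str] = None
    expression_table: Optional[str] = None
    output_dir: str = "dmrkit_out"

    qc: QcConfig = field(default_factory=QcConfig)
    promoter_up: int = 1000
    promoter_down: int = 1000
    shore_bp: int = 2000
    windowbp: int = 1_000_000

    families: Sequence[str] = ALL_FAMILIES
    diffgroups: Optional[Tuple[str, str]] = None
    covariates: Sequence[str] = ()
    adjust_method: str = "BH"
    qvalue_cut: float = 0.01
    methdiff_cut: float = 0.05
    dmc_prepass: bool = False

    def validate(self) -> None:
        if self.coverage_dir is None and self.sample_sheet is None:
            raise ValueError("either coverage_dir or sample_sheet is required")
        if self.refseq_bed is None or self.cpgi_bed is None:
            raise ValueError("refseq_bed and cpgi_bed are required")
        if not (0 <= self.qvalue_cut <= 1):
            raise ValueError("qvalue_cut must lie in [0, 1]")
        if not (0 <= self.methdiff_cut <= 1):
            raise ValueError("methdiff_cut must lie in [0, 1] (proportion scale)")
        if self.adjust_method not in ADJUST_METHODS:
            raise ValueError(f"unknown adjustment method {self.adjust_method!r}; choices: {ADJUST_METHODS}")
        unknown = set(self.families) - set(ALL_FAMILIES)
        if unknown:
            raise ValueError(f"unknown families: {sorted(unknown)}; choices: {ALL_FAMILIES}")
        if self.covariates and self.sample_sheet is None:
            raise ValueError("covariates require an explicit sample sheet")
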