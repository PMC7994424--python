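"""Readers and writers for every external format the tool touches.

Supported inputs: Bismark-style coverage files (5 or 6 whitespace/tab
delimited columns, optionally gzipped), UCSC BED12 gene models, BED3+ CpG
island tracks, a delimited expression table (gene name + logFC), an
optional sample sheet, and chrom.sizes. All BED coordinates are converted
to the internal 1-based inclusive convention on read.
"""

from __future__ import annotations

import gzip
import logging
import os
import re
from typing import Dict, IO, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import GeneModel, Region, SampleSpec, SITE_COLUMNS

logger = logging.getLogger(__name__)

COVERAGE_EXTENSIONS = (".bismark.cov.gz", ".bismark.cov", ".cov.gz", ".cov", ".txt", ".gz")

RESULT_COLUMNS = [
    "region_id",
    "chrom",
    "start",
    "end",
    "feature",
    "ordinal",
    "gene",
]


class ParseError(ValueError):
    """Malformed input file; the message names the file and line."""


def _open_text(path: str) -> IO[str]:
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_coverage(path: str, sample_id: Optional[str] = None) -> pd.DataFrame:
    """Read one per-sample cytosine coverage file.

    The 6-column dialect is ``chrom start end meth% meth_reads
    unmeth_reads``; the 5-column dialect drops the percentage. The printed
    percentage is never used for computation — methylated/unmethylated read
    counts are the statistical substrate — but a disagreement of more than
    one percentage point with the counts is logged once per file.

    Returns a DataFrame with :data:`dmrkit.core.SITE_COLUMNS`, one row per
    cytosine, ``pos`` taken from the start column.
    """
    if sample_id is None:
        sample_id = strip_coverage_extension(os.path.basename(path))
    try:
        with _open_text(path) as fh:
            raw = pd.read_csv(fh, sep=r"\s+", header=None, dtype=str)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty coverage file") from None
    if raw.empty:
        raise ParseError(f"{path}: empty coverage file")
    ncol = raw.shape[1]
    if ncol == 6:
        raw.columns = ["chrom", "start", "end", "pct", "meth_reads", "unmeth_reads"]
    elif ncol == 5:
        raw.columns = ["chrom", "start", "end", "meth_reads", "unmeth_reads"]
    else:
        raise ParseError(f"{path}: expected 5 or 6 columns, found {ncol}")

    def _to_int(col: str) -> np.ndarray:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() | (converted != converted.round())
        if bad.any():
            line = int(bad.idxmax()) + 1
            raise ParseError(f"{path}: line {line}: non-integer value in column {col!r}")
        return converted.astype(np.int64).to_numpy()

    start = _to_int("start")
    end = _to_int("end")
    mismatched = start != end
    if mismatched.any():
        line = int(np.argmax(mismatched)) + 1
        raise ParseError(f"{path}: line {line}: start != end for a single-cytosine record")
    meth = _to_int("meth_reads")
    unmeth = _to_int("unmeth_reads")
    if (meth < 0).any() or (unmeth < 0).any():
        raise ParseError(f"{path}: negative read counts")
    if (start < 1).any():
        line = int(np.argmax(start < 1)) + 1
        raise ParseError(f"{path}: line {line}: position must be >= 1")

    sites = pd.DataFrame(
        {
            "sample_id": sample_id,
            "chrom": raw["chrom"].to_numpy(),
            "pos": start,
            "meth_reads": meth,
            "unmeth_reads": unmeth,
            "total_reads": meth + unmeth,
        }
    )
    dup = sites.duplicated(["chrom", "pos"])
    if dup.any():
        line = int(dup.idxmax()) + 1
        raise ParseError(f"{path}: line {line}: duplicate record for the same (chrom, pos)")

    if ncol == 6:
        pct = pd.to_numeric(raw["pct"], errors="coerce").to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            recomputed = np.where(
                sites["total_reads"] > 0, 100.0 * meth / np.maximum(sites["total_reads"], 1), 0.0
            )
        disagree = np.abs(pct - recomputed) > 1.0
        if np.nan_to_num(disagree).any():
            logger.warning(
                "%s: %d rows where the printed methylation %% disagrees with the "
                "counts by >1 point; counts are used",
                path,
                int(np.nansum(disagree)),
            )
    return sites


def strip_coverage_extension(filename: str) -> str:
    for ext in COVERAGE_EXTENSIONS:
        if filename.endswith(ext):
            return filename[: -len(ext)]
    return os.path.splitext(filename)[0]


_SAMPLE_NAME_RE = re.compile(r"^(?P<group>[^_]+)_(?P<replicate>\d+)$")


def parse_sample_name(filename: str) -> SampleSpec:
    """Derive group/replicate from a ``<group>_<replicate>`` file name.

    ``"2_1.bismark.cov"`` parses to group ``"2"``, replicate 1. Names not
    matching the convention raise, pointing the user at an explicit sample
    sheet (which also carries covariates).
    """
    base = strip_coverage_extension(os.path.basename(filename))
    m = _SAMPLE_NAME_RE.match(base)
    if not m:
        raise ValueError(
            f"cannot derive group/replicate from file name {filename!r} "
            "(expected '<group>_<replicate>', e.g. '1_2.cov'); "
            "provide an explicit sample sheet instead"
        )
    return SampleSpec(sample_id=base, group=m.group("group"), replicate=int(m.group("replicate")))


def read_sample_sheet(path: str) -> Tuple[List[SampleSpec], Dict[str, str]]:
    """Read a TSV sample sheet: sample_id, path, group, replicate, [covariates...].

    Any extra column is treated as a categorical covariate. Returns the
    sample specs and a mapping sample_id -> coverage-file path.
    """
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "path", "group", "replicate"}
    missing = required - set(sheet.columns)
    if missing:
        raise ParseError(f"{path}: sample sheet missing columns {sorted(missing)}")
    covariate_cols = [c for c in sheet.columns if c not in required]
    specs: List[SampleSpec] = []
    paths: Dict[str, str] = {}
    for _, row in sheet.iterrows():
        specs.append(
            SampleSpec(
                sample_id=row["sample_id"],
                group=row["group"],
                replicate=int(row["replicate"]),
                covariates={c: row[c] for c in covariate_cols},
            )
        )
        paths[row["sample_id"]] = row["path"]
    if len(paths) != len(specs):
        raise ParseError(f"{path}: duplicate sample_id in sample sheet")
    return specs, paths


def read_bed12(path: str) -> List[GeneModel]:
    """Read UCSC BED12 gene models into 1-based inclusive :class:`GeneModel`.

    internal start = chromStart + 1, internal end = chromEnd; each exon is
    (chromStart + blockStart + 1, chromStart + blockStart + blockSize).
    """
    genes: List[GeneModel] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 12:
                raise ParseError(f"{path}: line {lineno}: BED12 requires 12 fields, found {len(fields)}")
            chrom = fields[0]
            chrom_start = int(fields[1])
            chrom_end = int(fields[2])
            name = fields[3]
            strand = fields[5]
            block_count = int(fields[9])
            block_sizes = [int(x) for x in fields[10].rstrip(",").split(",") if x != ""]
            block_starts = [int(x) for x in fields[11].rstrip(",").split(",") if x != ""]
            if len(block_sizes) != block_count or len(block_starts) != block_count:
                raise ParseError(
                    f"{path}: line {lineno}: blockCount={block_count} inconsistent with "
                    f"{len(block_sizes)} sizes / {len(block_starts)} starts"
                )
            exons = tuple(
                (chrom_start + off + 1, chrom_start + off + size)
                for off, size in zip(block_starts, block_sizes)
            )
            gene_id, gene_name = _split_bed_name(name)
            genes.append(
                GeneModel(
                    gene_id=gene_id,
                    gene_name=gene_name,
                    chrom=chrom,
                    start=chrom_start + 1,
                    end=chrom_end,
                    strand=strand,
                    exon_intervals=exons,
                )
            )
    return genes


def _split_bed_name(name: str) -> Tuple[str, str]:
    # Accession and symbol may be packed as "NM_001|Adora1"; otherwise the
    # single token serves as both.
    if "|" in name:
        gene_id, gene_name = name.split("|", 1)
        return gene_id, gene_name
    return name, name


def read_cpgi_bed(path: str) -> List[Region]:
    """Read a BED3+ CpG-island track; islands are sorted and overlapping
    islands merged (with a logged warning)."""
    rows = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ParseError(f"{path}: line {lineno}: BED requires >= 3 fields")
            rows.append((fields[0], int(fields[1]) + 1, int(fields[2])))
    rows.sort()
    merged: List[Tuple[str, int, int]] = []
    n_merged = 0
    for chrom, start, end in rows:
        if merged and merged[-1][0] == chrom and start <= merged[-1][2]:
            prev = merged.pop()
            merged.append((chrom, prev[1], max(prev[2], end)))
            n_merged += 1
        else:
            merged.append((chrom, start, end))
    if n_merged:
        logger.warning("%s: merged %d overlapping CpG islands", path, n_merged)
    islands = []
    counter: Dict[str, int] = {}
    for chrom, start, end in merged:
        counter[chrom] = counter.get(chrom, 0) + 1
        islands.append(
            Region(
                region_id=f"cpgi:{chrom}:{counter[chrom]}",
                chrom=chrom,
                start=start,
                end=end,
                kind="CpGisland",
                ordinal=counter[chrom],
            )
        )
    return islands


def read_chrom_sizes(path: str) -> Dict[str, int]:
    sizes = pd.read_csv(path, sep=r"\s+", header=None, names=["chrom", "size"], dtype={"chrom": str})
    return dict(zip(sizes["chrom"], sizes["size"].astype(int)))


def read_expression(path: str) -> pd.DataFrame:
    """Read a differential-expression table with gene name and logFC columns.

    Column names containing 'gene' and 'logfc'/'log_fc'/'lfc' are used when
    present; otherwise the first two columns are taken as (gene_name, logfc).
    Duplicate gene names are an error.
    """
    table = pd.read_csv(path, sep=None, engine="python")
    cols = {c.lower().replace("_", "").replace(".", ""): c for c in table.columns}
    gene_col = next((cols[k] for k in cols if "gene" in k), table.columns[0])
    logfc_col = next((cols[k] for k in cols if k in ("logfc", "lfc") or "logfc" in k), None)
    if logfc_col is None:
        if table.shape[1] < 2:
            raise ParseError(f"{path}: expression table needs gene and logFC columns")
        logfc_col = table.columns[1]
    out = table[[gene_col, logfc_col]].rename(columns={gene_col: "gene_name", logfc_col: "logfc"})
    out["logfc"] = pd.to_numeric(out["logfc"], errors="raise")
    if out["logfc"].isna().any():
        raise ParseError(f"{path}: missing logFC value")
    if out["gene_name"].duplicated().any():
        dup = out.loc[out["gene_name"].duplicated(), "gene_name"].iloc[0]
        raise ParseError(f"{path}: duplicate gene name {dup!r} in expression table")
    return out.reset_index(drop=True)


def write_results(results: pd.DataFrame, path: str) -> str:
    """Write a result table as TSV with the fixed schema and deterministic order.

    Expected columns: region_id, chrom, start, end, feature, ordinal, gene,
    pi_<group> per group, diff, pvalue, qvalue, direction. Rows are sorted by
    (chrom, start, region_id); floats are printed at 10 significant digits so
    reruns are byte-identical.
    """
    if results.empty:
        logger.warning("%s: writing header-only result file (no results)", path)
    pi_cols = [c for c in results.columns if c.startswith("pi_")]
    columns = RESULT_COLUMNS + pi_cols + ["diff", "pvalue", "qvalue", "direction"]
    out = results.reindex(columns=columns)
    if not out.empty:
        out = out.sort_values(["chrom", "start", "region_id"], kind="mergesort")
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


def write_sites_table(sites: pd.DataFrame, path: str) -> str:
    """Persist a long-format site table (intermediate pipeline artifact)."""
    sites.reindex(columns=SITE_COLUMNS).sort_values(
        ["sample_id", "chrom", "pos"], kind="mergesort"
    ).to_csv(path, sep="\t", index=False)
    return path


def read_sites_table(path: str) -> pd.DataFrame:
    sites = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample_id": str})
    missing = set(SITE_COLUMNS) - set(sites.columns)
    if missing:
        raise ParseError(f"{path}: site table missing columns {sorted(missing)}")
    return sites


def discover_coverage_files(directory: str) -> Dict[str, str]:
    """Find coverage files in a directory, keyed by sample id from the file name."""
    found: Dict[str, str] = {}
    for entry in sorted(os.listdir(directory)):
        if any(entry.endswith(ext) for ext in (".cov", ".cov.gz", ".bismark.cov", ".bismark.cov.gz")):
            sample_id = strip_coverage_extension(entry)
            found[sample_id] = os.path.join(directory, entry)
    if not found:
        raise FileNotFoundError(f"no coverage files (*.cov[.gz]) found in {directory}")
    return found


def write_regions_bed(regions: Sequence[Region], path: str) -> str:
    """Export derived regions back to 0-based half-open BED for browser checks."""
    with open(path, "w") as fh:
        for r in sorted(regions, key=lambda r: (r.chrom, r.start, r.region_id)):
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.region_id}\t0\t{r.strand or '.'}\n")
    return path
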