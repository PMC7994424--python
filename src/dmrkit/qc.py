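"""Coverage-based quality control of cytosine sites.

Two per-sample rules, both with strict inequalities: sites whose read
coverage exceeds that sample's empirical high percentile are discarded
(PCR clonal-read guard) and sites with coverage below a floor are discarded
(unstable methylation-percentage estimates). The percentile uses the
nearest-rank definition, so with all-equal coverages nothing is dropped by
the upper rule. Sites are not required to be covered in every sample; the
statistical layer handles per-comparison completeness.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Tuple

import numpy as np
import pandas as pd

from .core import QcConfig

logger = logging.getLogger(__name__)


def nearest_rank_percentile(values: np.ndarray, percentile: float) -> float:
    """Nearest-rank empirical percentile: the k-th smallest value with
    k = ceil(percentile/100 * n)."""
    arr = np.sort(np.asarray(values))
    if arr.size == 0:
        raise ValueError("cannot take a percentile of an empty set")
    k = max(1, math.ceil(percentile / 100.0 * arr.size))
    return float(arr[min(k, arr.size) - 1])


def qc_filter(sites: pd.DataFrame, cfg: QcConfig = QcConfig()) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Apply both coverage rules per sample.

    Returns the surviving sites and a per-sample report with the number of
    sites dropped by each rule. A sample losing every site is an error.
    """
    kept_parts = []
    report_rows = []
    for sample_id, block in sites.groupby("sample_id", sort=True):
        coverage = block["total_reads"].to_numpy()
        cutoff = nearest_rank_percentile(coverage, cfg.high_quantile)
        too_high = coverage > cutoff
        too_low = coverage < cfg.low_coveragenum
        keep = ~(too_high | too_low)
        if not keep.any():
            raise ValueError(
                f"sample {sample_id!r} lost all {len(block)} sites during QC "
                f"(high cutoff {cutoff}, low cutoff {cfg.low_coveragenum})"
            )
        kept_parts.append(block.loc[keep])
        report_rows.append(
            {
                "sample_id": sample_id,
                "n_input": int(len(block)),
                "high_cutoff": cutoff,
                "n_dropped_high": int(too_high.sum()),
                "n_dropped_low": int((too_low & ~too_high).sum()),
                "n_retained": int(keep.sum()),
            }
        )
    filtered = pd.concat(kept_parts, ignore_index=True)
    report = pd.DataFrame(report_rows)
    for row in report.itertuples(index=False):
        logger.info(
            "QC %s: %d sites in, %d dropped high (> %.6g), %d dropped low (< %d), %d retained",
            row.sample_id,
            row.n_input,
            row.n_dropped_high,
            row.high_cutoff,
            row.n_dropped_low,
            cfg.low_coveragenum,
            row.n_retained,
        )
    return filtered, report


def dmc_restrict(sites: pd.DataFrame, dmcs: Iterable[Tuple[str, int]]) -> pd.DataFrame:
    """Keep only records at previously identified DMC positions, all samples.

    ``dmcs`` is an iterable of (chrom, pos) pairs (or a DataFrame with those
    columns) produced by the site-level significance filter. Region means
    computed downstream then pool DMCs only. An empty DMC set is an error —
    there is nothing left to compute.
    """
    if isinstance(dmcs, pd.DataFrame):
        keys = dmcs[["chrom", "pos"]].drop_duplicates()
    else:
        keys = pd.DataFrame(list(dmcs), columns=["chrom", "pos"]).drop_duplicates()
    if keys.empty:
        raise ValueError("no DMCs to restrict to; the site-level filter returned nothing")
    restricted = sites.merge(keys, on=["chrom", "pos"], how="inner")
    logger.info(
        "DMC restriction: %d of %d site records retained at %d DMC positions",
        len(restricted),
        len(sites),
        len(keys),
    )
    return restricted.reset_index(drop=True)
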