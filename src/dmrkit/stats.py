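"""Weighted methylation means, logistic-regression tests, and filtering.

The methylation level of a site for one group is the read-weighted mean
pi = (sum_i MR_i) / (sum_i TR_i) over the group's samples; for a region it
additionally pools the m cytosines assigned to the region,
pi = (sum_i sum_j MR_ij) / (sum_i sum_j TR_ij). Group differences are
tested with a binomial logistic regression ln(pi/(1-pi)) = u + beta*T,
one aggregated observation per sample, and a chi-squared likelihood-ratio
test on the group term (df = number of groups - 1). With two groups and no
covariates the likelihood-ratio statistic reduces algebraically to the
G-statistic of the pooled 2x2 methylated/unmethylated-by-group table.
P-values are adjusted to Q-values within each analysis family, and regions
pass the significance filter when Q < qvalue_cut and |difference| >
methdiff_cut (strict), with direction hyper/hypo by the sign of
group2 - group1.
"""

from __future__ import annotations

import logging
import os
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import xlogy
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from . import io as dio
from . import qc as dqc
from . import regions as dregions
from .core import (
    ADJUST_METHODS,
    ALL_FAMILIES,
    GroupMean,
    QcConfig,
    Region,
    RunConfig,
    SampleSpec,
)

logger = logging.getLogger(__name__)

_STATSMODELS_METHOD = {
    "bonferroni": "bonferroni",
    "holm": "holm",
    "hochberg": "simes-hochberg",
    "hommel": "hommel",
    "BH": "fdr_bh",
    "fdr": "fdr_bh",
    "BY": "fdr_by",
}


def samples_frame(samples: Sequence[SampleSpec]) -> pd.DataFrame:
    """Tabulate sample specs; covariates become one column each."""
    covariate_names = sorted({name for s in samples for name in s.covariates})
    rows = []
    for s in samples:
        row = {"sample_id": s.sample_id, "group": s.group, "replicate": s.replicate}
        for name in covariate_names:
            row[name] = s.covariates.get(name)
        rows.append(row)
    frame = pd.DataFrame(rows)
    if frame["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id among samples")
    return frame


# ---------------------------------------------------------------------------
# Weighted means
# ---------------------------------------------------------------------------

def site_group_mean(sites: pd.DataFrame, samples: Sequence[SampleSpec], group: str) -> GroupMean:
    """Read-weighted methylation mean of one cytosine site for one group.

    ``sites`` holds the records of a single (chrom, pos) across samples.
    Zero total coverage in the group excludes the site (raises).
    """
    keys = sites[["chrom", "pos"]].drop_duplicates()
    if len(keys) != 1:
        raise ValueError("site_group_mean expects records of exactly one (chrom, pos)")
    chrom, pos = keys.iloc[0]["chrom"], int(keys.iloc[0]["pos"])
    members = {s.sample_id for s in samples if s.group == group}
    block = sites[sites["sample_id"].isin(members)]
    meth = int(block["meth_reads"].sum())
    total = int(block["total_reads"].sum())
    if total == 0:
        raise ValueError(f"site {chrom}:{pos} has zero coverage in group {group!r}")
    return GroupMean(
        target_id=f"site:{chrom}:{pos}",
        group=group,
        meth_sum=meth,
        total_sum=total,
        pi=meth / total,
        n_sites=1,
        n_samples=int((block["total_reads"] > 0).sum()),
    )


def region_group_mean(
    assignments: pd.DataFrame,
    sites: pd.DataFrame,
    samples: Sequence[SampleSpec],
    group: str,
    region_id: str,
) -> GroupMean:
    """Read-weighted methylation mean of one region for one group, pooling
    all cytosines assigned to the region over the group's samples."""
    members = {s.sample_id for s in samples if s.group == group}
    keys = assignments.loc[assignments["region_id"] == region_id, ["chrom", "pos"]]
    block = sites.merge(keys, on=["chrom", "pos"], how="inner")
    block = block[block["sample_id"].isin(members)]
    meth = int(block["meth_reads"].sum())
    total = int(block["total_reads"].sum())
    if total == 0:
        raise ValueError(f"region {region_id!r} has zero coverage in group {group!r}")
    return GroupMean(
        target_id=region_id,
        group=group,
        meth_sum=meth,
        total_sum=total,
        pi=meth / total,
        n_sites=int(block[["chrom", "pos"]].drop_duplicates().shape[0]),
        n_samples=int(block.loc[block["total_reads"] > 0, "sample_id"].nunique()),
    )


def _group_sums(counts: pd.DataFrame, sample_groups: pd.DataFrame) -> pd.DataFrame:
    """Per (target_id, group) pooled meth/total sums from per-sample counts."""
    merged = counts.merge(sample_groups[["sample_id", "group"]], on="sample_id", how="inner")
    agg = (
        merged.groupby(["target_id", "group"], sort=True)[["meth", "total"]]
        .sum()
        .reset_index()
    )
    return agg[agg["total"] > 0]


# ---------------------------------------------------------------------------
# Logistic-regression likelihood-ratio tests
# ---------------------------------------------------------------------------

def logistic_tests(
    counts: pd.DataFrame,
    samples: Sequence[SampleSpec],
    diffgroups: Tuple[str, str],
    covariates: Sequence[str] = (),
) -> pd.DataFrame:
    """Test every target for a group effect on methylation.

    ``counts`` is long-format with columns target_id, sample_id, meth,
    total — one aggregated binomial observation per sample per target.
    The group factor enters the logistic model with (k-1) indicators; the
    p-value is the upper chi-squared tail of the deviance difference between
    the models without and with the group term. ``diff`` is
    pi(diffgroups[1]) - pi(diffgroups[0]) from the pooled weighted means.

    Targets with zero coverage in either compared group are excluded (and
    counted in the log); groups without coverage at a target drop out of
    that target's fit.

    Without covariates the binomial MLE under both models is closed-form
    (pooled proportions), so the deviance difference is computed directly;
    with covariates each target is fitted by IRLS (statsmodels GLM).
    """
    frame = samples_frame(samples)
    groups = sorted(frame["group"].unique())
    if len(groups) < 2:
        raise ValueError("differential testing requires >= 2 groups")
    g1, g2 = diffgroups
    for g in (g1, g2):
        if g not in groups:
            raise ValueError(f"diffgroup {g!r} not among sample groups {groups}")

    agg = _group_sums(counts, frame)
    meth = agg.pivot(index="target_id", columns="group", values="meth")
    total = agg.pivot(index="target_id", columns="group", values="total")
    covered = total.notna()
    usable = covered.get(g1, False) & covered.get(g2, False) & (covered.sum(axis=1) >= 2)
    n_excluded = int((~usable).sum())
    if n_excluded:
        logger.info(
            "%d of %d targets excluded: no coverage in one of the compared groups",
            n_excluded,
            len(usable),
        )
    meth = meth.loc[usable].fillna(0.0)
    total = total.loc[usable].fillna(0.0)
    if meth.empty:
        return pd.DataFrame(
            columns=["target_id", "pvalue", "diff", "statistic", "df"]
            + [f"pi_{g}" for g in groups]
        )

    if not covariates:
        stat, df = _lrt_closed_form(meth.to_numpy(), total.to_numpy())
    else:
        stat, df = _lrt_glm(meth, total, counts, frame, covariates)

    pvalue = chi2.sf(stat, np.maximum(df, 1))
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = meth.to_numpy() / np.where(total.to_numpy() > 0, total.to_numpy(), np.nan)
    pi_frame = pd.DataFrame(pi, index=meth.index, columns=[f"pi_{g}" for g in meth.columns])
    out = pd.DataFrame(
        {
            "target_id": meth.index,
            "statistic": stat,
            "df": df,
            "pvalue": pvalue,
            "diff": pi_frame[f"pi_{g2}"].to_numpy() - pi_frame[f"pi_{g1}"].to_numpy(),
        }
    )
    out = pd.concat([out.reset_index(drop=True), pi_frame.reset_index(drop=True)], axis=1)
    return out


def _lrt_closed_form(meth: np.ndarray, total: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Deviance difference between the group logistic model and the
    intercept-only model, from the pooled binomial MLEs.

    Because the fitted probability of every observation equals its group's
    pooled proportion (full model) or the overall pooled proportion (null),
    per-sample log-likelihood terms collapse onto the group sums.
    """
    unmeth = total - meth
    with np.errstate(invalid="ignore", divide="ignore"):
        ll_full = np.nansum(
            xlogy(meth, np.where(total > 0, meth / np.where(total > 0, total, 1), 0))
            + xlogy(unmeth, np.where(total > 0, unmeth / np.where(total > 0, total, 1), 0)),
            axis=1,
        )
    m_sum = meth.sum(axis=1)
    t_sum = total.sum(axis=1)
    u_sum = t_sum - m_sum
    ll_null = xlogy(m_sum, m_sum / t_sum) + xlogy(u_sum, u_sum / t_sum)
    stat = np.maximum(2.0 * (ll_full - ll_null), 0.0)
    df = (total > 0).sum(axis=1) - 1
    return stat, df


def _lrt_glm(
    meth: pd.DataFrame,
    total: pd.DataFrame,
    counts: pd.DataFrame,
    frame: pd.DataFrame,
    covariates: Sequence[str],
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-target IRLS fits with categorical covariates (statsmodels GLM)."""
    import statsmodels.api as sm

    for cov in covariates:
        if cov not in frame.columns:
            raise ValueError(f"covariate {cov!r} not present in the sample specs")
        if frame[cov].isna().any():
            raise ValueError(f"covariate {cov!r} missing for some samples")

    design = frame[["sample_id", "group", *covariates]].copy()
    cov_dummies = (
        pd.get_dummies(design[list(covariates)], drop_first=True, dtype=float)
        if covariates
        else pd.DataFrame(index=design.index)
    )
    group_dummies = pd.get_dummies(design["group"], prefix="group", drop_first=True, dtype=float)

    base = np.column_stack([np.ones(len(design))] + ([cov_dummies.to_numpy()] if len(cov_dummies.columns) else []))
    if np.linalg.matrix_rank(base) < base.shape[1]:
        for cov in covariates:
            d = pd.get_dummies(design[[cov]], drop_first=True, dtype=float).to_numpy()
            x = np.column_stack([np.ones(len(design)), d])
            if np.linalg.matrix_rank(x) < x.shape[1]:
                raise ValueError(f"singular design: covariate {cov!r} is degenerate")
        raise ValueError(f"singular design among covariates {list(covariates)}")

    by_target = {t: b for t, b in counts.groupby("target_id")}
    stats_out = np.empty(len(meth.index))
    dfs_out = np.empty(len(meth.index), dtype=int)
    for i, target in enumerate(meth.index):
        block = by_target[target].merge(design, on="sample_id")
        block = block[block["total"] > 0]
        idx = block.index
        endog = np.column_stack([block["meth"].to_numpy(), (block["total"] - block["meth"]).to_numpy()])
        ones = np.ones(len(block))
        x_null_parts = [ones]
        x_full_parts = [ones]
        if len(cov_dummies.columns):
            x_null_parts.append(cov_dummies.loc[idx].to_numpy())
            x_full_parts.append(cov_dummies.loc[idx].to_numpy())
        gdum = group_dummies.loc[idx]
        present = [c for c in gdum.columns if gdum[c].sum() > 0]
        x_full_parts.append(gdum[present].to_numpy())
        x_null = np.column_stack(x_null_parts)
        x_full = np.column_stack(x_full_parts)
        fit_null = sm.GLM(endog, x_null, family=sm.families.Binomial()).fit()
        fit_full = sm.GLM(endog, x_full, family=sm.families.Binomial()).fit()
        stats_out[i] = max(fit_null.deviance - fit_full.deviance, 0.0)
        dfs_out[i] = len(present)
    return stats_out, dfs_out


def logistic_test(
    target_id: str,
    counts_by_sample: pd.DataFrame,
    samples: Sequence[SampleSpec],
    diffgroups: Tuple[str, str],
    covariates: Sequence[str] = (),
) -> Tuple[float, float]:
    """Single-target convenience wrapper; returns (pvalue, diff).

    ``counts_by_sample`` needs columns sample_id, meth, total.
    """
    counts = counts_by_sample.copy()
    counts["target_id"] = target_id
    result = logistic_tests(counts, samples, diffgroups, covariates)
    if result.empty:
        raise ValueError(
            f"target {target_id!r} has zero coverage in one of the compared groups"
        )
    row = result.iloc[0]
    return float(row["pvalue"]), float(row["diff"])


# ---------------------------------------------------------------------------
# Multiple testing and filtering
# ---------------------------------------------------------------------------

def adjust_pvalues(pvalues: Sequence[float], method: str = "BH") -> np.ndarray:
    """Adjust p-values to Q-values; input order is preserved.

    Supported: bonferroni, holm, hochberg, hommel, BH (alias fdr), BY, none.
    """
    arr = np.asarray(pvalues, dtype=float)
    if arr.size and (np.nanmin(arr) < 0 or np.nanmax(arr) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "none":
        return arr.copy()
    if method not in _STATSMODELS_METHOD:
        raise ValueError(f"unknown adjustment method {method!r}; choices: {ADJUST_METHODS}")
    if arr.size == 0:
        return arr.copy()
    return multipletests(arr, method=_STATSMODELS_METHOD[method])[1]


def significant_filter(
    results: pd.DataFrame, qvalue_cut: float = 0.01, methdiff_cut: float = 0.05
) -> pd.DataFrame:
    """Keep targets with Q-value < ``qvalue_cut`` and |diff| > ``methdiff_cut``.

    Both inequalities are strict; ``methdiff_cut`` is on the proportion
    scale (0.05 = 5 percentage points). Survivors are labeled hyper
    (diff > 0) or hypo (diff < 0).
    """
    keep = (results["qvalue"] < qvalue_cut) & (results["diff"].abs() > methdiff_cut)
    out = results.loc[keep].copy()
    out["direction"] = np.where(out["diff"] > 0, "hyper", "hypo")
    return out.reset_index(drop=True)


def categorize_with_expression(dmgs: pd.DataFrame, expression: pd.DataFrame) -> pd.DataFrame:
    """Cross hyper/hypo DMGs with up/down expression into four categories.

    Inner join on gene name; logFC > 0 is "up", < 0 "down", exactly 0 is
    excluded with a warning. Genes present on only one side are dropped and
    counted in the log.
    """
    dmg = dmgs.dropna(subset=["gene"]).copy()
    joined = dmg.merge(expression, left_on="gene", right_on="gene_name", how="inner")
    n_unmatched = dmg["gene"].nunique() - joined["gene"].nunique()
    if n_unmatched:
        logger.info("%d DMGs absent from the expression table were dropped", n_unmatched)
    zero = joined["logfc"] == 0
    if zero.any():
        logger.warning("%d genes with logFC == 0 excluded from categorization", int(zero.sum()))
        joined = joined[~zero]
    reg = np.where(joined["logfc"] > 0, "up", "down")
    joined["category"] = joined["direction"] + "-" + reg
    return joined[["gene", "direction", "logfc", "category"]].reset_index(drop=True)


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

def _load_samples(cfg: RunConfig) -> Tuple[List[SampleSpec], Dict[str, str]]:
    if cfg.sample_sheet:
        return dio.read_sample_sheet(cfg.sample_sheet)
    paths = dio.discover_coverage_files(cfg.coverage_dir)
    specs = [dio.parse_sample_name(p) for p in paths.values()]
    return specs, {s.sample_id: paths[s.sample_id] for s in specs}


def _site_counts_long(sites: pd.DataFrame) -> pd.DataFrame:
    counts = sites[["sample_id", "chrom", "pos", "meth_reads", "total_reads"]].copy()
    counts["target_id"] = "site:" + counts["chrom"].astype(str) + ":" + counts["pos"].astype(str)
    return counts.rename(columns={"meth_reads": "meth", "total_reads": "total"})[
        ["target_id", "sample_id", "meth", "total"]
    ]


def site_tests(
    sites: pd.DataFrame,
    samples: Sequence[SampleSpec],
    diffgroups: Tuple[str, str],
    covariates: Sequence[str] = (),
    adjust_method: str = "BH",
) -> pd.DataFrame:
    """Per-cytosine differential tests with family-wide Q-values attached."""
    results = logistic_tests(_site_counts_long(sites), samples, diffgroups, covariates)
    results["qvalue"] = adjust_pvalues(results["pvalue"].to_numpy(), adjust_method)
    parts = results["target_id"].str.split(":", n=2, expand=True)
    results.insert(1, "chrom", parts[1])
    results.insert(2, "pos", parts[2].astype(int))
    return results


def region_tests(
    assignments: pd.DataFrame,
    sites: pd.DataFrame,
    samples: Sequence[SampleSpec],
    diffgroups: Tuple[str, str],
    covariates: Sequence[str] = (),
) -> pd.DataFrame:
    """Per-region differential tests from site assignments (no adjustment)."""
    merged = assignments.merge(sites, on=["chrom", "pos"], how="inner")
    counts = (
        merged.groupby(["region_id", "sample_id"], sort=True)[["meth_reads", "total_reads"]]
        .sum()
        .reset_index()
        .rename(columns={"region_id": "target_id", "meth_reads": "meth", "total_reads": "total"})
    )
    n_sites = (
        merged[["region_id", "chrom", "pos"]]
        .drop_duplicates()
        .groupby("region_id")
        .size()
        .rename("n_sites")
    )
    results = logistic_tests(counts, samples, diffgroups, covariates)
    return results.merge(n_sites, left_on="target_id", right_index=True, how="left")


def run_pipeline(cfg: RunConfig) -> Dict[str, object]:
    """Execute the full workflow: read, QC, optional DMC pre-pass, region
    derivation, assignment, means, tests, adjustment, filter, writers.

    Returns a dict with the per-family result frames ("results",
    "filtered"), the QC report, window densities, expression categories and
    all written paths.
    """
    cfg.validate()
    os.makedirs(cfg.output_dir, exist_ok=True)
    paths_out: Dict[str, str] = {}

    samples, coverage_paths = _load_samples(cfg)
    frame = samples_frame(samples)
    logger.info("pipeline: %d samples, groups %s", len(samples), sorted(frame["group"].unique()))
    sites = pd.concat(
        [dio.read_coverage(coverage_paths[s.sample_id], s.sample_id) for s in samples],
        ignore_index=True,
    )
    logger.info("pipeline: %d site records read", len(sites))

    sites_qc, qc_report = dqc.qc_filter(sites, cfg.qc)
    paths_out["qc_report"] = os.path.join(cfg.output_dir, "qc_report.tsv")
    qc_report.to_csv(paths_out["qc_report"], sep="\t", index=False)
    paths_out["sites_qc"] = dio.write_sites_table(
        sites_qc, os.path.join(cfg.output_dir, "sites_qc.tsv")
    )

    groups = sorted(frame["group"].unique())
    diffgroups = tuple(cfg.diffgroups) if cfg.diffgroups else (groups[0], groups[1])

    site_results = site_tests(
        sites_qc, samples, diffgroups, cfg.covariates, cfg.adjust_method
    )
    if cfg.dmc_prepass:
        dmcs = significant_filter(site_results, cfg.qvalue_cut, cfg.methdiff_cut)
        logger.info("DMC pre-pass: %d DMCs at q<%g, |diff|>%g", len(dmcs), cfg.qvalue_cut, cfg.methdiff_cut)
        sites_qc = dqc.dmc_restrict(sites_qc, dmcs[["chrom", "pos"]])

    genes = dregions.dedupe_gene_ids(dio.read_bed12(cfg.refseq_bed))
    islands = dio.read_cpgi_bed(cfg.cpgi_bed)
    logger.info("pipeline: %d genes (after first-ID rule), %d CpG islands", len(genes), len(islands))

    gene_feats = dregions.derive_gene_features(genes, cfg.promoter_up, cfg.promoter_down)
    cpgi_feats = dregions.derive_cpgi_features(islands, cfg.shore_bp)
    overlaps = dregions.intersect_features(gene_feats, cpgi_feats)

    if cfg.chrom_sizes:
        chrom_sizes = dio.read_chrom_sizes(cfg.chrom_sizes)
    else:
        ends = [r.end for r in gene_feats + cpgi_feats]
        bound = pd.DataFrame(
            {"chrom": [r.chrom for r in gene_feats + cpgi_feats], "end": ends}
        )
        site_max = sites_qc.groupby("chrom")["pos"].max()
        chrom_sizes = (
            pd.concat([bound.groupby("chrom")["end"].max(), site_max], axis=1)
            .max(axis=1)
            .astype(int)
            .to_dict()
        )
        logger.info("pipeline: chromosome sizes inferred from data (no chrom.sizes given)")
    windows = dregions.divide_windows(chrom_sizes, cfg.windowbp)

    all_regions: List[Region] = gene_feats + cpgi_feats + overlaps + windows
    wanted = set(cfg.families)
    regions_used = [r for r in all_regions if r.family() in wanted]
    region_meta = dregions.regions_to_frame(regions_used)
    assignments = dregions.assign_sites(sites_qc, regions_used)
    logger.info(
        "pipeline: %d regions in %d families, %d site-region assignments",
        len(regions_used),
        region_meta["family"].nunique(),
        len(assignments),
    )

    results: Dict[str, pd.DataFrame] = {}
    filtered: Dict[str, pd.DataFrame] = {}

    if "Site" in wanted:
        site_table = site_results.rename(columns={"target_id": "region_id"}).copy()
        site_table["start"] = site_table["pos"]
        site_table["end"] = site_table["pos"]
        site_table["feature"] = "site"
        site_table["ordinal"] = np.nan
        site_table["gene"] = None
        site_table["direction"] = "none"
        results["Site"] = site_table
        filt = significant_filter(site_table, cfg.qvalue_cut, cfg.methdiff_cut)
        filtered["Site"] = filt
        paths_out["results_Site"] = dio.write_results(
            site_table, os.path.join(cfg.output_dir, "results_Site.tsv")
        )
        paths_out["filtered_Site"] = dio.write_results(
            filt, os.path.join(cfg.output_dir, "filtered_Site.tsv")
        )

    region_results = region_tests(assignments, sites_qc, samples, diffgroups, cfg.covariates)
    region_results = region_results.merge(
        region_meta[["region_id", "chrom", "start", "end", "kind", "ordinal", "gene_name", "family"]],
        left_on="target_id",
        right_on="region_id",
        how="left",
    )
    for family, fam_block in region_results.groupby("family", sort=True):
        fam = fam_block.copy()
        fam["qvalue"] = adjust_pvalues(fam["pvalue"].to_numpy(), cfg.adjust_method)
        fam["feature"] = fam["kind"]
        fam["gene"] = fam["gene_name"]
        fam["direction"] = "none"
        results[family] = fam
        filt = significant_filter(fam, cfg.qvalue_cut, cfg.methdiff_cut)
        filtered[family] = filt
        logger.info(
            "family %s: %d targets tested, %d significant (q<%g, |diff|>%g)",
            family,
            len(fam),
            len(filt),
            cfg.qvalue_cut,
            cfg.methdiff_cut,
        )
        paths_out[f"results_{family}"] = dio.write_results(
            fam, os.path.join(cfg.output_dir, f"results_{family}.tsv")
        )
        paths_out[f"filtered_{family}"] = dio.write_results(
            filt, os.path.join(cfg.output_dir, f"filtered_{family}.tsv")
        )

    density = None
    if "Window" in wanted:
        countable = [
            r for r in gene_feats + cpgi_feats if r.kind in ("gene", "CpGisland", "Shore")
        ]
        density = dregions.window_density(countable, windows)
        paths_out["window_density"] = os.path.join(cfg.output_dir, "window_density.tsv")
        density.to_csv(paths_out["window_density"], sep="\t", index=False)

    categories = None
    if cfg.expression_table and "Gene" in filtered and not filtered["Gene"].empty:
        expression = dio.read_expression(cfg.expression_table)
        categories = categorize_with_expression(filtered["Gene"], expression)
        paths_out["gene_categories"] = os.path.join(cfg.output_dir, "gene_categories.tsv")
        categories.to_csv(paths_out["gene_categories"], sep="\t", index=False)

    return {
        "samples": frame,
        "qc_report": qc_report,
        "diffgroups": diffgroups,
        "results": results,
        "filtered": filtered,
        "density": density,
        "categories": categories,
        "paths": paths_out,
    }
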