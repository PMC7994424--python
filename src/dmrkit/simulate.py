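"""Synthetic methylome generator.

Produces a self-contained test dataset: a BED12 gene annotation, a BED3
CpG-island track, chrom.sizes, and per-sample 6-column coverage files named
``<group>_<replicate>.cov``, plus truth tables for recovery checks.

The generative model mirrors the statistical structure the analysis
assumes: true methylation is locally correlated, drawn per methylation
domain (island / gene / intergenic tile) from a bimodal Beta baseline with
small per-site jitter, and shared by all samples; group effects add a
specified delta on the proportion scale inside chosen target regions;
per-sample read depth is negative-binomial (overdispersed, like real
library coverage) and methylated-read counts are binomial. Sites drawing
zero reads in a sample are simply absent from that sample's file, as in
real coverage output. Islands are placed relative to gene features
(promoter-only islands and exon/intron-junction islands) plus intergenic
ones, so that every overlap class — gene/promoter/exon/intron crossed with
island/shore — is instantiated.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import GeneModel, Region, SampleSpec

_MIN_GENE_SPAN = 4000
_MAX_GENE_SPAN = 16000
_MIN_SEGMENT = 100  # minimum exon/intron length
_GENE_MARGIN = 4000  # room for promoter + shore on each side of a gene


@dataclass(frozen=True)
class EffectTarget:
    """A methylation effect: ``delta`` (proportion scale) added for ``group``
    at every site inside the selected region.

    ``selector`` is a gene id (effect over the gene span) or an explicit
    interval ``"chrom:start-end"``.
    """

    selector: str
    group: str
    delta: float


@dataclass(frozen=True)
class SimConfig:
    """All parameters of the synthetic methylome generator."""

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 3_000_000
    n_genes: int = 200
    exons_per_gene: Tuple[int, int] = (2, 6)
    n_islands: int = 80
    n_groups: int = 2
    replicates_per_group: int = 3
    baseline_beta: Tuple[float, float] = (0.6, 0.6)
    coverage_mean: float = 30.0
    coverage_dispersion: float = 5.0  # NB size; smaller = more overdispersed
    effect_targets: Tuple[EffectTarget, ...] = ()
    site_density: float = 1.0  # expected CpG sites per kb, genome-wide
    island_site_density: float = 10.0  # additional density inside islands
    domain_bp: int = 2000  # intergenic methylation-domain tile size
    site_jitter_kappa: float = 100.0  # Beta concentration of sites around their domain mean

    def __post_init__(self) -> None:
        for t in self.effect_targets:
            if not (-0.98 <= t.delta <= 0.98):
                raise ValueError("effect deltas must keep proportions within [0.01, 0.99]")


@dataclass
class Annotation:
    genes: List[GeneModel]
    islands: List[Region]
    chrom_sizes: Dict[str, int]
    refseq_bed: Optional[str] = None
    cpgi_bed: Optional[str] = None
    chrom_sizes_path: Optional[str] = None


@dataclass
class SimulatedDataset:
    annotation: Annotation
    samples: List[SampleSpec]
    coverage_paths: Dict[str, str]
    truth_sites: pd.DataFrame
    truth_genes: pd.DataFrame
    truth_sites_path: Optional[str] = None
    truth_genes_path: Optional[str] = None


def default_effect_targets(
    cfg: SimConfig, n_affected: int, delta: float, group: str = "2"
) -> Tuple[EffectTarget, ...]:
    """Select ``n_affected`` evenly spaced genes as effect carriers."""
    if n_affected > cfg.n_genes:
        raise ValueError("cannot affect more genes than exist")
    idx = np.linspace(0, cfg.n_genes - 1, n_affected).astype(int)
    return tuple(EffectTarget(selector=f"NM_{i + 1:06d}", group=group, delta=delta) for i in idx)


def _split_lengths(rng: np.random.Generator, span: int, n_segments: int) -> List[int]:
    """Split span into n_segments parts, each >= _MIN_SEGMENT, deterministically."""
    base = _MIN_SEGMENT * n_segments
    rem = span - base
    props = rng.random(n_segments)
    extra = np.floor(props / props.sum() * rem).astype(int)
    lengths = (_MIN_SEGMENT + extra).tolist()
    lengths[0] += span - sum(lengths)
    return lengths


def simulate_annotation(cfg: SimConfig, outdir: Optional[str] = None) -> Annotation:
    """Generate non-overlapping gene models and CpG islands (deterministic
    given ``cfg.seed``); optionally write BED12 / BED3 / chrom.sizes."""
    rng = np.random.default_rng(cfg.seed)
    chrom_sizes = {f"chr{c + 1}": cfg.chrom_length for c in range(cfg.n_chroms)}
    per_chrom = [cfg.n_genes // cfg.n_chroms] * cfg.n_chroms
    for c in range(cfg.n_genes % cfg.n_chroms):
        per_chrom[c] += 1

    genes: List[GeneModel] = []
    islands: List[Tuple[str, int, int]] = []
    gene_index = 0
    lo_ex, hi_ex = cfg.exons_per_gene
    for c, chrom in enumerate(sorted(chrom_sizes)):
        n_here = per_chrom[c]
        if n_here == 0:
            continue
        slot = cfg.chrom_length // n_here
        max_span = min(_MAX_GENE_SPAN, slot - 2 * _GENE_MARGIN)
        if max_span < _MIN_GENE_SPAN:
            raise ValueError(
                f"infeasible packing: {n_here} genes on {chrom} of length "
                f"{cfg.chrom_length} leave slots of {slot} bp"
            )
        for s in range(n_here):
            slot_start = s * slot + 1
            span = int(rng.integers(_MIN_GENE_SPAN, max_span + 1))
            slack = slot - 2 * _GENE_MARGIN - span
            start = slot_start + _GENE_MARGIN + int(rng.integers(0, slack + 1))
            end = start + span - 1
            strand = "+" if rng.random() < 0.5 else "-"
            n_ex = int(rng.integers(lo_ex, hi_ex + 1))
            n_ex = max(1, min(n_ex, (span // _MIN_SEGMENT + 1) // 2))
            n_seg = 2 * n_ex - 1
            lengths = _split_lengths(rng, span, n_seg)
            exons = []
            pos = start
            for seg, length in enumerate(lengths):
                if seg % 2 == 0:
                    exons.append((pos, pos + length - 1))
                pos += length
            gene_index += 1
            gene_id = f"NM_{gene_index:06d}"
            gene = GeneModel(
                gene_id=gene_id,
                gene_name=f"gene{gene_index}",
                chrom=chrom,
                start=start,
                end=end,
                strand=strand,
                exon_intervals=tuple(exons),
            )
            genes.append(gene)

            # targeted island placement so every overlap class exists
            pattern = (gene_index - 1) % 3
            if pattern == 0:
                # island inside the promoter, outside the gene body
                if strand == "+":
                    islands.append((chrom, start - 900, start - 400))
                else:
                    islands.append((chrom, end + 400, end + 900))
            elif pattern == 1 and len(exons) >= 2:
                # island straddling the first exon/intron junction
                junction = exons[0][1]
                s0 = max(start, junction - 150)
                e0 = min(end, junction + 150)
                islands.append((chrom, s0, e0))
            # pattern == 2: no gene-linked island

    # intergenic islands up to the requested count, placed at slot boundaries
    n_intergenic = max(0, cfg.n_islands - len(islands))
    gaps = []
    by_chrom: Dict[str, List[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom in sorted(by_chrom):
        ordered = sorted(by_chrom[chrom], key=lambda g: g.start)
        for a, b in zip(ordered, ordered[1:]):
            gap_mid = (a.end + b.start) // 2
            if b.start - a.end > 2 * _GENE_MARGIN + 1200:
                gaps.append((chrom, gap_mid - 250, gap_mid + 250))
    for i in range(min(n_intergenic, len(gaps))):
        islands.append(gaps[i])

    islands.sort()
    merged: List[Tuple[str, int, int]] = []
    for chrom, s, e in islands:
        if merged and merged[-1][0] == chrom and s <= merged[-1][2]:
            prev = merged.pop()
            merged.append((chrom, prev[1], max(prev[2], e)))
        else:
            merged.append((chrom, s, e))
    island_regions = []
    counter: Dict[str, int] = {}
    for chrom, s, e in merged:
        counter[chrom] = counter.get(chrom, 0) + 1
        island_regions.append(
            Region(
                region_id=f"cpgi:{chrom}:{counter[chrom]}",
                chrom=chrom,
                start=s,
                end=e,
                kind="CpGisland",
                ordinal=counter[chrom],
            )
        )

    ann = Annotation(genes=genes, islands=island_regions, chrom_sizes=chrom_sizes)
    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        ann.refseq_bed = write_bed12(genes, os.path.join(outdir, "refseq.bed"))
        ann.cpgi_bed = write_bed3(island_regions, os.path.join(outdir, "cpgi.bed"))
        ann.chrom_sizes_path = os.path.join(outdir, "chrom.sizes")
        with open(ann.chrom_sizes_path, "w") as fh:
            for chrom in sorted(chrom_sizes):
                fh.write(f"{chrom}\t{chrom_sizes[chrom]}\n")
    return ann


def write_bed12(genes: Sequence[GeneModel], path: str) -> str:
    """Write gene models as UCSC BED12 (0-based half-open)."""
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
            chrom_start = g.start - 1
            sizes = ",".join(str(e - s + 1) for s, e in g.exon_intervals) + ","
            starts = ",".join(str(s - 1 - chrom_start) for s, _ in g.exon_intervals) + ","
            fh.write(
                "\t".join(
                    [
                        g.chrom,
                        str(chrom_start),
                        str(g.end),
                        f"{g.gene_id}|{g.gene_name}",
                        "0",
                        g.strand,
                        str(chrom_start),
                        str(g.end),
                        "0",
                        str(len(g.exon_intervals)),
                        sizes,
                        starts,
                    ]
                )
                + "\n"
            )
    return path


def write_bed3(islands: Sequence[Region], path: str) -> str:
    with open(path, "w") as fh:
        for r in sorted(islands, key=lambda r: (r.chrom, r.start)):
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\n")
    return path


_INTERVAL_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)$")


def _resolve_selector(selector: str, genes: Sequence[GeneModel]) -> Tuple[str, int, int]:
    m = _INTERVAL_RE.match(selector)
    if m:
        return m.group("chrom"), int(m.group("start")), int(m.group("end"))
    for g in genes:
        if g.gene_id == selector or g.gene_name == selector:
            return g.chrom, g.start, g.end
    raise ValueError(f"effect selector {selector!r} matches no gene and is not chrom:start-end")


def _draw_baseline(
    cfg: SimConfig,
    annotation: Annotation,
    rng: np.random.Generator,
    site_chrom: np.ndarray,
    site_pos: np.ndarray,
) -> np.ndarray:
    """True baseline methylation per site, locally correlated.

    DNA methylation is regionally coherent: neighboring CpGs share their
    methylation state. The baseline is therefore drawn per methylation
    domain — one draw from Beta(a, b) for each CpG island, each gene span,
    and each ``domain_bp`` intergenic tile — and individual sites scatter
    around their domain mean with Beta concentration ``site_jitter_kappa``.
    A gene is one domain end to end: islands lying inside a gene share the
    gene's baseline, keeping each gene internally homogeneous, which is the
    within-region structure the pooled binomial test assumes. Fully
    independent per-site baselines are neither realistic nor
    model-consistent.
    """
    n_sites = len(site_pos)
    domain = np.array([f"tile:{c}:{p // cfg.domain_bp}" for c, p in zip(site_chrom, site_pos)], dtype=object)
    for isl in annotation.islands:  # islands override tiles
        mask = (site_chrom == isl.chrom) & (site_pos >= isl.start) & (site_pos <= isl.end)
        domain[mask] = isl.region_id
    for g in annotation.genes:  # genes override everything they contain
        mask = (site_chrom == g.chrom) & (site_pos >= g.start) & (site_pos <= g.end)
        domain[mask] = f"gene:{g.gene_id}"
    a, b = cfg.baseline_beta
    unique_domains = sorted(set(domain.tolist()))
    level = dict(zip(unique_domains, rng.beta(a, b, size=len(unique_domains))))
    means = np.array([level[d] for d in domain])
    kappa = cfg.site_jitter_kappa
    if kappa and np.isfinite(kappa):
        means = np.clip(means, 0.01, 0.99)
        base = rng.beta(kappa * means, kappa * (1.0 - means), size=n_sites)
    else:
        base = means
    return np.clip(base, 0.01, 0.99)


def simulate_methylome(
    cfg: SimConfig, annotation: Annotation, outdir: Optional[str] = None
) -> SimulatedDataset:
    """Place CpG sites, draw true methylation and counts, and write the
    per-sample coverage files plus truth tables."""
    rng = np.random.default_rng(cfg.seed + 1)  # independent of annotation stream
    groups = [str(g + 1) for g in range(cfg.n_groups)]
    samples = [
        SampleSpec(sample_id=f"{g}_{r}", group=g, replicate=r)
        for g in groups
        for r in range(1, cfg.replicates_per_group + 1)
    ]

    chroms: List[str] = []
    positions: List[np.ndarray] = []
    for chrom in sorted(annotation.chrom_sizes):
        length = annotation.chrom_sizes[chrom]
        n_bg = int(round(cfg.site_density * length / 1000.0))
        pos = rng.choice(length, size=min(n_bg, length), replace=False) + 1
        extra = []
        for isl in annotation.islands:
            if isl.chrom != chrom:
                continue
            n_isl = int(round(cfg.island_site_density * isl.length / 1000.0))
            if n_isl > 0:
                extra.append(rng.integers(isl.start, isl.end + 1, size=n_isl))
        if extra:
            pos = np.concatenate([pos] + extra)
        pos = np.unique(pos)
        chroms.append(chrom)
        positions.append(np.sort(pos))

    site_chrom = np.concatenate([[c] * len(p) for c, p in zip(chroms, positions)])
    site_pos = np.concatenate(positions)
    n_sites = len(site_pos)

    base = _draw_baseline(cfg, annotation, rng, site_chrom, site_pos)

    # apply effects: squeeze the shared baseline so the shifted proportion
    # stays inside [0.01, 0.99] and the between-group delta is exact
    pi = np.tile(base[:, None], (1, cfg.n_groups))
    gene_delta = {g.gene_id: (0.0, None) for g in annotation.genes}
    for target in cfg.effect_targets:
        chrom, start, end = _resolve_selector(target.selector, annotation.genes)
        if target.group not in groups:
            raise ValueError(f"effect group {target.group!r} not among groups {groups}")
        gcol = groups.index(target.group)
        mask = (site_chrom == chrom) & (site_pos >= start) & (site_pos <= end)
        d = target.delta
        squeezed = np.clip(base[mask], max(0.01, 0.01 - d), min(0.99, 0.99 - d))
        pi[mask, :] = squeezed[:, None]
        pi[mask, gcol] = squeezed + d
        for g in annotation.genes:
            if g.gene_id == target.selector or g.gene_name == target.selector:
                gene_delta[g.gene_id] = (d, target.group)

    p_nb = cfg.coverage_dispersion / (cfg.coverage_dispersion + cfg.coverage_mean)
    coverage_paths: Dict[str, str] = {}
    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
    rows_truth = {
        "chrom": site_chrom,
        "pos": site_pos,
        **{f"pi_{g}": pi[:, i] for i, g in enumerate(groups)},
    }
    truth_sites = pd.DataFrame(rows_truth)

    for spec in samples:
        gcol = groups.index(spec.group)
        tr = rng.negative_binomial(cfg.coverage_dispersion, p_nb, size=n_sites)
        mr = rng.binomial(np.maximum(tr, 0), pi[:, gcol])
        covered = tr > 0
        if outdir is not None:
            path = os.path.join(outdir, f"{spec.sample_id}.cov")
            with open(path, "w") as fh:
                for c, p, m, t in zip(
                    site_chrom[covered], site_pos[covered], mr[covered], tr[covered]
                ):
                    pct = 100.0 * m / t
                    fh.write(f"{c}\t{p}\t{p}\t{pct:.6g}\t{m}\t{t - m}\n")
            coverage_paths[spec.sample_id] = path
        truth_sites[f"meth_{spec.sample_id}"] = mr
        truth_sites[f"total_{spec.sample_id}"] = tr

    truth_genes = pd.DataFrame(
        [
            {
                "gene_id": g.gene_id,
                "gene_name": g.gene_name,
                "chrom": g.chrom,
                "start": g.start,
                "end": g.end,
                "delta": gene_delta[g.gene_id][0],
                "affected_group": gene_delta[g.gene_id][1],
            }
            for g in annotation.genes
        ]
    )

    ds = SimulatedDataset(
        annotation=annotation,
        samples=samples,
        coverage_paths=coverage_paths,
        truth_sites=truth_sites,
        truth_genes=truth_genes,
    )
    if outdir is not None:
        ds.truth_sites_path = os.path.join(outdir, "truth_sites.tsv")
        truth_sites.to_csv(ds.truth_sites_path, sep="\t", index=False)
        ds.truth_genes_path = os.path.join(outdir, "truth_genes.tsv")
        truth_genes.to_csv(ds.truth_genes_path, sep="\t", index=False)
    return ds


def simulate_dataset(cfg: SimConfig, outdir: str) -> SimulatedDataset:
    """Convenience: annotation + methylome in one call, everything written."""
    ann = simulate_annotation(cfg, outdir)
    return simulate_methylome(cfg, ann, outdir)


def recovery_config(seed: int = 0, n_affected: int = 30, delta: float = 0.2) -> SimConfig:
    """The parameter-recovery study conditions: 200 genes of which
    ``n_affected`` carry a +``delta`` effect in group 2, 2 groups x 3
    replicates at coverage mean 30."""
    cfg = SimConfig(seed=seed)
    return replace(cfg, effect_targets=default_effect_targets(cfg, n_affected, delta, group="2"))


def null_config(seed: int = 0) -> SimConfig:
    """Null study conditions: no group effect anywhere."""
    return SimConfig(seed=seed, effect_targets=())
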