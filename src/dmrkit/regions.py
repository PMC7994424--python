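"""Derivation of analyzable region classes and site-to-region assignment.

From BED gene models and CpG islands this module derives windows, genes,
promoters, exons, introns, single-base TSSes, islands, island shores and
the eight overlap classes (gene/promoter/exon/intron x island/shore), then
assigns cytosines to every region containing them. Exon and intron ordinals
are transcript-strand-aware (ordinal 1 is 5'-most); shores are numbered per
chromosome in coordinate order.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .core import CPG_SIDE_KINDS, GENE_SIDE_KINDS, GeneModel, Region

logger = logging.getLogger(__name__)


def dedupe_gene_ids(genes: Sequence[GeneModel]) -> List[GeneModel]:
    """Keep only the first-encountered accession per gene name (file order)."""
    seen: set = set()
    kept = []
    for g in genes:
        if g.gene_name in seen:
            continue
        seen.add(g.gene_name)
        kept.append(g)
    return kept


def derive_gene_features(
    genes: Sequence[GeneModel], promoter_up: int = 1000, promoter_down: int = 1000
) -> List[Region]:
    """Split each gene into promoter, single-base TSS, exons and introns.

    The promoter brackets the TSS: ``[TSS - promoter_up, TSS + promoter_down - 1]``
    on the + strand, mirrored in the 3'->5' sense on the - strand, clipped at
    position 1. With a symmetric promoter (up == down) the promoter midpoint
    coincides with the gene start (+) or gene end (-), which is what the
    promoter-to-gene annotation rule relies on. Introns are the gaps between
    consecutive exons; single-exon genes yield none.
    """
    if promoter_up < 0 or promoter_down < 0:
        raise ValueError("promoter extents must be >= 0")
    if promoter_up == 0 and promoter_down == 0:
        raise ValueError("promoter_up and promoter_down cannot both be 0")
    out: List[Region] = []
    for g in genes:
        common = dict(chrom=g.chrom, strand=g.strand, gene_id=g.gene_id, gene_name=g.gene_name)
        out.append(Region(region_id=f"gene:{g.gene_id}", start=g.start, end=g.end, kind="gene", **common))
        if g.strand == "+":
            tss = g.start
            prom = (tss - promoter_up, tss + promoter_down - 1)
        else:
            tss = g.end
            prom = (tss - promoter_down + 1, tss + promoter_up)
        out.append(Region(region_id=f"tss:{g.gene_id}", start=tss, end=tss, kind="TSS", **common))
        out.append(
            Region(
                region_id=f"promoter:{g.gene_id}",
                start=max(1, prom[0]),
                end=prom[1],
                kind="promoter",
                **common,
            )
        )
        exons = list(g.exon_intervals)
        introns = [(exons[i][1] + 1, exons[i + 1][0] - 1) for i in range(len(exons) - 1)]
        if g.strand == "-":
            exon_order = list(reversed(exons))
            intron_order = list(reversed(introns))
        else:
            exon_order = exons
            intron_order = introns
        for k, (s, e) in enumerate(exon_order, start=1):
            out.append(
                Region(region_id=f"exon:{g.gene_id}:{k}", start=s, end=e, kind="exon", ordinal=k, **common)
            )
        for k, (s, e) in enumerate(intron_order, start=1):
            out.append(
                Region(
                    region_id=f"intron:{g.gene_id}:{k}", start=s, end=e, kind="intron", ordinal=k, **common
                )
            )
    return out


def derive_cpgi_features(islands: Sequence[Region], shore_bp: int = 2000) -> List[Region]:
    """Flank each CpG island with up to two shores of width <= ``shore_bp``.

    Shores never overlap any island; two shores facing each other across an
    inter-island gap are split at the gap midpoint (the upstream shore takes
    the extra base when the gap length is odd). Shores are clipped at
    position 1 and numbered per chromosome in coordinate order; the returned
    list contains the input islands followed by the derived shores.
    """
    if shore_bp < 1:
        raise ValueError("shore_bp must be >= 1")
    by_chrom: Dict[str, List[Region]] = defaultdict(list)
    for isl in islands:
        if isl.kind != "CpGisland":
            raise ValueError(f"expected CpGisland regions, got kind={isl.kind!r}")
        by_chrom[isl.chrom].append(isl)

    out: List[Region] = list(islands)
    for chrom in sorted(by_chrom):
        chrom_islands = sorted(by_chrom[chrom], key=lambda r: r.start)
        for a, b in zip(chrom_islands, chrom_islands[1:]):
            if b.start <= a.end:
                raise ValueError(f"islands on {chrom} overlap; merge them first")
        candidates: List[Tuple[int, int, str]] = []  # (start, end, side)
        for idx, isl in enumerate(chrom_islands):
            left = (max(1, isl.start - shore_bp), isl.start - 1, "left")
            right = (isl.end + 1, isl.end + shore_bp, "right")
            # clip against the neighboring islands
            if idx > 0:
                prev = chrom_islands[idx - 1]
                gap_start, gap_end = prev.end + 1, isl.start - 1
                gap_len = gap_end - gap_start + 1
                if gap_len < 2 * shore_bp:
                    # facing shores: split the gap at its midpoint
                    mid = gap_start + gap_len // 2 - 1 if gap_len > 0 else gap_start - 1
                    left = (max(left[0], mid + 1), left[1], "left")
            if idx + 1 < len(chrom_islands):
                nxt = chrom_islands[idx + 1]
                gap_start, gap_end = isl.end + 1, nxt.start - 1
                gap_len = gap_end - gap_start + 1
                if gap_len < 2 * shore_bp:
                    mid = gap_start + gap_len // 2 - 1 if gap_len > 0 else gap_start - 1
                    right = (right[0], min(right[1], mid), "right")
            for s, e, side in (left, right):
                if s <= e:
                    candidates.append((s, e, side))
        candidates.sort()
        for k, (s, e, side) in enumerate(candidates, start=1):
            out.append(
                Region(
                    region_id=f"shore:{chrom}:{k}",
                    chrom=chrom,
                    start=s,
                    end=e,
                    kind="Shore",
                    ordinal=k,
                    side=side,
                )
            )
    return out


def _component_label(region: Region) -> str:
    base = {"gene": "Gene", "promoter": "Promoter", "exon": "Exon", "intron": "Intron"}.get(region.kind)
    if base is None:
        base = {"CpGisland": "CpGi", "Shore": "Shore"}[region.kind]
    if region.ordinal is not None:
        return f"{base}{region.ordinal}"
    return base


def intersect_features(
    gene_features: Sequence[Region], cpgi_features: Sequence[Region]
) -> List[Region]:
    """Emit one overlap region per nonempty gene-side x CpG-side intersection.

    Gene-side regions are genes, promoters, exons and introns (TSSes are
    excluded); CpG-side regions are islands and shores. The overlap interval
    is the intersection of the two components; for the gene kind this equals
    the union of that gene's per-exon/per-intron intersections with the same
    island or shore, since exons and introns partition the gene span.
    """
    gene_side = [r for r in gene_features if r.kind in GENE_SIDE_KINDS]
    cpg_side = [r for r in cpgi_features if r.kind in CPG_SIDE_KINDS]
    trees: Dict[str, IntervalTree] = defaultdict(IntervalTree)
    for r in cpg_side:
        trees[r.chrom][r.start : r.end + 1] = r
    out: List[Region] = []
    for gr in gene_side:
        if gr.chrom not in trees:
            continue
        for hit in sorted(trees[gr.chrom][gr.start : gr.end + 1], key=lambda iv: iv.begin):
            cr: Region = hit.data
            s, e = max(gr.start, cr.start), min(gr.end, cr.end)
            if s > e:
                continue
            out.append(
                Region(
                    region_id=f"overlap:{gr.region_id}|{cr.region_id}",
                    chrom=gr.chrom,
                    start=s,
                    end=e,
                    kind="overlap",
                    strand=gr.strand,
                    gene_id=gr.gene_id,
                    gene_name=gr.gene_name,
                    components=(_component_label(gr), _component_label(cr)),
                )
            )
    return out


def divide_windows(chrom_sizes: Mapping[str, int], windowbp: int = 1_000_000) -> List[Region]:
    """Tile each chromosome with consecutive windows of ``windowbp`` bases.

    Windows are ``[1, w], [w+1, 2w], ...``; the last window is truncated at
    the chromosome end so the tiling is exact.
    """
    if windowbp < 1:
        raise ValueError("windowbp must be >= 1")
    out: List[Region] = []
    for chrom in sorted(chrom_sizes):
        length = int(chrom_sizes[chrom])
        if length < 1:
            raise ValueError(f"chromosome {chrom} has non-positive length")
        k = 1
        for start in range(1, length + 1, windowbp):
            out.append(
                Region(
                    region_id=f"window:{chrom}:{k}",
                    chrom=chrom,
                    start=start,
                    end=min(start + windowbp - 1, length),
                    kind="window",
                    ordinal=k,
                )
            )
            k += 1
    return out


def assign_sites(sites: pd.DataFrame, regions: Sequence[Region]) -> pd.DataFrame:
    """Assign every cytosine position to every region containing it.

    ``sites`` is a long-format site table (only ``chrom``/``pos`` are used;
    duplicate positions across samples collapse to one assignment).
    Containment is closed at both endpoints. Returns a DataFrame with
    columns region_id, chrom, pos.
    """
    trees: Dict[str, IntervalTree] = defaultdict(IntervalTree)
    for r in regions:
        trees[r.chrom][r.start : r.end + 1] = r.region_id
    positions = sites[["chrom", "pos"]].drop_duplicates()
    rows: List[Tuple[str, str, int]] = []
    for chrom, chrom_pos in positions.groupby("chrom", sort=True):
        tree = trees.get(chrom)
        if tree is None:
            continue
        for pos in chrom_pos["pos"].to_numpy():
            for hit in tree[int(pos)]:
                rows.append((hit.data, chrom, int(pos)))
    assignments = pd.DataFrame(rows, columns=["region_id", "chrom", "pos"])
    return assignments.sort_values(["chrom", "pos", "region_id"], kind="mergesort").reset_index(
        drop=True
    )


def window_density(features: Sequence[Region], windows: Sequence[Region]) -> pd.DataFrame:
    """Count features whose midpoint falls in each window, per feature kind.

    The midpoint is ``floor((start + end) / 2)``; a midpoint on a window
    boundary base belongs to the window containing that base. Returns one
    row per window with a count column per feature kind present.
    """
    window_list = [w for w in windows if w.kind == "window"]
    kinds = sorted({f.kind for f in features})
    counts: Dict[str, Dict[str, int]] = {w.region_id: {k: 0 for k in kinds} for w in window_list}
    trees: Dict[str, IntervalTree] = defaultdict(IntervalTree)
    for w in window_list:
        trees[w.chrom][w.start : w.end + 1] = w.region_id
    for f in features:
        tree = trees.get(f.chrom)
        if tree is None:
            continue
        for hit in tree[f.midpoint]:
            counts[hit.data][f.kind] += 1
    rows = []
    for w in sorted(window_list, key=lambda w: (w.chrom, w.start)):
        row = {"region_id": w.region_id, "chrom": w.chrom, "start": w.start, "end": w.end}
        row.update(counts[w.region_id])
        rows.append(row)
    return pd.DataFrame(rows)


def annotate_promoter_gene(
    promoters: Sequence[Region], genes: Optional[Sequence[GeneModel]] = None
) -> List[Region]:
    """Link each promoter to the gene anchored at the promoter's midpoint.

    A + promoter matches the gene whose start equals ``floor((start+end)/2)``;
    a - promoter matches on the gene end. When ``genes`` is omitted the
    promoters' own gene links are used to build the lookup (a consistency
    re-derivation). Unmatched promoters are logged and returned unlinked.
    """
    lookup: Dict[Tuple[str, str, int], Tuple[str, str]] = {}
    if genes is not None:
        for g in genes:
            anchor = g.start if g.strand == "+" else g.end
            lookup.setdefault((g.chrom, g.strand, anchor), (g.gene_id, g.gene_name))
    out: List[Region] = []
    n_unmatched = 0
    for p in promoters:
        if p.kind != "promoter":
            raise ValueError(f"expected promoter regions, got kind={p.kind!r}")
        match = lookup.get((p.chrom, p.strand, p.midpoint))
        if match is None:
            n_unmatched += 1
        gene_id, gene_name = match if match is not None else (None, None)
        out.append(
            Region(
                region_id=p.region_id,
                chrom=p.chrom,
                start=p.start,
                end=p.end,
                kind="promoter",
                strand=p.strand,
                gene_id=gene_id,
                gene_name=gene_name,
            )
        )
    if n_unmatched:
        logger.warning("%d promoters matched no gene at their midpoint; left unlinked", n_unmatched)
    return out


def regions_to_frame(regions: Iterable[Region]) -> pd.DataFrame:
    """Tabulate regions (one row each) for persistence and joins."""
    rows = []
    for r in regions:
        rows.append(
            {
                "region_id": r.region_id,
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "kind": r.kind,
                "strand": r.strand,
                "ordinal": r.ordinal,
                "gene_id": r.gene_id,
                "gene_name": r.gene_name,
                "family": r.family(),
                "components": "|".join(r.components) if r.components else None,
                "side": r.side,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "region_id",
            "chrom",
            "start",
            "end",
            "kind",
            "strand",
            "ordinal",
            "gene_id",
            "gene_name",
            "family",
            "components",
            "side",
        ],
    )


def frame_to_regions(frame: pd.DataFrame) -> List[Region]:
    regions = []
    for row in frame.itertuples(index=False):
        comps = None
        if isinstance(row.components, str) and row.components:
            parts = row.components.split("|")
            comps = (parts[0], parts[1])
        regions.append(
            Region(
                region_id=row.region_id,
                chrom=str(row.chrom),
                start=int(row.start),
                end=int(row.end),
                kind=row.kind,
                strand=row.strand if isinstance(row.strand, str) else None,
                ordinal=int(row.ordinal) if pd.notna(row.ordinal) else None,
                gene_id=row.gene_id if isinstance(row.gene_id, str) else None,
                gene_name=row.gene_name if isinstance(row.gene_name, str) else None,
                components=comps,
                side=row.side if isinstance(row.side, str) else None,
            )
        )
    return regions
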