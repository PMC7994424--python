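import numpy as np
import pandas as pd
import pytest

from dmrkit import regions as dregions
from dmrkit.core import GeneModel, Region
from tests.conftest import make_sites


def by_kind(regions, kind):
    return sorted((r for r in regions if r.kind == kind), key=lambda r: (r.ordinal or 0, r.start))


class TestDeriveGeneFeatures:
    def test_plus_strand_intervals(self, plus_gene):
        feats = dregions.derive_gene_features([plus_gene])
        tss = by_kind(feats, "TSS")[0]
        assert (tss.start, tss.end) == (1000, 1000)
        prom = by_kind(feats, "promoter")[0]
        # [1000-1000, 1000+999] clipped at 1
        assert (prom.start, prom.end) == (1, 1999)
        exons = by_kind(feats, "exon")
        assert [(e.start, e.end, e.ordinal) for e in exons] == [
            (1000, 1099, 1),
            (1900, 2000, 2),
        ]
        introns = by_kind(feats, "intron")
        assert [(i.start, i.end, i.ordinal) for i in introns] == [(1100, 1899, 1)]

    def test_minus_strand_mirrored(self, minus_gene):
        feats = dregions.derive_gene_features([minus_gene])
        tss = by_kind(feats, "TSS")[0]
        assert (tss.start, tss.end) == (2000, 2000)
        prom = by_kind(feats, "promoter")[0]
        assert (prom.start, prom.end) == (1001, 3000)
        # ordinal 1 is the 5'-most exon on the transcript strand = last genomic block
        exons = by_kind(feats, "exon")
        assert (exons[0].start, exons[0].end, exons[0].ordinal) == (1900, 2000, 1)
        assert (exons[1].start, exons[1].end, exons[1].ordinal) == (1000, 1099, 2)

    def test_single_exon_gene_cardinality(self):
        g = GeneModel("NM_3", "g3", "chr1", 100, 500, "+", ((100, 500),))
        feats = dregions.derive_gene_features([g])
        kinds = pd.Series([f.kind for f in feats]).value_counts().to_dict()
        assert kinds == {"gene": 1, "promoter": 1, "TSS": 1, "exon": 1}

    def test_exon_intron_partition_property(self):
        """Exons and introns are disjoint and tile the gene span exactly."""
        rng = np.random.default_rng(11)
        for _ in range(30):
            start = int(rng.integers(1, 10000))
            n_ex = int(rng.integers(1, 6))
            pos, exons = start, []
            for _ in range(n_ex):
                e = pos + int(rng.integers(1, 200))
                exons.append((pos, e))
                pos = e + int(rng.integers(2, 100))
            end = exons[-1][1]
            strand = "+" if rng.random() < 0.5 else "-"
            g = GeneModel("NM_x", "gx", "chr1", start, end, strand, tuple(exons))
            feats = dregions.derive_gene_features([g])
            pieces = sorted(
                (r.start, r.end) for r in feats if r.kind in ("exon", "intron")
            )
            assert pieces[0][0] == start and pieces[-1][1] == end
            for (s1, e1), (s2, e2) in zip(pieces, pieces[1:]):
                assert s2 == e1 + 1  # no gap, no overlap

    def test_strand_symmetry_of_ordinals(self, plus_gene):
        """Mirroring the genome and flipping strand preserves exon ordinals."""
        L = 5000
        mirrored_exons = tuple(
            sorted((L - e + 1, L - s + 1) for s, e in plus_gene.exon_intervals)
        )
        mirrored = GeneModel("NM_1m", "gm", "chr1", L - plus_gene.end + 1,
                             L - plus_gene.start + 1, "-", mirrored_exons)
        fwd = by_kind(dregions.derive_gene_features([plus_gene]), "exon")
        rev = by_kind(dregions.derive_gene_features([mirrored]), "exon")
        for f, r in zip(fwd, rev):
            assert f.ordinal == r.ordinal
            assert (r.start, r.end) == (L - f.end + 1, L - f.start + 1)

    def test_degenerate_promoter_widths_rejected(self, plus_gene):
        with pytest.raises(ValueError):
            dregions.derive_gene_features([plus_gene], promoter_up=0, promoter_down=0)


class TestDeriveCpgiFeatures:
    def island(self, chrom, start, end, i=1):
        return Region(f"cpgi:{chrom}:{i}", chrom, start, end, "CpGisland", ordinal=i)

    def test_lone_island_two_shores(self):
        feats = dregions.derive_cpgi_features([self.island("chr1", 5001, 6000)], shore_bp=2000)
        shores = by_kind(feats, "Shore")
        assert [(s.start, s.end) for s in shores] == [(3001, 5000), (6001, 8000)]

    def test_facing_shores_split_at_midpoint(self):
        feats = dregions.derive_cpgi_features(
            [self.island("chr1", 5001, 6000, 1), self.island("chr1", 7001, 8000, 2)], shore_bp=2000
        )
        shores = by_kind(feats, "Shore")
        inner = [(s.start, s.end) for s in shores if 6000 < s.start and s.end < 7001]
        assert inner == [(6001, 6500), (6501, 7000)]

    def test_island_at_position_one_has_only_right_shore(self):
        feats = dregions.derive_cpgi_features([self.island("chr1", 1, 200)], shore_bp=500)
        shores = by_kind(feats, "Shore")
        assert [(s.start, s.end, s.side) for s in shores] == [(201, 700, "right")]

    def test_shores_never_overlap_islands_or_each_other(self):
        """Brute-force disjointness on random island sets."""
        rng = np.random.default_rng(5)
        for _ in range(20):
            starts = np.sort(rng.choice(50_000, size=8, replace=False) + 1)
            islands = []
            prev_end = 0
            for i, s in enumerate(starts):
                s = max(int(s), prev_end + 2)
                e = s + int(rng.integers(100, 2000))
                islands.append(self.island("chr1", s, e, i + 1))
                prev_end = e
            feats = dregions.derive_cpgi_features(islands, shore_bp=1500)
            shores = by_kind(feats, "Shore")
            occupied = [(r.start, r.end) for r in islands] + [(s.start, s.end) for s in shores]
            occupied.sort()
            for (s1, e1), (s2, e2) in zip(occupied, occupied[1:]):
                assert s2 > e1, f"overlap between ({s1},{e1}) and ({s2},{e2})"

    def test_shore_ordinals_per_chromosome(self):
        feats = dregions.derive_cpgi_features(
            [self.island("chr1", 5001, 6000, 1), self.island("chr2", 5001, 6000, 1)]
        )
        for chrom in ("chr1", "chr2"):
            ords = [s.ordinal for s in by_kind(feats, "Shore") if s.chrom == chrom]
            assert ords == [1, 2]


class TestIntersectFeatures:
    def test_exon_island_overlap_labeled(self):
        exon = Region("exon:NM_1:1", "chr1", 1000, 1099, "exon", strand="+", ordinal=1, gene_id="NM_1")
        island = Region("cpgi:chr1:1", "chr1", 1050, 1200, "CpGisland", ordinal=1)
        overlaps = dregions.intersect_features([exon], [island])
        assert len(overlaps) == 1
        ov = overlaps[0]
        assert (ov.start, ov.end) == (1050, 1099)
        assert ov.components == ("Exon1", "CpGi1")
        assert ov.family() == "Exon-CpGi"

    def test_disjoint_no_region(self):
        exon = Region("exon:NM_1:1", "chr1", 1000, 1099, "exon", ordinal=1)
        island = Region("cpgi:chr1:1", "chr1", 2000, 2100, "CpGisland")
        assert dregions.intersect_features([exon], [island]) == []

    def test_promoter_and_exon_share_one_shore(self):
        prom = Region("promoter:NM_1", "chr1", 1, 1999, "promoter", strand="+", gene_id="NM_1")
        exon = Region("exon:NM_1:1", "chr1", 1000, 1099, "exon", strand="+", ordinal=1, gene_id="NM_1")
        shore = Region("shore:chr1:1", "chr1", 900, 1049, "Shore", ordinal=1)
        overlaps = dregions.intersect_features([prom, exon], [shore])
        labels = {ov.components for ov in overlaps}
        assert labels == {("Promoter", "Shore1"), ("Exon1", "Shore1")}

    def test_matches_brute_force_on_random_instances(self):
        """Overlap set equals the all-pairs interval intersection."""
        rng = np.random.default_rng(3)
        for _ in range(20):
            gene_side = [
                Region(f"exon:g:{i}", "chr1", s := int(rng.integers(1, 3000)),
                       s + int(rng.integers(0, 500)), "exon", ordinal=i + 1)
                for i in range(int(rng.integers(1, 25)))
            ]
            cpg_side = [
                Region(f"cpgi:chr1:{i}", "chr1", s := int(rng.integers(1, 3000)),
                       s + int(rng.integers(0, 500)), "CpGisland", ordinal=i + 1)
                for i in range(int(rng.integers(1, 25)))
            ]
            got = {
                (ov.region_id, ov.start, ov.end)
                for ov in dregions.intersect_features(gene_side, cpg_side)
            }
            expected = set()
            for g in gene_side:
                for c in cpg_side:
                    s, e = max(g.start, c.start), min(g.end, c.end)
                    if s <= e:
                        expected.add((f"overlap:{g.region_id}|{c.region_id}", s, e))
            assert got == expected


class TestDivideWindows:
    def test_truncation_and_tiling(self):
        windows = dregions.divide_windows({"chr1": 2_500_000}, windowbp=1_000_000)
        assert [(w.start, w.end) for w in windows] == [
            (1, 1_000_000),
            (1_000_001, 2_000_000),
            (2_000_001, 2_500_000),
        ]

    def test_short_chromosome_single_window(self):
        windows = dregions.divide_windows({"chr1": 999}, windowbp=1_000_000)
        assert [(w.start, w.end) for w in windows] == [(1, 999)]

    def test_window_lengths_sum_to_chromosome_length(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            length = int(rng.integers(1, 5_000_000))
            w = int(rng.integers(1, 1_000_000))
            windows = dregions.divide_windows({"chrX": length}, windowbp=w)
            assert sum(win.length for win in windows) == length
            # no overlap, no gap
            for a, b in zip(windows, windows[1:]):
                assert b.start == a.end + 1


class TestAssignSites:
    def test_multi_membership_and_boundaries(self):
        exon = Region("exon:NM_1:1", "chr1", 1000, 1099, "exon", ordinal=1, gene_id="NM_1")
        gene = Region("gene:NM_1", "chr1", 1000, 2000, "gene", gene_id="NM_1")
        island = Region("cpgi:chr1:1", "chr1", 1050, 1200, "CpGisland")
        overlap = dregions.intersect_features([exon, gene], [island])
        regions = [exon, gene, island] + overlap
        sites = make_sites([("s1", "chr1", 1050, 1, 1), ("s1", "chr2", 5, 1, 1),
                            ("s1", "chr1", 2000, 1, 1)])
        assignments = dregions.assign_sites(sites, regions)
        at_1050 = set(assignments.loc[assignments["pos"] == 1050, "region_id"])
        assert {"exon:NM_1:1", "gene:NM_1", "cpgi:chr1:1"} <= at_1050
        assert any(r.startswith("overlap:exon") for r in at_1050)
        # region end is inclusive
        assert "gene:NM_1" in set(assignments.loc[assignments["pos"] == 2000, "region_id"])
        # chromosome absent from regions -> no assignment
        assert (assignments["chrom"] == "chr2").sum() == 0

    def test_matches_brute_force_containment(self):
        rng = np.random.default_rng(9)
        regions = []
        for i in range(50):
            s = int(rng.integers(1, 5000))
            regions.append(Region(f"r{i}", "chr1", s, s + int(rng.integers(0, 300)), "window"))
        pos = rng.choice(6000, size=200, replace=False) + 1
        sites = make_sites([("s1", "chr1", int(p), 1, 1) for p in pos])
        got = set(map(tuple, dregions.assign_sites(sites, regions)[["region_id", "pos"]].values))
        expected = {
            (r.region_id, int(p)) for r in regions for p in pos if r.start <= p <= r.end
        }
        assert got == expected


class TestWindowDensity:
    def test_midpoint_counting_and_conservation(self):
        windows = dregions.divide_windows({"chr1": 3000}, windowbp=1000)
        feats = [
            Region("gene:a", "chr1", 1, 999, "gene"),          # mid 500 -> w1
            Region("gene:b", "chr1", 900, 1100, "gene"),        # mid 1000 -> w1 (boundary base)
            Region("gene:c", "chr1", 1001, 1001, "gene"),       # mid 1001 -> w2
            Region("cpgi:chr1:1", "chr1", 2500, 2600, "CpGisland"),
        ]
        table = dregions.window_density(feats, windows)
        assert table["gene"].tolist() == [2, 1, 0]
        assert table["CpGisland"].tolist() == [0, 0, 1]
        assert table["gene"].sum() == 3  # conservation

    def test_total_counts_conserved_random(self):
        rng = np.random.default_rng(4)
        windows = dregions.divide_windows({"chr1": 100_000}, windowbp=7777)
        feats = []
        for i in range(100):
            s = int(rng.integers(1, 99_000))
            feats.append(Region(f"g{i}", "chr1", s, s + int(rng.integers(0, 900)), "gene"))
        table = dregions.window_density(feats, windows)
        # midpoints can exceed the last window only if the feature end does; keep all inside
        assert table["gene"].sum() == sum(1 for f in feats if f.midpoint <= 100_000)


class TestGeneIdRules:
    def test_first_accession_kept(self):
        mk = lambda gid: GeneModel(gid, "Adora1", "chr1", 100, 200, "+", ((100, 200),))
        genes = [mk("NM_001291930"), mk("NM_001282945"), mk("NM_001039510"), mk("NM_001008533")]
        kept = dregions.dedupe_gene_ids(genes)
        assert [g.gene_id for g in kept] == ["NM_001291930"]

    def test_unique_names_untouched(self):
        a = GeneModel("NM_1", "a", "chr1", 1, 10, "+", ((1, 10),))
        b = GeneModel("NM_2", "b", "chr1", 20, 30, "+", ((20, 30),))
        assert dregions.dedupe_gene_ids([a, b]) == [a, b]


class TestAnnotatePromoterGene:
    def test_midpoint_matching_both_strands(self, plus_gene, minus_gene):
        feats = dregions.derive_gene_features([plus_gene])
        proms = [r for r in feats if r.kind == "promoter"]
        linked = dregions.annotate_promoter_gene(proms, [plus_gene])
        assert linked[0].gene_id == "NM_1"
        # minus strand: promoter (1001,3000) has midpoint 2000 == gene end
        featsm = dregions.derive_gene_features([minus_gene])
        promsm = [r for r in featsm if r.kind == "promoter"]
        linkedm = dregions.annotate_promoter_gene(promsm, [minus_gene])
        assert linkedm[0].gene_id == "NM_2"

    def test_unmatched_promoter_left_unlinked(self, caplog):
        orphan = Region("promoter:x", "chr1", 1, 100, "promoter", strand="+")
        with caplog.at_level("WARNING"):
            out = dregions.annotate_promoter_gene([orphan], [])
        assert out[0].gene_id is None
        assert any("unlinked" in r.message for r in caplog.records)
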