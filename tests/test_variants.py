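"""Proxy filtering, accessibility, SNP->gene routes and nearest-gene
categories."""

import pandas as pd
import pytest

from v2gmap.atlas import Ocr, OcrAtlas
from v2gmap.genome import GenomicInterval, Transcript, promoter_windows
from v2gmap.interactions import OcrInteraction
from v2gmap.variants import (
    categorize_all,
    categorize_variant,
    filter_proxies,
    interaction_pairs,
    locate_in_ocr,
    nearest_gene,
    promoter_resident_pairs,
    summarize_categories,
)


def proxy_df(rows):
    return pd.DataFrame(
        rows, columns=["rsid", "chrom", "pos", "sentinel_rsid", "r2"]
    )


class TestFilterProxies:
    def _df(self, r2s):
        return proxy_df(
            [(f"rs{i}", "chr1", 100 + i, "rsS", r2) for i, r2 in enumerate(r2s)]
        )

    def test_threshold_is_inclusive(self):
        out = filter_proxies(self._df([0.8, 0.79]), 0.8)
        assert list(out["r2"]) == [0.8]

    def test_below_relaxed_threshold_dropped(self):
        out = filter_proxies(self._df([0.39, 0.4]), 0.4)
        assert list(out["r2"]) == [0.4]

    def test_perfect_ld_always_kept(self):
        for thr in (0.0, 0.4, 0.8, 1.0):
            assert len(filter_proxies(self._df([1.0]), thr)) == 1

    @pytest.mark.parametrize("thr", [-0.1, 1.5])
    def test_threshold_out_of_range_rejected(self, thr):
        with pytest.raises(ValueError):
            filter_proxies(self._df([0.5]), thr)


def _atlas():
    return OcrAtlas(
        [
            Ocr("O1", GenomicInterval("chr1", 100, 200), open_in={"tfh"}),
            Ocr("O2", GenomicInterval("chr1", 500, 600), open_in=set()),
        ]
    )


class TestLocateInOcr:
    def test_one_based_boundary_conversion(self):
        # 1-based 150 -> 0-based 149: inside [100, 200)
        # 1-based 201 -> 0-based 200: outside the half-open interval
        proxies = proxy_df(
            [("rsA", "chr1", 149, "rsS", 0.9), ("rsB", "chr1", 200, "rsS", 0.9)]
        )
        out = locate_in_ocr(proxies, _atlas(), "tfh")
        assert list(out["rsid"]) == ["rsA"]
        assert list(out["ocr_id"]) == ["O1"]

    def test_closed_ocr_not_accessible(self):
        proxies = proxy_df([("rsC", "chr1", 550, "rsS", 0.9)])
        assert len(locate_in_ocr(proxies, _atlas(), "tfh")) == 0

    def test_chromosome_without_ocrs_excluded(self):
        proxies = proxy_df([("rsD", "chr9", 150, "rsS", 0.9)])
        assert len(locate_in_ocr(proxies, _atlas(), "tfh")) == 0


def _windows():
    txs = [
        Transcript("t1", "g1", "G1", "chr1", "+", 1000),
        Transcript("t2", "g2", "G2", "chr1", "-", 1100),  # window [600, 2600)
    ]
    return promoter_windows(txs, 1500, 500, {"chr1": 1_000_000})


class TestPromoterResidentPairs:
    def _accessible(self, pos):
        df = proxy_df([("rsP", "chr1", pos, "rsS", 0.9)])
        df["ocr_id"] = "OP"
        return df

    def _atlas(self):
        return OcrAtlas([Ocr("OP", GenomicInterval("chr1", 0, 3000), open_in={"tfh"})])

    def test_snp_in_single_window(self):
        out = promoter_resident_pairs(self._accessible(100), self._atlas(), _windows(), "tfh")
        assert list(out["gene_id"]) == ["g1"]
        assert set(out["route"]) == {"promoter_resident"}

    def test_snp_in_overlapping_windows_yields_two_pairs(self):
        out = promoter_resident_pairs(self._accessible(1000), self._atlas(), _windows(), "tfh")
        assert sorted(out["gene_id"]) == ["g1", "g2"]

    def test_snp_outside_all_windows(self):
        out = promoter_resident_pairs(
            self._accessible(500_000), self._atlas(), _windows(), "tfh"
        )
        assert len(out) == 0


class TestInteractionPairs:
    def _world(self):
        atlas = OcrAtlas(
            [
                Ocr("OS", GenomicInterval("chr1", 50_000, 50_400), open_in={"tfh"}),
                Ocr("OP", GenomicInterval("chr1", 800, 1300), open_in={"tfh"}),
                Ocr("OX", GenomicInterval("chr1", 90_000, 90_300), open_in={"tfh"}),
            ]
        )
        accessible = proxy_df([("rsI", "chr1", 50_100, "rsS", 0.9)])
        accessible["ocr_id"] = "OS"
        return atlas, accessible

    def test_partner_promoter_gives_pair(self):
        atlas, acc = self._world()
        inter = [
            OcrInteraction("OP", "OS", "tfh", 7.0, frozenset({1}), "prOCR", "nonprOCR", 0)
        ]
        out = interaction_pairs(acc, inter, atlas, _windows(), "tfh")
        assert sorted(out["gene_id"]) == ["g1", "g2"]  # both windows overlap OP
        assert set(out["route"]) == {"interaction"}
        assert set(out["partner_ocr_id"]) == {"OP"}

    def test_no_interactions_no_pairs(self):
        atlas, acc = self._world()
        assert len(interaction_pairs(acc, [], atlas, _windows(), "tfh")) == 0

    def test_partner_without_promoter_overlap_gives_nothing(self):
        atlas, acc = self._world()
        inter = [
            OcrInteraction("OS", "OX", "tfh", 7.0, frozenset({1}), "nonprOCR", "nonprOCR", 0)
        ]
        assert len(interaction_pairs(acc, inter, atlas, _windows(), "tfh")) == 0


class TestNearestGene:
    TXS = [
        Transcript("tA", "A", "A", "chr1", "+", 10_000),
        Transcript("tB", "B", "B", "chr1", "+", 20_000),
        Transcript("tC", "C", "C", "chr2", "+", 5_000),
    ]

    def test_smallest_tss_distance_wins(self):
        assert nearest_gene("chr1", 11_000, self.TXS) == "A"
        assert nearest_gene("chr1", 19_000, self.TXS) == "B"

    def test_equidistant_breaks_ties_lexicographically(self):
        assert nearest_gene("chr1", 15_000, self.TXS) == "A"

    def test_gene_body_does_not_matter_only_tss(self):
        # position just downstream of A's TSS but closer to B's TSS
        assert nearest_gene("chr1", 16_000, self.TXS) == "B"

    def test_universe_restriction(self):
        assert nearest_gene("chr1", 11_000, self.TXS, gene_universe={"B"}) == "B"

    def test_empty_chromosome_rejected(self):
        with pytest.raises(ValueError):
            nearest_gene("chrX", 100, self.TXS)


class TestCategorize:
    @pytest.mark.parametrize(
        "genes,nearest,expected",
        [
            ({"STAT4"}, "STAT4", "nearest_only"),
            ({"IKZF3", "ERBB2", "PGAP3"}, "IKZF3", "nearest_plus_distant"),
            ({"BCL6"}, "LPP", "skip"),
        ],
    )
    def test_three_way_scheme(self, genes, nearest, expected):
        assert categorize_variant(genes, nearest) == expected

    def test_empty_gene_set_has_no_category(self):
        assert categorize_variant(set(), "X") is None

    def test_partition_is_exhaustive_and_exclusive(self, small_run):
        study, pipe = small_run
        cats = pipe._categories
        inter = pipe._v2g[pipe._v2g["route"] == "interaction"]
        assert set(cats["proxy_rsid"]) == set(inter["proxy_rsid"])
        assert cats["proxy_rsid"].is_unique
        assert cats["category"].isin(
            ["nearest_only", "nearest_plus_distant", "skip"]
        ).all()


class TestSummarize:
    def test_counts_and_fractions(self):
        cats = pd.DataFrame(
            {
                "proxy_rsid": ["a", "b", "c"],
                "nearest_gene": ["g"] * 3,
                "category": ["nearest_only", "nearest_only", "skip"],
            }
        )
        s = summarize_categories(cats)
        assert s["counts"] == {
            "nearest_only": 2,
            "nearest_plus_distant": 0,
            "skip": 1,
        }
        assert s["fractions"]["nearest_only"] == pytest.approx(2 / 3)
        assert sum(s["fractions"].values()) == pytest.approx(1.0)

    def test_empty_input_all_zero(self):
        s = summarize_categories(pd.DataFrame(columns=["proxy_rsid", "category"]))
        assert s["n_categorized"] == 0
        assert all(v == 0 for v in s["counts"].values())


class TestMonotonicityAndPrecision:
    def _pairs_at(self, pipe, study, threshold):
        from v2gmap import variants as vmod
        from v2gmap.io import read_snp_table

        proxies = read_snp_table(pipe.workdir / "proxies.tsv")
        kept = vmod.filter_proxies(proxies, threshold)
        acc = vmod.locate_in_ocr(kept, pipe._atlas, "tfh")
        inter = vmod.interaction_pairs(
            acc, pipe._interactions["tfh"], pipe._atlas, pipe._windows, "tfh"
        )
        return set(zip(inter["proxy_rsid"], inter["gene_id"]))

    def test_strict_pairs_subset_of_relaxed(self, small_run):
        study, pipe = small_run
        strict = self._pairs_at(pipe, study, 0.8)
        relaxed = self._pairs_at(pipe, study, 0.4)
        assert strict <= relaxed
        assert len(relaxed) >= len(strict)

    def test_interaction_pairs_have_fragment_level_path(self, small_run):
        """Precision = 1: every emitted interaction-route pair is backed by a
        significant fragment-level record linking the SNP's OCR to an OCR
        overlapping the gene's promoter window (brute-force path search)."""
        study, pipe = small_run
        inter = pipe._v2g[pipe._v2g["route"] == "interaction"]
        atlas, windows = pipe._atlas, pipe._windows
        focal_calls = [
            r
            for res in (1, 4)
            for r in study.interactions.calls["tfh"][res]
            if r.score >= 5
        ]
        pos_of = {
            row.rsid: (row.chrom, int(row.pos))
            for row in study.variants.proxies.itertuples()
        }
        for row in inter.itertuples():
            chrom, pos = pos_of[row.proxy_rsid]
            snp_ocrs = set(atlas.overlapping(chrom, pos, pos + 1))
            target_ocrs = {
                o
                for w in windows
                if w.gene_id == row.gene_id
                for o in atlas.overlapping(
                    w.interval.chrom, w.interval.start, w.interval.end
                )
            }
            found = any(
                (set(atlas.overlapping(r.bait.chrom, r.bait.start, r.bait.end))
                 & target_ocrs
                 and set(atlas.overlapping(r.other.chrom, r.other.start, r.other.end))
                 & snp_ocrs)
                or (set(atlas.overlapping(r.bait.chrom, r.bait.start, r.bait.end))
                    & snp_ocrs
                    and set(atlas.overlapping(r.other.chrom, r.other.start, r.other.end))
                    & target_ocrs)
                for r in focal_calls
            )
            assert found, f"no fragment path for {row.proxy_rsid} -> {row.gene_id}"
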