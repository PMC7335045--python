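"""ibed parsing, dual-resolution merging, and OCR-pair projection."""

import numpy as np
import pytest

from conftest import brute_force_project, random_projection_instance
from v2gmap.atlas import Ocr, OcrAtlas
from v2gmap.genome import GenomicInterval, Transcript, promoter_windows
from v2gmap.interactions import (
    FragmentInteraction,
    classify_ends,
    connectivity_stats,
    merge_resolutions,
    project_to_ocr,
    read_ibed,
    write_ibed,
)
from v2gmap.io import ParseError


def rec(b0, b1, o0, o1, score, chrom="chr1", res=1, ct="ct"):
    return FragmentInteraction(
        bait=GenomicInterval(chrom, b0, b1),
        bait_name="G",
        other=GenomicInterval(chrom, o0, o1),
        other_name=".",
        n_reads=10,
        score=score,
        resolution=res,
        cell_type=ct,
    )


class TestReadIbed:
    HEADER = (
        "bait_chr\tbait_start\tbait_end\tbait_name\totherEnd_chr\t"
        "otherEnd_start\totherEnd_end\totherEnd_name\tN_reads\tscore\n"
    )

    def _write(self, tmp_path, rows):
        path = tmp_path / "x.ibed"
        path.write_text(self.HEADER + "".join(r + "\n" for r in rows))
        return path

    def test_score_filter_is_inclusive(self, tmp_path):
        path = self._write(
            tmp_path,
            [
                "chr1\t0\t100\tG\tchr1\t500\t600\t.\t12\t9.2",
                "chr1\t0\t100\tG\tchr1\t700\t800\t.\t8\t5.0",
                "chr1\t0\t100\tG\tchr1\t900\t950\t.\t3\t4.9",
            ],
        )
        out = read_ibed(path, "ct", 1, score_threshold=5)
        assert [r.score for r in out] == [9.2, 5.0]

    def test_malformed_row_names_line(self, tmp_path):
        path = self._write(
            tmp_path, ["chr1\t0\t100\tG\tchr1\t500\t600\t.\t12"]
        )
        with pytest.raises(ParseError, match=":2"):
            read_ibed(path, "ct", 1)

    def test_negative_score_rejected(self, tmp_path):
        path = self._write(
            tmp_path, ["chr1\t0\t100\tG\tchr1\t500\t600\t.\t12\t-1"]
        )
        with pytest.raises(ParseError):
            read_ibed(path, "ct", 1)

    def test_roundtrip(self, tmp_path):
        recs = [rec(0, 100, 500, 600, 7.25), rec(0, 100, 900, 1000, 11.0)]
        write_ibed(tmp_path / "y.ibed", recs)
        assert read_ibed(tmp_path / "y.ibed", "ct", 1) == recs


class TestMergeResolutions:
    def test_keeps_max_score_for_identical_coordinates(self):
        a = rec(0, 100, 500, 600, 6.0, res=1)
        b = rec(0, 100, 500, 600, 9.0, res=4)
        (merged,) = merge_resolutions([a], [b])
        assert merged.score == 9.0

    def test_disjoint_sets_concatenate(self):
        a = rec(0, 100, 500, 600, 6.0)
        b = rec(0, 100, 900, 1000, 7.0, res=4)
        assert len(merge_resolutions([a], [b])) == 2

    def test_idempotent(self):
        a = rec(0, 100, 500, 600, 6.0)
        b = rec(0, 100, 500, 600, 9.0, res=4)
        once = merge_resolutions([a], [b])
        assert merge_resolutions(once, []) == once

    def test_orientation_flipped_duplicates_collapse(self):
        fwd = rec(0, 100, 500, 600, 6.0)
        back = rec(500, 600, 0, 100, 8.0)
        (merged,) = merge_resolutions([fwd], [back])
        assert merged.score == 8.0

    def test_nested_calls_are_not_redundant(self):
        one = rec(0, 100, 500, 600, 6.0, res=1)
        four = rec(0, 400, 400, 800, 7.0, res=4)  # spans containing the 1-frag call
        assert len(merge_resolutions([one], [four])) == 2

    def test_never_reduces_max_score_and_no_duplicates(self):
        rng = np.random.default_rng(5)
        recs = [
            rec(
                int(s) * 100,
                int(s) * 100 + 100,
                int(o) * 100,
                int(o) * 100 + 100,
                round(float(rng.uniform(5, 15)), 2),
            )
            for s, o in rng.integers(0, 6, size=(60, 2))
            if s != o
        ]
        merged = merge_resolutions(recs[:30], recs[30:])
        keys = set()
        for m in merged:
            key = tuple(
                sorted(
                    [
                        (m.bait.chrom, m.bait.start, m.bait.end),
                        (m.other.chrom, m.other.start, m.other.end),
                    ]
                )
            )
            assert key not in keys
            keys.add(key)
            best = max(
                r.score
                for r in recs
                if tuple(
                    sorted(
                        [
                            (r.bait.chrom, r.bait.start, r.bait.end),
                            (r.other.chrom, r.other.start, r.other.end),
                        ]
                    )
                )
                == key
            )
            assert m.score == best


def _toy_world():
    """Atlas with a promoter OCR, two distal OCRs (one closed) and windows."""
    ocrs = [
        Ocr("P", GenomicInterval("chr1", 900, 1200), open_in={"ct"}),
        Ocr("D1", GenomicInterval("chr1", 5000, 5400), open_in={"ct"}),
        Ocr("D2", GenomicInterval("chr1", 8000, 8300), open_in=set()),
        Ocr("D3", GenomicInterval("chr1", 9000, 9300), open_in={"ct"}),
    ]
    atlas = OcrAtlas(ocrs)
    tx = Transcript("t", "g1", "G1", "chr1", "+", 1000)
    windows = promoter_windows([tx], 1500, 500, {"chr1": 20_000})
    return atlas, windows


class TestProjection:
    def test_promoter_to_open_distal_pair_emitted(self):
        atlas, windows = _toy_world()
        out = project_to_ocr([rec(950, 1100, 5100, 5200, 6.5)], atlas, windows, "ct")
        assert [(x.ocr_a, x.ocr_b) for x in out] == [("P", "D1")]
        assert out[0].class_a == "prOCR" and out[0].class_b == "nonprOCR"
        assert out[0].distance == pytest.approx(abs(1050 - 5200))

    def test_closed_partner_gives_no_pair(self):
        atlas, windows = _toy_world()
        out = project_to_ocr([rec(950, 1100, 8100, 8200, 6.5)], atlas, windows, "ct")
        assert out == []

    def test_pair_without_promoter_end_removed(self):
        atlas, windows = _toy_world()
        out = project_to_ocr([rec(5100, 5200, 9100, 9200, 7.0)], atlas, windows, "ct")
        assert out == []

    def test_multiple_records_keep_max_score_and_union_resolutions(self):
        atlas, windows = _toy_world()
        out = project_to_ocr(
            [
                rec(950, 1100, 5100, 5200, 6.5, res=1),
                rec(900, 1300, 5000, 5600, 9.5, res=4),
            ],
            atlas,
            windows,
            "ct",
        )
        (pair,) = out
        assert pair.score == 9.5
        assert pair.resolutions == frozenset({1, 4})

    def test_unknown_cell_type_rejected(self):
        atlas, windows = _toy_world()
        with pytest.raises(ValueError):
            project_to_ocr([], atlas, windows, "nope")

    def test_subthreshold_records_never_change_projection(self, tmp_path):
        atlas, windows = _toy_world()
        sig = [rec(950, 1100, 5100, 5200, 6.5)]
        extra = rec(950, 1100, 9100, 9200, 4.2)
        write_ibed(tmp_path / "a.ibed", sig + [extra])
        kept = read_ibed(tmp_path / "a.ibed", "ct", 1, score_threshold=5)
        assert project_to_ocr(kept, atlas, windows, "ct") == project_to_ocr(
            sig, atlas, windows, "ct"
        )

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            _, atlas, windows, records = random_projection_instance(rng)
            got = {
                (x.ocr_a, x.ocr_b): (x.score, x.resolutions)
                for x in project_to_ocr(records, atlas, windows, "ct")
            }
            assert got == brute_force_project(records, atlas, windows, "ct")

    def test_emitted_pairs_satisfy_invariants(self):
        rng = np.random.default_rng(23)
        for _ in range(10):
            _, atlas, windows, records = random_projection_instance(rng)
            for x in project_to_ocr(records, atlas, windows, "ct"):
                assert x.ocr_a != x.ocr_b
                assert atlas.is_open(x.ocr_a, "ct") and atlas.is_open(x.ocr_b, "ct")
                assert atlas.interval(x.ocr_a).chrom == atlas.interval(x.ocr_b).chrom
                assert "prOCR" in (x.class_a, x.class_b)
                assert x.score >= 5


class TestClassifyEnds:
    def test_own_location_decides_class(self):
        atlas, windows = _toy_world()
        out = project_to_ocr([rec(950, 1100, 5100, 5200, 6.0)], atlas, windows, "ct")
        relabeled = classify_ends(out, atlas, windows)
        assert relabeled == out  # projection already labels consistently

    def test_promoter_of_other_gene_still_procr(self):
        ocrs = [
            Ocr("P1", GenomicInterval("chr1", 900, 1200), open_in={"ct"}),
            Ocr("P2", GenomicInterval("chr1", 40_900, 41_200), open_in={"ct"}),
        ]
        atlas = OcrAtlas(ocrs)
        txs = [
            Transcript("t1", "g1", "G1", "chr1", "+", 1000),
            Transcript("t2", "g2", "G2", "chr1", "+", 41_000),
        ]
        windows = promoter_windows(txs, 1500, 500, {"chr1": 100_000})
        out = project_to_ocr(
            [rec(950, 1100, 40_950, 41_100, 8.0)], atlas, windows, "ct"
        )
        (pair,) = out
        assert (pair.class_a, pair.class_b) == ("prOCR", "prOCR")


class TestConnectivityStats:
    def test_distance_median_and_partner_counts(self):
        ocrs = [
            Ocr("P", GenomicInterval("chr1", 0, 1000), open_in={"ct"}),
            Ocr("A", GenomicInterval("chr1", 10_000, 11_000), open_in={"ct"}),
            Ocr("B", GenomicInterval("chr1", 100_000, 101_000), open_in={"ct"}),
            Ocr("C", GenomicInterval("chr1", 1_000_000, 1_001_000), open_in={"ct"}),
        ]
        atlas = OcrAtlas(ocrs)
        tx = Transcript("t", "g1", "G1", "chr1", "+", 600)
        windows = promoter_windows([tx], 1500, 500, {"chr1": 2_000_000})
        recs = [
            rec(500, 700, 10_100, 10_300, 6.0),
            rec(500, 700, 100_100, 100_300, 6.0),
            rec(500, 700, 1_000_100, 1_000_300, 6.0),
        ]
        out = project_to_ocr(recs, atlas, windows, "ct")
        stats = connectivity_stats(out, atlas, windows)
        assert stats["per_gene_partner_counts"]["g1"] == 3
        assert stats["distance_median"] == pytest.approx(100_000, rel=0.01)

    def test_gene_without_interactions_counts_zero(self):
        atlas, windows = _toy_world()
        stats = connectivity_stats([], atlas, windows)
        assert stats["per_gene_partner_counts"]["g1"] == 0
        assert stats["n_interactions"] == 0
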