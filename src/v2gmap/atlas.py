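"""Reference open-chromatin atlas built from replicate ATAC-seq peak sets.

The atlas construction follows the consensus-peak recipe used for ATAC
atlases: peaks from all replicates of a cell type are union-merged
(bookended intervals coalesce), merged peaks supported by fewer than two
biological replicates are discarded, the per-cell-type sets are merged
across cell types into reference OCRs, and any OCR touching a blacklist
region is removed. A cell type is called "open" at an OCR if at least one
replicate peak from that cell type overlaps it. A CPM-based retention
filter (>=1.5 CPM in at least half the samples) mirrors the pre-filter used
before differential accessibility testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .genome import GenomicInterval

__all__ = [
    "Ocr",
    "merge_intervals",
    "merge_replicate_peaks",
    "build_reference_ocrs",
    "OcrAtlas",
    "cpm_filter",
]


@dataclass
class Ocr:
    id: str
    interval: GenomicInterval
    support: dict[str, int] = field(default_factory=dict)
    open_in: set[str] = field(default_factory=set)


def merge_intervals(
    intervals: Iterable[GenomicInterval],
) -> list[GenomicInterval]:
    """Union-merge: overlapping or bookended (distance-0) intervals coalesce."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    merged: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda x: (x.start, x.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:  # overlap or bookended
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_start, cur_end))
    return merged


def merge_replicate_peaks(
    peak_sets: Sequence[Sequence[GenomicInterval]],
    min_replicates: int = 2,
) -> list[tuple[GenomicInterval, int]]:
    """Merge peaks across replicates and drop weakly supported ones.

    Returns (merged peak, support) pairs where support is the number of
    replicates contributing at least one overlapping original peak; a
    replicate contributes at most 1 regardless of how many of its peaks fall
    inside the merged region. Peaks with support < ``min_replicates`` are
    removed.
    """
    if len(peak_sets) == 0:
        raise ValueError("need at least one replicate peak set")
    merged = merge_intervals(iv for peaks in peak_sets for iv in peaks)
    out: list[tuple[GenomicInterval, int]] = []
    trees: list[dict[str, IntervalTree]] = []
    for peaks in peak_sets:
        d: dict[str, IntervalTree] = {}
        for iv in peaks:
            d.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
        trees.append(d)
    for peak in merged:
        support = sum(
            1
            for d in trees
            if peak.chrom in d and d[peak.chrom].overlap(peak.start, peak.end)
        )
        if support >= min_replicates:
            out.append((peak, support))
    return out


class OcrAtlas:
    """Reference OCR set with per-cell-type replicate support and openness."""

    def __init__(self, ocrs: Sequence[Ocr]) -> None:
        self._ocrs = {o.id: o for o in ocrs}
        self._trees: dict[str, IntervalTree] = {}
        for o in ocrs:
            self._trees.setdefault(o.interval.chrom, IntervalTree()).addi(
                o.interval.start, o.interval.end, o.id
            )

    def __len__(self) -> int:
        return len(self._ocrs)

    def __contains__(self, ocr_id: str) -> bool:
        return ocr_id in self._ocrs

    def __iter__(self):
        return iter(self.ocrs())

    def ocrs(self) -> list[Ocr]:
        return sorted(
            self._ocrs.values(),
            key=lambda o: (o.interval.chrom, o.interval.start, o.interval.end),
        )

    def get(self, ocr_id: str) -> Ocr:
        return self._ocrs[ocr_id]

    def interval(self, ocr_id: str) -> GenomicInterval:
        return self._ocrs[ocr_id].interval

    def cell_types(self) -> set[str]:
        return {ct for o in self._ocrs.values() for ct in o.open_in}

    def overlapping(self, chrom: str, start: int, end: int) -> list[str]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted(
            (iv.data for iv in tree.overlap(start, end)),
            key=lambda i: self._ocrs[i].interval.start,
        )

    def ocr_at(self, chrom: str, pos: int) -> str | None:
        """OCR containing 0-based position ``pos``; atlas intervals do not
        overlap so at most one can match."""
        hits = self.overlapping(chrom, pos, pos + 1)
        return hits[0] if hits else None

    def is_open(self, ocr_id: str, cell_type: str) -> bool:
        return cell_type in self._ocrs[ocr_id].open_in

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "ocr_id": o.id,
                "chrom": o.interval.chrom,
                "start": o.interval.start,
                "end": o.interval.end,
                "open_in": ",".join(sorted(o.open_in)) or ".",
                "support": ";".join(
                    f"{ct}={n}" for ct, n in sorted(o.support.items())
                )
                or ".",
            }
            for o in self.ocrs()
        ]
        return pd.DataFrame(
            rows, columns=["ocr_id", "chrom", "start", "end", "open_in", "support"]
        )

    def write_bed(self, path) -> None:
        """BED with openness and support encoded in the name field."""
        df = self.to_frame()
        with open(path, "w") as fh:
            for row in df.itertuples():
                name = f"{row.ocr_id}|open={row.open_in}|support={row.support}"
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{name}\n")


def build_reference_ocrs(
    merged_per_cell_type: Mapping[str, Sequence[tuple[GenomicInterval, int]]],
    blacklist: Sequence[GenomicInterval] = (),
) -> OcrAtlas:
    """Union-merge replicate-filtered peaks across cell types into reference
    OCRs, dropping any OCR that overlaps a blacklist interval. Ids are the
    deterministic ``chrom:start-end``."""
    all_peaks = [
        iv for peaks in merged_per_cell_type.values() for iv, _ in peaks
    ]
    reference = merge_intervals(all_peaks)
    black: dict[str, IntervalTree] = {}
    for iv in blacklist:
        black.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    ocrs: list[Ocr] = []
    for iv in reference:
        tree = black.get(iv.chrom)
        if tree is not None and tree.overlap(iv.start, iv.end):
            continue
        ocrs.append(Ocr(id=f"{iv.chrom}:{iv.start}-{iv.end}", interval=iv))
    return OcrAtlas(ocrs)


def call_openness(
    atlas: OcrAtlas,
    replicate_peaks: Mapping[str, Sequence[Sequence[GenomicInterval]]],
) -> OcrAtlas:
    """Mark each OCR open in a cell type iff >=1 peak from >=1 replicate of
    that cell type overlaps it; also records per-cell-type replicate support
    (number of replicates with an overlapping peak). Mutates and returns the
    atlas."""
    for ct, replicates in replicate_peaks.items():
        rep_trees: list[dict[str, IntervalTree]] = []
        for peaks in replicates:
            d: dict[str, IntervalTree] = {}
            for iv in peaks:
                d.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
            rep_trees.append(d)
        for ocr in atlas.ocrs():
            chrom = ocr.interval.chrom
            n_rep = sum(
                1
                for d in rep_trees
                if chrom in d and d[chrom].overlap(ocr.interval.start, ocr.interval.end)
            )
            if n_rep:
                ocr.support[ct] = n_rep
                ocr.open_in.add(ct)
    return atlas


def cpm_filter(
    counts: pd.DataFrame,
    library_sizes: pd.Series,
    cpm_threshold: float = 1.5,
    sample_fraction: float = 0.5,
) -> list[str]:
    """Retain OCRs with >= ``cpm_threshold`` CPM in at least
    ``ceil(sample_fraction * n_samples)`` samples.

    CPM = count * 1e6 / library size. The threshold is inclusive: a sample at
    exactly 1.5 CPM counts as passing, because the removal rule targets OCRs
    with *less than* 1.5 CPM support.
    """
    libs = library_sizes.loc[counts.columns].astype(float)
    if (libs <= 0).any():
        raise ValueError("library sizes must be positive")
    cpm = counts.to_numpy(dtype=float) * 1e6 / libs.to_numpy()
    n_pass = (cpm >= cpm_threshold).sum(axis=1)
    needed = math.ceil(sample_fraction * counts.shape[1])
    keep = n_pass >= needed
    return [ocr_id for ocr_id, k in zip(counts.index, keep) if k]
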