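"""Dual-resolution capture interaction calls and their projection onto OCR
pairs.

Significant promoter-capture interactions are called upstream at two
restriction-fragment resolutions (single DpnII fragment, and four-fragment
bins) and exported in ibed format with a significance score. This module
parses those calls, merges the two resolutions keeping the maximum score for
coordinate-identical records, and projects the fragment-level contacts onto
pairs of reference open-chromatin regions: a pair is emitted when some
interaction's bait end overlaps one OCR and its other end overlaps the
other, at either resolution, with both OCRs open in the cell type. Pairs
where neither OCR touches a promoter window are removed, and each end is
classed promoter (prOCR) or regulatory (nonprOCR) by promoter-window
overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .atlas import OcrAtlas
from .genome import GenomicInterval, PromoterWindows
from .io import IBED_COLUMNS, ParseError

__all__ = [
    "FragmentInteraction",
    "OcrInteraction",
    "read_ibed",
    "write_ibed",
    "merge_resolutions",
    "project_to_ocr",
    "classify_ends",
    "connectivity_stats",
    "SCORE_THRESHOLD",
]

#: Significance threshold on the interaction caller's score. Applied
#: inclusively (score >= 5 is significant).
SCORE_THRESHOLD = 5.0


@dataclass(frozen=True)
class FragmentInteraction:
    bait: GenomicInterval
    bait_name: str
    other: GenomicInterval
    other_name: str
    n_reads: int
    score: float
    resolution: int
    cell_type: str

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError("interaction score must be non-negative")

    @property
    def is_cis(self) -> bool:
        return self.bait.chrom == self.other.chrom


@dataclass(frozen=True)
class OcrInteraction:
    """A projected contact between two reference OCRs in one cell type.

    ``ocr_a`` is the coordinate-lower OCR; ``class_a``/``class_b`` are
    'prOCR' or 'nonprOCR'; ``distance`` is the absolute difference of OCR
    midpoints (cis pairs only).
    """

    ocr_a: str
    ocr_b: str
    cell_type: str
    score: float
    resolutions: frozenset[int]
    class_a: str = ""
    class_b: str = ""
    distance: float = 0.0


def read_ibed(
    path: str | Path,
    cell_type: str,
    resolution: int,
    score_threshold: float = SCORE_THRESHOLD,
) -> list[FragmentInteraction]:
    """Parse a 10-column ibed file, keeping records with score >= threshold."""
    out: list[FragmentInteraction] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) != 10:
            raise ParseError(f"{path}:1: expected 10-column ibed header")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 10:
                raise ParseError(
                    f"{path}:{lineno}: expected 10 columns, got {len(fields)}"
                )
            try:
                rec = FragmentInteraction(
                    bait=GenomicInterval(fields[0], int(fields[1]), int(fields[2])),
                    bait_name=fields[3],
                    other=GenomicInterval(fields[4], int(fields[5]), int(fields[6])),
                    other_name=fields[7],
                    n_reads=int(fields[8]),
                    score=float(fields[9]),
                    resolution=resolution,
                    cell_type=cell_type,
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if rec.score >= score_threshold:
                out.append(rec)
    return out


def write_ibed(path: str | Path, interactions: Iterable[FragmentInteraction]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(IBED_COLUMNS) + "\n")
        for rec in interactions:
            fh.write(
                f"{rec.bait.chrom}\t{rec.bait.start}\t{rec.bait.end}\t{rec.bait_name}\t"
                f"{rec.other.chrom}\t{rec.other.start}\t{rec.other.end}\t"
                f"{rec.other_name}\t{rec.n_reads}\t{rec.score:g}\n"
            )


def _canonical_key(rec: FragmentInteraction) -> tuple:
    a = (rec.bait.chrom, rec.bait.start, rec.bait.end)
    b = (rec.other.chrom, rec.other.start, rec.other.end)
    return (a, b) if a <= b else (b, a)


def merge_resolutions(
    calls_1frag: Sequence[FragmentInteraction],
    calls_4frag: Sequence[FragmentInteraction],
) -> list[FragmentInteraction]:
    """Collapse coordinate-identical records to one, keeping the max score.

    Redundancy means exact identity of both end coordinates after canonical
    ordering (lower-coordinate end first); a 1-fragment call nested inside a
    4-fragment bin is *not* redundant and both records are retained —
    projection unions their evidence anyway.
    """
    best: dict[tuple, FragmentInteraction] = {}
    for rec in list(calls_1frag) + list(calls_4frag):
        key = _canonical_key(rec)
        prev = best.get(key)
        if prev is None or rec.score > prev.score:
            best[key] = rec
    return sorted(
        best.values(),
        key=lambda r: (
            r.bait.chrom,
            r.bait.start,
            r.bait.end,
            r.other.chrom,
            r.other.start,
            r.other.end,
        ),
    )


def _end_class(atlas: OcrAtlas, windows: PromoterWindows, ocr_id: str) -> str:
    iv = atlas.interval(ocr_id)
    hit = windows.overlapping(iv.chrom, iv.start, iv.end)
    return "prOCR" if hit else "nonprOCR"


def project_to_ocr(
    merged_calls: Sequence[FragmentInteraction],
    atlas: OcrAtlas,
    windows: PromoterWindows,
    cell_type: str,
) -> list[OcrInteraction]:
    """Project fragment-level interactions onto OCR pairs for one cell type.

    An OCR pair (O1, O2) is emitted iff some interaction's bait end overlaps
    O1 and its other end overlaps O2 (at either resolution), both OCRs are
    open in ``cell_type``, the pair is cis and non-self, and at least one OCR
    overlaps a promoter window. The pair score is the max over contributing
    interactions and contributing resolutions are unioned. Output is sorted
    by coordinates so runs are byte-identical.
    """
    if cell_type not in atlas.cell_types():
        raise ValueError(f"cell type {cell_type!r} has no openness calls in atlas")
    acc: dict[tuple[str, str], tuple[float, set[int]]] = {}
    for rec in merged_calls:
        bait_hits = [
            o
            for o in atlas.overlapping(rec.bait.chrom, rec.bait.start, rec.bait.end)
            if atlas.is_open(o, cell_type)
        ]
        other_hits = [
            o
            for o in atlas.overlapping(rec.other.chrom, rec.other.start, rec.other.end)
            if atlas.is_open(o, cell_type)
        ]
        for o1 in bait_hits:
            for o2 in other_hits:
                if o1 == o2:
                    continue
                iv1, iv2 = atlas.interval(o1), atlas.interval(o2)
                if iv1.chrom != iv2.chrom:
                    continue
                key = (o1, o2) if (iv1.start, iv1.end) <= (iv2.start, iv2.end) else (o2, o1)
                score, resolutions = acc.get(key, (0.0, set()))
                acc[key] = (max(score, rec.score), resolutions | {rec.resolution})
    out: list[OcrInteraction] = []
    for (a, b), (score, resolutions) in acc.items():
        ca = _end_class(atlas, windows, a)
        cb = _end_class(atlas, windows, b)
        if ca != "prOCR" and cb != "prOCR":
            continue  # neither end overlaps a gene promoter
        iva, ivb = atlas.interval(a), atlas.interval(b)
        out.append(
            OcrInteraction(
                ocr_a=a,
                ocr_b=b,
                cell_type=cell_type,
                score=score,
                resolutions=frozenset(resolutions),
                class_a=ca,
                class_b=cb,
                distance=abs(iva.midpoint - ivb.midpoint),
            )
        )
    out.sort(key=lambda x: (atlas.interval(x.ocr_a).chrom,
                            atlas.interval(x.ocr_a).start,
                            atlas.interval(x.ocr_b).start))
    return out


def classify_ends(
    interactions: Sequence[OcrInteraction],
    atlas: OcrAtlas,
    windows: PromoterWindows,
) -> list[OcrInteraction]:
    """(Re)label each end prOCR iff its OCR overlaps >=1 promoter window."""
    return [
        replace(
            rec,
            class_a=_end_class(atlas, windows, rec.ocr_a),
            class_b=_end_class(atlas, windows, rec.ocr_b),
        )
        for rec in interactions
    ]


def connectivity_stats(
    interactions: Sequence[OcrInteraction],
    atlas: OcrAtlas,
    windows: PromoterWindows,
) -> dict:
    """Per-gene distinct-partner-OCR counts and a cis distance summary.

    A gene's promoter OCRs are the OCRs overlapping any of its promoter
    windows; its partners are the distinct OCRs those promoter OCRs contact.
    """
    gene_partners: dict[str, set[str]] = {g: set() for g in sorted(windows.gene_ids())}
    ocr_genes: dict[str, list[str]] = {}

    def genes_of(ocr_id: str) -> list[str]:
        if ocr_id not in ocr_genes:
            iv = atlas.interval(ocr_id)
            ocr_genes[ocr_id] = sorted(
                windows.genes_overlapping(iv.chrom, iv.start, iv.end)
            )
        return ocr_genes[ocr_id]

    distances: list[float] = []
    for rec in interactions:
        distances.append(rec.distance)
        for gene in genes_of(rec.ocr_a):
            gene_partners[gene].add(rec.ocr_b)
        for gene in genes_of(rec.ocr_b):
            gene_partners[gene].add(rec.ocr_a)
    counts = {g: len(p) for g, p in sorted(gene_partners.items())}
    connected = [n for n in counts.values() if n > 0]
    dist = np.asarray(distances, dtype=float)
    return {
        "per_gene_partner_counts": counts,
        "n_interactions": len(interactions),
        "n_connected_genes": len(connected),
        "mean_partners_per_connected_gene": (
            float(np.mean(connected)) if connected else 0.0
        ),
        "distance_median": float(np.median(dist)) if len(dist) else float("nan"),
        "distance_mean": float(np.mean(dist)) if len(dist) else float("nan"),
    }


def interactions_to_frame(
    interactions: Sequence[OcrInteraction],
) -> pd.DataFrame:
    rows = [
        {
            "ocr_a": rec.ocr_a,
            "ocr_b": rec.ocr_b,
            "cell_type": rec.cell_type,
            "score": rec.score,
            "resolutions": ",".join(str(r) for r in sorted(rec.resolutions)),
            "class_a": rec.class_a,
            "class_b": rec.class_b,
            "distance": rec.distance,
        }
        for rec in interactions
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "ocr_a",
            "ocr_b",
            "cell_type",
            "score",
            "resolutions",
            "class_a",
            "class_b",
            "distance",
        ],
    )
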