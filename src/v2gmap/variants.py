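"""GWAS variant-to-gene assignment over the OCR atlas and projected
promoter interactome.

Proxy SNPs in LD with disease sentinels are filtered by r², located in open
chromatin, and assigned to genes by two routes: *promoter residency* (the
SNP sits inside an OCR that overlaps a gene's promoter window) and
*interaction* (the SNP's OCR physically contacts an OCR overlapping a gene's
promoter window). Each proxy with at least one interaction-route gene is
then classified against its nearest gene (by TSS distance): interacting
exclusively with the nearest gene, with the nearest plus at least one
distant gene, or skipping the nearest gene entirely.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .atlas import OcrAtlas
from .genome import PromoterWindows, Transcript
from .interactions import OcrInteraction

__all__ = [
    "filter_proxies",
    "locate_in_ocr",
    "promoter_resident_pairs",
    "interaction_pairs",
    "nearest_gene",
    "categorize_variant",
    "categorize_all",
    "summarize_categories",
]

CATEGORIES = ("nearest_only", "nearest_plus_distant", "skip")

PAIR_COLUMNS = [
    "proxy_rsid",
    "sentinel_rsid",
    "r2",
    "gene_id",
    "gene_symbol",
    "route",
    "cell_type",
    "ocr_id",
    "partner_ocr_id",
]


def filter_proxies(proxies: pd.DataFrame, r2_threshold: float) -> pd.DataFrame:
    """Keep proxies with r² >= threshold (inclusive).

    The LD cutoffs in use are nominally "r² > 0.8" / "r² > 0.4" but proxies
    at exactly the cutoff are retained, so the comparison is inclusive.
    """
    if not (0 <= r2_threshold <= 1):
        raise ValueError("r2 threshold must be in [0, 1]")
    return proxies[proxies["r2"] >= r2_threshold].reset_index(drop=True)


def locate_in_ocr(
    proxies: pd.DataFrame, atlas: OcrAtlas, cell_type: str
) -> pd.DataFrame:
    """Accessible variants: proxies whose position falls inside an OCR open
    in ``cell_type``. Adds an ``ocr_id`` column; atlas intervals do not
    overlap, so each proxy hits at most one OCR."""
    rows = []
    for row in proxies.itertuples():
        ocr_id = atlas.ocr_at(row.chrom, int(row.pos))
        if ocr_id is not None and atlas.is_open(ocr_id, cell_type):
            rows.append({**row._asdict(), "ocr_id": ocr_id})
    out = pd.DataFrame(rows)
    if len(out):
        out = out.drop(columns=["Index"], errors="ignore")
    else:
        out = pd.DataFrame(columns=list(proxies.columns) + ["ocr_id"])
    return out.reset_index(drop=True)


def promoter_resident_pairs(
    accessible: pd.DataFrame,
    atlas: OcrAtlas,
    windows: PromoterWindows,
    cell_type: str,
) -> pd.DataFrame:
    """SNP->gene pairs for SNPs whose own position lies inside a promoter
    window (and inside an open OCR); one row per (proxy, sentinel, gene)."""
    rows = []
    for row in accessible.itertuples():
        for win in windows.containing(row.chrom, int(row.pos)):
            rows.append(
                {
                    "proxy_rsid": row.rsid,
                    "sentinel_rsid": row.sentinel_rsid,
                    "r2": row.r2,
                    "gene_id": win.gene_id,
                    "gene_symbol": win.gene_symbol,
                    "route": "promoter_resident",
                    "cell_type": cell_type,
                    "ocr_id": row.ocr_id,
                    "partner_ocr_id": ".",
                }
            )
    df = pd.DataFrame(rows, columns=PAIR_COLUMNS)
    return df.drop_duplicates(
        subset=["proxy_rsid", "sentinel_rsid", "gene_id"]
    ).reset_index(drop=True)


def interaction_pairs(
    accessible: pd.DataFrame,
    ocr_interactions: Sequence[OcrInteraction],
    atlas: OcrAtlas,
    windows: PromoterWindows,
    cell_type: str,
) -> pd.DataFrame:
    """SNP->gene pairs routed through OCR-OCR interactions.

    For each accessible variant in OCR O and each interaction involving O,
    a pair is emitted for every gene whose promoter window overlaps the
    partner OCR; deduplicated per (proxy, sentinel, gene) with the first
    supporting OCR pair recorded.
    """
    partners: dict[str, list[str]] = defaultdict(list)
    for rec in ocr_interactions:
        partners[rec.ocr_a].append(rec.ocr_b)
        partners[rec.ocr_b].append(rec.ocr_a)
    rows = []
    for row in accessible.itertuples():
        for partner in partners.get(row.ocr_id, ()):
            iv = atlas.interval(partner)
            for gene_id, symbol in sorted(
                windows.genes_overlapping(iv.chrom, iv.start, iv.end).items()
            ):
                rows.append(
                    {
                        "proxy_rsid": row.rsid,
                        "sentinel_rsid": row.sentinel_rsid,
                        "r2": row.r2,
                        "gene_id": gene_id,
                        "gene_symbol": symbol,
                        "route": "interaction",
                        "cell_type": cell_type,
                        "ocr_id": row.ocr_id,
                        "partner_ocr_id": partner,
                    }
                )
    df = pd.DataFrame(rows, columns=PAIR_COLUMNS)
    return df.drop_duplicates(
        subset=["proxy_rsid", "sentinel_rsid", "gene_id"]
    ).reset_index(drop=True)


def nearest_gene(
    chrom: str,
    pos: int,
    transcripts: Iterable[Transcript],
    gene_universe: set[str] | None = None,
) -> str:
    """Gene with the smallest min-over-transcripts |TSS - pos| on the SNP's
    chromosome; ties broken by lexicographic gene id. ``gene_universe``
    optionally restricts candidates (e.g. to captured-promoter genes)."""
    best: dict[str, int] = {}
    for t in transcripts:
        if t.chrom != chrom:
            continue
        if gene_universe is not None and t.gene_id not in gene_universe:
            continue
        d = abs(t.tss - pos)
        if t.gene_id not in best or d < best[t.gene_id]:
            best[t.gene_id] = d
    if not best:
        raise ValueError(f"no transcripts on chromosome {chrom}")
    return min(best.items(), key=lambda kv: (kv[1], kv[0]))[0]


def categorize_variant(interaction_genes: set[str], nearest: str) -> str | None:
    """Three-way classification of a proxy's interaction-route gene set
    against its nearest gene; None when the set is empty (no category)."""
    if not interaction_genes:
        return None
    if interaction_genes == {nearest}:
        return "nearest_only"
    if nearest in interaction_genes:
        return "nearest_plus_distant"
    return "skip"


def categorize_all(
    interaction_pair_table: pd.DataFrame,
    proxies: pd.DataFrame,
    transcripts: Sequence[Transcript],
    gene_universe: set[str] | None = None,
) -> pd.DataFrame:
    """Categorize every proxy with >=1 interaction-route pair.

    Returns columns (proxy_rsid, nearest_gene, category). The nearest gene
    is computed from the SNP position over ``transcripts`` (optionally
    restricted to ``gene_universe``).
    """
    pos_of = {row.rsid: (row.chrom, int(row.pos)) for row in proxies.itertuples()}
    gene_sets: dict[str, set[str]] = defaultdict(set)
    for row in interaction_pair_table.itertuples():
        gene_sets[row.proxy_rsid].add(row.gene_id)
    rows = []
    for rsid in sorted(gene_sets):
        chrom, pos = pos_of[rsid]
        near = nearest_gene(chrom, pos, transcripts, gene_universe)
        cat = categorize_variant(gene_sets[rsid], near)
        rows.append({"proxy_rsid": rsid, "nearest_gene": near, "category": cat})
    return pd.DataFrame(rows, columns=["proxy_rsid", "nearest_gene", "category"])


def summarize_categories(categories: pd.DataFrame) -> dict:
    """Counts and fractions per category over all categorized proxies."""
    counts = {c: 0 for c in CATEGORIES}
    if len(categories):
        for c, n in categories["category"].value_counts().items():
            counts[c] = int(n)
    total = sum(counts.values())
    fractions = {
        c: (counts[c] / total if total else 0.0) for c in CATEGORIES
    }
    return {"n_categorized": total, "counts": counts, "fractions": fractions}
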