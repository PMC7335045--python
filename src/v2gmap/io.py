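"""Readers and writers for the plain-text formats the pipeline consumes and
produces: BED/narrowPeak, rmap/baitmap, ibed, transcript tables (TSV and a
minimal GTF subset), FASTA, SNP tables, eQTL pair lists and count matrices.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .genome import FragmentMap, GenomicInterval, Transcript

IBED_COLUMNS = [
    "bait_chr",
    "bait_start",
    "bait_end",
    "bait_name",
    "otherEnd_chr",
    "otherEnd_start",
    "otherEnd_end",
    "otherEnd_name",
    "N_reads",
    "score",
]


class ParseError(ValueError):
    """Malformed input file; message names the offending line."""


# ---------------------------------------------------------------------------
# BED / narrowPeak


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3+ / narrowPeak; columns beyond chrom/start/end are ignored."""
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                intervals.append(
                    GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return intervals


def write_bed(
    path: str | Path,
    intervals: Iterable[GenomicInterval],
    names: Iterable[str] | None = None,
) -> None:
    with open(path, "w") as fh:
        if names is None:
            for iv in intervals:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
        else:
            for iv, name in zip(intervals, names):
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\n")


# ---------------------------------------------------------------------------
# rmap / baitmap


def write_rmap(path: str | Path, fmap: FragmentMap) -> None:
    """rmap TSV: chrom, start, end, fragment_id (no header)."""
    with open(path, "w") as fh:
        for chrom, start, end, frag_id, _ in fmap.iter_fragments():
            fh.write(f"{chrom}\t{start}\t{end}\t{frag_id}\n")


def write_baitmap(
    path: str | Path, fmap: FragmentMap, annotations: Mapping[int, str] | None = None
) -> None:
    """baitmap TSV: bait fragments only, rmap columns + annotation."""
    annotations = annotations or {}
    with open(path, "w") as fh:
        for chrom, start, end, frag_id, bait in fmap.iter_fragments():
            if bait:
                ann = annotations.get(frag_id, ".")
                fh.write(f"{chrom}\t{start}\t{end}\t{frag_id}\t{ann}\n")


def read_rmap(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "fragment_id"],
        dtype={"chrom": str},
    )
    return df


def read_baitmap(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "fragment_id", "annotation"],
        dtype={"chrom": str},
    )
    return df


def fragment_map_from_rmap(
    rmap: pd.DataFrame, baitmap: pd.DataFrame | None = None, resolution: int = 1
) -> FragmentMap:
    """Reconstruct a FragmentMap from rmap (and optional baitmap) tables."""
    frags: dict[str, np.ndarray] = {}
    bait: dict[str, np.ndarray] = {}
    bait_ids = set(baitmap["fragment_id"]) if baitmap is not None else set()
    for chrom, grp in rmap.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        frags[chrom] = grp[["start", "end"]].to_numpy(dtype=np.int64)
        bait[chrom] = grp["fragment_id"].isin(bait_ids).to_numpy()
    return FragmentMap(frags, resolution=resolution, bait=bait)


# ---------------------------------------------------------------------------
# transcripts


def read_transcripts_tsv(path: str | Path) -> list[Transcript]:
    """TSV with header: transcript_id, gene_id, gene_symbol, chrom, strand,
    tss_1based, biotype. The 1-based TSS is converted to 0-based."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {
        "transcript_id",
        "gene_id",
        "gene_symbol",
        "chrom",
        "strand",
        "tss_1based",
        "biotype",
    }
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return [
        Transcript(
            transcript_id=row.transcript_id,
            gene_id=row.gene_id,
            gene_symbol=row.gene_symbol,
            chrom=row.chrom,
            strand=row.strand,
            tss=int(row.tss_1based) - 1,
            biotype=row.biotype,
        )
        for row in df.itertuples()
    ]


def write_transcripts_tsv(path: str | Path, transcripts: Sequence[Transcript]) -> None:
    with open(path, "w") as fh:
        fh.write(
            "transcript_id\tgene_id\tgene_symbol\tchrom\tstrand\ttss_1based\tbiotype\n"
        )
        for t in transcripts:
            fh.write(
                f"{t.transcript_id}\t{t.gene_id}\t{t.gene_symbol}\t{t.chrom}\t"
                f"{t.strand}\t{t.tss + 1}\t{t.biotype}\n"
            )


def _gtf_attributes(field: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for item in field.strip().split(";"):
        item = item.strip()
        if not item:
            continue
        key, _, value = item.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def read_transcripts_gtf(path: str | Path) -> list[Transcript]:
    """Minimal GTF subset: 'transcript' feature lines with gene_id /
    gene_name / transcript_id attributes; the TSS is the strand-dependent
    5' end of the feature."""
    transcripts: list[Transcript] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GTF columns")
            chrom, _, feature, start, end, _, strand, _, attr_field = fields
            if feature != "transcript":
                continue
            attrs = _gtf_attributes(attr_field)
            start_1b, end_1b = int(start), int(end)
            tss = start_1b - 1 if strand == "+" else end_1b - 1
            transcripts.append(
                Transcript(
                    transcript_id=attrs.get("transcript_id", f"tx_{lineno}"),
                    gene_id=attrs.get("gene_id", f"gene_{lineno}"),
                    gene_symbol=attrs.get("gene_name", attrs.get("gene_id", "")),
                    chrom=chrom,
                    strand=strand,
                    tss=tss,
                    biotype=attrs.get("transcript_type", "protein_coding"),
                )
            )
    return transcripts


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, sequences: Mapping[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


# ---------------------------------------------------------------------------
# count matrix


def read_count_matrix(
    counts_path: str | Path, library_sizes_path: str | Path
) -> tuple[pd.DataFrame, pd.Series]:
    """Counts TSV (rows = OCR ids, header = sample ids) plus a sidecar TSV of
    per-sample library sizes (sample_id, library_size)."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    libs = pd.read_csv(library_sizes_path, sep="\t", index_col=0)["library_size"]
    missing = set(counts.columns) - set(libs.index)
    if missing:
        raise ParseError(f"library sizes missing for samples: {sorted(missing)}")
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative read counts")
    return counts, libs.loc[counts.columns]


def write_count_matrix(
    counts_path: str | Path,
    library_sizes_path: str | Path,
    counts: pd.DataFrame,
    library_sizes: pd.Series,
) -> None:
    counts.to_csv(counts_path, sep="\t", index_label="ocr_id")
    library_sizes.rename("library_size").to_csv(
        library_sizes_path, sep="\t", index_label="sample_id"
    )


# ---------------------------------------------------------------------------
# SNP tables and eQTL pair lists


def read_snp_table(path: str | Path) -> pd.DataFrame:
    """Proxy/sentinel TSV: rsid, chrom, pos_1based, sentinel_rsid, r2.
    Positions are converted to 0-based in the returned 'pos' column."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"rsid", "chrom", "pos_1based", "sentinel_rsid", "r2"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    if ((df["r2"] < 0) | (df["r2"] > 1)).any():
        raise ValueError("r2 outside [0, 1]")
    df = df.copy()
    df["pos"] = df["pos_1based"].astype(int) - 1
    return df


def write_snp_table(path: str | Path, df: pd.DataFrame) -> None:
    out = df[["rsid", "chrom", "pos_1based", "sentinel_rsid", "r2"]]
    out.to_csv(path, sep="\t", index=False)


def read_eqtl_pairs(path: str | Path) -> pd.DataFrame:
    """eQTL pair TSV: sentinel_rsid, gene_symbol, source_label."""
    df = pd.read_csv(path, sep="\t")
    required = {"sentinel_rsid", "gene_symbol"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    if "source_label" not in df.columns:
        df["source_label"] = "."
    return df


def write_eqtl_pairs(path: str | Path, df: pd.DataFrame) -> None:
    df[["sentinel_rsid", "gene_symbol", "source_label"]].to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# JSON helpers


def write_json(path: str | Path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
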