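"""Genomic coordinate scaffold: restriction-fragment maps, transcripts and
promoter windows.

All coordinates are 0-based, half-open (BED convention). One-based positions
from external tables (SNPs, transcript TSS columns) are converted at parse
time. The fragment map models an in-silico DpnII digest: every chromosome is
tiled gap-free by fragments whose boundaries are the GATC motif starts, and a
lower-resolution map is obtained by concatenating k consecutive fragments
into one bin (trailing partial groups are kept as smaller bins).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "Transcript",
    "PromoterWindow",
    "PromoterWindows",
    "FragmentMap",
    "scan_motif",
    "digest_chromosome",
    "promoter_windows",
]

_DNA = set("ACGTN")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """At least 1 bp of half-open intersection on the same chromosome."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end


@dataclass(frozen=True)
class Transcript:
    transcript_id: str
    gene_id: str
    gene_symbol: str
    chrom: str
    strand: str
    tss: int  # 0-based position of the first transcribed base
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.tss < 0:
            raise ValueError("tss must be non-negative")


@dataclass(frozen=True)
class PromoterWindow:
    interval: GenomicInterval
    transcript_id: str
    gene_id: str
    gene_symbol: str


def scan_motif(sequence: str, motif: str = "GATC") -> list[int]:
    """Return sorted 0-based start positions of every occurrence of ``motif``.

    ``N`` is accepted in the sequence but never matches. Overlapping
    occurrences are reported (GATC cannot self-overlap, but the scan is
    generic).
    """
    seq = sequence.upper()
    bad = set(seq) - _DNA
    if bad:
        raise ValueError(f"non-DNA characters in sequence: {sorted(bad)}")
    positions: list[int] = []
    start = 0
    while True:
        idx = seq.find(motif, start)
        if idx < 0:
            break
        positions.append(idx)
        start = idx + 1
    return positions


def digest_chromosome(
    cut_sites: Sequence[int], chrom_length: int
) -> list[tuple[int, int]]:
    """Fragment a chromosome at the given cut positions.

    Fragment boundaries are ``{0} ∪ cut_sites ∪ {chrom_length}``; the
    returned fragments tile ``[0, chrom_length)`` exactly.
    """
    sites = list(cut_sites)
    if any(sites[i] >= sites[i + 1] for i in range(len(sites) - 1)):
        raise ValueError("cut sites must be strictly increasing")
    if sites and (sites[0] <= 0 or sites[-1] >= chrom_length):
        raise ValueError("cut sites must lie strictly inside (0, chrom_length)")
    bounds = [0] + sites + [chrom_length]
    return [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]


class FragmentMap:
    """Ordered, gap-free restriction fragments per chromosome.

    Fragments within a chromosome are sorted, abutting, start at 0 and end at
    the chromosome length. Fragment ids are genome-wide unique integers
    assigned in chromosome order. ``resolution`` is 1 for the raw digest and
    k for a map built by :meth:`concatenate`.
    """

    def __init__(
        self,
        fragments: Mapping[str, np.ndarray],
        resolution: int = 1,
        bait: Mapping[str, np.ndarray] | None = None,
    ) -> None:
        self.resolution = int(resolution)
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._first_id: dict[str, int] = {}
        self._bait: dict[str, np.ndarray] = {}
        next_id = 1
        for chrom, arr in fragments.items():
            arr = np.asarray(arr, dtype=np.int64).reshape(-1, 2)
            starts, ends = arr[:, 0], arr[:, 1]
            if len(starts) == 0:
                raise ValueError(f"chromosome {chrom} has no fragments")
            if starts[0] != 0:
                raise ValueError(f"{chrom}: first fragment must start at 0")
            if not np.all(starts[1:] == ends[:-1]):
                raise ValueError(f"{chrom}: fragments must abut without gaps")
            if not np.all(ends > starts):
                raise ValueError(f"{chrom}: empty fragment")
            self._starts[chrom] = starts
            self._ends[chrom] = ends
            self._first_id[chrom] = next_id
            next_id += len(starts)
            if bait is not None and chrom in bait:
                flags = np.asarray(bait[chrom], dtype=bool)
                if len(flags) != len(starts):
                    raise ValueError(f"{chrom}: bait flag length mismatch")
                self._bait[chrom] = flags
            else:
                self._bait[chrom] = np.zeros(len(starts), dtype=bool)

    # -- construction -----------------------------------------------------

    @classmethod
    def from_cut_sites(
        cls,
        cut_sites: Mapping[str, Sequence[int]],
        chrom_lengths: Mapping[str, int],
    ) -> "FragmentMap":
        frags = {
            chrom: np.array(
                digest_chromosome(cut_sites.get(chrom, []), length), dtype=np.int64
            )
            for chrom, length in chrom_lengths.items()
        }
        return cls(frags, resolution=1)

    @classmethod
    def from_sequences(
        cls, sequences: Mapping[str, str], motif: str = "GATC"
    ) -> "FragmentMap":
        sites = {c: scan_motif(s, motif) for c, s in sequences.items()}
        lengths = {c: len(s) for c, s in sequences.items()}
        # drop a cut at position 0: boundary already present
        sites = {c: [p for p in v if p > 0] for c, v in sites.items()}
        return cls.from_cut_sites(sites, lengths)

    # -- queries ----------------------------------------------------------

    @property
    def chroms(self) -> list[str]:
        return list(self._starts)

    def chrom_length(self, chrom: str) -> int:
        return int(self._ends[chrom][-1])

    def n_fragments(self, chrom: str | None = None) -> int:
        if chrom is not None:
            return len(self._starts[chrom])
        return sum(len(v) for v in self._starts.values())

    def starts(self, chrom: str) -> np.ndarray:
        return self._starts[chrom]

    def ends(self, chrom: str) -> np.ndarray:
        return self._ends[chrom]

    def bait_flags(self, chrom: str) -> np.ndarray:
        return self._bait[chrom]

    def fragment_id(self, chrom: str, index: int) -> int:
        return self._first_id[chrom] + index

    def fragment(self, chrom: str, index: int) -> GenomicInterval:
        return GenomicInterval(
            chrom, int(self._starts[chrom][index]), int(self._ends[chrom][index])
        )

    def index_at(self, chrom: str, pos: int) -> int:
        """Index of the fragment containing 0-based position ``pos``."""
        if chrom not in self._starts:
            raise KeyError(chrom)
        if not (0 <= pos < self.chrom_length(chrom)):
            raise ValueError(f"position {pos} outside {chrom}")
        return int(np.searchsorted(self._ends[chrom], pos, side="right"))

    def overlapping(self, chrom: str, start: int, end: int) -> range:
        """Indices of fragments with >=1 bp overlap with [start, end)."""
        if chrom not in self._starts:
            return range(0)
        lo = int(np.searchsorted(self._ends[chrom], start, side="right"))
        hi = int(np.searchsorted(self._starts[chrom], end, side="left"))
        return range(lo, hi)

    def iter_fragments(self) -> Iterator[tuple[str, int, int, int, bool]]:
        """Yield (chrom, start, end, fragment_id, is_bait) in genome order."""
        for chrom in self.chroms:
            first = self._first_id[chrom]
            for i in range(len(self._starts[chrom])):
                yield (
                    chrom,
                    int(self._starts[chrom][i]),
                    int(self._ends[chrom][i]),
                    first + i,
                    bool(self._bait[chrom][i]),
                )

    def to_frame(self) -> pd.DataFrame:
        rows = list(self.iter_fragments())
        return pd.DataFrame(
            rows, columns=["chrom", "start", "end", "fragment_id", "bait"]
        )

    # -- transforms -------------------------------------------------------

    def concatenate(self, k: int = 4) -> "FragmentMap":
        """Merge consecutive groups of ``k`` fragments into one bin.

        The trailing partial group on each chromosome is kept as a smaller
        bin; a bin is bait-flagged iff any member fragment is. The coordinate
        cover of the output is identical to the input.
        """
        if k < 1:
            raise ValueError("k must be >= 1")
        if self.resolution != 1:
            raise ValueError("can only concatenate a resolution-1 map")
        frags: dict[str, np.ndarray] = {}
        bait: dict[str, np.ndarray] = {}
        for chrom in self.chroms:
            starts, ends = self._starts[chrom], self._ends[chrom]
            n = len(starts)
            bs = starts[0::k]
            be = np.append(ends[k - 1 :: k], ends[-1]) if n % k else ends[k - 1 :: k]
            be = be[: len(bs)]
            flags = np.array(
                [bool(self._bait[chrom][i : i + k].any()) for i in range(0, n, k)]
            )
            frags[chrom] = np.column_stack([bs, be])
            bait[chrom] = flags
        return FragmentMap(frags, resolution=k, bait=bait)

    def bin_index_of(self, chrom: str, frag_index: int, k: int) -> int:
        """Bin index (in the k-concatenated map) containing fragment ``frag_index``."""
        return frag_index // k

    def assign_baits(self, windows: "PromoterWindows") -> "FragmentMap":
        """Return a copy with fragments flagged bait iff they overlap (>=1 bp)
        any promoter window."""
        bait: dict[str, np.ndarray] = {}
        for chrom in self.chroms:
            flags = np.zeros(len(self._starts[chrom]), dtype=bool)
            for win in windows.on_chrom(chrom):
                idx = self.overlapping(chrom, win.interval.start, win.interval.end)
                flags[idx.start : idx.stop] = True
            bait[chrom] = flags
        frags = {
            chrom: np.column_stack([self._starts[chrom], self._ends[chrom]])
            for chrom in self.chroms
        }
        return FragmentMap(frags, resolution=self.resolution, bait=bait)


def promoter_windows(
    transcripts: Iterable[Transcript],
    upstream: int = 1500,
    downstream: int = 500,
    chrom_lengths: Mapping[str, int] | None = None,
) -> "PromoterWindows":
    """Strand-aware promoter windows around each transcript TSS.

    On the + strand the window is ``[tss - upstream, tss + downstream)``; on
    the - strand it is reflected to ``[tss - downstream, tss + upstream)``.
    Windows are clipped to ``[0, chromosome length)``.
    """
    wins: list[PromoterWindow] = []
    for t in transcripts:
        if t.strand == "+":
            start, end = t.tss - upstream, t.tss + downstream
        else:
            start, end = t.tss - downstream, t.tss + upstream
        start = max(start, 0)
        if chrom_lengths is not None and t.chrom in chrom_lengths:
            end = min(end, chrom_lengths[t.chrom])
        if end <= start:
            continue  # fully clipped away at a chromosome edge
        wins.append(
            PromoterWindow(
                GenomicInterval(t.chrom, start, end),
                t.transcript_id,
                t.gene_id,
                t.gene_symbol,
            )
        )
    return PromoterWindows(wins)


class PromoterWindows:
    """Indexed collection of promoter windows supporting overlap queries."""

    def __init__(self, windows: Sequence[PromoterWindow]) -> None:
        self._windows = list(windows)
        self._trees: dict[str, IntervalTree] = {}
        for w in self._windows:
            tree = self._trees.setdefault(w.interval.chrom, IntervalTree())
            tree.addi(w.interval.start, w.interval.end, w)

    def __len__(self) -> int:
        return len(self._windows)

    def __iter__(self) -> Iterator[PromoterWindow]:
        return iter(self._windows)

    def on_chrom(self, chrom: str) -> list[PromoterWindow]:
        return [w for w in self._windows if w.interval.chrom == chrom]

    def overlapping(self, chrom: str, start: int, end: int) -> list[PromoterWindow]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted(
            (iv.data for iv in tree.overlap(start, end)),
            key=lambda w: (w.interval.start, w.interval.end, w.transcript_id),
        )

    def containing(self, chrom: str, pos: int) -> list[PromoterWindow]:
        return self.overlapping(chrom, pos, pos + 1)

    def genes_overlapping(self, chrom: str, start: int, end: int) -> dict[str, str]:
        """gene_id -> gene_symbol for windows overlapping the interval."""
        return {
            w.gene_id: w.gene_symbol for w in self.overlapping(chrom, start, end)
        }

    def gene_ids(self) -> set[str]:
        return {w.gene_id for w in self._windows}
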