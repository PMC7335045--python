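"""Seeded synthetic datasets with known ground truth for every pipeline
stage.

The generator emulates the study's inputs on a toy multi-chromosome genome:
GATC cut sites are Poisson-spaced at a configurable density (~4/kb, the
empirical DpnII site density); genes sit on a regular grid with jittered,
strand-assigned TSS; each inter-gene interval hosts one distal open-chromatin
region (OCR) slot; replicate ATAC peak sets are emitted with jittered
boundaries and partial reproducibility plus single-replicate noise peaks
that the two-replicate consensus filter must remove; significant capture
interactions (scores straddling the threshold of 5) connect baited promoter
fragments to distal fragments at 1- and 4-fragment resolution; sentinel and
proxy SNPs are planted inside chosen OCRs so that the three nearest-gene
categories (nearest-only / nearest-plus-distant / skip) are realized at an
exact planned mix; and eQTL pair lists contain a planted number of
overlapping sentinel-gene pairs.

Planted contacts are verified at generation time so that no proxy can gain
an unplanned gene through fragment- or bin-level overlap spillover: a
contact is only emitted at 4-fragment resolution when the bin touches no
foreign promoter OCR or proxy-bearing OCR (otherwise it falls back to
1-fragment resolution).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import (
    FragmentMap,
    GenomicInterval,
    PromoterWindows,
    Transcript,
    promoter_windows,
)
from .interactions import FragmentInteraction
from . import io as vio

__all__ = [
    "SimulationConfig",
    "GenomeBundle",
    "AtacBundle",
    "InteractionBundle",
    "VariantBundle",
    "TruthTable",
    "simulate_genome",
    "simulate_atac",
    "simulate_interactions",
    "simulate_variants",
    "simulate_study",
    "write_study",
]

# distances within a 25 kb gene slot (see module docstring); the free zone
# past the distal OCR hosts sentinels, inaccessible proxies and noise peaks
_TSS_OFFSET = 4000
_TSS_JITTER = 2000
_DISTAL_OFFSET = 14_000
_DISTAL_JITTER = 2000
_SENTINEL_OFFSET = 20_000
_INACCESSIBLE_OFFSET = 21_500
_NOISE_OFFSET = 23_000
_SAFETY_PAD = 60  # guards against replicate-peak boundary jitter


@dataclass
class SimulationConfig:
    """Study-scale defaults: ~60 GWAS sentinels, ~460 proxy SNPs of which
    250 are planted in distal open chromatin with the published category mix
    (8.5 / 29 / 62.5 %), promoter windows −1500/+500, score threshold 5,
    CPM filter 1.5 in ≥50% of samples, LD thresholds 0.8/0.4, 5 Mb pool
    window and 100,000 resampling reps."""

    seed: int = 0
    n_chroms: int = 4
    n_genes: int = 1200
    gene_spacing: int = 25_000
    margin: int = 50_000
    chrom_lengths: dict[str, int] | None = None  # derived when None
    gatc_per_kb: float = 4.0
    promoter_upstream: int = 1500
    promoter_downstream: int = 500
    cell_types: tuple[str, ...] = ("naive", "tfh")
    focal_cell_type: str = "tfh"
    n_replicates: int = 3
    peak_reproducibility: float = 0.85
    peak_jitter: int = 40
    ocr_halfwidth_min: int = 150
    ocr_halfwidth_max: int = 450
    p_distal_open_focal: float = 0.9
    p_distal_open_other: float = 0.5
    noise_peaks_per_replicate: int = 10
    n_blacklist: int = 2
    library_size: int = 2_000_000
    open_count_mean: float = 30.0
    closed_count_mean: float = 0.5
    noise_count_mean: float = 1.0
    score_sig_range: tuple[float, float] = (5.0, 20.0)
    score_decoy_range: tuple[float, float] = (0.5, 4.99)
    n_decoys: int = 150
    p_share_other: float = 0.7
    min_contact_bp: int = 10_000
    max_contact_bp: int = 1_500_000
    n_sentinels: int = 60
    n_categorized: int = 250
    n_promoter_resident: int = 60
    n_inaccessible: int = 150
    category_mix: tuple[float, float, float] = (0.085, 0.29, 0.625)
    p_r2_high: float = 0.6
    planted_eqtl_overlap: int = 19
    n_eqtl_extra: int = 65
    cpm_threshold: float = 1.5
    cpm_sample_fraction: float = 0.5
    r2_threshold_strict: float = 0.8
    r2_threshold_relaxed: float = 0.4
    empirical_reps: int = 100_000
    pool_window_bp: int = 5_000_000

    def __post_init__(self) -> None:
        if abs(sum(self.category_mix) - 1.0) > 1e-9:
            raise ValueError("category mix must sum to 1")
        if not (0 <= self.peak_reproducibility <= 1):
            raise ValueError("peak reproducibility must be in [0, 1]")
        for name in ("n_genes", "n_chroms", "n_replicates"):
            if getattr(self, name) < 0 or (name != "n_genes" and getattr(self, name) < 1):
                raise ValueError(f"{name} must be positive")
        if self.focal_cell_type not in self.cell_types:
            raise ValueError("focal cell type must be among cell types")

    def genes_per_chrom(self) -> list[int]:
        base, rem = divmod(self.n_genes, self.n_chroms)
        return [base + (1 if i < rem else 0) for i in range(self.n_chroms)]

    def derived_chrom_lengths(self) -> dict[str, int]:
        if self.chrom_lengths is not None:
            for i, n in enumerate(self.genes_per_chrom()):
                chrom = f"chr{i + 1}"
                need = 2 * self.margin + n * self.gene_spacing
                have = self.chrom_lengths.get(chrom, 0)
                if have < need:
                    raise ValueError(
                        f"{chrom}: length {have} too small for {n} genes at "
                        f"spacing {self.gene_spacing} (need {need})"
                    )
            return dict(self.chrom_lengths)
        return {
            f"chr{i + 1}": 2 * self.margin + n * self.gene_spacing
            for i, n in enumerate(self.genes_per_chrom())
        }


@dataclass
class GenomeBundle:
    chrom_lengths: dict[str, int]
    cut_sites: dict[str, list[int]]
    transcripts: list[Transcript]
    gene_slots: dict[str, list[int]]  # slot start coordinates per chromosome
    _fmap1: FragmentMap | None = None
    _fmap4: FragmentMap | None = None
    _windows: PromoterWindows | None = None

    def fragment_map(self) -> FragmentMap:
        if self._fmap1 is None:
            self._fmap1 = FragmentMap.from_cut_sites(self.cut_sites, self.chrom_lengths)
        return self._fmap1

    def fragment_map4(self) -> FragmentMap:
        if self._fmap4 is None:
            self._fmap4 = self.fragment_map().concatenate(4)
        return self._fmap4

    def windows(self, upstream: int = 1500, downstream: int = 500) -> PromoterWindows:
        if self._windows is None:
            self._windows = promoter_windows(
                self.transcripts, upstream, downstream, self.chrom_lengths
            )
        return self._windows


@dataclass
class TrueOcr:
    id: str
    interval: GenomicInterval
    kind: str  # 'promoter' | 'distal' | 'noise'
    gene_id: str | None = None
    slot: tuple[str, int] | None = None  # (chrom, slot index)
    emitted: dict[str, int] = field(default_factory=dict)  # ct -> n replicates
    in_atlas: bool = False
    open_in: set[str] = field(default_factory=set)
    blacklisted: bool = False


@dataclass
class AtacBundle:
    ocrs: list[TrueOcr]
    replicate_peaks: dict[str, list[list[GenomicInterval]]]  # ct -> per-rep
    blacklist: list[GenomicInterval]
    counts: pd.DataFrame
    library_sizes: pd.Series

    def by_id(self) -> dict[str, TrueOcr]:
        return {o.id: o for o in self.ocrs}

    def promoter_ocr_of(self) -> dict[str, TrueOcr]:
        return {o.gene_id: o for o in self.ocrs if o.kind == "promoter"}


@dataclass
class PlannedProxy:
    rsid: str
    chrom: str
    pos: int  # 0-based
    ocr_id: str | None  # true OCR id, None when inaccessible
    category: str | None  # None for non-categorized proxies
    genes: tuple[str, ...]  # planted interaction-route gene ids
    route: str  # 'interaction' | 'promoter_resident' | 'none'
    sentinel_rsid: str = ""
    r2: float = 1.0


@dataclass
class InteractionBundle:
    calls: dict[str, dict[int, list[FragmentInteraction]]]  # ct -> res -> recs
    plan: list[PlannedProxy]
    resident_genes: list[str]


@dataclass
class VariantBundle:
    proxies: pd.DataFrame  # rsid, chrom, pos_1based, pos, sentinel_rsid, r2
    sentinels: pd.DataFrame  # rsid, chrom, pos
    eqtl: pd.DataFrame  # sentinel_rsid, gene_symbol, source_label
    planted_overlap: list[tuple[str, str]]


@dataclass
class TruthTable:
    proxies: list[PlannedProxy]
    eqtl_overlap_pairs: list[tuple[str, str]]
    ocr_openness: dict[str, list[str]]  # true OCR id -> open cell types
    gene_symbols: dict[str, str]

    def planted_pairs(self) -> set[tuple[str, str]]:
        """Planted interaction-route (proxy rsid, gene id) pairs."""
        return {
            (p.rsid, g)
            for p in self.proxies
            if p.route == "interaction"
            for g in p.genes
        }

    def categories(self) -> dict[str, str]:
        return {
            p.rsid: p.category for p in self.proxies if p.category is not None
        }


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


# ---------------------------------------------------------------------------
# genome


def simulate_genome(config: SimulationConfig) -> GenomeBundle:
    """Toy genome: Poisson GATC sites, gridded genes with jittered TSS."""
    rng = _rng(config, 1)
    lengths = config.derived_chrom_lengths()
    cut_sites: dict[str, list[int]] = {}
    transcripts: list[Transcript] = []
    gene_slots: dict[str, list[int]] = {}
    gene_idx = 0
    per_chrom = config.genes_per_chrom()
    for ci, (chrom, length) in enumerate(lengths.items()):
        mean_gap = 1000.0 / config.gatc_per_kb
        n_expect = int(length / mean_gap * 1.3) + 100
        gaps = np.maximum(1, rng.exponential(mean_gap, size=n_expect).astype(np.int64))
        sites = np.cumsum(gaps)
        sites = sites[sites < length]
        cut_sites[chrom] = [int(s) for s in sites]
        slots: list[int] = []
        n_here = per_chrom[ci] if ci < len(per_chrom) else 0
        for i in range(n_here):
            slot = config.margin + i * config.gene_spacing
            slots.append(slot)
            tss = slot + _TSS_OFFSET + int(rng.integers(-_TSS_JITTER, _TSS_JITTER + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            gid = f"G{gene_idx:05d}"
            transcripts.append(
                Transcript(
                    transcript_id=f"{gid}.t1",
                    gene_id=gid,
                    gene_symbol=f"GENE{gene_idx:05d}",
                    chrom=chrom,
                    strand=strand,
                    tss=tss,
                )
            )
            gene_idx += 1
        gene_slots[chrom] = slots
    return GenomeBundle(
        chrom_lengths=lengths,
        cut_sites=cut_sites,
        transcripts=transcripts,
        gene_slots=gene_slots,
    )


# ---------------------------------------------------------------------------
# ATAC


def simulate_atac(genome: GenomeBundle, config: SimulationConfig) -> AtacBundle:
    """Replicate peak sets, blacklist, and an OCR read-count matrix.

    True OCRs open in the focal cell type (and all promoter OCRs) are
    guaranteed support from at least two replicates so every planted
    variant-to-gene path survives the consensus filter; noise peaks appear
    in exactly one replicate and are removed by it. Counts are drawn so
    true-open OCRs pass the CPM retention rule and noise rows fail it.
    """
    rng = _rng(config, 2)
    cts = list(config.cell_types)
    focal = config.focal_cell_type
    ocrs: list[TrueOcr] = []

    # promoter OCRs: one per gene, centered on the TSS, open in all cell types
    for t in genome.transcripts:
        iv = GenomicInterval(t.chrom, t.tss - 200, t.tss + 200)
        ocrs.append(
            TrueOcr(
                id=f"{iv.chrom}:{iv.start}-{iv.end}",
                interval=iv,
                kind="promoter",
                gene_id=t.gene_id,
            )
        )
    # distal OCRs: one slot per inter-gene interval
    for chrom, slots in genome.gene_slots.items():
        for si, slot in enumerate(slots):
            center = slot + _DISTAL_OFFSET + int(
                rng.integers(-_DISTAL_JITTER, _DISTAL_JITTER + 1)
            )
            hw = int(rng.integers(config.ocr_halfwidth_min, config.ocr_halfwidth_max + 1))
            iv = GenomicInterval(chrom, center - hw, center + hw)
            ocrs.append(
                TrueOcr(
                    id=f"{iv.chrom}:{iv.start}-{iv.end}",
                    interval=iv,
                    kind="distal",
                    slot=(chrom, si),
                )
            )
    # intended openness
    for o in ocrs:
        if o.kind == "promoter":
            intended = set(cts)
        else:
            intended = set()
            if rng.random() < config.p_distal_open_focal:
                intended.add(focal)
            for ct in cts:
                if ct != focal and rng.random() < config.p_distal_open_other:
                    intended.add(ct)
        o.open_in = intended  # refined below from emitted replicate counts

    # noise OCRs in the free zone: exactly one (cell type, replicate) each
    n_noise_total = config.noise_peaks_per_replicate * config.n_replicates * len(cts)
    free_slots = [
        (chrom, slot) for chrom, slots in genome.gene_slots.items() for slot in slots
    ]
    noise_assign: list[tuple[TrueOcr, str, int]] = []
    if n_noise_total > len(free_slots):
        raise ValueError("too many noise peaks for the available free zones")
    chosen = rng.choice(len(free_slots), size=n_noise_total, replace=False)
    k = 0
    for ct in cts:
        for rep in range(config.n_replicates):
            for _ in range(config.noise_peaks_per_replicate):
                chrom, slot = free_slots[int(chosen[k])]
                center = slot + _NOISE_OFFSET + int(rng.integers(0, 501))
                hw = int(rng.integers(100, 201))
                iv = GenomicInterval(chrom, center - hw, center + hw)
                o = TrueOcr(
                    id=f"{iv.chrom}:{iv.start}-{iv.end}", interval=iv, kind="noise"
                )
                ocrs.append(o)
                noise_assign.append((o, ct, rep))
                k += 1

    # replicate peaks with boundary jitter
    peaks: dict[str, list[list[GenomicInterval]]] = {
        ct: [[] for _ in range(config.n_replicates)] for ct in cts
    }

    def jittered(iv: GenomicInterval) -> GenomicInterval:
        j = config.peak_jitter
        s = iv.start + int(rng.integers(-j, j + 1))
        e = iv.end + int(rng.integers(-j, j + 1))
        if e <= s + 50:
            e = s + 50
        return GenomicInterval(iv.chrom, max(0, s), e)

    for o in ocrs:
        if o.kind == "noise":
            continue
        essential = o.kind == "promoter" or focal in o.open_in
        for ct in cts:
            if ct not in o.open_in:
                continue
            present = rng.random(config.n_replicates) < config.peak_reproducibility
            if essential and (ct == focal or o.kind == "promoter") and present.sum() < 2:
                forced = rng.choice(config.n_replicates, size=2, replace=False)
                present[:] = False
                present[forced] = True
            n_present = int(present.sum())
            o.emitted[ct] = n_present
            for rep in np.flatnonzero(present):
                peaks[ct][int(rep)].append(jittered(o.interval))
    for o, ct, rep in noise_assign:
        o.emitted[ct] = 1
        peaks[ct][rep].append(jittered(o.interval))

    # blacklist: pick distal OCR slots, mark them removed from the atlas
    distal = [o for o in ocrs if o.kind == "distal"]
    if config.n_blacklist:
        picks = rng.choice(len(distal), size=min(config.n_blacklist, len(distal)), replace=False)
        for p in picks:
            distal[int(p)].blacklisted = True
    blacklist = [
        GenomicInterval(o.interval.chrom, o.interval.start - 100, o.interval.end + 100)
        for o in ocrs
        if o.blacklisted
    ]

    # realized atlas membership / openness (mirrors the consensus rules)
    for o in ocrs:
        o.in_atlas = (not o.blacklisted) and any(n >= 2 for n in o.emitted.values())
        o.open_in = (
            {ct for ct, n in o.emitted.items() if n >= 1} if o.in_atlas else set()
        )

    # count matrix
    samples = [f"{ct}_rep{r + 1}" for ct in cts for r in range(config.n_replicates)]
    rows = []
    index = []
    for o in ocrs:
        index.append(o.id)
        row = []
        for ct in cts:
            if o.kind == "noise":
                lam = config.noise_count_mean
            elif ct in o.open_in or (o.kind != "noise" and ct in o.emitted):
                lam = config.open_count_mean
            else:
                lam = config.closed_count_mean
            row.extend(rng.poisson(lam, size=config.n_replicates))
        rows.append(row)
    counts = pd.DataFrame(rows, index=pd.Index(index, name="ocr_id"), columns=samples)
    libs = pd.Series(
        [config.library_size] * len(samples), index=samples, name="library_size"
    )
    return AtacBundle(
        ocrs=ocrs,
        replicate_peaks=peaks,
        blacklist=blacklist,
        counts=counts,
        library_sizes=libs,
    )


# ---------------------------------------------------------------------------
# interactions


def _category_counts(n: int, mix: Sequence[float]) -> list[int]:
    """Largest-remainder rounding of ``n * mix`` summing exactly to n."""
    raw = [n * m for m in mix]
    base = [math.floor(x) for x in raw]
    rem = n - sum(base)
    order = sorted(range(len(mix)), key=lambda i: raw[i] - base[i], reverse=True)
    for i in order[:rem]:
        base[i] += 1
    return base


class _OcrIndex:
    """Sorted-array overlap lookup over a set of non-overlapping intervals."""

    def __init__(self, ocrs: Sequence[TrueOcr]) -> None:
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[TrueOcr]]] = {}
        grouped: dict[str, list[TrueOcr]] = {}
        for o in ocrs:
            grouped.setdefault(o.interval.chrom, []).append(o)
        for chrom, items in grouped.items():
            items.sort(key=lambda o: o.interval.start)
            starts = np.array([o.interval.start for o in items])
            ends = np.array([o.interval.end for o in items])
            self._by_chrom[chrom] = (starts, ends, items)

    def overlapping(self, chrom: str, start: int, end: int, pad: int = 0) -> list[TrueOcr]:
        if chrom not in self._by_chrom:
            return []
        starts, ends, items = self._by_chrom[chrom]
        lo = int(np.searchsorted(ends, start - pad, side="right"))
        hi = int(np.searchsorted(starts, end + pad, side="left"))
        return items[lo:hi]


def simulate_interactions(
    genome: GenomeBundle, atac: AtacBundle, config: SimulationConfig
) -> InteractionBundle:
    """Plant promoter-fragment <-> distal-fragment contacts realizing the
    configured category mix, plus sub-threshold decoys, and plan the proxy
    SNPs those contacts will implicate."""
    rng = _rng(config, 3)
    focal = config.focal_cell_type
    fmap1 = genome.fragment_map()
    fmap4 = genome.fragment_map4()
    tx_by_gene = {t.gene_id: t for t in genome.transcripts}
    prom_ocr = atac.promoter_ocr_of()

    # genes per chromosome sorted by TSS, for nearest-gene computation
    tss_by_chrom: dict[str, tuple[np.ndarray, list[str]]] = {}
    for chrom in genome.chrom_lengths:
        genes = sorted(
            (t for t in genome.transcripts if t.chrom == chrom),
            key=lambda t: t.tss,
        )
        tss_by_chrom[chrom] = (
            np.array([t.tss for t in genes], dtype=np.int64),
            [t.gene_id for t in genes],
        )

    def nearest(chrom: str, pos: int) -> str:
        tss, gids = tss_by_chrom[chrom]
        d = np.abs(tss - pos)
        best = d.min()
        return min(g for g, dd in zip(gids, d) if dd == best)

    eligible = [
        o
        for o in atac.ocrs
        if o.kind == "distal"
        and not o.blacklisted
        and focal in o.open_in
    ]
    if len(eligible) < config.n_categorized:
        raise ValueError(
            f"cannot plant {config.n_categorized} categorized proxies: only "
            f"{len(eligible)} focal-open distal OCRs available"
        )
    pick = sorted(rng.choice(len(eligible), size=config.n_categorized, replace=False))
    chosen = [eligible[int(i)] for i in pick]
    counts = _category_counts(config.n_categorized, config.category_mix)
    labels = (
        ["nearest_only"] * counts[0]
        + ["nearest_plus_distant"] * counts[1]
        + ["skip"] * counts[2]
    )
    rng.shuffle(labels)

    # promoter-resident host genes, chosen up front so contact planting can
    # steer clear of their promoter OCRs (a stray bin overlap would hand the
    # resident proxy an unplanned interaction-route gene)
    all_genes = [t.gene_id for t in genome.transcripts]
    n_res = min(config.n_promoter_resident, len(all_genes))
    resident_genes = sorted(
        all_genes[int(i)]
        for i in rng.choice(len(all_genes), size=n_res, replace=False)
    )
    resident_prom_ocrs = {prom_ocr[g].id for g in resident_genes}

    prom_index = _OcrIndex([o for o in atac.ocrs if o.kind == "promoter"])
    chosen_index = _OcrIndex(chosen)

    def bait_safe(iv: GenomicInterval, own: str) -> bool:
        hits = prom_index.overlapping(iv.chrom, iv.start, iv.end, pad=_SAFETY_PAD)
        return all(h.id == own for h in hits)

    def other_safe(iv: GenomicInterval, own: str) -> bool:
        prox = chosen_index.overlapping(iv.chrom, iv.start, iv.end, pad=_SAFETY_PAD)
        if any(h.id != own for h in prox):
            return False
        proms = prom_index.overlapping(iv.chrom, iv.start, iv.end, pad=_SAFETY_PAD)
        return not any(h.id in resident_prom_ocrs for h in proms)

    calls: dict[str, dict[int, list[FragmentInteraction]]] = {
        ct: {1: [], 4: []} for ct in config.cell_types
    }
    plan: list[PlannedProxy] = []

    def frag_iv(chrom: str, pos: int, k: int) -> GenomicInterval:
        idx = fmap1.index_at(chrom, pos)
        if k == 1:
            return fmap1.fragment(chrom, idx)
        return fmap4.fragment(chrom, idx // 4)

    def emit_contact(gene_id: str, ocr: TrueOcr, pos: int, share_other: bool) -> None:
        t = tx_by_gene[gene_id]
        chrom = t.chrom
        own_prom = prom_ocr[gene_id].id
        res_mode = int(rng.integers(3))  # 0: 1-frag, 1: 4-frag, 2: both
        use = {1} if res_mode == 0 else ({4} if res_mode == 1 else {1, 4})
        if 4 in use:
            b4 = frag_iv(chrom, t.tss, 4)
            o4 = frag_iv(chrom, pos, 4)
            if not (bait_safe(b4, own_prom) and other_safe(o4, ocr.id)):
                use = {1}
        for k in sorted(use):
            bait = frag_iv(chrom, t.tss, k)
            other = frag_iv(chrom, pos, k)
            if k == 1 and not (bait_safe(bait, own_prom) and other_safe(other, ocr.id)):
                raise RuntimeError(
                    "1-fragment contact failed safety check; layout too dense"
                )
            rec = FragmentInteraction(
                bait=bait,
                bait_name=t.gene_symbol,
                other=other,
                other_name=".",
                n_reads=int(rng.integers(5, 200)),
                score=round(float(rng.uniform(*config.score_sig_range)), 2),
                resolution=k,
                cell_type=focal,
            )
            calls[focal][k].append(rec)
            if share_other:
                for ct in config.cell_types:
                    if ct != focal and ct in ocr.open_in:
                        calls[ct][k].append(
                            FragmentInteraction(
                                bait=rec.bait,
                                bait_name=rec.bait_name,
                                other=rec.other,
                                other_name=rec.other_name,
                                n_reads=rec.n_reads,
                                score=rec.score,
                                resolution=k,
                                cell_type=ct,
                            )
                        )

    proxy_idx = 0
    for ocr, label in zip(chosen, labels):
        chrom = ocr.interval.chrom
        pos = int(rng.integers(ocr.interval.start + 50, ocr.interval.end - 50))
        near = nearest(chrom, pos)
        tss_arr, gids = tss_by_chrom[chrom]
        dist = np.abs(tss_arr - pos)
        distant_ok = [
            g
            for g, d in zip(gids, dist)
            if g != near and config.min_contact_bp <= d <= config.max_contact_bp
        ]
        if label != "nearest_only" and not distant_ok:
            raise ValueError(
                "no distant gene available within contact range; increase genome size"
            )
        if label == "nearest_only":
            targets = [near]
        elif label == "nearest_plus_distant":
            n_extra = int(rng.integers(1, 3))
            extra = rng.choice(len(distant_ok), size=min(n_extra, len(distant_ok)), replace=False)
            targets = [near] + sorted(distant_ok[int(i)] for i in extra)
        else:  # skip
            n_t = int(rng.integers(1, 3))
            picks = rng.choice(len(distant_ok), size=min(n_t, len(distant_ok)), replace=False)
            targets = sorted(distant_ok[int(i)] for i in picks)
        share = rng.random() < config.p_share_other
        for g in targets:
            emit_contact(g, ocr, pos, share)
        plan.append(
            PlannedProxy(
                rsid=f"rs{1_000_000 + proxy_idx}",
                chrom=chrom,
                pos=pos,
                ocr_id=ocr.id,
                category=label,
                genes=tuple(sorted(targets)),
                route="interaction",
            )
        )
        proxy_idx += 1

    # promoter-resident proxies: positioned at the TSS, inside the promoter
    # OCR and promoter window; no planted interaction route
    for g in resident_genes:
        t = tx_by_gene[g]
        plan.append(
            PlannedProxy(
                rsid=f"rs{1_000_000 + proxy_idx}",
                chrom=t.chrom,
                pos=t.tss,
                ocr_id=prom_ocr[g].id,
                category=None,
                genes=(g,),
                route="promoter_resident",
            )
        )
        proxy_idx += 1

    # inaccessible proxies in free zones (no OCR)
    free = [
        (chrom, slot) for chrom, slots in genome.gene_slots.items() for slot in slots
    ]
    if config.n_inaccessible > len(free):
        raise ValueError("too many inaccessible proxies for the available free zones")
    picks = rng.choice(len(free), size=config.n_inaccessible, replace=False)
    for i in picks:
        chrom, slot = free[int(i)]
        pos = slot + _INACCESSIBLE_OFFSET + int(rng.integers(0, 1001))
        plan.append(
            PlannedProxy(
                rsid=f"rs{1_000_000 + proxy_idx}",
                chrom=chrom,
                pos=pos,
                ocr_id=None,
                category=None,
                genes=(),
                route="none",
            )
        )
        proxy_idx += 1

    # sub-threshold decoys: would rewire the map if the score filter leaked
    tx_list = genome.transcripts
    for _ in range(config.n_decoys):
        t = tx_list[int(rng.integers(len(tx_list)))]
        offset = int(rng.integers(config.min_contact_bp, config.max_contact_bp))
        sign = -1 if rng.random() < 0.5 else 1
        pos = min(
            max(t.tss + sign * offset, 1), genome.chrom_lengths[t.chrom] - 2
        )
        for ct in config.cell_types:
            k = 1 if rng.random() < 0.5 else 4
            calls[ct][k].append(
                FragmentInteraction(
                    bait=frag_iv(t.chrom, t.tss, k),
                    bait_name=t.gene_symbol,
                    other=frag_iv(t.chrom, pos, k),
                    other_name=".",
                    n_reads=int(rng.integers(1, 10)),
                    score=round(float(rng.uniform(*config.score_decoy_range)), 2),
                    resolution=k,
                    cell_type=ct,
                )
            )
    return InteractionBundle(calls=calls, plan=plan, resident_genes=resident_genes)


# ---------------------------------------------------------------------------
# variants


def simulate_variants(
    genome: GenomeBundle,
    interactions: InteractionBundle,
    config: SimulationConfig,
) -> tuple[VariantBundle, TruthTable]:
    """Sentinel/proxy tables with assigned r² and an eQTL pair list holding
    the planted sentinel-gene overlap."""
    rng = _rng(config, 4)
    plan = [
        PlannedProxy(**{**p.__dict__}) for p in interactions.plan
    ]  # shallow copies so the input bundle stays unmodified
    if len(plan) < config.n_sentinels:
        raise ValueError("fewer proxies than sentinels; reduce n_sentinels")

    # assign proxies to sentinels round-robin; sentinel sits in the free zone
    # of its first proxy's gene slot
    sentinel_rows = []
    for s in range(config.n_sentinels):
        first = plan[s]
        slot = (
            (first.pos - config.margin) // config.gene_spacing
        ) * config.gene_spacing + config.margin
        pos = slot + _SENTINEL_OFFSET + int(rng.integers(0, 1001))
        pos = min(max(pos, 0), genome.chrom_lengths[first.chrom] - 1)
        sentinel_rows.append(
            {"rsid": f"rs{500_000 + s}", "chrom": first.chrom, "pos": pos}
        )
    sentinels = pd.DataFrame(sentinel_rows)

    for i, p in enumerate(plan):
        p.sentinel_rsid = sentinels.iloc[i % config.n_sentinels]["rsid"]
        if rng.random() < config.p_r2_high:
            p.r2 = round(float(rng.uniform(0.8, 1.0)), 3)
        else:
            p.r2 = round(float(rng.uniform(0.4, 0.8)), 3)

    proxy_rows = [
        {
            "rsid": p.rsid,
            "chrom": p.chrom,
            "pos_1based": p.pos + 1,
            "pos": p.pos,
            "sentinel_rsid": p.sentinel_rsid,
            "r2": p.r2,
        }
        for p in plan
    ]
    # sentinels appear as their own proxies with r2 = 1
    for row in sentinel_rows:
        proxy_rows.append(
            {
                "rsid": row["rsid"],
                "chrom": row["chrom"],
                "pos_1based": row["pos"] + 1,
                "pos": row["pos"],
                "sentinel_rsid": row["rsid"],
                "r2": 1.0,
            }
        )
    proxies = pd.DataFrame(proxy_rows)

    # eQTL pairs: planted overlap drawn from realized sentinel-gene pairs,
    # filler pairs drawn from the 5 Mb pool minus the realized map
    symbol_of = {t.gene_id: t.gene_symbol for t in genome.transcripts}
    realized = sorted(
        {
            (p.sentinel_rsid, symbol_of[g].upper())
            for p in plan
            if p.route == "interaction"
            for g in p.genes
        }
    )
    if config.planted_eqtl_overlap > len(realized):
        raise ValueError(
            "planted eQTL overlap exceeds the number of realized sentinel-gene pairs"
        )
    picks = rng.choice(len(realized), size=config.planted_eqtl_overlap, replace=False)
    overlap_pairs = sorted(realized[int(i)] for i in picks)
    realized_set = set(realized)
    tss_of = {t.gene_id: t.tss for t in genome.transcripts}
    chrom_of = {t.gene_id: t.chrom for t in genome.transcripts}
    extras: list[tuple[str, str]] = []
    sent_pos = {r["rsid"]: (r["chrom"], r["pos"]) for r in sentinel_rows}
    candidates = sorted(
        {
            (srs, symbol_of[g].upper())
            for srs, (schrom, spos) in sent_pos.items()
            for g in symbol_of
            if chrom_of[g] == schrom
            and abs(tss_of[g] - spos) <= config.pool_window_bp
        }
        - realized_set
    )
    if config.n_eqtl_extra > len(candidates):
        raise ValueError("not enough non-overlapping pool pairs for eQTL filler")
    picks = rng.choice(len(candidates), size=config.n_eqtl_extra, replace=False)
    extras = sorted(candidates[int(i)] for i in picks)
    eqtl = pd.DataFrame(
        [
            {"sentinel_rsid": s, "gene_symbol": g, "source_label": "synthetic_eqtl"}
            for s, g in sorted(overlap_pairs + extras)
        ]
    )

    truth = TruthTable(
        proxies=plan,
        eqtl_overlap_pairs=overlap_pairs,
        ocr_openness={},
        gene_symbols=symbol_of,
    )
    bundle = VariantBundle(
        proxies=proxies,
        sentinels=sentinels,
        eqtl=eqtl,
        planted_overlap=overlap_pairs,
    )
    return bundle, truth


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class SimulatedStudy:
    config: SimulationConfig
    genome: GenomeBundle
    atac: AtacBundle
    interactions: InteractionBundle
    variants: VariantBundle
    truth: TruthTable


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    genome = simulate_genome(config)
    atac = simulate_atac(genome, config)
    inter = simulate_interactions(genome, atac, config)
    variants, truth = simulate_variants(genome, inter, config)
    truth.ocr_openness = {o.id: sorted(o.open_in) for o in atac.ocrs}
    return SimulatedStudy(
        config=config,
        genome=genome,
        atac=atac,
        interactions=inter,
        variants=variants,
        truth=truth,
    )


def write_study(study: SimulatedStudy, outdir: str | Path) -> dict[str, Path]:
    """Write the study to disk in the standard on-disk formats."""
    from .interactions import write_ibed

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    cfg = study.config

    fmap1 = study.genome.fragment_map()
    windows = study.genome.windows(cfg.promoter_upstream, cfg.promoter_downstream)
    fmap1b = fmap1.assign_baits(windows)
    fmap4b = fmap1b.concatenate(4)
    paths["rmap_1frag"] = out / "digest_1frag.rmap"
    vio.write_rmap(paths["rmap_1frag"], fmap1b)
    paths["baitmap_1frag"] = out / "digest_1frag.baitmap"
    vio.write_baitmap(paths["baitmap_1frag"], fmap1b)
    paths["rmap_4frag"] = out / "digest_4frag.rmap"
    vio.write_rmap(paths["rmap_4frag"], fmap4b)
    paths["baitmap_4frag"] = out / "digest_4frag.baitmap"
    vio.write_baitmap(paths["baitmap_4frag"], fmap4b)

    paths["transcripts"] = out / "transcripts.tsv"
    vio.write_transcripts_tsv(paths["transcripts"], study.genome.transcripts)

    with open(out / "chrom_lengths.tsv", "w") as fh:
        fh.write("chrom\tlength\n")
        for chrom, length in study.genome.chrom_lengths.items():
            fh.write(f"{chrom}\t{length}\n")
    paths["chrom_lengths"] = out / "chrom_lengths.tsv"

    for ct, reps in study.atac.replicate_peaks.items():
        for i, peaks in enumerate(reps):
            p = out / f"peaks_{ct}_rep{i + 1}.bed"
            vio.write_bed(p, sorted(peaks))
            paths[f"peaks_{ct}_rep{i + 1}"] = p
    paths["blacklist"] = out / "blacklist.bed"
    vio.write_bed(paths["blacklist"], study.atac.blacklist)
    paths["counts"] = out / "ocr_counts.tsv"
    paths["library_sizes"] = out / "library_sizes.tsv"
    vio.write_count_matrix(
        paths["counts"], paths["library_sizes"], study.atac.counts, study.atac.library_sizes
    )

    for ct, by_res in study.interactions.calls.items():
        for res, recs in by_res.items():
            p = out / f"interactions_{ct}_{res}frag.ibed"
            write_ibed(p, recs)
            paths[f"ibed_{ct}_{res}frag"] = p

    paths["proxies"] = out / "proxies.tsv"
    vio.write_snp_table(paths["proxies"], study.variants.proxies)
    paths["sentinels"] = out / "sentinels.tsv"
    sent = study.variants.sentinels.copy()
    sent["pos_1based"] = sent["pos"] + 1
    sent[["rsid", "chrom", "pos_1based"]].to_csv(
        paths["sentinels"], sep="\t", index=False
    )
    paths["eqtl"] = out / "eqtl_pairs.tsv"
    vio.write_eqtl_pairs(paths["eqtl"], study.variants.eqtl)

    paths["truth"] = out / "truth.json"
    vio.write_json(
        paths["truth"],
        {
            "proxies": [
                {
                    "rsid": p.rsid,
                    "chrom": p.chrom,
                    "pos": p.pos,
                    "ocr_id": p.ocr_id,
                    "category": p.category,
                    "genes": list(p.genes),
                    "route": p.route,
                    "sentinel_rsid": p.sentinel_rsid,
                    "r2": p.r2,
                }
                for p in study.truth.proxies
            ],
            "eqtl_overlap_pairs": [list(x) for x in study.truth.eqtl_overlap_pairs],
            "ocr_openness": study.truth.ocr_openness,
            "gene_symbols": study.truth.gene_symbols,
        },
    )
    return paths
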