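"""Shared fixtures: a small synthetic study, a completed pipeline run over
it, and brute-force oracles for interval merging and OCR projection."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from v2gmap.atlas import Ocr, OcrAtlas
from v2gmap.genome import (
    FragmentMap,
    GenomicInterval,
    PromoterWindows,
    Transcript,
    promoter_windows,
)
from v2gmap.pipeline import Pipeline, PipelineParams
from v2gmap.simulate import SimulationConfig, simulate_study, write_study


SMALL_CONFIG = dict(
    seed=7,
    n_genes=120,
    n_chroms=2,
    n_categorized=30,
    n_sentinels=10,
    n_promoter_resident=8,
    n_inaccessible=10,
    n_eqtl_extra=10,
    planted_eqtl_overlap=5,
    n_decoys=20,
)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(**SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config)


@pytest.fixture(scope="session")
def small_run(small_study, tmp_path_factory):
    """The small study written to disk and pushed through every stage."""
    workdir = tmp_path_factory.mktemp("study")
    write_study(small_study, workdir)
    pipe = Pipeline(
        workdir,
        params=PipelineParams(seed=7, empirical_reps=2000),
    )
    pipe.run("run-all")
    pipe.write_manifest()
    return small_study, pipe


# ---------------------------------------------------------------------------
# brute-force oracles


def brute_force_merge(intervals: list[GenomicInterval]) -> list[GenomicInterval]:
    """Union-merge by pairwise overlap testing + connected components."""
    n = len(intervals)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            a, b = intervals[i], intervals[j]
            if a.chrom == b.chrom and a.start <= b.end and b.start <= a.end:
                parent[find(i)] = find(j)  # overlap or bookended
    groups: dict[int, list[GenomicInterval]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(intervals[i])
    out = [
        GenomicInterval(
            g[0].chrom, min(x.start for x in g), max(x.end for x in g)
        )
        for g in groups.values()
    ]
    return sorted(out, key=lambda iv: (iv.chrom, iv.start))


def brute_force_project(records, atlas: OcrAtlas, windows: PromoterWindows, cell_type):
    """Exhaustive O(interactions x OCR^2) projection oracle.

    Returns {(ocr_a, ocr_b): (max score, frozenset(resolutions))} with pairs
    in coordinate order, applying openness, cis, non-self and the
    promoter-end removal rule by direct pairwise checks.
    """

    def overlaps(iv: GenomicInterval, ocr_id: str) -> bool:
        o = atlas.interval(ocr_id)
        return iv.chrom == o.chrom and iv.start < o.end and o.start < iv.end

    open_ids = [o.id for o in atlas.ocrs() if cell_type in o.open_in]
    result = {}
    for a, b in itertools.combinations(open_ids, 2):
        iva, ivb = atlas.interval(a), atlas.interval(b)
        if iva.chrom != ivb.chrom:
            continue
        if (iva.start, iva.end) > (ivb.start, ivb.end):
            a, b, iva, ivb = b, a, ivb, iva
        score, resolutions = None, set()
        for rec in records:
            fwd = overlaps(rec.bait, a) and overlaps(rec.other, b)
            rev = overlaps(rec.bait, b) and overlaps(rec.other, a)
            if fwd or rev:
                score = rec.score if score is None else max(score, rec.score)
                resolutions.add(rec.resolution)
        if score is None:
            continue
        a_pr = bool(windows.overlapping(iva.chrom, iva.start, iva.end))
        b_pr = bool(windows.overlapping(ivb.chrom, ivb.start, ivb.end))
        if not (a_pr or b_pr):
            continue
        result[(a, b)] = (score, frozenset(resolutions))
    return result


def random_projection_instance(rng: np.random.Generator):
    """A random fragment map / atlas / window set / interaction list with
    <=200 fragments, <=50 OCRs and <=100 interactions."""
    from v2gmap.interactions import FragmentInteraction

    n_chroms = int(rng.integers(1, 3))
    chrom_lengths = {
        f"chr{i + 1}": int(rng.integers(30_000, 60_000)) for i in range(n_chroms)
    }
    cut_sites = {}
    budget = 200 - n_chroms
    for chrom, length in chrom_lengths.items():
        n_cuts = int(rng.integers(5, min(80, budget)))
        budget -= n_cuts + 1
        sites = np.sort(rng.choice(np.arange(1, length), size=n_cuts, replace=False))
        cut_sites[chrom] = [int(s) for s in sites]
    fmap = FragmentMap.from_cut_sites(cut_sites, chrom_lengths)

    ocrs = []
    n_ocr = int(rng.integers(5, 51))
    for chrom, length in chrom_lengths.items():
        pos = np.sort(rng.choice(np.arange(0, length - 600), size=n_ocr // n_chroms, replace=False))
        prev_end = -1
        for p in pos:
            w = int(rng.integers(100, 500))
            start, end = int(p), min(int(p) + w, length)
            if start <= prev_end:
                continue
            prev_end = end
            ocr = Ocr(id=f"{chrom}:{start}-{end}", interval=GenomicInterval(chrom, start, end))
            if rng.random() < 0.75:
                ocr.open_in.add("ct")
            ocrs.append(ocr)
    if not any("ct" in o.open_in for o in ocrs):
        ocrs[0].open_in.add("ct")
    atlas = OcrAtlas(ocrs)

    transcripts = []
    for i in range(int(rng.integers(2, 8))):
        chrom = f"chr{int(rng.integers(1, n_chroms + 1))}"
        tss = int(rng.integers(2000, chrom_lengths[chrom] - 2000))
        strand = "+" if rng.random() < 0.5 else "-"
        transcripts.append(
            Transcript(f"t{i}", f"g{i}", f"G{i}", chrom, strand, tss)
        )
    windows = promoter_windows(transcripts, 1500, 500, chrom_lengths)

    records = []
    for _ in range(int(rng.integers(10, 101))):
        chrom = f"chr{int(rng.integers(1, n_chroms + 1))}"
        res = 1 if rng.random() < 0.5 else 4
        n = fmap.n_fragments(chrom)

        def rand_iv():
            i = int(rng.integers(n))
            span = 1 if res == 1 else int(rng.integers(1, 5))
            j = min(i + span - 1, n - 1)
            return GenomicInterval(
                chrom, int(fmap.starts(chrom)[i]), int(fmap.ends(chrom)[j])
            )

        other_chrom = chrom
        if n_chroms > 1 and rng.random() < 0.1:  # occasional trans record
            other_chrom = f"chr{int(rng.integers(1, n_chroms + 1))}"
        bait = rand_iv()
        if other_chrom == chrom:
            other = rand_iv()
        else:
            m = fmap.n_fragments(other_chrom)
            i = int(rng.integers(m))
            other = GenomicInterval(
                other_chrom,
                int(fmap.starts(other_chrom)[i]),
                int(fmap.ends(other_chrom)[i]),
            )
        records.append(
            FragmentInteraction(
                bait=bait,
                bait_name=".",
                other=other,
                other_name=".",
                n_reads=int(rng.integers(1, 50)),
                score=round(float(rng.uniform(5, 15)), 2),
                resolution=res,
                cell_type="ct",
            )
        )
    return fmap, atlas, windows, records
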