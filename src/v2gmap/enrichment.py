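"""Empirical resampling test of variant-to-gene / eQTL overlap, and a
one-sided Fisher feature-enrichment statistic.

The resampling test asks whether the number of sentinel-gene pairs shared
between a physical variant-to-gene map and an eQTL catalog exceeds chance.
The null model draws, from the pool of all (sentinel, gene) pairs with the
gene's TSS within ±5 Mb of the sentinel, the same number of pairs as
observed, and counts their overlap with the eQTL catalog; repeating this
many times yields an empirical distribution. The Monte-Carlo p-value uses
the add-one correction p = (1 + #{null >= observed}) / (reps + 1) so it is
never exactly zero, and fold enrichment is observed over the null mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome import Transcript

__all__ = [
    "SentinelGenePair",
    "EmpiricalTestResult",
    "FisherResult",
    "make_pairs",
    "overlap_statistic",
    "build_null_pool",
    "empirical_overlap_test",
    "fisher_feature_enrichment",
]

#: A sentinel-gene association; gene symbols are matched case-insensitively.
SentinelGenePair = tuple[str, str]


def make_pairs(
    records: Iterable[tuple[str, str]], by_symbol: bool = True
) -> set[SentinelGenePair]:
    """Normalize (sentinel, gene) records into a deduplicated pair set.

    With ``by_symbol`` (default) the gene key is the uppercased symbol;
    otherwise the identifier is used verbatim.
    """
    return {
        (sentinel, gene.upper() if by_symbol else gene)
        for sentinel, gene in records
    }


def overlap_statistic(
    v2g_pairs: set[SentinelGenePair], eqtl_pairs: set[SentinelGenePair]
) -> int:
    """Number of sentinel-gene pairs present in both sets."""
    return len(v2g_pairs & eqtl_pairs)


def build_null_pool(
    sentinels: pd.DataFrame,
    transcripts: Sequence[Transcript],
    window_bp: int = 5_000_000,
) -> list[SentinelGenePair]:
    """Candidate pool: every (sentinel, gene) with >=1 gene TSS within
    ±``window_bp`` of the sentinel position, deduplicated and sorted.

    ``sentinels`` needs columns rsid, chrom, pos (0-based). Sentinels on
    chromosomes absent from the annotation contribute nothing.
    """
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for t in transcripts:
        by_chrom.setdefault(t.chrom, []).append((t.tss, t.gene_symbol.upper()))
    pool: set[SentinelGenePair] = set()
    for row in sentinels.itertuples():
        genes = by_chrom.get(row.chrom)
        if not genes:
            continue
        pos = int(row.pos)
        for tss, symbol in genes:
            if abs(tss - pos) <= window_bp:
                pool.add((row.rsid, symbol))
    return sorted(pool)


@dataclass
class EmpiricalTestResult:
    observed: int
    reps: int
    null_mean: float
    null_histogram: dict[int, int]
    fold_enrichment: float | None
    p_value: float
    seed: int
    draw_size: int

    def to_dict(self) -> dict:
        return {
            "observed": self.observed,
            "reps": self.reps,
            "null_mean": self.null_mean,
            "null_histogram": {str(k): v for k, v in sorted(self.null_histogram.items())},
            "fold_enrichment": self.fold_enrichment,
            "p_value": self.p_value,
            "seed": self.seed,
            "draw_size": self.draw_size,
        }


def empirical_overlap_test(
    v2g_pairs: set[SentinelGenePair],
    eqtl_pairs: set[SentinelGenePair],
    pool: Sequence[SentinelGenePair],
    reps: int = 100_000,
    seed: int = 0,
    with_replacement: bool = False,
) -> EmpiricalTestResult:
    """Monte-Carlo test of the v2g/eQTL overlap against equal-size random
    draws from ``pool``.

    Each rep draws ``len(v2g_pairs)`` pairs uniformly (without replacement
    by default, mimicking the observed set of distinct pairs) and counts
    their overlap with the eQTL set. Deterministic given ``seed``.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    draw = len(v2g_pairs)
    pool = list(pool)
    n = len(pool)
    if not with_replacement and n < draw:
        raise ValueError(f"pool size {n} smaller than draw size {draw}")
    observed = overlap_statistic(v2g_pairs, eqtl_pairs)
    flags = np.array([p in eqtl_pairs for p in pool], dtype=bool)
    rng = np.random.default_rng(seed)
    null = np.empty(reps, dtype=np.int64)
    if draw == 0:
        null[:] = 0
    else:
        # chunked vectorized draws: a without-replacement draw of m items is
        # the m smallest of n iid uniform keys (uniform over m-subsets)
        chunk = max(1, int(4_000_000 // max(n, draw)))
        done = 0
        while done < reps:
            m = min(chunk, reps - done)
            if with_replacement:
                idx = rng.integers(0, n, size=(m, draw))
            elif draw == n:
                idx = np.tile(np.arange(n), (m, 1))
            else:
                keys = rng.random((m, n))
                idx = np.argpartition(keys, draw - 1, axis=1)[:, :draw]
            null[done : done + m] = flags[idx].sum(axis=1)
            done += m
    null_mean = float(null.mean())
    p = (1 + int((null >= observed).sum())) / (reps + 1)
    fold = observed / null_mean if null_mean > 0 else None
    values, counts = np.unique(null, return_counts=True)
    hist = {int(v): int(c) for v, c in zip(values, counts)}
    return EmpiricalTestResult(
        observed=observed,
        reps=reps,
        null_mean=null_mean,
        null_histogram=hist,
        fold_enrichment=fold,
        p_value=p,
        seed=seed,
        draw_size=draw,
    )


@dataclass
class FisherResult:
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float | None
    p_value: float


def fisher_feature_enrichment(
    hits_a: int, total_a: int, hits_b: int, total_b: int
) -> FisherResult:
    """One-sided (greater) Fisher exact test of feature hit rates.

    The 2x2 table is [[hits_a, total_a - hits_a], [hits_b, total_b - hits_b]]
    and the odds ratio is the sample odds ratio
    hits_a*(total_b - hits_b) / ((total_a - hits_a)*hits_b), reported as None
    when its denominator is zero.
    """
    if not (0 <= hits_a <= total_a and 0 <= hits_b <= total_b):
        raise ValueError("hits must be within [0, total]")
    if total_a <= 0 or total_b <= 0:
        raise ValueError("totals must be positive")
    table = ((hits_a, total_a - hits_a), (hits_b, total_b - hits_b))
    _, p = stats.fisher_exact(table, alternative="greater")
    denom = (total_a - hits_a) * hits_b
    odds = (hits_a * (total_b - hits_b)) / denom if denom else None
    return FisherResult(table=table, odds_ratio=odds, p_value=float(p))
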