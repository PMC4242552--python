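"""Level-preserving Monte-Carlo nulls for segment heterogeneity scores.

The null model for a segment keeps its read depth N and its methylation
level fixed and otherwise randomizes: the M observed methylated calls are
re-arranged uniformly at random among the b*N call slots of the read-by-CpG
matrix, pattern counts are recomputed, and entropy / weighted entropy are
evaluated on the scrambled segment. Repeating this ``n_reps`` times yields
the median null entropy and an empirical p-value

    p = #{reps : WME_sim < WME_obs} / n_reps      (strict inequality)

so a segment whose observed weighted entropy is already minimal for its
level — e.g. a purely bipolar segment — gets p = 0, and ties count against
significance. Each segment gets its own RNG stream derived from the global
seed and the segment key, making results independent of processing order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from .entropy_core import (
    SegmentStats,
    _popcounts,
    _shannon_terms,
    transition_counts,
    weighted_entropy,
)
from .segmentation import SegmentPatterns

DEFAULT_N_REPS = 1000
DEFAULT_P_THRESHOLD = 0.05


@dataclass
class NullConfig:
    """Monte-Carlo null settings.

    ``downsample_fraction`` supports depth-matching across samples (e.g.
    keeping 20/28 of reads to compare a 28x methylome against a 20x one).
    """

    n_reps: int = DEFAULT_N_REPS
    seed: int = 0
    p_threshold: float = DEFAULT_P_THRESHOLD
    downsample_fraction: float = 1.0

    def __post_init__(self):
        if self.n_reps < 1:
            raise ValueError(f"n_reps must be >= 1, got {self.n_reps}")
        if not 0 < self.downsample_fraction <= 1:
            raise ValueError("downsample_fraction must be in (0, 1]")
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must be in (0, 1)")


def segment_rng(seed: int, seg: SegmentPatterns) -> np.random.Generator:
    """Independent RNG stream per (seed, segment key)."""
    chrom_hash = zlib.crc32(seg.chrom.encode())
    return np.random.default_rng(
        np.random.SeedSequence(
            entropy=int(seed) % (2**31),
            spawn_key=(chrom_hash, seg.cpg_positions[0]),
        )
    )


def _methylated_call_count(seg: SegmentPatterns) -> int:
    return int(np.dot(seg.pattern_counts, _popcounts(seg.b)))


def _simulate_counts(N: int, b: int, M: int, reps: int, rng) -> np.ndarray:
    """Pattern-count matrices for ``reps`` level-preserving scrambles.

    Returns an int array of shape (reps, 2**b): each row is the pattern
    count vector of one uniformly random placement of M methylated calls
    among the b*N call slots.
    """
    slots = b * N
    base = np.zeros(slots, dtype=np.int8)
    base[:M] = 1
    calls = np.tile(base, (reps, 1))
    rng.permuted(calls, axis=1, out=calls)
    weights = (1 << np.arange(b - 1, -1, -1)).astype(np.int64)
    pats = calls.reshape(reps, N, b) @ weights  # (reps, N) pattern ids
    counts = np.zeros((reps, 2**b), dtype=np.int64)
    np.add.at(counts, (np.repeat(np.arange(reps), N), pats.ravel()), 1)
    return counts


def simulate_level_preserving(seg: SegmentPatterns, rng) -> SegmentPatterns:
    """One level-preserving scramble of a segment's call matrix."""
    if seg.N == 0:
        raise ValueError("cannot simulate a segment with no reads")
    M = _methylated_call_count(seg)
    counts = _simulate_counts(seg.N, seg.b, M, 1, rng)[0]
    return SegmentPatterns(seg.chrom, seg.cpg_positions, counts)


def _null_scores(seg: SegmentPatterns, cfg: NullConfig) -> tuple[np.ndarray, np.ndarray]:
    """(entropy, weighted entropy) arrays over cfg.n_reps null scrambles."""
    rng = segment_rng(cfg.seed, seg)
    M = _methylated_call_count(seg)
    counts = _simulate_counts(seg.N, seg.b, M, cfg.n_reps, rng)
    p = counts / seg.N
    logp = np.zeros_like(p)
    np.log2(p, where=p > 0, out=logp)
    terms = -p * logp
    me = terms.sum(axis=1) / seg.b
    wme = (terms * transition_counts(seg.b)).sum(axis=1) / seg.b
    return me, wme


def null_median_entropy(seg: SegmentPatterns, cfg: NullConfig) -> float:
    """Median methylation entropy over level-preserving simulations."""
    me, _ = _null_scores(seg, cfg)
    return float(np.median(me))


def weighted_entropy_pvalue(seg: SegmentPatterns, cfg: NullConfig) -> float:
    """Fraction of simulations with weighted entropy strictly below observed."""
    _, wme = _null_scores(seg, cfg)
    obs = weighted_entropy(seg)
    return float(np.count_nonzero(wme < obs) / cfg.n_reps)


def attach_null_results(stats: SegmentStats, cfg: NullConfig) -> SegmentStats:
    """Fill null_median_entropy and p_value on a SegmentStats (one RNG pass)."""
    me, wme = _null_scores(stats.segment, cfg)
    stats.null_median_entropy = float(np.median(me))
    stats.p_value = float(np.count_nonzero(wme < stats.weighted_entropy) / cfg.n_reps)
    return stats


def downsample_reads(seg: SegmentPatterns, fraction: float, rng) -> SegmentPatterns:
    """Keep round(fraction * N) reads sampled without replacement."""
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    keep = int(round(fraction * seg.N))
    if keep == 0:
        raise ValueError(f"downsampling {seg.N} reads by {fraction} leaves none")
    if keep == seg.N:
        return SegmentPatterns(seg.chrom, seg.cpg_positions, seg.pattern_counts.copy())
    reads = np.repeat(np.arange(2**seg.b), seg.pattern_counts)
    chosen = rng.choice(reads, size=keep, replace=False)
    counts = np.bincount(chosen, minlength=2**seg.b)
    return SegmentPatterns(seg.chrom, seg.cpg_positions, counts)
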