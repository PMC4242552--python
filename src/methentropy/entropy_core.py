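"""Segment-level heterogeneity scores.

For a window of b CpGs covered in full by N fragments showing pattern i with
count n_i:

  methylation level     L   = (sum_i n_i * popcount(i)) / (b * N)
  methylation entropy   ME  = (1/b) * sum_i -(n_i/N) * log2(n_i/N)
  weighted entropy      WME = (1/b) * sum_i t_i * [-(n_i/N) * log2(n_i/N)]

where t_i is the number of adjacent methylation-state transitions within
pattern i (0 for all-methylated / all-unmethylated, at most b-1 = 3 for four
CpGs). ME is 0 for a homogeneous segment and 1 when all 16 patterns of a
four-CpG segment are used uniformly. WME deliberately zeroes the
contribution of the two transition-free patterns, so a purely bipolar
segment (only all-M and all-U reads) scores exactly 0 — the signature the
downstream cell-subset detection exploits.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .segmentation import SegmentPatterns


@dataclass
class SegmentStats:
    """Scores (and, once computed, null-simulation results) for one segment."""

    segment: SegmentPatterns
    level: float
    entropy: float
    weighted_entropy: float
    has_bipolar: bool
    null_median_entropy: float | None = None
    p_value: float | None = None

    @property
    def key(self):
        return self.segment.key


def _require_reads(seg: SegmentPatterns) -> None:
    if seg.N == 0:
        raise ValueError("segment has no reads; scores are undefined for N = 0")


@lru_cache(maxsize=None)
def _popcounts(b: int) -> np.ndarray:
    return np.array([bin(i).count("1") for i in range(2**b)], dtype=np.int64)


@lru_cache(maxsize=None)
def transition_counts(b: int) -> np.ndarray:
    """t_i for every pattern id: adjacent state changes along the b sites."""
    ids = np.arange(2**b)
    t = np.zeros(2**b, dtype=np.int64)
    for k in range(b - 1):
        hi = (ids >> (b - 1 - k)) & 1
        lo = (ids >> (b - 2 - k)) & 1
        t += hi ^ lo
    return t


def transitions(pattern_id: int, b: int = 4) -> int:
    """Number of M<->U state changes along one pattern (0..b-1)."""
    if not 0 <= pattern_id < 2**b:
        raise ValueError(f"pattern id must be in [0, {2**b}), got {pattern_id}")
    return int(transition_counts(b)[pattern_id])


def methylation_level(seg: SegmentPatterns) -> float:
    """Fraction of methylated CpG calls among all b*N calls of the segment."""
    _require_reads(seg)
    meth_calls = int(np.dot(seg.pattern_counts, _popcounts(seg.b)))
    return meth_calls / (seg.b * seg.N)


def _shannon_terms(counts: np.ndarray, N: int) -> np.ndarray:
    """-(n_i/N) * log2(n_i/N) per pattern, with 0*log 0 := 0."""
    p = counts / N
    out = np.zeros_like(p, dtype=float)
    nz = p > 0
    out[nz] = -p[nz] * np.log2(p[nz])
    return out


def methylation_entropy(seg: SegmentPatterns) -> float:
    """Shannon entropy of the pattern distribution, normalized by b."""
    _require_reads(seg)
    return float(_shannon_terms(seg.pattern_counts, seg.N).sum() / seg.b)


def weighted_entropy(seg: SegmentPatterns) -> float:
    """Entropy with each pattern's term multiplied by its transition count."""
    _require_reads(seg)
    t = transition_counts(seg.b)
    return float((t * _shannon_terms(seg.pattern_counts, seg.N)).sum() / seg.b)


def has_bipolar_reads(seg: SegmentPatterns) -> bool:
    """True iff both the all-methylated and all-unmethylated patterns occur."""
    return bool(seg.pattern_counts[0] > 0 and seg.pattern_counts[-1] > 0)


def segment_stats(seg: SegmentPatterns) -> SegmentStats:
    """Compute level, entropy, weighted entropy and the bipolar flag."""
    return SegmentStats(
        segment=seg,
        level=methylation_level(seg),
        entropy=methylation_entropy(seg),
        weighted_entropy=weighted_entropy(seg),
        has_bipolar=has_bipolar_reads(seg),
    )


def write_stats(stats, path) -> None:
    """Write a stats TSV (segment coordinates + scores + null columns)."""
    stats = list(stats)
    with open(path, "w") as fh:
        b = stats[0].segment.b if stats else 4
        pos_cols = "\t".join(f"cpg{i+1}" for i in range(b))
        cnt_cols = "\t".join(f"n{i:0{b}b}" for i in range(2**b))
        fh.write(
            f"chrom\tstart\tend\t{pos_cols}\t{cnt_cols}\tN\tlevel\tentropy\t"
            "weighted_entropy\thas_bipolar\tnull_median_entropy\tp_value\n"
        )
        for s in stats:
            seg = s.segment
            fh.write(
                "\t".join(
                    [seg.chrom, str(seg.start), str(seg.end)]
                    + [str(p) for p in seg.cpg_positions]
                    + [str(int(c)) for c in seg.pattern_counts]
                    + [
                        str(seg.N),
                        f"{s.level:.6g}",
                        f"{s.entropy:.6g}",
                        f"{s.weighted_entropy:.6g}",
                        "1" if s.has_bipolar else "0",
                        "" if s.null_median_entropy is None else f"{s.null_median_entropy:.6g}",
                        "" if s.p_value is None else f"{s.p_value:.6g}",
                    ]
                )
                + "\n"
            )


def read_stats(path) -> list[SegmentStats]:
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        b = sum(1 for c in header if c.startswith("cpg"))
        n_pat = 2**b
        col = {name: i for i, name in enumerate(header)}
        for line in fh:
            p = line.rstrip("\n").split("\t")
            seg = SegmentPatterns(
                chrom=p[0],
                cpg_positions=tuple(int(x) for x in p[3 : 3 + b]),
                pattern_counts=np.array([int(x) for x in p[3 + b : 3 + b + n_pat]]),
            )
            nme = p[col["null_median_entropy"]]
            pv = p[col["p_value"]]
            out.append(
                SegmentStats(
                    segment=seg,
                    level=float(p[col["level"]]),
                    entropy=float(p[col["entropy"]]),
                    weighted_entropy=float(p[col["weighted_entropy"]]),
                    has_bipolar=p[col["has_bipolar"]] == "1",
                    null_median_entropy=float(nme) if nme else None,
                    p_value=float(pv) if pv else None,
                )
            )
    return out
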