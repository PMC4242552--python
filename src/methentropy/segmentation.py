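"""Sliding four-CpG window scan over per-read methylation calls.

The methylome is scanned window by window along the CpG index: every run of
``window_cpgs`` consecutive indexed CpG units defines a candidate segment
(windows slide by one CpG and therefore overlap). A sequenced fragment
contributes one methylation pattern to a window iff it carries unambiguous
calls at ALL CpGs of the window; a window is emitted when at least
``min_reads`` fragments do so, which guarantees the pattern count vector is
informative over all 2^4 = 16 possible patterns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

from .methylome_io import CpGIndex, GenomicInterval, ReadCall

DEFAULT_WINDOW_CPGS = 4
DEFAULT_MIN_READS = 16
DEFAULT_MIN_CPGS_PER_READ = 4


def pattern_of(states: Iterable[bool]) -> int:
    """Encode an ordered run of binary methylation states as a pattern id.

    Bit k is the state of the k-th CpG with the most-significant bit the
    leftmost CpG: (M,M,M,M) -> 15, (M,U,U,U) -> 8, (U,...,U) -> 0.
    """
    states = list(states)
    pid = 0
    for s in states:
        pid = (pid << 1) | int(bool(s))
    return pid


@dataclass
class SegmentPatterns:
    """A four-CpG window with its per-read pattern count vector.

    ``pattern_counts[i]`` is the number of fragments showing pattern i
    (the n_i of the entropy formulas); N = sum(n_i).
    """

    chrom: str
    cpg_positions: tuple[int, ...]
    pattern_counts: np.ndarray  # length 2**b, non-negative ints

    def __post_init__(self):
        self.cpg_positions = tuple(int(p) for p in self.cpg_positions)
        self.pattern_counts = np.asarray(self.pattern_counts, dtype=np.int64)
        b = len(self.cpg_positions)
        if self.pattern_counts.shape != (2**b,):
            raise ValueError(
                f"pattern_counts must have length 2^{b}, got {self.pattern_counts.shape}"
            )
        if (self.pattern_counts < 0).any():
            raise ValueError("pattern counts must be non-negative")
        if any(a >= b_ for a, b_ in zip(self.cpg_positions, self.cpg_positions[1:])):
            raise ValueError("cpg_positions must be strictly increasing")

    @property
    def b(self) -> int:
        """Number of CpG sites in the window."""
        return len(self.cpg_positions)

    @property
    def N(self) -> int:
        """Total fragments covering the whole window."""
        return int(self.pattern_counts.sum())

    @property
    def start(self) -> int:
        return self.cpg_positions[0]

    @property
    def end(self) -> int:
        # span covers both bases of the last CpG dinucleotide
        return self.cpg_positions[-1] + 2

    @property
    def key(self) -> tuple[str, tuple[int, ...]]:
        return (self.chrom, self.cpg_positions)

    def interval(self, label: str = "") -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, ".", label)


Fragment = tuple[str, str, dict[int, bool]]  # (read_id, chrom, {cpg_pos: state})


def group_fragments(calls: Iterable[ReadCall]) -> list[Fragment]:
    """Group calls into fragments keyed by (read_id, chrom).

    Conflicting duplicate calls at one position void that position for the
    fragment (paired-end mates disagreeing after overlap).
    """
    frags: dict[tuple[str, str], dict[int, bool | None]] = {}
    for c in calls:
        d = frags.setdefault((c.read_id, c.chrom), {})
        if c.cpg_pos in d and d[c.cpg_pos] != c.methylated:
            d[c.cpg_pos] = None
        elif c.cpg_pos not in d:
            d[c.cpg_pos] = c.methylated
    return [
        (rid, chrom, {p: s for p, s in d.items() if s is not None})
        for (rid, chrom), d in frags.items()
    ]


def filter_reads(fragments: Iterable[Fragment], min_cpgs: int = DEFAULT_MIN_CPGS_PER_READ) -> list[Fragment]:
    """Keep only fragments carrying at least ``min_cpgs`` CpG calls."""
    return [f for f in fragments if len(f[2]) >= min_cpgs]


def scan_segments(
    fragments: Iterable[Fragment],
    cpg_index: CpGIndex,
    min_reads: int = DEFAULT_MIN_READS,
    window_cpgs: int = DEFAULT_WINDOW_CPGS,
) -> Iterator[SegmentPatterns]:
    """Emit every window of consecutive CpG units with >= min_reads full patterns.

    Windows slide by one CpG along the index. A fragment contributes a
    pattern to a window only if it has an unambiguous call at every CpG of
    the window; partial coverage contributes nothing. Output is ordered by
    (chrom, first CpG position) and deterministic.
    """
    if min_reads < 1:
        raise ValueError(f"min_reads must be >= 1, got {min_reads}")
    if window_cpgs < 2:
        raise ValueError(f"window_cpgs must be >= 2, got {window_cpgs}")
    w = window_cpgs
    by_chrom: dict[str, list[dict[int, bool]]] = {}
    for _rid, chrom, d in fragments:
        if d:
            by_chrom.setdefault(chrom, []).append(d)

    for chrom in sorted(by_chrom):
        pos = cpg_index.positions(chrom)
        if len(pos) < w:
            continue
        pos_to_idx = {int(p): i for i, p in enumerate(pos)}
        # counts[window_start_index] -> length-16 pattern count vector
        counts: dict[int, np.ndarray] = {}
        for d in by_chrom[chrom]:
            idx_state = sorted(
                (pos_to_idx[p], s) for p, s in d.items() if p in pos_to_idx
            )
            if len(idx_state) < w:
                continue
            # walk runs of consecutive CpG indices within the fragment
            run_start = 0
            for k in range(1, len(idx_state) + 1):
                if k == len(idx_state) or idx_state[k][0] != idx_state[k - 1][0] + 1:
                    run = idx_state[run_start:k]
                    for j in range(len(run) - w + 1):
                        win_idx = run[j][0]
                        pid = pattern_of(s for _i, s in run[j : j + w])
                        vec = counts.get(win_idx)
                        if vec is None:
                            vec = counts[win_idx] = np.zeros(2**w, dtype=np.int64)
                        vec[pid] += 1
                    run_start = k
        for win_idx in sorted(counts):
            vec = counts[win_idx]
            if vec.sum() >= min_reads:
                yield SegmentPatterns(
                    chrom=chrom,
                    cpg_positions=tuple(int(p) for p in pos[win_idx : win_idx + w]),
                    pattern_counts=vec,
                )


# ---------------------------------------------------------------------------
# Plain-text serialization of segment tables


def write_segments(segments: Iterable[SegmentPatterns], path) -> None:
    segments = list(segments)
    with open(path, "w") as fh:
        b = segments[0].b if segments else DEFAULT_WINDOW_CPGS
        pos_cols = "\t".join(f"cpg{i+1}" for i in range(b))
        cnt_cols = "\t".join(f"n{i:0{b}b}" for i in range(2**b))
        fh.write(f"chrom\tstart\tend\t{pos_cols}\t{cnt_cols}\tN\n")
        for s in segments:
            fh.write(
                "\t".join(
                    [s.chrom, str(s.start), str(s.end)]
                    + [str(p) for p in s.cpg_positions]
                    + [str(int(c)) for c in s.pattern_counts]
                    + [str(s.N)]
                )
                + "\n"
            )


def read_segments(path) -> list[SegmentPatterns]:
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        b = sum(1 for c in header if c.startswith("cpg"))
        n_pat = 2**b
        for line in fh:
            p = line.rstrip("\n").split("\t")
            out.append(
                SegmentPatterns(
                    chrom=p[0],
                    cpg_positions=tuple(int(x) for x in p[3 : 3 + b]),
                    pattern_counts=np.array([int(x) for x in p[3 + b : 3 + b + n_pat]]),
                )
            )
    return out
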