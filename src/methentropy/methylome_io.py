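"""Input/output for every external format the toolkit touches.

All internal coordinates are 0-based half-open. Bismark methylation-extractor
input is 1-based and converted on read; BED stays 0-based. A CpG dinucleotide
is treated as a single strand-collapsed unit anchored at the position of the C
on the forward strand: a call at position p+1 (the reverse-strand cytosine)
is folded onto the unit at p.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, TextIO

import numpy as np


class MalformedLineError(ValueError):
    """A line in an input file could not be parsed; carries the line number."""

    def __init__(self, path, lineno: int, reason: str):
        self.lineno = lineno
        super().__init__(f"{path}:{lineno}: {reason}")


@dataclass(frozen=True)
class ReadCall:
    """One CpG methylation observation on one sequenced read.

    ``cpg_pos`` is the 0-based forward-strand position of the C of the CpG
    unit; ``methylated`` is strictly binary (ambiguous calls never enter).
    """

    read_id: str
    chrom: str
    cpg_pos: int
    methylated: bool

    def __post_init__(self):
        if self.cpg_pos < 0:
            raise ValueError(f"cpg_pos must be >= 0, got {self.cpg_pos}")


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval with optional strand and label."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    label: str = ""

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end}) "
                f"for {self.label or self.chrom}"
            )

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share >= 1 bp on the same chromosome."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class CpGIndex:
    """Per-chromosome sorted arrays of 0-based forward-strand CpG positions."""

    def __init__(self, positions: dict[str, Iterable[int]] | None = None):
        self._pos: dict[str, np.ndarray] = {}
        if positions:
            for chrom, pos in positions.items():
                arr = np.asarray(sorted(set(int(p) for p in pos)), dtype=np.int64)
                self._pos[chrom] = arr

    @property
    def chroms(self) -> list[str]:
        return list(self._pos)

    def positions(self, chrom: str) -> np.ndarray:
        return self._pos.get(chrom, np.empty(0, dtype=np.int64))

    def __contains__(self, key: tuple[str, int]) -> bool:
        chrom, pos = key
        arr = self.positions(chrom)
        i = np.searchsorted(arr, pos)
        return i < len(arr) and arr[i] == pos

    def n_cpgs(self, chrom: str | None = None) -> int:
        if chrom is not None:
            return len(self.positions(chrom))
        return sum(len(a) for a in self._pos.values())

    def count_in(self, interval: GenomicInterval) -> int:
        """Number of CpG units whose C position lies inside the interval."""
        arr = self.positions(interval.chrom)
        return int(
            np.searchsorted(arr, interval.end) - np.searchsorted(arr, interval.start)
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self._pos):
                for p in self._pos[chrom]:
                    fh.write(f"{chrom}\t{p}\n")

    @classmethod
    def load(cls, path) -> "CpGIndex":
        acc: dict[str, list[int]] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise MalformedLineError(path, lineno, "expected chrom<TAB>pos")
                acc.setdefault(parts[0], []).append(int(parts[1]))
        return cls(acc)


def build_cpg_index(fasta_path) -> CpGIndex:
    """Scan a reference FASTA for every CG dinucleotide (case-insensitive).

    Each occurrence is recorded at the 0-based position of the C.
    """
    from pyfaidx import Fasta

    fa = Fasta(str(fasta_path), rebuild=False, read_ahead=10_000_000)
    positions: dict[str, np.ndarray] = {}
    idx = CpGIndex()
    for name in fa.keys():
        seq = str(fa[name][:]).upper()
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        if len(arr) < 2:
            positions[name] = np.empty(0, dtype=np.int64)
            continue
        is_cg = (arr[:-1] == ord("C")) & (arr[1:] == ord("G"))
        positions[name] = np.flatnonzero(is_cg).astype(np.int64)
    idx._pos = positions
    return idx


#: Bismark methylation-extractor context codes for CpG context.
_CPG_CODES = {"Z": True, "z": False}


def read_bismark_calls(
    path,
    cpg_index: CpGIndex,
    collapse_strands: bool = True,
    warn_counts: dict[str, int] | None = None,
) -> Iterator[ReadCall]:
    """Parse Bismark methylation-extractor TSV into ReadCalls.

    Lines have >= 5 tab-separated columns: read_id, orientation, chrom,
    1-based position, single-letter code. Z/z denote a methylated /
    unmethylated CpG-context call; every other code (CHG/CHH/unknown) is
    skipped. Positions are converted to 0-based; a call landing on the G of a
    CpG unit (reverse-strand cytosine, position p+1 where p is indexed) is
    collapsed onto the unit at p unless ``collapse_strands`` is False. Calls
    matching no indexed CpG are dropped and counted in ``warn_counts``.
    """
    counts = warn_counts if warn_counts is not None else {}
    counts.setdefault("unmatched_position", 0)
    counts.setdefault("unknown_chrom", 0)
    with open(path) as fh:
        yield from _parse_bismark(fh, path, cpg_index, collapse_strands, counts)
    if warn_counts is None and (counts["unmatched_position"] or counts["unknown_chrom"]):
        warnings.warn(
            f"{path}: dropped {counts['unmatched_position']} calls at non-CpG "
            f"positions and {counts['unknown_chrom']} on unknown chromosomes"
        )


def _parse_bismark(
    fh: TextIO, path, cpg_index: CpGIndex, collapse: bool, counts: dict[str, int]
) -> Iterator[ReadCall]:
    for lineno, line in enumerate(fh, 1):
        line = line.rstrip("\n")
        if not line or line.startswith(("#", "Bismark")):
            continue
        parts = line.split("\t")
        if len(parts) < 5:
            raise MalformedLineError(path, lineno, f"expected >=5 columns, got {len(parts)}")
        read_id, _orient, chrom, pos_s, code = (p.strip() for p in parts[:5])
        if code not in _CPG_CODES:
            continue  # CHG/CHH and other contexts are out of scope
        try:
            pos0 = int(pos_s) - 1
        except ValueError:
            raise MalformedLineError(path, lineno, f"non-integer position {pos_s!r}")
        if pos0 < 0:
            raise MalformedLineError(path, lineno, f"position must be >= 1, got {pos_s}")
        if chrom not in cpg_index._pos:
            counts["unknown_chrom"] += 1
            continue
        if (chrom, pos0) in cpg_index:
            unit = pos0
        elif collapse and pos0 >= 1 and (chrom, pos0 - 1) in cpg_index:
            unit = pos0 - 1  # reverse-strand C of the same CpG
        else:
            counts["unmatched_position"] += 1
            continue
        yield ReadCall(read_id, chrom, unit, _CPG_CODES[code])


def dedupe_fragment_calls(calls: Iterable[ReadCall]) -> list[ReadCall]:
    """Resolve duplicate calls within fragments sharing a read_id.

    Paired-end mates share a read_id and are treated as one fragment;
    concordant duplicate calls at one CpG collapse to one call, conflicting
    calls discard that position for the fragment.
    """
    seen: dict[tuple[str, str, int], bool | None] = {}
    order: list[tuple[str, str, int]] = []
    for c in calls:
        key = (c.read_id, c.chrom, c.cpg_pos)
        if key not in seen:
            seen[key] = c.methylated
            order.append(key)
        elif seen[key] is not None and seen[key] != c.methylated:
            seen[key] = None  # conflict: drop this position for the fragment
    return [
        ReadCall(rid, chrom, pos, state)
        for (rid, chrom, pos) in order
        if (state := seen[(rid, chrom, pos)]) is not None
    ]


# ---------------------------------------------------------------------------
# BED and annotation tables


def read_bed(path) -> list[GenomicInterval]:
    """Read BED3/BED6 (0-based half-open) into GenomicIntervals."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise MalformedLineError(path, lineno, "BED needs >= 3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if end <= start:
                raise MalformedLineError(path, lineno, f"end {end} <= start {start}")
            label = parts[3] if len(parts) > 3 else ""
            strand = parts[5] if len(parts) > 5 else "."
            out.append(GenomicInterval(chrom, start, end, strand, label))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path, scores=None) -> None:
    """Write GenomicIntervals as BED (BED6 when strand/label present)."""
    intervals = list(intervals)
    scores = list(scores) if scores is not None else None
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            if iv.label or iv.strand != "." or scores is not None:
                score = scores[i] if scores is not None else 0
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label or '.'}"
                    f"\t{score:g}\t{iv.strand}\n"
                )
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


@dataclass(frozen=True)
class GeneModel:
    """RefSeq-style transcript model; TSS is strand-resolved."""

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: int = -1
    cds_end: int = -1
    exon_starts: tuple[int, ...] = field(default_factory=tuple)
    exon_ends: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self):
        if not self.tx_start < self.tx_end:
            raise ValueError(f"{self.gene_id}: txStart {self.tx_start} >= txEnd {self.tx_end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be + or -, got {self.strand!r}")

    @property
    def tss(self) -> int:
        """Transcription start: txStart on +, txEnd on - (0-based)."""
        return self.tx_start if self.strand == "+" else self.tx_end


def read_gene_table(path) -> list[GeneModel]:
    """Read a RefSeq-style TSV gene table.

    Columns: name, chrom, strand, txStart, txEnd, cdsStart, cdsEnd,
    exonStarts (comma list), exonEnds (comma list). Extra columns ignored.
    """
    out: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            p = line.split("\t")
            if len(p) < 5:
                raise MalformedLineError(path, lineno, "gene table needs >= 5 columns")
            try:
                exon_starts = _int_list(p[7]) if len(p) > 7 else ()
                exon_ends = _int_list(p[8]) if len(p) > 8 else ()
                gm = GeneModel(
                    gene_id=p[0],
                    chrom=p[1],
                    strand=p[2],
                    tx_start=int(p[3]),
                    tx_end=int(p[4]),
                    cds_start=int(p[5]) if len(p) > 5 else -1,
                    cds_end=int(p[6]) if len(p) > 6 else -1,
                    exon_starts=exon_starts,
                    exon_ends=exon_ends,
                )
            except ValueError as e:
                raise MalformedLineError(path, lineno, str(e))
            out.append(gm)
    return out


def _int_list(s: str) -> tuple[int, ...]:
    return tuple(int(x) for x in s.strip(",").split(",")) if s.strip(",") else ()


@dataclass(frozen=True)
class ExpressionRecord:
    gene_id: str
    value: float

    def __post_init__(self):
        if self.value < 0:
            raise ValueError(f"{self.gene_id}: expression must be >= 0, got {self.value}")


def read_expression(path) -> list[ExpressionRecord]:
    """Read two-column (gene_id, value >= 0) expression TSV."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            p = line.split("\t")
            if len(p) < 2:
                raise MalformedLineError(path, lineno, "expression needs 2 columns")
            try:
                out.append(ExpressionRecord(p[0], float(p[1])))
            except ValueError as e:
                raise MalformedLineError(path, lineno, str(e))
    return out
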