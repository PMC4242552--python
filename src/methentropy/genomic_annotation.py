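"""Genomic-feature stratification, methylation-state classes and TSS profiles.

Feature classes follow the usual UCSC-table conventions: promoters are the
1 kb upstream of each transcript's TSS (strand-aware); 5'UTR, coding exon,
intron and 3'UTR come from the RefSeq-style gene model; repeats keep their
RepeatMasker class label; CpG-island shores are the 2 kb flanks of (merged)
CGIs and shelves the next 2 kb beyond the shores. Classes are not mutually
exclusive: a segment belongs to every class its span overlaps by >= 1 bp.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats as sps

from .bipolar_detection import promoter_interval
from .entropy_core import SegmentStats
from .methylome_io import ExpressionRecord, GeneModel, GenomicInterval

REPEAT_CLASSES = ("LINE", "SINE", "LTR", "Satellite", "SimpleRepeat")
SHORE_WIDTH = 2000
SHELF_WIDTH = 2000
HYPER_CUTOFF = 0.8
HYPO_CUTOFF = 0.2


@dataclass
class FeatureSummary:
    feature: str
    n_segments: int
    level_quartiles: tuple[float, float, float]
    entropy_quartiles: tuple[float, float, float]


class FeatureSet:
    """Typed genomic intervals indexed for >= 1 bp overlap queries."""

    def __init__(self):
        self.intervals: dict[str, list[GenomicInterval]] = {}
        self._trees: dict[tuple[str, str], IntervalTree] = {}

    @property
    def classes(self) -> list[str]:
        return list(self.intervals)

    def add(self, label: str, ivs: Iterable[GenomicInterval]) -> None:
        ivs = list(ivs)
        self.intervals.setdefault(label, []).extend(ivs)
        for iv in ivs:
            self._trees.setdefault((label, iv.chrom), IntervalTree()).addi(iv.start, iv.end)

    def overlaps(self, label: str, chrom: str, start: int, end: int) -> bool:
        tree = self._trees.get((label, chrom))
        return tree is not None and tree.overlaps(start, end)


# ---------------------------------------------------------------------------
# interval arithmetic on merged, sorted (start, end) lists per chromosome


def _merge(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _subtract(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out = []
    for s, e in a:
        cur = s
        for bs, be in b:
            if be <= cur or bs >= e:
                continue
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if cur >= e:
                break
        if cur < e:
            out.append((cur, e))
    return out


def _gene_structure(genes: Sequence[GeneModel]) -> dict[str, list[GenomicInterval]]:
    feats: dict[str, list[GenomicInterval]] = {
        "promoter_1kb": [],
        "utr5": [],
        "coding_exon": [],
        "intron": [],
        "utr3": [],
    }
    for g in genes:
        if g.strand == "+":
            ps, pe = g.tss - 1000, g.tss
        else:
            ps, pe = g.tss, g.tss + 1000
        if pe > max(0, ps):
            feats["promoter_1kb"].append(
                GenomicInterval(g.chrom, max(0, ps), pe, g.strand, g.gene_id)
            )
        exons = list(zip(g.exon_starts, g.exon_ends)) or [(g.tx_start, g.tx_end)]
        has_cds = 0 <= g.cds_start < g.cds_end
        for i, (es, ee) in enumerate(exons):
            if has_cds:
                cs, ce = max(es, g.cds_start), min(ee, g.cds_end)
                if cs < ce:
                    feats["coding_exon"].append(GenomicInterval(g.chrom, cs, ce, g.strand, g.gene_id))
                left = (es, min(ee, g.cds_start))  # exon part 5' of CDS in genome coords
                right = (max(es, g.cds_end), ee)
                for (us, ue), genomic_left in (((left), True), ((right), False)):
                    if us < ue:
                        label = ("utr5" if genomic_left else "utr3") if g.strand == "+" else (
                            "utr3" if genomic_left else "utr5"
                        )
                        feats[label].append(GenomicInterval(g.chrom, us, ue, g.strand, g.gene_id))
            if i + 1 < len(exons) and ee < exons[i + 1][0]:
                feats["intron"].append(
                    GenomicInterval(g.chrom, ee, exons[i + 1][0], g.strand, g.gene_id)
                )
    return feats


def build_features(
    genes: Sequence[GeneModel],
    repeats: Sequence[GenomicInterval] = (),
    cgis: Sequence[GenomicInterval] = (),
) -> FeatureSet:
    """Assemble the full typed feature catalog.

    Overlapping CGIs are merged before shores/shelves are derived; shores
    never overlap a CGI, shelves never overlap shores or CGIs (set
    subtraction, clipped at position 0).
    """
    fs = FeatureSet()
    gene_feats = _gene_structure(genes)
    for label, ivs in gene_feats.items():
        fs.add(label, ivs)

    for r in repeats:
        label = r.label if r.label in REPEAT_CLASSES else r.label or "repeat"
        fs.add(label, [r])

    cgi_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for c in cgis:
        cgi_by_chrom.setdefault(c.chrom, []).append((c.start, c.end))
    for chrom, ivs in cgi_by_chrom.items():
        merged = _merge(ivs)
        fs.add("cgi", [GenomicInterval(chrom, s, e, ".", "cgi") for s, e in merged])
        shore_raw = _merge(
            [(max(0, s - SHORE_WIDTH), s) for s, e in merged]
            + [(e, e + SHORE_WIDTH) for s, e in merged]
        )
        shores = [iv for iv in _subtract(shore_raw, merged) if iv[0] < iv[1]]
        fs.add("cgi_shore", [GenomicInterval(chrom, s, e, ".", "shore") for s, e in shores])
        shelf_raw = _merge(
            [(max(0, s - SHORE_WIDTH - SHELF_WIDTH), s) for s, e in merged]
            + [(e, e + SHORE_WIDTH + SHELF_WIDTH) for s, e in merged]
        )
        shelves = _subtract(_subtract(shelf_raw, merged), _merge(shores))
        shelves = [iv for iv in shelves if iv[0] < iv[1]]
        fs.add("cgi_shelf", [GenomicInterval(chrom, s, e, ".", "shelf") for s, e in shelves])

    # split promoters by CGI overlap (>= 1 bp)
    cgi_promoters, non_cgi_promoters = [], []
    for p in gene_feats["promoter_1kb"]:
        if fs.overlaps("cgi", p.chrom, p.start, p.end):
            cgi_promoters.append(p)
        else:
            non_cgi_promoters.append(p)
    fs.add("cgi_promoter", cgi_promoters)
    fs.add("non_cgi_promoter", non_cgi_promoters)
    return fs


def assign_segments(
    stats: Sequence[SegmentStats], features: FeatureSet
) -> dict[str, list[SegmentStats]]:
    """Per-class segment lists; a segment joins every class it overlaps >= 1 bp.

    Segments overlapping no class land in "unassigned". Within a class each
    segment key appears once.
    """
    out: dict[str, list[SegmentStats]] = {label: [] for label in features.classes}
    out["unassigned"] = []
    for s in stats:
        seg = s.segment
        hit = False
        for label in features.classes:
            if features.overlaps(label, seg.chrom, seg.start, seg.end):
                out[label].append(s)
                hit = True
        if not hit:
            out["unassigned"].append(s)
    return out


def summarize_classes(assigned: dict[str, list[SegmentStats]]) -> list[FeatureSummary]:
    out = []
    for label, members in assigned.items():
        if not members:
            continue
        lv = np.array([m.level for m in members])
        en = np.array([m.entropy for m in members])
        out.append(
            FeatureSummary(
                feature=label,
                n_segments=len(members),
                level_quartiles=tuple(np.percentile(lv, [25, 50, 75])),
                entropy_quartiles=tuple(np.percentile(en, [25, 50, 75])),
            )
        )
    return out


def classify_level(level: float) -> str:
    """Hyper (> 80%), hypo (< 20%) or intermediate methylation state."""
    if level > HYPER_CUTOFF:
        return "hypermethylated"
    if level < HYPO_CUTOFF:
        return "hypomethylated"
    return "intermediate"


def is_completely_unmethylated(level: float) -> bool:
    return level == 0.0


def is_completely_methylated(level: float) -> bool:
    return level == 1.0


def common_segments(samples: Sequence[Sequence[SegmentStats]]) -> dict:
    """Segments present in every sample, keyed by (chrom, CpG positions)."""
    if not samples:
        return {}
    maps = [{s.key: s for s in sample} for sample in samples]
    keys = set(maps[0])
    for m in maps[1:]:
        keys &= set(m)
    return {k: [m[k] for m in maps] for k in sorted(keys)}


def pairwise_correlation(
    common: dict, i: int = 0, j: int = 1, metric: str = "level"
) -> float:
    """Pearson correlation of one metric between two samples on common segments."""
    if metric not in ("level", "entropy"):
        raise ValueError(f"metric must be 'level' or 'entropy', got {metric!r}")
    if len(common) < 2:
        raise ValueError("need >= 2 common segments for a correlation")
    x = np.array([getattr(v[i], metric) for v in common.values()])
    y = np.array([getattr(v[j], metric) for v in common.values()])
    return float(sps.pearsonr(x, y).statistic)


# ---------------------------------------------------------------------------
# expression quintiles and TSS profiles


def assign_quintiles(
    records: Sequence[ExpressionRecord], n_groups: int = 5
) -> dict[str, int]:
    """Group genes into n equally sized expression categories (5 = highest).

    Rank-based with stable ties; group sizes differ by at most one. Zero
    expression ranks lowest.
    """
    order = sorted(range(len(records)), key=lambda k: records[k].value)
    chunks = np.array_split(np.array(order), n_groups)
    out: dict[str, int] = {}
    for q, chunk in enumerate(chunks, start=1):
        for k in chunk:
            out[records[int(k)].gene_id] = q
    return out


def tss_profile(
    stats: Sequence[SegmentStats],
    genes: Sequence[GeneModel],
    expression: Sequence[ExpressionRecord],
    window: int = 100,
    span: int = 3000,
    n_groups: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Mean level and entropy per expression group per 100 bp bin around TSSs.

    A segment is assigned to the bin containing its midpoint, with offsets
    oriented so upstream of transcription is negative. Returns
    (level matrix, entropy matrix, number of genes lacking expression);
    matrices are (group x bin) with NaN for empty bins.
    """
    quint = assign_quintiles(expression, n_groups)
    n_bins = 2 * span // window
    edges = np.arange(-span, span + window, window)
    sums_l = np.zeros((n_groups, n_bins))
    sums_e = np.zeros((n_groups, n_bins))
    counts = np.zeros((n_groups, n_bins), dtype=int)
    missing = 0

    by_chrom: dict[str, list[SegmentStats]] = {}
    for s in stats:
        by_chrom.setdefault(s.segment.chrom, []).append(s)

    for g in genes:
        q = quint.get(g.gene_id)
        if q is None:
            missing += 1
            continue
        for s in by_chrom.get(g.chrom, ()):
            mid = (s.segment.start + s.segment.end) // 2
            offset = mid - g.tss if g.strand == "+" else g.tss - mid
            if not (-span <= offset < span):
                continue
            b = (offset + span) // window
            sums_l[q - 1, b] += s.level
            sums_e[q - 1, b] += s.entropy
            counts[q - 1, b] += 1

    with np.errstate(invalid="ignore"):
        mean_l = np.where(counts > 0, sums_l / np.maximum(counts, 1), np.nan)
        mean_e = np.where(counts > 0, sums_e / np.maximum(counts, 1), np.nan)
    cols = [f"[{edges[i]},{edges[i+1]})" for i in range(n_bins)]
    idx = [f"q{q}" for q in range(1, n_groups + 1)]
    return (
        pd.DataFrame(mean_l, index=idx, columns=cols),
        pd.DataFrame(mean_e, index=idx, columns=cols),
        missing,
    )


def gene_body_stats(
    stats: Sequence[SegmentStats],
    genes: Sequence[GeneModel],
    up: int = 1000,
    down: int = 200,
) -> pd.DataFrame:
    """Mean level/entropy of segments overlapping each gene's TSS window.

    The window runs ``up`` bp upstream to ``down`` bp downstream of the TSS
    (strand-aware); a segment counts if it overlaps by >= 1 bp. Genes with
    no segment are absent from the result.
    """
    rows = []
    by_chrom: dict[str, list[SegmentStats]] = {}
    for s in stats:
        by_chrom.setdefault(s.segment.chrom, []).append(s)
    for g in genes:
        win = promoter_interval(g, up, down)
        members = [
            s
            for s in by_chrom.get(g.chrom, ())
            if s.segment.start < win.end and win.start < s.segment.end
        ]
        if not members:
            continue
        rows.append(
            {
                "gene_id": g.gene_id,
                "n_segments": len(members),
                "mean_level": float(np.mean([m.level for m in members])),
                "mean_entropy": float(np.mean([m.entropy for m in members])),
            }
        )
    return pd.DataFrame(rows, columns=["gene_id", "n_segments", "mean_level", "mean_entropy"])
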