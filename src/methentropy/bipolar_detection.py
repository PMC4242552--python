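"""Detection of putative cell-subset-specific methylated regions and genes.

A bipolar segment — one carrying both completely methylated and completely
unmethylated reads — is the read-level signature of a locus methylated in
one cell subset and unmethylated in another. The pipeline:

  1. keep bipolar segments;
  2. score each against the level-preserving null (weighted-entropy p-value);
  3. drop segments overlapping known allele-specific-methylation (ASM)
     regions by >= 1 bp, and segments consistent with stochastic methylation
     (p-value > 0.05);
  4. merge surviving segments within 1 bp into regions;
  5. associate regions to gene promoters (1 kb upstream to 200 bp downstream
     of the TSS), merging regions within one promoter, and discard genes
     with fewer than 10 CpGs in the promoter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .entropy_core import SegmentStats, has_bipolar_reads, segment_stats
from .methylome_io import CpGIndex, GeneModel, GenomicInterval
from .null_simulation import NullConfig, attach_null_results
from .segmentation import SegmentPatterns

DEFAULT_MERGE_GAP = 1
DEFAULT_PROMOTER_UP = 1000
DEFAULT_PROMOTER_DOWN = 200
DEFAULT_MIN_PROMOTER_CPGS = 10


@dataclass
class BipolarRegion:
    """Merged run of bipolar segments; spans all of its members."""

    interval: GenomicInterval
    member_keys: list
    min_p: float


@dataclass
class CandidateGene:
    """A gene whose promoter hosts at least one bipolar region."""

    gene_id: str
    promoter: GenomicInterval
    n_promoter_cpgs: int
    regions: list[BipolarRegion] = field(default_factory=list)

    @property
    def min_p(self) -> float:
        return min(r.min_p for r in self.regions)


def select_bipolar(segs: Iterable[SegmentPatterns]) -> list[SegmentPatterns]:
    """Keep segments with >= 1 fully methylated AND >= 1 fully unmethylated read."""
    return [s for s in segs if has_bipolar_reads(s)]


def _interval_tree(regions: Sequence[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for r in regions:
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end)
    return trees


def filter_asm(
    stats: Iterable[SegmentStats], asm_regions: Sequence[GenomicInterval]
) -> list[SegmentStats]:
    """Remove segments overlapping any ASM region by >= 1 bp (half-open)."""
    trees = _interval_tree(asm_regions)
    out = []
    for s in stats:
        seg = s.segment
        tree = trees.get(seg.chrom)
        if tree is not None and tree.overlaps(seg.start, seg.end):
            continue
        out.append(s)
    return out


def filter_stochastic(
    stats: Iterable[SegmentStats], p_threshold: float = 0.05
) -> list[SegmentStats]:
    """Remove segments whose null p-value exceeds the threshold.

    The removal condition is p > threshold, so p exactly at the threshold is
    retained.
    """
    out = []
    for s in stats:
        if s.p_value is None:
            raise ValueError(f"segment {s.key} has no p-value; run the null first")
        if s.p_value <= p_threshold:
            out.append(s)
    return out


def merge_regions(
    stats: Iterable[SegmentStats], max_gap: int = DEFAULT_MERGE_GAP
) -> list[BipolarRegion]:
    """Transitively merge segment spans that overlap or sit within max_gap bp."""
    items = sorted(stats, key=lambda s: (s.segment.chrom, s.segment.start, s.segment.end))
    regions: list[BipolarRegion] = []
    for s in items:
        seg = s.segment
        p = s.p_value if s.p_value is not None else 1.0
        if (
            regions
            and regions[-1].interval.chrom == seg.chrom
            and seg.start - regions[-1].interval.end <= max_gap
        ):
            last = regions[-1]
            last.interval = GenomicInterval(
                seg.chrom,
                last.interval.start,
                max(last.interval.end, seg.end),
                ".",
                last.interval.label,
            )
            last.member_keys.append(s.key)
            last.min_p = min(last.min_p, p)
        else:
            regions.append(
                BipolarRegion(
                    interval=GenomicInterval(seg.chrom, seg.start, seg.end),
                    member_keys=[s.key],
                    min_p=p,
                )
            )
    return regions


def promoter_interval(
    gene: GeneModel,
    up: int = DEFAULT_PROMOTER_UP,
    down: int = DEFAULT_PROMOTER_DOWN,
) -> GenomicInterval:
    """Promoter as [TSS - up, TSS + down) in transcription orientation.

    On the minus strand the window reflects: it extends ``up`` bp to the
    genomic right of the TSS and ``down`` bp to the left.
    """
    if gene.strand == "+":
        start, end = gene.tss - up, gene.tss + down
    else:
        start, end = gene.tss - down, gene.tss + up
    return GenomicInterval(gene.chrom, max(0, start), end, gene.strand, gene.gene_id)


def associate_promoters(
    regions: Sequence[BipolarRegion],
    genes: Sequence[GeneModel],
    up: int = DEFAULT_PROMOTER_UP,
    down: int = DEFAULT_PROMOTER_DOWN,
) -> list[CandidateGene]:
    """Genes whose promoter overlaps >= 1 region by >= 1 bp.

    Multiple transcripts sharing a gene_id contribute the union of their
    promoters; regions falling in one promoter are merged into a single
    spanning region regardless of gap.
    """
    by_gene: dict[str, list[GenomicInterval]] = {}
    for g in genes:
        by_gene.setdefault(g.gene_id, []).append(promoter_interval(g, up, down))

    out: list[CandidateGene] = []
    for gene_id, promoters in by_gene.items():
        hits: list[BipolarRegion] = []
        for r in regions:
            if any(r.interval.overlaps(p) for p in promoters):
                hits.append(r)
        if not hits:
            continue
        # merge all hit regions within this promoter into one spanning region
        chrom = hits[0].interval.chrom
        merged = BipolarRegion(
            interval=GenomicInterval(
                chrom,
                min(h.interval.start for h in hits),
                max(h.interval.end for h in hits),
                ".",
                gene_id,
            ),
            member_keys=[k for h in hits for k in h.member_keys],
            min_p=min(h.min_p for h in hits),
        )
        span = GenomicInterval(
            chrom,
            min(p.start for p in promoters),
            max(p.end for p in promoters),
            promoters[0].strand,
            gene_id,
        )
        out.append(
            CandidateGene(gene_id=gene_id, promoter=span, n_promoter_cpgs=-1, regions=[merged])
        )
    return sorted(out, key=lambda c: (c.promoter.chrom, c.promoter.start, c.gene_id))


def filter_low_cpg(
    candidates: Iterable[CandidateGene],
    cpg_index: CpGIndex,
    min_cpgs: int = DEFAULT_MIN_PROMOTER_CPGS,
) -> list[CandidateGene]:
    """Keep genes with >= min_cpgs CpG units inside the promoter."""
    out = []
    for c in candidates:
        n = cpg_index.count_in(c.promoter)
        c.n_promoter_cpgs = n
        if n >= min_cpgs:
            out.append(c)
    return out


def run_pipeline(
    segments: Iterable[SegmentPatterns],
    genes: Sequence[GeneModel],
    cpg_index: CpGIndex,
    asm_regions: Sequence[GenomicInterval] = (),
    null_cfg: NullConfig | None = None,
    p_threshold: float = 0.05,
    merge_gap: int = DEFAULT_MERGE_GAP,
    promoter_up: int = DEFAULT_PROMOTER_UP,
    promoter_down: int = DEFAULT_PROMOTER_DOWN,
    min_promoter_cpgs: int = DEFAULT_MIN_PROMOTER_CPGS,
) -> tuple[list[BipolarRegion], list[CandidateGene], dict[str, int]]:
    """Full region/gene pipeline; returns regions, genes and per-step counts."""
    cfg = null_cfg or NullConfig()
    segments = list(segments)
    counts = {"input_segments": len(segments)}

    bipolar = select_bipolar(segments)
    counts["bipolar_segments"] = len(bipolar)

    scored = [attach_null_results(segment_stats(s), cfg) for s in bipolar]

    kept = filter_asm(scored, asm_regions)
    counts["after_asm_filter"] = len(kept)
    kept = filter_stochastic(kept, p_threshold)
    counts["after_stochastic_filter"] = len(kept)

    regions = merge_regions(kept, merge_gap)
    counts["merged_regions"] = len(regions)

    candidates = associate_promoters(regions, genes, promoter_up, promoter_down)
    counts["promoter_genes"] = len(candidates)
    final = filter_low_cpg(candidates, cpg_index, min_promoter_cpgs)
    counts["genes_after_cpg_filter"] = len(final)
    return regions, final, counts


def write_regions_bed(regions: Sequence[BipolarRegion], path, n_reps: int = 1000) -> None:
    """BED6 with score = -10*log10(p + 1/n_reps), capped to BED's 0..1000."""
    import math

    from .methylome_io import write_bed

    intervals = [
        GenomicInterval(r.interval.chrom, r.interval.start, r.interval.end, ".", f"region{i+1}")
        for i, r in enumerate(regions)
    ]
    scores = [
        min(1000, round(-10 * math.log10(r.min_p + 1.0 / n_reps), 1)) for r in regions
    ]
    write_bed(intervals, path, scores=scores)


def write_candidate_genes(candidates: Sequence[CandidateGene], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tpromoter_start\tpromoter_end\tn_cpgs\tn_regions\tmin_p\n")
        for c in candidates:
            fh.write(
                f"{c.gene_id}\t{c.promoter.chrom}\t{c.promoter.start}\t"
                f"{c.promoter.end}\t{c.n_promoter_cpgs}\t{len(c.regions)}\t{c.min_p:.6g}\n"
            )
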