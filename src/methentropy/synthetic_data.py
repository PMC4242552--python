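"""Synthetic mixed-cell methylomes with known ground truth.

The generator emulates what a bisulfite experiment on a mixed cell
population produces at the methylation-extractor level: a CpG landscape
(loci of hypo-/hypermethylated, stochastic-intermediate, cell-subset-
specific and allele-specifically methylated CpGs), fragments drawn per
four-CpG window from subpopulations with distinct per-CpG methylation
probabilities, symmetric call-flip noise, and matching toy gene / CGI /
repeat / ASM annotation fixtures whose promoters cover the designated loci.
Every stage of the toolkit can therefore be tested against a truth table
without any download.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .methylome_io import CpGIndex, GeneModel, GenomicInterval

LABEL_HYPO = "uniform-hypo"
LABEL_HYPER = "uniform-hyper"
LABEL_SUBSET = "cell-subset-specific"
LABEL_ASM = "ASM"
LABEL_STOCHASTIC = "stochastic-intermediate"

CHROM = "chrSim"


@dataclass(frozen=True)
class Locus:
    """A run of CpG units (index coordinates, half-open) with one truth label."""

    label: str
    cpg_start: int
    cpg_end: int


@dataclass
class PopulationSpec:
    """Generative description of a synthetic mixed-cell methylome.

    ``subpopulations`` is a list of (fraction, per-CpG methylation
    probability vector); fractions sum to 1. ``depth`` is the mean number of
    fragments drawn per four-CpG window (Poisson). ``error_rate`` flips each
    call symmetrically; ``non_conversion_rate`` is an optional asymmetric
    bisulfite-failure mode (unmethylated calls misread as methylated),
    default off. ``asm_loci`` mark CpG runs where two equal-fraction alleles
    carry opposite methylation states regardless of subpopulation.
    """

    subpopulations: list[tuple[float, np.ndarray]]
    cpg_spacing: int = 25
    depth: float = 20.0
    read_cpg_span: int = 4
    error_rate: float = 0.01
    non_conversion_rate: float = 0.0
    asm_loci: list[Locus] = field(default_factory=list)
    loci: list[Locus] = field(default_factory=list)
    positions: np.ndarray | None = None  # explicit CpG positions; else regular grid
    max_fragment_span_bp: int = 500  # no fragment covers a window wider than this
    seed: int = 0

    def __post_init__(self):
        fracs = [f for f, _ in self.subpopulations]
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError(f"subpopulation fractions must sum to 1, got {sum(fracs)}")
        n = len(self.subpopulations[0][1])
        for f, p in self.subpopulations:
            p = np.asarray(p, dtype=float)
            if len(p) != n:
                raise ValueError("all probability vectors must share one length")
            if ((p < 0) | (p > 1)).any():
                raise ValueError("methylation probabilities must be in [0, 1]")
        if self.depth < 1:
            raise ValueError(f"depth must be >= 1, got {self.depth}")
        if self.read_cpg_span < 4:
            raise ValueError("read_cpg_span must be >= 4")

    @property
    def n_cpgs(self) -> int:
        return len(self.subpopulations[0][1])

    def cpg_positions(self) -> np.ndarray:
        if self.positions is not None:
            return np.asarray(self.positions, dtype=np.int64)
        return 1000 + self.cpg_spacing * np.arange(self.n_cpgs, dtype=np.int64)


@dataclass
class TruthTable:
    """Ground-truth labels: one per locus and one per four-CpG window start."""

    loci: list[Locus]
    window_labels: list[str]

    def windows_with(self, label: str) -> list[int]:
        return [i for i, l in enumerate(self.window_labels) if l == label]


@dataclass
class SyntheticMethylome:
    spec: PopulationSpec
    calls: list[str]  # Bismark-dialect TSV lines
    cpg_index: CpGIndex
    truth: TruthTable
    genes: list[GeneModel]
    asm_regions: list[GenomicInterval]
    cgis: list[GenomicInterval]
    repeats: list[GenomicInterval]

    def write(self, out_dir) -> dict[str, Path]:
        from .methylome_io import write_bed

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        paths["calls"] = out / "calls.tsv"
        with open(paths["calls"], "w") as fh:
            fh.write(f"# synthetic methylome, seed={self.spec.seed}\n")
            fh.write("\n".join(self.calls) + ("\n" if self.calls else ""))
        paths["cpg_index"] = out / "cpg_index.tsv"
        self.cpg_index.save(paths["cpg_index"])
        paths["genes"] = out / "genes.tsv"
        with open(paths["genes"], "w") as fh:
            for g in self.genes:
                fh.write(
                    f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.tx_start}\t{g.tx_end}"
                    f"\t{g.cds_start}\t{g.cds_end}\t"
                    + ",".join(map(str, g.exon_starts))
                    + "\t"
                    + ",".join(map(str, g.exon_ends))
                    + "\n"
                )
        for name, ivs in (("asm", self.asm_regions), ("cgi", self.cgis), ("repeats", self.repeats)):
            paths[name] = out / f"{name}.bed"
            write_bed(ivs, paths[name])
        paths["truth"] = out / "truth.tsv"
        with open(paths["truth"], "w") as fh:
            fh.write("# window_start_index\tlabel\n")
            for i, label in enumerate(self.truth.window_labels):
                fh.write(f"{i}\t{label}\n")
        return paths


def _window_label(spec: PopulationSpec, j: int, w: int) -> str:
    for locus in spec.asm_loci:
        if j < locus.cpg_end and locus.cpg_start < j + w:
            return LABEL_ASM
    probs = [np.asarray(p, dtype=float)[j : j + w] for _f, p in spec.subpopulations]
    stacked = np.stack(probs)
    if len(stacked) >= 2:
        hi = stacked.max(axis=0)
        lo = stacked.min(axis=0)
        if ((hi >= 0.9) & (lo <= 0.1)).all():
            return LABEL_SUBSET
    if (stacked >= 0.8).all():
        return LABEL_HYPER
    if (stacked <= 0.2).all():
        return LABEL_HYPO
    return LABEL_STOCHASTIC


def generate_methylome(spec: PopulationSpec) -> SyntheticMethylome:
    """Draw a methylome from the spec and build matching annotation fixtures.

    Fragments are drawn per window start: the window count is
    Poisson(depth), each fragment samples a subpopulation by fraction (or an
    allele, 50/50, where the window touches an ASM locus), draws each CpG
    call Bernoulli(per-CpG probability), then applies call-flip noise.
    Roughly half the fragments are emitted in reverse orientation (call
    positions on the G of the CpG) to exercise strand collapsing.
    """
    rng = np.random.default_rng(int(spec.seed) % (2**31))
    positions = spec.cpg_positions()
    n = spec.n_cpgs
    w = spec.read_cpg_span
    fracs = np.array([f for f, _ in spec.subpopulations])
    probs = np.stack([np.asarray(p, dtype=float) for _f, p in spec.subpopulations])

    asm_mask = np.zeros(n, dtype=bool)
    for locus in spec.asm_loci:
        asm_mask[locus.cpg_start : locus.cpg_end] = True

    lines: list[str] = []
    read_counter = 0
    n_windows = max(0, n - w + 1)
    window_labels = [_window_label(spec, j, w) for j in range(n_windows)]

    for j in range(n_windows):
        span_bp = int(positions[j + w - 1]) + 2 - int(positions[j])
        if span_bp > spec.max_fragment_span_bp:
            continue  # no sequenced fragment reaches across this gap
        n_frags = rng.poisson(spec.depth)
        if n_frags == 0:
            continue
        sub = rng.choice(len(fracs), size=n_frags, p=fracs)
        p_mat = probs[sub][:, j : j + w]  # (n_frags, w)
        calls = (rng.random((n_frags, w)) < p_mat).astype(np.int8)
        window_asm = asm_mask[j : j + w]
        if window_asm.any():
            allele = rng.integers(0, 2, size=n_frags)  # 0 = methylated allele
            calls[:, window_asm] = (allele[:, None] == 0).astype(np.int8)
        if spec.error_rate > 0:
            flips = rng.random((n_frags, w)) < spec.error_rate
            calls ^= flips.astype(np.int8)
        if spec.non_conversion_rate > 0:
            fail = (calls == 0) & (rng.random((n_frags, w)) < spec.non_conversion_rate)
            calls[fail] = 1
        reverse = rng.random(n_frags) < 0.5
        for k in range(n_frags):
            read_counter += 1
            rid = f"r{read_counter:08d}"
            orient = "-" if reverse[k] else "+"
            shift = 1 if reverse[k] else 0
            for c in range(w):
                pos1 = int(positions[j + c]) + shift + 1  # 1-based output
                code = "Z" if calls[k, c] else "z"
                lines.append(f"{rid}\t{orient}\t{CHROM}\t{pos1}\t{code}")

    index = CpGIndex({CHROM: positions})
    truth = TruthTable(loci=list(spec.loci), window_labels=window_labels)
    genes, cgis, repeats = _annotation_fixtures(spec, positions)
    asm_regions = [
        GenomicInterval(
            CHROM,
            int(positions[l.cpg_start]),
            int(positions[l.cpg_end - 1]) + 2,
            ".",
            LABEL_ASM,
        )
        for l in spec.asm_loci
    ]
    return SyntheticMethylome(
        spec=spec,
        calls=lines,
        cpg_index=index,
        truth=truth,
        genes=genes,
        asm_regions=asm_regions,
        cgis=cgis,
        repeats=repeats,
    )


def _annotation_fixtures(spec: PopulationSpec, positions: np.ndarray):
    """One gene per labelled locus, promoter covering the locus; toy CGIs on
    hypomethylated loci and LINE repeats on hypermethylated ones."""
    genes, cgis, repeats = [], [], []
    for i, locus in enumerate(spec.loci):
        start = int(positions[locus.cpg_start])
        end = int(positions[locus.cpg_end - 1]) + 2
        tss = end  # + strand promoter [-1000, +200) covers the locus
        genes.append(
            GeneModel(
                gene_id=f"{locus.label.upper().replace('-', '_')}_{i}",
                chrom=CHROM,
                strand="+",
                tx_start=tss,
                tx_end=tss + 500,
                cds_start=tss + 100,
                cds_end=tss + 400,
                exon_starts=(tss,),
                exon_ends=(tss + 500,),
            )
        )
        if locus.label == LABEL_HYPO:
            cgis.append(GenomicInterval(CHROM, start, end, ".", f"cgi_{i}"))
        elif locus.label == LABEL_HYPER:
            repeats.append(GenomicInterval(CHROM, start, end, ".", "LINE"))
    return genes, cgis, repeats


def mixture_study_spec(
    n_subset_loci: int = 20,
    n_hypo_loci: int = 15,
    n_hyper_loci: int = 15,
    n_stochastic_loci: int = 5,
    n_asm_loci: int = 0,
    cpgs_per_locus: int = 12,
    locus_pitch_bp: int = 2500,
    cpg_spacing: int = 25,
    depth: float = 20.0,
    error_rate: float = 0.01,
    seed: int = 0,
) -> PopulationSpec:
    """Two-subpopulation 50/50 study conditions with labelled loci.

    Cell-subset loci are methylated in one subpopulation and unmethylated in
    the other; uniform loci are near-deterministically hypo- or
    hypermethylated in both; stochastic loci have probability 0.5
    everywhere. Loci are laid out on one chromosome with a large bp pitch so
    each gene's promoter covers exactly its own locus, and same-kind loci
    are grouped so boundary windows never mix a uniform locus with a
    cell-subset one.
    """
    blocks = (
        [LABEL_HYPO] * n_hypo_loci
        + [LABEL_HYPER] * n_hyper_loci
        + [LABEL_STOCHASTIC] * n_stochastic_loci
        + [LABEL_SUBSET] * n_subset_loci
        + [LABEL_ASM] * n_asm_loci
    )
    n_loci = len(blocks)
    n_cpgs = n_loci * cpgs_per_locus
    p_a = np.empty(n_cpgs)
    p_b = np.empty(n_cpgs)
    positions = np.empty(n_cpgs, dtype=np.int64)
    loci: list[Locus] = []
    asm_loci: list[Locus] = []
    for i, label in enumerate(blocks):
        lo, hi = i * cpgs_per_locus, (i + 1) * cpgs_per_locus
        positions[lo:hi] = 1000 + i * locus_pitch_bp + cpg_spacing * np.arange(cpgs_per_locus)
        if label == LABEL_HYPO:
            p_a[lo:hi] = p_b[lo:hi] = 0.02
        elif label == LABEL_HYPER:
            p_a[lo:hi] = p_b[lo:hi] = 0.98
        elif label == LABEL_STOCHASTIC:
            p_a[lo:hi] = p_b[lo:hi] = 0.5
        else:  # subset or ASM: opposite states in the two subpopulations
            p_a[lo:hi] = 0.995
            p_b[lo:hi] = 0.005
        locus = Locus(label, lo, hi)
        loci.append(locus)
        if label == LABEL_ASM:
            asm_loci.append(locus)
    return PopulationSpec(
        subpopulations=[(0.5, p_a), (0.5, p_b)],
        cpg_spacing=cpg_spacing,
        depth=depth,
        error_rate=error_rate,
        asm_loci=asm_loci,
        loci=loci,
        positions=positions,
        seed=seed,
    )


def generate_expression(
    genes: Sequence[GeneModel],
    base_values: dict[str, float] | None = None,
    seed: int = 0,
    noise_sd: float = 0.1,
):
    """Expression records with a plantable gene -> value association.

    ``base_values`` maps gene_id to a mean expression; unlisted genes get 1.
    Values are lognormal around the base, so the quantile grouping of genes
    is controlled by the planted means.
    """
    from .methylome_io import ExpressionRecord

    rng = np.random.default_rng(int(seed) % (2**31))
    out = []
    for g in genes:
        base = (base_values or {}).get(g.gene_id, 1.0)
        value = float(base * np.exp(noise_sd * rng.standard_normal())) if base > 0 else 0.0
        out.append(ExpressionRecord(g.gene_id, value))
    return out


def write_expression(records, path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.gene_id}\t{r.value:.6g}\n")
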