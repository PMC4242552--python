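import numpy as np
import pytest

from methentropy.segmentation import SegmentPatterns


def make_segment(counts: dict[int, int], positions=(100, 110, 120, 130), chrom="chr1"):
    """SegmentPatterns from a {pattern_id: count} mapping."""
    vec = np.zeros(16, dtype=np.int64)
    for pid, n in counts.items():
        vec[pid] = n
    return SegmentPatterns(chrom, positions, vec)


@pytest.fixture
def bipolar_8_8():
    """Purely bipolar segment: 8 all-methylated + 8 all-unmethylated reads."""
    return make_segment({0b1111: 8, 0b0000: 8})


@pytest.fixture(scope="session")
def study_methylome():
    """Synthetic two-subpopulation methylome at the default study conditions.

    ~500 four-CpG windows: 25 cell-subset loci (opposite methylation in the
    two 50/50 subpopulations), 20 uniform loci, 5 stochastic loci and 6 ASM
    loci, depth 20, 1% call-flip noise.
    """
    from methentropy.synthetic_data import generate_methylome, mixture_study_spec

    spec = mixture_study_spec(
        n_subset_loci=25,
        n_hypo_loci=10,
        n_hyper_loci=10,
        n_stochastic_loci=5,
        n_asm_loci=6,
        depth=20,
        error_rate=0.01,
        seed=20140978,
    )
    return generate_methylome(spec)


@pytest.fixture(scope="session")
def study_segments(study_methylome):
    """Segments scanned from the study methylome via the full I/O path."""
    import io

    from methentropy.methylome_io import _parse_bismark
    from methentropy.segmentation import filter_reads, group_fragments, scan_segments

    sm = study_methylome

    counts = {"unmatched_position": 0, "unknown_chrom": 0}
    calls = list(
        _parse_bismark(
            io.StringIO("\n".join(sm.calls)), "<memory>", sm.cpg_index, True, counts
        )
    )
    frags = filter_reads(group_fragments(calls))
    return list(scan_segments(frags, sm.cpg_index))
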