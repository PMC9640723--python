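from __future__ import annotations

import numpy as np
import pytest

from lohscape.model import GenomeAnnotation, Segment, SegmentProfile
from lohscape.synthetic_cohort import genome_preset


@pytest.fixture(scope="session")
def toy_annotation() -> GenomeAnnotation:
    return genome_preset("toy")


@pytest.fixture(scope="session")
def medium_annotation() -> GenomeAnnotation:
    return genome_preset("medium")


def make_profile(segs, sample_id="S1", purity=1.0, ploidy=2.0) -> SegmentProfile:
    """Profile from (chrom, start, end, major, minor) tuples."""
    segments = [Segment(c, s, e, ma + mi, ma, mi) for c, s, e, ma, mi in segs]
    return SegmentProfile(sample_id, segments, purity=purity, ploidy=ploidy)


def random_profile(rng: np.random.Generator, annotation: GenomeAnnotation,
                   max_segments_per_chrom: int = 8) -> SegmentProfile:
    """Random small profile: contiguous cover of each chromosome split at
    random breakpoints with random allele-specific states (gaps allowed)."""
    states = [(1, 1), (1, 0), (2, 0), (2, 1), (2, 2), (3, 1), (3, 0), (3, 3), (0, 0)]
    segments = []
    for chrom, length in annotation.chrom_lengths.items():
        n = int(rng.integers(1, max_segments_per_chrom + 1))
        cuts = sorted(rng.choice(np.arange(2, length, 500_000), size=n - 1, replace=False)) if n > 1 else []
        bounds = [1, *map(int, cuts), length + 1]
        for lo, hi in zip(bounds, bounds[1:]):
            if rng.random() < 0.1:  # leave an uncovered gap
                continue
            ma, mi = states[rng.integers(len(states))]
            segments.append(Segment(chrom, lo, hi - 1, ma + mi, ma, mi))
    return SegmentProfile("R", segments)
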