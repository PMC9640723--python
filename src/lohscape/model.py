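"""Core domain types shared across the pipeline.

Coordinate convention: all intervals are 1-based inclusive (Sequenza-style);
BED input/output is the only place 0-based half-open coordinates appear, and
the conversion happens in :mod:`lohscape.io_formats`.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

# Sentinel for annotations that are genuinely absent (REVEL, PopFreqMax).
# Kept distinct from None so "never looked up" and "looked up, not found"
# cannot be conflated downstream.
UNKNOWN = "unknown"


class ValidationError(ValueError):
    """Raised when an input record violates a documented invariant."""


@dataclass(frozen=True)
class Segment:
    """One allele-specific copy-number interval.

    ``cn_major`` counts A (major) alleles, ``cn_minor`` counts B (minor)
    alleles; their sum is the total copy number.  A segment with zero B
    alleles has undergone loss of heterozygosity.
    """

    chrom: str
    start: int  # 1-based inclusive
    end: int
    cn_total: int
    cn_major: int
    cn_minor: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(f"segment {self.chrom}:{self.start}-{self.end}: start > end")
        if self.cn_minor < 0 or self.cn_major < self.cn_minor:
            raise ValidationError(
                f"segment {self.chrom}:{self.start}-{self.end}: "
                f"require cn_major >= cn_minor >= 0, got ({self.cn_major},{self.cn_minor})"
            )
        if self.cn_major + self.cn_minor != self.cn_total:
            raise ValidationError(
                f"segment {self.chrom}:{self.start}-{self.end}: "
                f"cn_major + cn_minor = {self.cn_major + self.cn_minor} != cn_total = {self.cn_total}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def state(self) -> tuple[int, int]:
        return (self.cn_major, self.cn_minor)

    def contains(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos <= self.end


@dataclass
class SegmentProfile:
    """All allele-specific segments of one tumor sample.

    ``purity`` is the tumor-cell fraction estimated upstream; ``ploidy`` the
    average tumor copy number.  Segments are kept sorted by (chrom, start)
    and must not overlap within a chromosome.
    """

    sample_id: str
    segments: list[Segment]
    purity: float = 1.0
    ploidy: float = 2.0

    def __post_init__(self) -> None:
        if not (0.0 < self.purity <= 1.0):
            raise ValidationError(f"{self.sample_id}: purity must be in (0, 1], got {self.purity}")
        if self.ploidy <= 0:
            raise ValidationError(f"{self.sample_id}: ploidy must be > 0, got {self.ploidy}")
        self.segments = sorted(self.segments, key=lambda s: (s.chrom, s.start))
        prev: Optional[Segment] = None
        for seg in self.segments:
            if prev is not None and prev.chrom == seg.chrom and seg.start <= prev.end:
                raise ValidationError(
                    f"{self.sample_id}: overlapping segments "
                    f"{prev.chrom}:{prev.start}-{prev.end} and {seg.chrom}:{seg.start}-{seg.end}"
                )
            prev = seg

    def by_chrom(self) -> dict[str, list[Segment]]:
        out: dict[str, list[Segment]] = {}
        for seg in self.segments:
            out.setdefault(seg.chrom, []).append(seg)
        return out

    def segment_at(self, chrom: str, pos: int) -> Optional[Segment]:
        """The unique segment containing a point locus, or None (gap)."""
        for seg in self.segments:
            if seg.contains(chrom, pos):
                return seg
        return None


@dataclass(frozen=True)
class GeneModel:
    """A gene locus, 1-based inclusive."""

    gene: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(f"gene {self.gene}: start > end")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class GenomeAnnotation:
    """Chromosome lengths, arm boundaries and centromere intervals.

    Arms are 1-based inclusive; the p and q arms of a chromosome flank the
    centromere interval and never overlap.
    """

    chrom_lengths: dict[str, int]
    # chrom -> (p_start, p_end, q_start, q_end)
    arms: dict[str, tuple[int, int, int, int]]
    # chrom -> (cen_start, cen_end)
    centromeres: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        for chrom, (ps, pe, qs, qe) in self.arms.items():
            length = self.chrom_lengths.get(chrom)
            if length is None:
                raise ValidationError(f"arm table references unknown chromosome {chrom}")
            cs, ce = self.centromeres[chrom]
            if not (1 <= ps <= pe < cs <= ce < qs <= qe <= length):
                raise ValidationError(
                    f"{chrom}: arms must flank the centromere within the chromosome "
                    f"(p {ps}-{pe}, cen {cs}-{ce}, q {qs}-{qe}, len {length})"
                )

    def arm_intervals(self, chrom: str) -> list[tuple[str, int, int]]:
        ps, pe, qs, qe = self.arms[chrom]
        return [("p", ps, pe), ("q", qs, qe)]

    def chroms(self) -> list[str]:
        return sorted(self.chrom_lengths)


class Zygosity(str, enum.Enum):
    LOH = "LOH"
    HETEROZYGOUS = "heterozygous"


class LohStatus(str, enum.Enum):
    LOH = "LOH"
    NON_LOH = "nonLOH"
    INDETERMINATE = "indeterminate"


class TrajectoryLabel(str, enum.Enum):
    CONCORDANT_LOH = "concordant_LOH"
    CONCORDANT_NON_LOH = "concordant_nonLOH"
    NON_LOH_TO_LOH = "nonLOH_to_LOH"
    LOH_TO_NON_LOH = "LOH_to_nonLOH"
    MIXED = "mixed"


@dataclass
class LohCall:
    sample_id: str
    status: LohStatus
    locus_chrom: str
    locus_pos: int
    segment: Optional[Segment] = None
    homozygous_deletion: bool = False


@dataclass
class LohTrajectory:
    patient_id: str
    label: TrajectoryLabel
    calls: list[LohCall] = field(default_factory=list)


class CNCategory(str, enum.Enum):
    DELETION = "Deletion"
    LOSS = "Loss"
    NEUTRAL = "Neutral"
    GAIN = "Gain"
    AMPLIFICATION = "Amplification"


class Effect(str, enum.Enum):
    FRAMESHIFT = "frameshift"
    NONSENSE = "nonsense"
    MISSENSE = "missense"
    SYNONYMOUS = "synonymous"
    SPLICE = "splice"
    OTHER = "other"


@dataclass(frozen=True)
class SomaticVariant:
    """One somatic call with the annotations the filter and classifiers use.

    ``pop_freq_max`` and ``revel`` may be the string sentinel
    :data:`UNKNOWN` when the annotation source had no entry.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    effect: Effect
    aaf: float
    alt_depth: int
    n_callers_pass: int
    exonic: bool
    pop_freq_max: float | str = UNKNOWN
    revel: float | str = UNKNOWN
    sample_id: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.aaf <= 1.0):
            raise ValidationError(f"variant {self.key()}: AAF {self.aaf} outside [0, 1]")
        if self.alt_depth < 0 or self.n_callers_pass < 0:
            raise ValidationError(f"variant {self.key()}: negative depth/caller count")

    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class ScarConfig:
    """Thresholds for the genomic-scar scores, in base pairs.

    Defaults follow the component literature: HRD-LOH counts loss-of-
    heterozygosity segments longer than 15 Mb but shorter than a whole
    chromosome; LST counts breakpoints between adjacent >=10 Mb segments
    after smoothing away segments below 3 Mb; NtAI counts allelic-imbalance
    segments reaching a telomere without crossing the centromere.
    """

    hrd_loh_min_len: int = 15_000_000
    lst_min_segment: int = 10_000_000
    lst_smooth_below: int = 3_000_000
    ntai_min_len: int = 1_000_000
    telomere_tolerance: int = 0

    def __post_init__(self) -> None:
        for name in ("hrd_loh_min_len", "lst_min_segment", "lst_smooth_below", "ntai_min_len"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"ScarConfig.{name} must be > 0")
        if self.lst_smooth_below >= self.lst_min_segment:
            raise ValidationError("lst_smooth_below must be < lst_min_segment")
        if self.telomere_tolerance < 0:
            raise ValidationError("telomere_tolerance must be >= 0")


@dataclass
class ScarScores:
    sample_id: str
    ntai: int
    lst: int
    hrd_loh: int
    aneuploidy: int
    tmb: float

    def __post_init__(self) -> None:
        for name in ("ntai", "lst", "hrd_loh", "aneuploidy"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.tmb < 0:
            raise ValidationError("tmb must be >= 0")

    @property
    def hrd_sum(self) -> int:
        return self.ntai + self.lst + self.hrd_loh
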