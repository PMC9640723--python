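"""Genomic-scarring scores: NtAI, LST, HRD-LOH, aneuploidy and TMB.

The three homologous-recombination-deficiency (HRD) components are computed
from allele-specific copy-number segments:

* **HRD-LOH** — number of loss-of-heterozygosity runs (zero B alleles)
  longer than ``hrd_loh_min_len`` (default 15 Mb) but shorter than the whole
  chromosome.
* **NtAI** — number of allelic-imbalance runs (major != minor) that reach a
  chromosome end (within ``telomere_tolerance``), do not cross the
  centromere, are at least ``ntai_min_len`` long and shorter than the whole
  chromosome.
* **LST** — number of breakpoints between adjacent segments that are both at
  least ``lst_min_segment`` (10 Mb) long, counted after merging identical
  neighbouring states and iteratively smoothing away segments shorter than
  ``lst_smooth_below`` (3 Mb).

The HRD score is the plain sum of the three.  The aneuploidy score counts
chromosome arms where at least 80% of the arm length deviates from the
sample's rounded ploidy.  TMB is exonic nonsynonymous SNVs + indels divided
by the capture size in Mbp.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import CohortMetadata
from .model import GenomeAnnotation, ScarConfig, ScarScores, SegmentProfile

#: Fraction of an arm that must deviate from ploidy to call the arm altered.
ARM_ALTERED_FRACTION = 0.8

_Run = tuple[int, int, tuple[int, int]]  # (start, end, (major, minor))


def _runs(segments, merge_gap: int = 1) -> list[_Run]:
    """Collapse sorted same-chromosome segments into maximal runs of one
    allele-specific state.  Neighbours merge when their state is identical
    and the gap between them is below ``merge_gap`` (1 = contiguous only)."""
    runs: list[_Run] = []
    for seg in segments:
        if runs:
            ps, pe, pstate = runs[-1]
            if pstate == seg.state and seg.start - pe - 1 < merge_gap:
                runs[-1] = (ps, seg.end, pstate)
                continue
        runs.append((seg.start, seg.end, seg.state))
    return runs


def _smooth(runs: list[_Run], below: int) -> list[_Run]:
    """Iteratively drop the shortest run below ``below`` and re-merge flanks
    that become identical (positional gap must stay below ``below``)."""
    runs = list(runs)
    while True:
        lengths = [e - s + 1 for s, e, _ in runs]
        small = [i for i, ln in enumerate(lengths) if ln < below]
        if not small:
            return runs
        i = min(small, key=lambda j: (lengths[j], j))
        del runs[i]
        if 0 < i < len(runs):
            ls, le, lstate = runs[i - 1]
            rs, re, rstate = runs[i]
            if lstate == rstate and rs - le - 1 < below:
                runs[i - 1] = (ls, re, lstate)
                del runs[i]


def compute_hrd_loh(profile: SegmentProfile, annotation: GenomeAnnotation,
                    config: ScarConfig | None = None) -> int:
    """Count sub-chromosomal LOH runs longer than the HRD-LOH threshold."""
    config = config or ScarConfig()
    count = 0
    for chrom, segs in profile.by_chrom().items():
        chrom_len = annotation.chrom_lengths[chrom]
        for s, e, (major, minor) in _runs(segs):
            length = e - s + 1
            if minor == 0 and length > config.hrd_loh_min_len and length < chrom_len:
                count += 1
    return count


def compute_ntai(profile: SegmentProfile, annotation: GenomeAnnotation,
                 config: ScarConfig | None = None) -> int:
    """Count telomeric, non-centromere-crossing allelic-imbalance runs."""
    config = config or ScarConfig()
    count = 0
    for chrom, segs in profile.by_chrom().items():
        if chrom not in annotation.chrom_lengths:
            raise ValueError(f"chromosome {chrom} missing from genome annotation")
        chrom_len = annotation.chrom_lengths[chrom]
        cen_s, cen_e = annotation.centromeres[chrom]
        for s, e, (major, minor) in _runs(segs):
            length = e - s + 1
            if major == minor or length < config.ntai_min_len or length >= chrom_len:
                continue
            reaches_telomere = (s - 1 <= config.telomere_tolerance
                                or chrom_len - e <= config.telomere_tolerance)
            crosses_centromere = s <= cen_e and e >= cen_s
            if reaches_telomere and not crosses_centromere:
                count += 1
    return count


def compute_lst(profile: SegmentProfile, config: ScarConfig | None = None) -> int:
    """Count large-scale state transitions after merging and smoothing."""
    config = config or ScarConfig()
    count = 0
    for _, segs in profile.by_chrom().items():
        runs = _runs(segs, merge_gap=config.lst_smooth_below)
        runs = _smooth(runs, config.lst_smooth_below)
        for (as_, ae, astate), (bs, be, bstate) in zip(runs, runs[1:]):
            if astate == bstate:
                continue
            if (ae - as_ + 1 >= config.lst_min_segment
                    and be - bs + 1 >= config.lst_min_segment
                    and bs - ae - 1 < config.lst_smooth_below):
                count += 1
    return count


def compute_aneuploidy(profile: SegmentProfile, annotation: GenomeAnnotation) -> int:
    """Count arms where >=80% of the arm length deviates from rounded ploidy."""
    target = math.floor(profile.ploidy + 0.5)  # nearest integer, ties up
    by_chrom = profile.by_chrom()
    count = 0
    for chrom in annotation.chroms():
        segs = by_chrom.get(chrom, [])
        for _, arm_s, arm_e in annotation.arm_intervals(chrom):
            arm_len = arm_e - arm_s + 1
            altered = 0
            for seg in segs:
                if seg.cn_total == target:
                    continue
                ov = min(seg.end, arm_e) - max(seg.start, arm_s) + 1
                if ov > 0:
                    altered += ov
            if altered >= ARM_ALTERED_FRACTION * arm_len:
                count += 1
    return count


def compute_tmb(n_nonsyn_snvs_and_indels: int, capture_size_mbp: float) -> float:
    """Mutations per Mbp: nonsynonymous exonic SNVs + indels over capture size."""
    if capture_size_mbp <= 0:
        raise ValueError(f"capture size must be > 0 Mbp, got {capture_size_mbp}")
    if n_nonsyn_snvs_and_indels < 0:
        raise ValueError("variant count must be >= 0")
    return n_nonsyn_snvs_and_indels / capture_size_mbp


def score_profile(profile: SegmentProfile, annotation: GenomeAnnotation,
                  config: ScarConfig | None = None,
                  n_nonsyn: int = 0, capture_size_mbp: float = 50.0) -> ScarScores:
    """All six per-sample scores in one pass."""
    config = config or ScarConfig()
    return ScarScores(
        sample_id=profile.sample_id,
        ntai=compute_ntai(profile, annotation, config),
        lst=compute_lst(profile, config),
        hrd_loh=compute_hrd_loh(profile, annotation, config),
        aneuploidy=compute_aneuploidy(profile, annotation),
        tmb=compute_tmb(n_nonsyn, capture_size_mbp),
    )


def scores_table(scores: list[ScarScores]) -> pd.DataFrame:
    return pd.DataFrame([
        {"sample_id": s.sample_id, "ntai": s.ntai, "lst": s.lst, "hrd_loh": s.hrd_loh,
         "hrd_sum": s.hrd_sum, "aneuploidy": s.aneuploidy, "tmb": s.tmb}
        for s in scores
    ])


@dataclass
class PairedTestResult:
    metric: str
    n_pairs: int
    statistic: float
    p_value: float


def compare_paired_scores(scores: pd.DataFrame, metadata: CohortMetadata,
                          metrics: tuple[str, ...] = ("ntai", "lst", "hrd_loh", "hrd_sum",
                                                      "aneuploidy", "tmb"),
                          seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-sided Wilcoxon signed-rank tests on (primary, one recurrence) pairs.

    For patients with multiple scored recurrences, one is chosen at random
    with the given seed; the chosen sample is recorded in the returned
    pairing table so the report is reproducible.  Zero differences are
    handled with the Pratt treatment; the exact null distribution is used
    when scipy permits (small n, no ties/zeros), the continuity-corrected
    normal approximation otherwise.  All-zero differences give p = 1.
    """
    rng = np.random.default_rng(seed)
    by_sample = scores.set_index("sample_id")
    pairs = []
    for patient in metadata.patients:
        samples = metadata.samples_of(patient)
        prim = samples[samples["group"] == "primary"]["sample_id"]
        recs = sorted(s for s in samples[samples["group"] == "recurrent"]["sample_id"]
                      if s in by_sample.index)
        prim = [s for s in prim if s in by_sample.index]
        if not prim or not recs:
            continue
        chosen = recs[rng.integers(len(recs))]
        pairs.append({"patient_id": patient, "primary": prim[0], "recurrence": chosen})
    if not pairs:
        raise ValueError("no patient has both a scored primary and a scored recurrence")
    pairing = pd.DataFrame(pairs)
    rows = []
    for metric in metrics:
        x = by_sample.loc[pairing["primary"], metric].to_numpy(dtype=float)
        y = by_sample.loc[pairing["recurrence"], metric].to_numpy(dtype=float)
        d = y - x
        if np.all(d == 0):
            stat, p = 0.0, 1.0
        else:
            res = stats.wilcoxon(y, x, zero_method="pratt", correction=True, method="auto")
            stat, p = float(res.statistic), float(res.pvalue)
        rows.append(PairedTestResult(metric, len(d), stat, p))
    report = pd.DataFrame([r.__dict__ for r in rows])
    return report, pairing
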