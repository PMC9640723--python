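"""Allele-specific LOH calling and patient-level LOH-trajectory classification.

Zygosity is read directly off the allele-specific copy number of a segment:
zero B (minor) alleles means the segment has undergone loss of
heterozygosity; at least one B allele means it is heterozygous.  A tumor is
called LOH when the segment containing the patient's pathogenic germline
BRCA1/2 locus has LOH (exact point containment; no padding window).

A homozygous deletion (0,0) also has zero B alleles and is classified LOH,
but is flagged separately because loss of both alleles removes the mutant
copy too.
"""
from __future__ import annotations

import pandas as pd

from .io_formats import CohortMetadata
from .model import (
    Effect,
    LohCall,
    LohStatus,
    LohTrajectory,
    Segment,
    SegmentProfile,
    SomaticVariant,
    TrajectoryLabel,
    Zygosity,
)

#: Minimum alternative allele fraction for a somatic LoF second hit to count
#: as biallelic inactivation (enough of the tumor to lose wild-type function).
BIALLELIC_AAF_THRESHOLD = 0.25


def segment_zygosity(segment: Segment) -> Zygosity:
    """LOH iff the segment carries zero B alleles."""
    return Zygosity.LOH if segment.cn_minor == 0 else Zygosity.HETEROZYGOUS


def call_brca_loh(profile: SegmentProfile, locus_chrom: str, locus_pos: int,
                  known_chroms: set[str] | None = None) -> LohCall:
    """Call LOH status at the germline pathogenic locus for one tumor.

    ``indeterminate`` means the locus falls in a gap between segments.  If
    ``known_chroms`` is given, a locus on a chromosome outside it is an error
    rather than an indeterminate call.
    """
    if known_chroms is not None and locus_chrom not in known_chroms:
        raise ValueError(f"locus chromosome {locus_chrom} not in genome annotation")
    seg = profile.segment_at(locus_chrom, locus_pos)
    if seg is None:
        return LohCall(profile.sample_id, LohStatus.INDETERMINATE, locus_chrom, locus_pos)
    status = LohStatus.LOH if segment_zygosity(seg) is Zygosity.LOH else LohStatus.NON_LOH
    return LohCall(profile.sample_id, status, locus_chrom, locus_pos, segment=seg,
                   homozygous_deletion=(seg.cn_major == 0 and seg.cn_minor == 0))


def classify_trajectory(patient_id: str, calls: list[LohCall]) -> LohTrajectory:
    """Classify a patient's LOH trajectory from timepoint-ordered calls.

    The first call is the primary tumor.  Indeterminate calls are excluded
    from all comparisons and never flip a label.  Rules, in order:

    * determinate recurrences disagreeing among themselves -> ``mixed``
    * all determinate calls equal -> ``concordant_LOH`` / ``concordant_nonLOH``
    * primary nonLOH with >=1 LOH recurrence -> ``nonLOH_to_LOH``
    * primary LOH with >=1 nonLOH recurrence -> ``LOH_to_nonLOH``
    * primary indeterminate with uniform recurrences -> concordant on those
    """
    if len(calls) < 2:
        raise ValueError(f"patient {patient_id}: need >=2 calls, got {len(calls)}")
    determinate = [c for c in calls if c.status is not LohStatus.INDETERMINATE]
    if len(determinate) < 2:
        raise ValueError(f"patient {patient_id}: insufficient evaluable tumors")
    primary = calls[0]
    rec_statuses = {c.status for c in calls[1:] if c.status is not LohStatus.INDETERMINATE}
    statuses = {c.status for c in determinate}
    if len(rec_statuses) > 1:
        label = TrajectoryLabel.MIXED
    elif len(statuses) == 1:
        label = (TrajectoryLabel.CONCORDANT_LOH if statuses == {LohStatus.LOH}
                 else TrajectoryLabel.CONCORDANT_NON_LOH)
    elif primary.status is LohStatus.NON_LOH:
        label = TrajectoryLabel.NON_LOH_TO_LOH
    elif primary.status is LohStatus.LOH:
        label = TrajectoryLabel.LOH_TO_NON_LOH
    else:
        # primary indeterminate, recurrences uniform but (unreachable) unequal
        label = TrajectoryLabel.MIXED
    return LohTrajectory(patient_id=patient_id, label=label, calls=calls)


def detect_biallelic_somatic(variants: list[SomaticVariant], germline_gene: str,
                             aaf_threshold: float = BIALLELIC_AAF_THRESHOLD) -> bool:
    """True iff any LoF variant in the germline-mutant gene has AAF >= 0.25.

    Uses the same LoF definition as the somatic-variant classifier
    (frameshift, nonsense, or missense with REVEL > 0.5).
    """
    from .somatic_variants import classify_lof

    return any(
        v.gene == germline_gene and classify_lof(v) and v.aaf >= aaf_threshold
        for v in variants
    )


def call_cohort_loh(profiles: dict[str, SegmentProfile], metadata: CohortMetadata,
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample LOH calls and per-patient trajectories for a cohort.

    Returns (calls table, trajectory table).  The calls table also carries
    group/tissue columns so LOH fractions per group fall out of a groupby.
    """
    call_rows, traj_rows = [], []
    for patient in metadata.patients:
        samples = metadata.samples_of(patient)
        _, chrom, pos = metadata.germline_locus(patient)
        calls = []
        for row in samples.itertuples():
            profile = profiles.get(row.sample_id)
            if profile is None:
                continue
            call = call_brca_loh(profile, chrom, pos)
            calls.append(call)
            call_rows.append({
                "sample_id": row.sample_id, "patient_id": patient,
                "group": row.group, "tissue": row.tissue, "timepoint": row.timepoint,
                "loh_status": call.status.value,
                "homozygous_deletion": call.homozygous_deletion,
            })
        if len(calls) >= 2:
            try:
                traj = classify_trajectory(patient, calls)
                traj_rows.append({"patient_id": patient, "trajectory": traj.label.value})
            except ValueError:
                traj_rows.append({"patient_id": patient, "trajectory": "unevaluable"})
    return pd.DataFrame(call_rows), pd.DataFrame(traj_rows)


def loh_fraction(calls: pd.DataFrame, group: str) -> tuple[int, int]:
    """(n LOH, n determinate) among samples of one group."""
    sub = calls[(calls["group"] == group) & (calls["loh_status"] != LohStatus.INDETERMINATE.value)]
    return int((sub["loh_status"] == LohStatus.LOH.value).sum()), len(sub)
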