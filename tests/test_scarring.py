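from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from lohscape import scarring
from lohscape.io_formats import CohortMetadata
from lohscape.model import GenomeAnnotation, ScarConfig, ScarScores, ValidationError

import naive_scoring
from conftest import make_profile, random_profile

MB = 1_000_000


@pytest.fixture(scope="module")
def simple_annotation() -> GenomeAnnotation:
    # one 100 Mb chromosome: p 1-45M, cen 45-50M, q 50M-100M
    return GenomeAnnotation(
        chrom_lengths={"chr1": 100 * MB},
        arms={"chr1": (1, 45 * MB, 50 * MB + 1, 100 * MB)},
        centromeres={"chr1": (45 * MB + 1, 50 * MB)},
    )


def pad(segs, length=100 * MB, chrom="chr1"):
    """Fill uncovered basepairs with diploid (1,1) background."""
    out, pos = [], 1
    for c, s, e, ma, mi in sorted(segs):
        if s > pos:
            out.append((chrom, pos, s - 1, 1, 1))
        out.append((c, s, e, ma, mi))
        pos = e + 1
    if pos <= length:
        out.append((chrom, pos, length, 1, 1))
    return out


class TestHrdLoh:
    def test_sub_chromosomal_long_loh_counts(self, simple_annotation):
        profile = make_profile(pad([("chr1", 10 * MB, 30 * MB - 1, 2, 0)]))
        assert scarring.compute_hrd_loh(profile, simple_annotation) == 1

    def test_whole_chromosome_loh_excluded(self, simple_annotation):
        profile = make_profile([("chr1", 1, 100 * MB, 1, 0)])
        assert scarring.compute_hrd_loh(profile, simple_annotation) == 0

    def test_short_loh_below_threshold_excluded(self, simple_annotation):
        profile = make_profile(pad([("chr1", 10 * MB, 20 * MB - 1, 2, 0)]))
        assert scarring.compute_hrd_loh(profile, simple_annotation) == 0

    def test_adjacent_same_state_pieces_merge(self, simple_annotation):
        split = make_profile(pad([("chr1", 10 * MB, 20 * MB, 2, 0),
                                  ("chr1", 20 * MB + 1, 30 * MB, 2, 0)]))
        assert scarring.compute_hrd_loh(split, simple_annotation) == 1


class TestNtai:
    def test_telomeric_imbalance_counts(self, simple_annotation):
        # 30 Mb (2,1) abutting the q terminus
        profile = make_profile(pad([("chr1", 70 * MB + 1, 100 * MB, 2, 1)]))
        assert scarring.compute_ntai(profile, simple_annotation) == 1

    def test_centromere_crossing_excluded(self, simple_annotation):
        profile = make_profile(pad([("chr1", 40 * MB, 100 * MB, 2, 1)]))
        assert scarring.compute_ntai(profile, simple_annotation) == 0

    def test_interstitial_imbalance_excluded(self, simple_annotation):
        profile = make_profile(pad([("chr1", 10 * MB, 30 * MB, 2, 0)]))
        assert scarring.compute_ntai(profile, simple_annotation) == 0

    def test_missing_chromosome_in_annotation_raises(self, simple_annotation):
        profile = make_profile([("chr9", 1, 10 * MB, 2, 1)])
        with pytest.raises(ValueError, match="chr9"):
            scarring.compute_ntai(profile, simple_annotation)


class TestLst:
    def test_single_breakpoint_between_large_segments(self):
        profile = make_profile([("chr1", 1, 15 * MB, 1, 1),
                                ("chr1", 15 * MB + 1, 30 * MB, 2, 1)])
        assert scarring.compute_lst(profile) == 1

    def test_small_segment_smoothed_flanks_merge(self):
        profile = make_profile([("chr1", 1, 15 * MB, 1, 1),
                                ("chr1", 15 * MB + 1, 17 * MB, 3, 0),
                                ("chr1", 17 * MB + 1, 32 * MB, 1, 1)])
        assert scarring.compute_lst(profile) == 0

    def test_uniform_diploid_chromosome(self):
        profile = make_profile([("chr1", 1, 100 * MB, 1, 1)])
        assert scarring.compute_lst(profile) == 0

    def test_invariant_under_segment_splitting(self):
        whole = make_profile([("chr1", 1, 15 * MB, 1, 1),
                              ("chr1", 15 * MB + 1, 30 * MB, 2, 1)])
        split = make_profile([("chr1", 1, 7 * MB, 1, 1),
                              ("chr1", 7 * MB + 1, 15 * MB, 1, 1),
                              ("chr1", 15 * MB + 1, 22 * MB, 2, 1),
                              ("chr1", 22 * MB + 1, 30 * MB, 2, 1)])
        assert scarring.compute_lst(whole) == scarring.compute_lst(split) == 1


class TestAneuploidy:
    def test_diploid_genome_scores_zero(self, simple_annotation):
        profile = make_profile([("chr1", 1, 100 * MB, 1, 1)])
        assert scarring.compute_aneuploidy(profile, simple_annotation) == 0

    def test_whole_arm_gain_counts(self, simple_annotation):
        profile = make_profile(pad([("chr1", 1, 45 * MB, 2, 1)]))
        assert scarring.compute_aneuploidy(profile, simple_annotation) == 1

    def test_half_arm_below_coverage_rule(self, simple_annotation):
        profile = make_profile(pad([("chr1", 1, 22 * MB, 2, 1)]))
        assert scarring.compute_aneuploidy(profile, simple_annotation) == 0


class TestTmb:
    @pytest.mark.parametrize("n, mbp, expected", [
        (0, 50, 0.0), (64, 50, 1.28), (640, 50, 12.8), (105, 50, 2.1),
    ])
    def test_quotient(self, n, mbp, expected):
        assert scarring.compute_tmb(n, mbp) == pytest.approx(expected)

    def test_nonpositive_capture_raises(self):
        with pytest.raises(ValueError):
            scarring.compute_tmb(10, 0)


def test_hrd_sum_is_component_sum():
    s = ScarScores("S", ntai=2, lst=3, hrd_loh=4, aneuploidy=0, tmb=0.0)
    assert s.hrd_sum == 9


def test_appending_qualifying_loh_segment_increments_hrd_loh(simple_annotation):
    base_segs = [("chr1", 10 * MB, 30 * MB - 1, 2, 0)]
    extra = base_segs + [("chr1", 50 * MB + 1, 70 * MB + 2, 2, 0)]
    base = make_profile(pad(base_segs))
    more = make_profile(pad(extra))
    assert scarring.compute_hrd_loh(more, simple_annotation) == \
        scarring.compute_hrd_loh(base, simple_annotation) + 1
    assert scarring.compute_ntai(more, simple_annotation) >= \
        scarring.compute_ntai(base, simple_annotation)


def test_scores_match_naive_enumerator_on_random_profiles(toy_annotation):
    rng = np.random.default_rng(2024)
    cfg = ScarConfig()
    for _ in range(100):
        profile = random_profile(rng, toy_annotation)
        assert scarring.compute_hrd_loh(profile, toy_annotation, cfg) == \
            naive_scoring.naive_hrd_loh(profile, toy_annotation)
        assert scarring.compute_ntai(profile, toy_annotation, cfg) == \
            naive_scoring.naive_ntai(profile, toy_annotation)
        assert scarring.compute_lst(profile, cfg) == naive_scoring.naive_lst(profile)
        assert scarring.compute_aneuploidy(profile, toy_annotation) == \
            naive_scoring.naive_aneuploidy(profile, toy_annotation)


def _paired_metadata(n_patients, recs=1):
    rows = []
    for i in range(n_patients):
        pid = f"P{i:03d}"
        rows.append(dict(sample_id=f"{pid}-T0", patient_id=pid, tissue="breast",
                         timepoint=0, group="primary", germline_gene="BRCA1",
                         germline_chrom="chr1", germline_pos=1))
        for t in range(1, recs + 1):
            rows.append(dict(sample_id=f"{pid}-T{t}", patient_id=pid, tissue="breast",
                             timepoint=t, group="recurrent", germline_gene="BRCA1",
                             germline_chrom="chr1", germline_pos=1))
    df = pd.DataFrame(rows)
    df["treatments"] = ""
    return CohortMetadata(df)


def _scores_frame(metadata, recurrence_shift=0):
    rows = []
    rng = np.random.default_rng(0)
    for row in metadata.table.itertuples():
        base = int(rng.integers(0, 10))
        val = base + (recurrence_shift if row.group == "recurrent" else 0)
        rows.append({"sample_id": row.sample_id, "ntai": val, "lst": val,
                     "hrd_loh": val, "hrd_sum": 3 * val, "aneuploidy": val,
                     "tmb": float(val)})
    return pd.DataFrame(rows)


class TestPairedComparison:
    def test_identical_scores_give_p_one(self):
        meta = _paired_metadata(10)
        scores = _scores_frame(meta)
        # force recurrence scores equal to the primary's
        by = scores.set_index("sample_id")
        for pid in meta.patients:
            by.loc[f"{pid}-T1"] = by.loc[f"{pid}-T0"]
        report, _ = scarring.compare_paired_scores(by.reset_index(), meta, seed=0)
        assert (report["p_value"] == 1.0).all()

    def test_constant_shift_detected(self):
        meta = _paired_metadata(20)
        report, _ = scarring.compare_paired_scores(
            _scores_frame(meta, recurrence_shift=5), meta, seed=0)
        assert (report["p_value"] < 0.01).all()

    def test_single_pair_trivial_p(self):
        meta = _paired_metadata(1)
        report, _ = scarring.compare_paired_scores(
            _scores_frame(meta, recurrence_shift=5), meta, seed=0)
        assert (report["p_value"] == 1.0).all()

    def test_recurrence_choice_is_seeded_and_recorded(self):
        meta = _paired_metadata(8, recs=3)
        scores = _scores_frame(meta, recurrence_shift=2)
        _, pairing_a = scarring.compare_paired_scores(scores, meta, seed=42)
        _, pairing_b = scarring.compare_paired_scores(scores, meta, seed=42)
        assert pairing_a.equals(pairing_b)
        assert set(pairing_a.columns) == {"patient_id", "primary", "recurrence"}

    def test_no_valid_pairs_raises(self):
        meta = _paired_metadata(2)
        scores = _scores_frame(meta)
        only_primaries = scores[scores["sample_id"].str.endswith("T0")]
        with pytest.raises(ValueError, match="no patient"):
            scarring.compare_paired_scores(only_primaries, meta, seed=0)


def test_scar_config_rejects_bad_thresholds():
    with pytest.raises(ValidationError):
        ScarConfig(lst_smooth_below=20 * MB)  # smoothing above flank size
    with pytest.raises(ValidationError):
        ScarConfig(hrd_loh_min_len=0)
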