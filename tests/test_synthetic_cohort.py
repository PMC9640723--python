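from __future__ import annotations

import filecmp
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lohscape import loh, scarring
from lohscape.model import ScarConfig
from lohscape.synthetic_cohort import (
    GERMLINE_LOCI,
    CapacityError,
    SimulationConfig,
    generate_cohort,
    genome_preset,
    inject_scar_events,
    read_cohort,
    simulate_survival,
)


class TestInjection:
    def test_zero_events_is_diploid(self, toy_annotation):
        p = inject_scar_events("s", 0, 0, 0, toy_annotation)
        cfg = ScarConfig()
        assert scarring.compute_ntai(p, toy_annotation, cfg) == 0
        assert scarring.compute_lst(p, cfg) == 0
        assert scarring.compute_hrd_loh(p, toy_annotation, cfg) == 0
        assert all(s.state == (1, 1) for s in p.segments)

    def test_three_telomeric_ai_regions(self, medium_annotation):
        p = inject_scar_events("s", 3, 0, 0, medium_annotation)
        assert scarring.compute_ntai(p, medium_annotation) == 3

    def test_two_long_loh_blocks(self, medium_annotation):
        p = inject_scar_events("s", 0, 0, 2, medium_annotation)
        assert scarring.compute_hrd_loh(p, medium_annotation) == 2

    def test_verification_is_built_in(self, medium_annotation):
        # inject() verifies recovery internally; a mix must pass end to end
        p = inject_scar_events("s", 2, 5, 3, medium_annotation, n_arm_events=2)
        assert scarring.compute_lst(p) == 5
        assert scarring.compute_aneuploidy(p, medium_annotation) == 2

    def test_capacity_error_names_the_shortfall(self, toy_annotation):
        with pytest.raises(CapacityError, match="telomere"):
            inject_scar_events("s", 50, 0, 0, toy_annotation)

    def test_loh_block_sets_locus_zygosity(self, toy_annotation):
        chrom, pos = GERMLINE_LOCI["BRCA1"]
        p = inject_scar_events("s", 1, 1, 1, toy_annotation, loh_at_locus=True,
                               locus=(chrom, pos), reserved_loci=tuple(GERMLINE_LOCI.values()))
        assert loh.call_brca_loh(p, chrom, pos).status.value == "LOH"
        q = inject_scar_events("s", 1, 1, 1, toy_annotation, loh_at_locus=False,
                               locus=(chrom, pos), reserved_loci=tuple(GERMLINE_LOCI.values()))
        assert loh.call_brca_loh(q, chrom, pos).status.value == "nonLOH"


class TestGenerateCohort:
    def test_empty_cohort(self, tmp_path):
        cohort = generate_cohort(SimulationConfig(n_patients=0, seed=1),
                                 out_dir=tmp_path / "c")
        assert cohort.profiles == {}
        assert cohort.truth.samples.empty
        assert (tmp_path / "c" / "metadata.csv").exists()

    def test_seeded_runs_are_byte_identical(self, tmp_path):
        cfg = SimulationConfig(n_patients=5, seed=1)
        generate_cohort(cfg, out_dir=tmp_path / "a")
        generate_cohort(cfg, out_dir=tmp_path / "b")
        a_files = sorted(p.relative_to(tmp_path / "a")
                         for p in (tmp_path / "a").rglob("*") if p.is_file())
        for rel in a_files:
            assert filecmp.cmp(tmp_path / "a" / rel, tmp_path / "b" / rel, shallow=False), rel

    def test_primary_loh_fraction_within_binomial_interval(self):
        cfg = SimulationConfig(n_patients=20, p_loh_primary=0.8, seed=7)
        cohort = generate_cohort(cfg)
        primaries = cohort.truth.samples[cohort.truth.samples["group"] == "primary"]
        k = int(primaries["loh"].sum())
        lo, hi = stats.binom.interval(0.95, 20, 0.8)
        assert lo <= k <= hi

    def test_scores_recover_injected_counts(self):
        cohort = generate_cohort(SimulationConfig(n_patients=6, seed=2))
        cfg = ScarConfig()
        for row in cohort.truth.samples.itertuples():
            p = cohort.profiles[row.sample_id]
            assert scarring.compute_ntai(p, cohort.annotation, cfg) == row.ntai
            assert scarring.compute_lst(p, cfg) == row.lst
            assert scarring.compute_hrd_loh(p, cohort.annotation, cfg) == row.hrd_loh
            assert scarring.compute_aneuploidy(p, cohort.annotation) == row.arm_events

    def test_clonal_aaf_respects_purity_scaling(self):
        cfg = SimulationConfig(n_patients=10, seed=4, aaf_noise_sd=0.01)
        cohort = generate_cohort(cfg)
        clonal_keys = cohort.truth.variants[cohort.truth.variants["clonal"]]
        for sample_id, vs in cohort.variants.items():
            purity = cohort.profiles[sample_id].purity
            keys = set(map(tuple, clonal_keys[clonal_keys["sample_id"] == sample_id]
                           [["chromosome", "position"]].itertuples(index=False)))
            for v in vs:
                if (v.chrom, v.pos) in keys:
                    assert v.aaf == pytest.approx(purity / 2, abs=5 * 0.01)

    def test_roundtrip_read_cohort(self, tmp_path):
        cfg = SimulationConfig(n_patients=4, seed=9)
        cohort = generate_cohort(cfg, out_dir=tmp_path / "c")
        back = read_cohort(tmp_path / "c")
        assert set(back.profiles) == set(cohort.profiles)
        assert back.truth.samples.equals(cohort.truth.samples)
        sid = next(iter(cohort.profiles))
        assert back.profiles[sid].segments == cohort.profiles[sid].segments
        assert back.variants[sid] == cohort.variants[sid]

    def test_infeasible_config_fails_before_writing(self, tmp_path):
        out = tmp_path / "never"
        cfg = SimulationConfig(n_patients=2, seed=1, n_ntai_range=(40, 40))
        with pytest.raises(CapacityError):
            generate_cohort(cfg, out_dir=out)
        assert not out.exists()

    def test_truth_trajectories_match_planted_statuses(self):
        cfg = SimulationConfig(n_patients=30, seed=12, p_loh_primary=0.5,
                               p_nonloh_to_loh=0.4, p_loh_to_nonloh=0.4)
        cohort = generate_cohort(cfg)
        labels = set(cohort.truth.patients["trajectory"])
        # with high transition probabilities every class should appear
        assert {"nonLOH_to_LOH", "LOH_to_nonLOH"} <= labels


class TestSimulateSurvival:
    def test_censor_rate_zero_all_events(self):
        rng = np.random.default_rng(0)
        df = simulate_survival([f"p{i}" for i in range(50)], [False] * 50,
                               true_hr=2.0, baseline_hazard=0.01, censor_rate=0.0, rng=rng)
        assert (df["event"] == 1).all()

    def test_invalid_parameters_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            simulate_survival(["a"], [True], true_hr=0.0, baseline_hazard=0.01,
                              censor_rate=0.1, rng=rng)
        with pytest.raises(ValueError):
            simulate_survival(["a"], [True], true_hr=2.0, baseline_hazard=0.01,
                              censor_rate=1.0, rng=rng)

    def test_null_hazard_ratio_recovered(self):
        from lohscape.isoform_survival import fit_cox

        rng = np.random.default_rng(8)
        n = 2000
        df = simulate_survival([f"p{i}" for i in range(n)],
                               list(rng.random(n) < 0.5), true_hr=1.0,
                               baseline_hazard=0.02, censor_rate=0.1, rng=rng)
        (term,) = fit_cox(df)
        assert term.ci_low < 1.0 < term.ci_high

    def test_probabilities_validated_in_config(self):
        with pytest.raises(ValueError):
            SimulationConfig(p_loh_primary=1.5)
        with pytest.raises(ValueError):
            SimulationConfig(censor_rate=-0.1)
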