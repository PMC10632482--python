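"""Synthetic-cohort generator: determinism and closed-loop recovery."""

import numpy as np
import pandas as pd
import pytest

from immunomet.scenith import compute_scenith_profile
from immunomet.seahorse import compute_indices, exogenous_fao_max
from immunomet.simulate import (
    SyntheticCohortConfig,
    generate_cell_events,
    generate_cohort,
    generate_seahorse_trace,
    generate_supernatant_table,
    generate_survival_cohort,
    panel_from_events,
)
from immunomet.stats import km_estimate, logrank_test


class TestConfigValidation:
    def test_dependence_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match="dependence"):
            SyntheticCohortConfig(
                seed=1, dependence={"good": {"glucose": 1.3, "mito": 0.5, "fao": 0.2, "glut": 0.2}}
            )

    def test_non_positive_hazard_ratio_rejected(self):
        with pytest.raises(ValueError, match="hazard"):
            SyntheticCohortConfig(seed=1, hr_high_mito=0.0)

    def test_validation_happens_before_sampling(self):
        with pytest.raises(ValueError):
            SyntheticCohortConfig(seed=1, censoring_rate=1.5)


class TestDeterminism:
    def test_events_byte_identical_across_runs(self):
        cfg = SyntheticCohortConfig(seed=123, cells_per_condition=50,
                                    n_patients={"good": 2, "bad": 2})
        a = generate_cell_events(cfg, "good", "good_01").data
        b = generate_cell_events(cfg, "good", "good_01").data
        pd.testing.assert_frame_equal(a, b)

    def test_different_seeds_differ(self):
        base = dict(cells_per_condition=50, n_patients={"good": 1, "bad": 1})
        a = generate_cell_events(SyntheticCohortConfig(seed=1, **base), "good", "g1").data
        b = generate_cell_events(SyntheticCohortConfig(seed=2, **base), "good", "g1").data
        assert not np.allclose(a["puromycin"], b["puromycin"])

    def test_streams_independent_of_other_generators(self):
        # drawing survival data must not perturb the cell stream
        cfg = SyntheticCohortConfig(seed=9, cells_per_condition=30,
                                    n_patients={"good": 1, "bad": 1})
        a = generate_cell_events(cfg, "good", "g1").data
        generate_survival_cohort(cfg)
        b = generate_cell_events(cfg, "good", "g1").data
        pd.testing.assert_frame_equal(a, b)


class TestCellEvents:
    def test_full_mito_dependence_matches_dgo_floor(self):
        cfg = SyntheticCohortConfig(
            seed=2, cells_per_condition=4000, noise_sigma=0.0, sample_sigma=0.0,
            background_fraction=0.0, latent_effect=0.0,
            dependence={"good": {"glucose": 0.3, "mito": 1.0, "fao": 0.2, "glut": 0.2}},
            n_patients={"good": 1},
        )
        events = generate_cell_events(cfg, "good", "g1")
        panel = panel_from_events(events)
        assert panel.mfi["O"] == pytest.approx(panel.mfi["DGO"], abs=1e-9)
        # zero-noise DGO floor is exactly 0 here; recovery needs a positive
        # denominator, so check the oligomycin median hit the floor instead

    def test_zero_mito_dependence_matches_control(self):
        cfg = SyntheticCohortConfig(
            seed=2, cells_per_condition=4000, noise_sigma=0.0, sample_sigma=0.0,
            latent_effect=0.0,
            dependence={"good": {"glucose": 0.3, "mito": 0.0, "fao": 0.2, "glut": 0.2}},
            n_patients={"good": 1},
        )
        panel = panel_from_events(generate_cell_events(cfg, "good", "g1"))
        assert panel.mfi["O"] == pytest.approx(panel.mfi["C"], abs=1e-9)
        profile = compute_scenith_profile(panel)
        assert profile.values["mitochondrial_dependence"] == pytest.approx(0.0, abs=1e-9)

    def test_mito_recovery_within_3_points_across_seeds(self):
        """m = 0.8 at 5000 cells/condition: recovered mitochondrial dependence
        within +-3 points of 80 in 20/20 seeds."""
        deps = {"good": {"glucose": 0.4, "mito": 0.8, "fao": 0.25, "glut": 0.3}}
        for seed in range(42, 62):
            cfg = SyntheticCohortConfig(
                seed=seed, cells_per_condition=5000, sample_sigma=0.0,
                dependence=deps, n_patients={"good": 1},
            )
            panel = panel_from_events(generate_cell_events(cfg, "good", "g1"))
            profile = compute_scenith_profile(panel)
            assert profile.values["mitochondrial_dependence"] == pytest.approx(80.0, abs=3.0)

    def test_harringtonine_below_all_other_conditions(self):
        cfg = SyntheticCohortConfig(seed=3, cells_per_condition=2000,
                                    n_patients={"good": 1, "bad": 1})
        panel = panel_from_events(generate_cell_events(cfg, "bad", "b1"))
        assert panel.mfi["H"] <= min(v for k, v in panel.mfi.items() if k != "H")


class TestSeahorseGenerator:
    def test_noiseless_closed_loop(self):
        cfg = SyntheticCohortConfig(seed=4, seahorse_noise_sd=0.0)
        idx = compute_indices(generate_seahorse_trace(cfg, "good"))
        means = cfg.seahorse_means["good"]
        assert idx.basal_respiration == pytest.approx(means["ocr_pre"] - means["ocr_post_ra"])
        assert idx.proton_leak == pytest.approx(means["ocr_post_oligo"] - means["ocr_post_ra"])
        assert idx.maximal_oxygen_consumption == pytest.approx(
            means["ocr_post_fccp"] - means["ocr_post_ra"]
        )

    def test_noiseless_exogenous_fao_equals_configured_delta(self):
        cfg = SyntheticCohortConfig(seed=4, seahorse_noise_sd=0.0, seahorse_fao_delta=40.0)
        ctrl = generate_seahorse_trace(cfg, "good", condition="control")
        palm = generate_seahorse_trace(cfg, "good", condition="palmitate+etomoxir")
        assert exogenous_fao_max(ctrl, palm) == pytest.approx(40.0)

    def test_noisy_basal_recovery_with_mean_aggregators(self):
        """Noise SD 5 with 6 points/segment: mean recovered basal across 50
        seeds within +-2 of the configured 90."""
        mean_agg = {s: "mean" for s in
                    ("pre-Oligo", "post-oligomycin", "post-FCCP", "post-rotenone/antimycinA")}
        basals = []
        for seed in range(50):
            cfg = SyntheticCohortConfig(seed=seed, seahorse_noise_sd=5.0,
                                        seahorse_points_per_segment=6)
            idx = compute_indices(generate_seahorse_trace(cfg, "good"), mean_agg)
            basals.append(idx.basal_respiration)
        assert np.mean(basals) == pytest.approx(90.0, abs=2.0)


class TestSupernatantGenerator:
    def test_media_change_reflected_in_readings(self):
        cfg = SyntheticCohortConfig(seed=5, supernatant_noise_sd=0.0)
        table = generate_supernatant_table(cfg, "bad", "b1")
        rates = cfg.supernatant_rates["bad"]
        # day 3 reading precedes the change; day 5 restarts from fresh medium
        assert table.loc[1, "glucose_mM"] == pytest.approx(25 - 3 * rates["glucose_per_day"])
        assert table.loc[2, "glucose_mM"] == pytest.approx(25 - 2 * rates["glucose_per_day"])
        assert table.loc[2, "lactate_mM"] == pytest.approx(2 * rates["lactate_per_day"])


class TestSurvivalGenerator:
    def test_full_censoring_km_flat(self):
        cfg = SyntheticCohortConfig(seed=6, censoring_rate=1.0)
        surv = generate_survival_cohort(cfg)
        assert (surv["os_event"] == 0).all()
        km = km_estimate(surv["os_months"], surv["os_event"])
        assert km.survival_at([surv["os_months"].max()])[0] == 1.0

    def test_protective_high_mito_separates_km_curves(self):
        rejections = 0
        for seed in range(20):
            cfg = SyntheticCohortConfig(
                seed=seed, n_patients={"good": 100, "bad": 100},
                hr_high_mito=1 / 3.0, censoring_rate=0.1,
            )
            surv = generate_survival_cohort(cfg)
            high = (surv["mitochondrial_dependence"] > cfg.mito_threshold).astype(int)
            if high.nunique() < 2:
                continue
            res = logrank_test(surv["os_months"], surv["os_event"], high)
            if res.p_value < 0.01:
                rejections += 1
        assert rejections >= 18

    def test_null_hr_type_one_error_near_nominal(self):
        """HR = 1: the log-rank on the high/low mitochondrial split rejects at
        roughly the nominal 5% over 200 seeded replicates."""
        hits = trials = 0
        for seed in range(200):
            cfg = SyntheticCohortConfig(
                seed=seed, n_patients={"good": 30, "bad": 30}, hr_high_mito=1.0,
                censoring_rate=0.1,
            )
            surv = generate_survival_cohort(cfg)
            high = (surv["mitochondrial_dependence"] > cfg.mito_threshold).astype(int)
            if high.nunique() < 2 or surv["os_event"].sum() < 2:
                continue
            trials += 1
            if logrank_test(surv["os_months"], surv["os_event"], high).p_value < 0.05:
                hits += 1
        assert trials > 150
        assert 0.01 <= hits / trials <= 0.10


class TestFullCohort:
    def test_cohort_covers_every_data_kind(self, tiny_cohort_config):
        cohort = generate_cohort(tiny_cohort_config)
        assert len(cohort.events) == 12
        assert len(cohort.panels) == 12
        assert len(cohort.seahorse) == 12
        assert len(cohort.survival) == 12
        assert set(cohort.sample_groups.values()) == {"good", "bad"}
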