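"""Synthetic microcosm generator: design, depths, interface, renders, nutrients."""

import numpy as np
import pandas as pd
import pytest

from fspimix import (
    DepthModel,
    RenderParams,
    TreatmentSpec,
    default_calibration,
    default_nutrient_model,
    generate_interface_trace,
    headline_calibration,
    make_design,
    render_profile_image,
    sample_particle_depths,
    segment_luminophores,
    simulate_experiment,
    simulate_nutrient_series,
    truncated_exponential_mean,
    write_experiment,
)


class TestDesign:
    def test_default_design_has_30_aquaria_in_6_groups(self):
        d = make_design()
        assert len(d.aquaria) == 30
        assert len(d.treatments) == 6
        assert d.control_label == "C"
        assert len(d.treatment_labels) == 5
        assert d.sampling_days == (0, 2, 5, 8, 12, 16, 21)

    def test_one_replicate_gives_one_aquarium_per_group(self):
        d = make_design(n_replicates=1)
        assert len(d.aquaria) == 6

    def test_aquarium_ids_unique(self):
        d = make_design()
        ids = [a for a, _, _ in d.aquaria]
        assert len(set(ids)) == len(ids)

    def test_empty_ratio_list_rejected(self):
        with pytest.raises(ValueError):
            make_design(ratios=())

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError):
            make_design(ratios=((8, 0), (8, 0)))

    def test_control_flag_must_match_clam_counts(self):
        with pytest.raises(ValueError):
            TreatmentSpec(n_rd=2, n_rp=0, label="x", is_control=True)


class TestParticleDepths:
    def test_full_surface_fraction_pins_all_particles_at_zero(self, rng):
        m = DepthModel(surface_fraction=1.0, mixing_scale_mm=10.0,
                       truncation_depth_mm=80.0, n_particles=500)
        assert np.all(sample_particle_depths(m, rng) == 0.0)

    def test_zero_mixing_scale_degenerates_to_surface(self, rng):
        m = DepthModel(surface_fraction=0.0, mixing_scale_mm=0.0,
                       truncation_depth_mm=80.0, n_particles=100)
        assert np.all(sample_particle_depths(m, rng) == 0.0)

    def test_truncated_exponential_mean_recovered(self, rng):
        # closed-form mean of Exp(5) truncated at 80 mm; 3-standard-error band
        m = DepthModel(surface_fraction=0.0, mixing_scale_mm=5.0,
                       truncation_depth_mm=80.0, n_particles=100_000)
        depths = sample_particle_depths(m, rng)
        expected = truncated_exponential_mean(5.0, 80.0)
        se = depths.std() / np.sqrt(depths.size)
        assert abs(depths.mean() - expected) < 3 * se
        assert depths.max() <= 80.0

    def test_zero_particles_rejected(self):
        with pytest.raises(ValueError):
            DepthModel(surface_fraction=0.0, mixing_scale_mm=5.0,
                       truncation_depth_mm=80.0, n_particles=0)


class TestInterfaceTrace:
    def test_zero_target_gives_flat_interface(self, rng):
        rel = generate_interface_trace(100, 0.0, 5.0, 0.07, rng)
        assert np.all(rel == 0)

    def test_span_matches_target_to_one_pixel(self, rng):
        rel = generate_interface_trace(500, 10.0, 10.0, 0.07, rng)
        span = rel.max() - rel.min()
        assert span == round(10.0 / 0.07)
        assert abs(span * 0.07 - 10.0) <= 0.07

    def test_single_column_rejected(self, rng):
        with pytest.raises(ValueError):
            generate_interface_trace(1, 5.0, 5.0, 0.07, rng)

    def test_negative_target_rejected(self, rng):
        with pytest.raises(ValueError):
            generate_interface_trace(100, -1.0, 5.0, 0.07, rng)


class TestRender:
    params = RenderParams(image_width_px=40, image_height_px=300,
                          resolution_mm_per_px=0.07, sediment_column_mm=15.0,
                          water_margin_px=50, particle_radius_px=1)

    def test_zero_particles_render_to_empty_mask(self):
        img = render_profile_image(
            np.zeros(40, dtype=np.int64), np.array([], dtype=int),
            np.array([]), self.params)
        assert segment_luminophores(img).count == 0

    def test_particle_disc_centred_at_expected_row(self):
        # depth 0.70 mm at 0.07 mm/px is 10 rows below the interface (row 50)
        img = render_profile_image(
            np.zeros(40, dtype=np.int64), np.array([20]),
            np.array([0.70]), self.params)
        mask = segment_luminophores(img).mask
        rows, cols = np.nonzero(mask)
        assert round(rows.mean()) == 60
        assert round(cols.mean()) == 20
        assert mask[60, 20]

    def test_too_deep_particle_rejected(self):
        with pytest.raises(ValueError):
            render_profile_image(
                np.zeros(40, dtype=np.int64), np.array([5]),
                np.array([20.0]), self.params)  # column is only 15 mm


class TestNutrients:
    def test_control_po4_matches_calibrated_endpoints(self):
        # noiseless control phosphate runs 0.10 -> 0.32 mg/L over 21 days
        model = default_nutrient_model()
        trend = model.trends["po4_p_mg_l"]
        noiseless = type(model)(trends={
            "po4_p_mg_l": type(trend)(trend.initial_mg_l, trend.endpoint_mg_l, 0.0)})
        df = simulate_nutrient_series("C", noiseless, (0, 2, 5, 8, 12, 16, 21),
                                      np.random.default_rng(0))
        assert df.loc[df.day == 0, "po4_p_mg_l"].item() == pytest.approx(0.10)
        assert df.loc[df.day == 21, "po4_p_mg_l"].item() == pytest.approx(0.32)
        # noiseless series is exactly linear in day
        resid = np.polyfit(df.day, df.po4_p_mg_l, 1, full=True)[1]
        assert resid[0] == pytest.approx(0.0, abs=1e-18)

    def test_flat_trend_gives_constant_series(self):
        model = default_nutrient_model()
        trend = model.trends["nox_n_mg_l"]
        noiseless = type(model)(trends={
            "nox_n_mg_l": type(trend)(trend.initial_mg_l, trend.endpoint_mg_l, 0.0)})
        df = simulate_nutrient_series("4Rd+4Rp", noiseless, (0, 21),
                                      np.random.default_rng(0))
        assert df["nox_n_mg_l"].nunique() == 1

    def test_same_seed_reproduces_series(self):
        model = default_nutrient_model()
        a = simulate_nutrient_series("C", model, (0, 2, 21),
                                     np.random.default_rng(42))
        b = simulate_nutrient_series("C", model, (0, 2, 21),
                                     np.random.default_rng(42))
        pd.testing.assert_frame_equal(a, b)

    def test_day_grid_must_start_at_zero(self):
        with pytest.raises(ValueError):
            simulate_nutrient_series("C", default_nutrient_model(), (2, 21),
                                     np.random.default_rng(0))


class TestSimulateExperiment:
    def test_default_cardinalities(self, small_design):
        exp = simulate_experiment(small_design, master_seed=3)
        assert len(exp.images) == 6
        assert len(exp.nutrients) == 6 * 2
        assert len(exp.ground_truth) == 6

    def test_control_truth_metrics_are_zero(self, small_design):
        exp = simulate_experiment(small_design, master_seed=3)
        ctrl = exp.ground_truth[
            exp.ground_truth.aquarium_id.str.startswith("C_")]
        assert (ctrl[["true_l_max_mm", "true_l_med_mm",
                      "true_l_mean_mm"]].to_numpy() == 0).all()

    def test_truth_metric_ordering(self, small_design):
        t = simulate_experiment(small_design, master_seed=5).ground_truth
        assert (t.true_l_med_mm <= t.true_l_max_mm + 1e-12).all()
        assert (t.true_l_mean_mm <= t.true_l_max_mm + 1e-12).all()
        assert (t[["true_l_max_mm", "true_l_med_mm", "true_l_mean_mm",
                   "true_sbr_mm"]].to_numpy() >= 0).all()

    def test_burial_truncation_respected(self):
        # Rd present -> 120 mm bound; Rp only -> 80 mm bound
        d = make_design(ratios=((8, 0), (0, 8)), n_replicates=3,
                        sampling_days=(0, 21), analysis_day=21,
                        include_control=False)
        t = simulate_experiment(d, master_seed=11).ground_truth
        rd = t[t.aquarium_id.str.startswith("8Rd")]
        rp = t[t.aquarium_id.str.startswith("0Rd")]
        assert (rd.true_l_max_mm <= 120.0).all()
        assert (rp.true_l_max_mm <= 80.0).all()

    def test_seed_scoping(self, small_design):
        a = simulate_experiment(small_design, master_seed=1)
        b = simulate_experiment(small_design, master_seed=2)
        assert a.design == b.design
        assert not a.ground_truth.equals(b.ground_truth)

    def test_written_bundle_is_byte_identical_across_reruns(
            self, small_design, tmp_path):
        for sub in ("a", "b"):
            exp = simulate_experiment(small_design, master_seed=9)
            write_experiment(exp, tmp_path / sub)
        for name in sorted(p.name for p in (tmp_path / "a").iterdir()):
            assert (tmp_path / "a" / name).read_bytes() == \
                   (tmp_path / "b" / name).read_bytes(), name

    def test_headline_calibration_shares_treatment_levels(self):
        cal, nm = headline_calibration()
        assert len(set(cal.scale_mm.values())) == 1
        assert len(set(cal.sbr_mm.values())) == 1
        for trend in nm.trends.values():
            treatment_ends = {v for k, v in trend.endpoint_mg_l.items()
                              if k != "C"}
            assert len(treatment_ends) == 1

    def test_default_calibration_covers_all_ratios(self):
        cal = default_calibration()
        d = make_design()
        assert set(cal.scale_mm) == set(d.treatment_labels)
        assert set(cal.sbr_mm) == set(d.treatment_labels)
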