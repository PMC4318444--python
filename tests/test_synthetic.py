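import dataclasses

import numpy as np
import pytest

import rhizotrace as rt
from rhizotrace.architecture import compute_lauz, measure_local_traits
from rhizotrace.synthetic import _draw_insertions


class TestSamplePlant:
    def test_zero_rate_means_no_laterals(self):
        model = dataclasses.replace(rt.PlantModel(), lateral_rate=0.0)
        geom = rt.sample_plant(model, 5)
        assert geom.laterals == []
        assert compute_lauz(geom.truth_topology()) == model.primary_length

    def test_deterministic_given_seed(self):
        a = rt.sample_plant(rt.PlantModel(), 11)
        b = rt.sample_plant(rt.PlantModel(), 11)
        np.testing.assert_array_equal(a.primary, b.primary)
        assert [l.insertion for l in a.laterals] == [l.insertion for l in b.laterals]
        assert [l.length for l in a.laterals] == [l.length for l in b.laterals]

    def test_different_seeds_differ(self):
        a = rt.sample_plant(rt.PlantModel(), 1)
        b = rt.sample_plant(rt.PlantModel(), 2)
        assert [l.insertion for l in a.laterals] != [l.insertion for l in b.laterals]

    def test_insertion_process_mean_count(self):
        """Intensity 1.5/cm on an 8 cm branched zone: the mean count over
        200 seeds must land within 3 SE of 12 (SE from the Poisson-rate
        yardstick sqrt(12)/sqrt(200))."""
        model = rt.PlantModel()
        counts = [len(_draw_insertions(model, 8.0, np.random.default_rng(s)))
                  for s in range(200)]
        assert abs(np.mean(counts) - 12.0) <= 3 * np.sqrt(12) / np.sqrt(200)

    def test_insertions_respect_hard_core_gap(self):
        model = rt.PlantModel()
        for s in range(20):
            ins = _draw_insertions(model, 15.0, np.random.default_rng(s))
            assert (np.diff(ins) >= model.lateral_min_gap - 1e-12).all()

    def test_primary_arclength_is_exact(self):
        geom = rt.sample_plant(rt.PlantModel(), 3)
        seg = np.sqrt(((geom.primary[1:] - geom.primary[:-1]) ** 2).sum(1))
        assert seg.sum() == pytest.approx(geom.primary_length, rel=1e-4)

    def test_truth_traits_self_consistent(self):
        """Stored truth traits must equal traits recomputed analytically
        from the truth topology."""
        scene = rt.render_scene(rt.sample_plant(rt.PlantModel(), 9), rng_seed=9)
        recomputed = measure_local_traits(scene.truth_topology)
        assert recomputed.lauz == pytest.approx(scene.truth_local.lauz, abs=1e-9)
        assert recomputed.n_laterals == scene.truth_local.n_laterals
        if recomputed.lateral_density is not None:
            assert recomputed.lateral_density == pytest.approx(
                scene.truth_local.lateral_density, abs=1e-9)


class TestRenderScene:
    def test_reproducible_from_seed(self):
        geom = rt.sample_plant(rt.PlantModel(), 4)
        a = rt.render_scene(geom, rng_seed=44)
        b = rt.render_scene(geom, rng_seed=44)
        np.testing.assert_array_equal(a.image.pixels, b.image.pixels)

    def test_under_exposed_dark_frame(self):
        scene = rt.render_scene(rt.sample_plant(rt.PlantModel(), 4), rng_seed=4)
        assert scene.image.pixels.mean() < 128  # darker than mid-grey

    def test_mesh_only_scene_has_empty_truth(self):
        scene = rt.render_scene(None, frame_cm=(5, 5), crop_margin_cm=None,
                                rng_seed=1)
        assert scene.truth_mask.is_empty
        assert scene.truth_topology is None

    def test_clean_render_recovered_at_high_f1(self):
        geom = rt.sample_plant(rt.PlantModel(), 8)
        scene = rt.render_scene(geom, rng_seed=8, noise_sd=0,
                                mesh_brightness=0, glint_fraction=0, vignette=0)
        mask = rt.segment_root(scene.image)
        assert rt.foreground_f1(mask, scene.truth_mask) >= 0.99

    def test_oversized_geometry_warns(self):
        model = dataclasses.replace(rt.PlantModel(), primary_length=40.0)
        geom = rt.sample_plant(model, 0)
        with pytest.warns(UserWarning):
            rt.render_scene(geom, rng_seed=0)


class TestRenderRosette:
    def test_single_circular_leaf_area_is_analytic(self):
        scene = rt.render_rosette(n_leaves=1, leaf_aspect=1.0,
                                  leaf_length_cm=2.0, noise_sd=0, vignette=0,
                                  rng_seed=2)
        assert scene.truth_global.projected_area == pytest.approx(
            np.pi * 1.0 ** 2, rel=0.01)

    def test_clean_render_segmented_within_three_percent(self):
        scene = rt.render_rosette(rng_seed=5, noise_sd=0, vignette=0)
        mask = rt.segment_shoot(scene.image)
        assert rt.projected_area(mask) == pytest.approx(
            scene.truth_global.projected_area, rel=0.03)

    def test_background_is_achromatic(self):
        scene = rt.render_rosette(rng_seed=7, noise_sd=0, vignette=0)
        _, sat, _ = rt.split_hsv(scene.image)
        assert sat[~scene.truth_mask.pixels].mean() < 5


class TestTimecourse:
    def test_null_treatment_identical_to_mock(self):
        _, mock = rt.simulate_timecourse(rt.PlantModel(), rng_seed=5,
                                         growth_factor=1.0,
                                         treatment_label="a")
        _, null_treated = rt.simulate_timecourse(rt.PlantModel(), rng_seed=5,
                                                 growth_factor=1.0,
                                                 treatment_label="b")
        va = [r.value for r in mock]
        vb = [r.value for r in null_treated]
        assert va == vb

    def test_truth_area_strictly_increasing(self):
        _, records = rt.simulate_timecourse(rt.PlantModel(), n_timepoints=12,
                                            rng_seed=6)
        areas = [r.value for r in records
                 if r.trait_name == "projected_root_surface"]
        assert all(b > a for a, b in zip(areas, areas[1:]))

    def test_treated_final_primary_length_closed_form(self):
        """growth factor g from day t0 of n days: final primary length is
        L0 + v*(t0-1) + v*g*(n-t0+1), by integrating the rate schedule."""
        model = rt.PlantModel()
        _, records = rt.simulate_timecourse(model, n_timepoints=18,
                                            treatment_start=5,
                                            growth_factor=0.5, rng_seed=3)
        final = [r.value for r in records
                 if r.trait_name == "primary_root_length" and r.timepoint == 18]
        expected = (model.initial_length
                    + model.primary_elong_rate * 4
                    + model.primary_elong_rate * 0.5 * 14)
        assert final[0] == pytest.approx(expected, abs=1e-9)

    def test_masks_nested_over_time(self):
        model = dataclasses.replace(rt.PlantModel(), primary_length=8.0)
        scenes, _ = rt.simulate_timecourse(model, n_timepoints=6, rng_seed=2,
                                           render=True,
                                           render_kwargs={"noise_sd": 0})
        for a, b in zip(scenes, scenes[1:]):
            assert not (a.truth_mask.pixels & ~b.truth_mask.pixels).any()

    def test_rejects_bad_arguments(self):
        with pytest.raises(ValueError):
            rt.simulate_timecourse(rt.PlantModel(), n_timepoints=1)
        with pytest.raises(ValueError):
            rt.simulate_timecourse(rt.PlantModel(), growth_factor=0.0)


def test_cohort_models_vary_but_reproduce():
    a = rt.cohort_models(10, 3)
    b = rt.cohort_models(10, 3)
    assert a == b
    lengths = {m.primary_length for m in a}
    assert len(lengths) > 5
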