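from dataclasses import replace

import numpy as np
import pytest

import vitreoct as vo
from oracles import rasterize_axis_aligned
from vitreoct.exceptions import SceneError
from vitreoct.synthetic import (
    CLASS_BOUNDS_UM2,
    GroupDesign,
    OpacityPopulation,
    OpacitySpec,
    generate_cohort,
    generate_series,
    rasterize_ellipse,
)

META = {"animal_id": "a0", "side": "RE", "group": "control", "sex": "female", "week": 0}


class TestRenderBScan:
    def test_noiseless_background_levels(self, clean_scene, clean_calibration):
        bscan, truth = vo.render_bscan(clean_scene, clean_calibration, seed=0)
        ilm = clean_scene.ilm_row[0]
        assert np.all(bscan.pixels[:ilm] == round(clean_scene.vitreous_level))
        assert truth.labels.max() == 0

    def test_ellipse_matches_brute_force_rasterization(self, clean_scene, clean_calibration):
        spec = OpacitySpec(center=(60.0, 80.0), semi_major_px=8, semi_minor_px=4, intensity=200)
        scene = replace(clean_scene, opacities=(spec,))
        _, truth = vo.render_bscan(scene, clean_calibration, seed=0)
        oracle = rasterize_axis_aligned(60.0, 80.0, 8, 4, clean_scene.shape)
        assert np.array_equal(truth.labels > 0, oracle)
        assert truth.opacities[0].n_pixels == oracle.sum()

    def test_rasterized_area_near_continuous_area(self, clean_scene):
        a, b = 9.0, 5.0
        mask = rasterize_ellipse(
            OpacitySpec(center=(100, 90), semi_major_px=a, semi_minor_px=b), clean_scene.shape
        )
        perimeter = np.pi * (3 * (a + b) - np.sqrt((3 * a + b) * (a + 3 * b)))
        assert abs(mask.sum() - np.pi * a * b) <= perimeter

    def test_seed_determinism(self, speckle_scene, speckle_calibration):
        b1, _ = vo.render_bscan(speckle_scene, speckle_calibration, seed=7)
        b2, _ = vo.render_bscan(speckle_scene, speckle_calibration, seed=7)
        b3, _ = vo.render_bscan(speckle_scene, speckle_calibration, seed=8)
        assert np.array_equal(b1.pixels, b2.pixels)
        assert not np.array_equal(b1.pixels, b3.pixels)

    def test_opacity_below_ilm_rejected(self, clean_scene, clean_calibration):
        ilm = clean_scene.ilm_row[0]
        spec = OpacitySpec(center=(50, ilm - 1), semi_major_px=4, semi_minor_px=3)
        with pytest.raises(SceneError, match="vitreous"):
            vo.render_bscan(replace(clean_scene, opacities=(spec,)), clean_calibration)

    def test_overlapping_opacities_rejected(self, clean_scene, clean_calibration):
        s1 = OpacitySpec(center=(50, 60), semi_major_px=5, semi_minor_px=4)
        s2 = OpacitySpec(center=(53, 60), semi_major_px=5, semi_minor_px=4)
        with pytest.raises(SceneError, match="overlap"):
            vo.render_bscan(replace(clean_scene, opacities=(s1, s2)), clean_calibration)

    def test_layer_ordering_validated(self):
        with pytest.raises(SceneError):
            vo.SceneSpec(shape=(100, 50), ilm_row=80, rpe_inner=70, rpe_outer=90)


class TestSampling:
    def test_masks_disjoint_and_above_ilm(self, speckle_scene, speckle_calibration, rng):
        pop = OpacityPopulation(count=("fixed", 25))
        specs = vo.synthetic.sample_opacities(rng, speckle_scene, pop, speckle_calibration)
        scene = replace(speckle_scene, opacities=specs)
        _, truth = vo.render_bscan(scene, speckle_calibration, seed=0)
        # disjoint by construction of the label mask; all strictly above ILM
        rows, cols = np.nonzero(truth.labels)
        assert np.all(rows < speckle_scene.ilm_row[cols])
        assert len(truth.opacities) == 25

    def test_class_mix_probabilities_validated(self):
        with pytest.raises(SceneError):
            OpacityPopulation(class_mix={"isolated": 0.5, "activated": 0.4})

    def test_class_bounds_cover_partition(self):
        edges = sorted(v for lo, hi in CLASS_BOUNDS_UM2.values() for v in (lo, hi))
        assert edges[1:-1:2] == edges[2:-1:2]  # intervals chain without gaps


class TestGenerateSeries:
    def test_degenerate_zero_counts(self, speckle_scene, speckle_calibration):
        pop = OpacityPopulation(count=("fixed", 0))
        series, truths = generate_series(
            speckle_scene, pop, META, speckle_calibration, n_bscans=8, seed=0
        )
        assert len(series) == 8
        assert all(len(t.opacities) == 0 for t in truths)

    def test_degenerate_fixed_counts(self, speckle_scene, speckle_calibration):
        pop = OpacityPopulation(count=("fixed", 5))
        _, truths = generate_series(
            speckle_scene, pop, META, speckle_calibration, n_bscans=6, seed=1
        )
        assert all(len(t.opacities) == 5 for t in truths)

    def test_poisson_counts_law_of_large_numbers(self):
        scene = vo.make_scene((124, 384), speckle_shape=10.0)
        cal = vo.default_calibration(384, 124)
        pop = OpacityPopulation(count=("poisson", 70), pixel_range=(3, 12))
        _, truths = generate_series(scene, pop, META, cal, n_bscans=61, seed=3)
        counts = np.array([len(t.opacities) for t in truths])
        se = np.sqrt(70 / 61)
        assert abs(counts.mean() - 70) <= 3 * se

    def test_series_determinism(self, speckle_scene, speckle_calibration):
        pop = OpacityPopulation(count=("uniform", 2, 6))
        s1, t1 = generate_series(speckle_scene, pop, META, speckle_calibration, 4, seed=9)
        s2, t2 = generate_series(speckle_scene, pop, META, speckle_calibration, 4, seed=9)
        for b1, b2 in zip(s1.bscans, s2.bscans):
            assert np.array_equal(b1.pixels, b2.pixels)
        for a, b in zip(t1, t2):
            assert np.array_equal(a.labels, b.labels)


def _tiny_design(master_seed=0, eyes=1):
    groups = (
        GroupDesign("control", ("uniform", 2, 4), {"activated": 1.0}, (0,)),
        GroupDesign("MEPI", ("poisson", 8), {"activated": 1.0}, (0,)),
    )
    return vo.CohortDesign(
        groups=groups, eyes_per_group=eyes, shape=(96, 256), n_bscans=2,
        master_seed=master_seed,
    )


class TestCohort:
    def test_single_cell_design_yields_one_series(self):
        design = vo.CohortDesign(
            groups=(GroupDesign("control", ("fixed", 1), {"activated": 1.0}, (0,)),),
            eyes_per_group=1, shape=(96, 256), n_bscans=1,
        )
        cohort = generate_cohort(design)
        assert len(cohort) == 1

    def test_group_counts_differ_as_planted(self):
        cohort = generate_cohort(_tiny_design(eyes=3))
        means = {}
        for series, truths in cohort:
            counts = [len(t.opacities) for t in truths]
            means.setdefault(series.group, []).extend(counts)
        assert np.mean(means["MEPI"]) > np.mean(means["control"])

    def test_master_seed_reproducibility(self):
        c1 = generate_cohort(_tiny_design(master_seed=4))
        c2 = generate_cohort(_tiny_design(master_seed=4))
        for (s1, t1), (s2, t2) in zip(c1, c2):
            assert s1.animal_id == s2.animal_id and s1.week == s2.week
            for b1, b2 in zip(s1.bscans, s2.bscans):
                assert np.array_equal(b1.pixels, b2.pixels)

    def test_control_weeks_constrained(self):
        with pytest.raises(SceneError):
            GroupDesign("control", ("fixed", 1), {"activated": 1.0}, (0, 2, 4))

    def test_default_design_regimes(self):
        design = vo.default_cohort_design(eyes_per_group=2)
        by_name = {g.name: g for g in design.groups}
        assert by_name["control"].count == ("uniform", 10, 20)
        assert by_name["MEPI"].count == ("poisson", 70)
        glaucoma_activated = by_name["MEPI"].class_mix["activated"]
        assert 0.40 <= glaucoma_activated <= 0.50
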