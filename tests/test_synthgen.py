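"""Generator contracts: protocol arithmetic, determinism, phenotype direction."""
from __future__ import annotations

import numpy as np
import pytest

import organotrace as ot
from organotrace.frames import DomainError
from organotrace.morphometrics import measure_objects
from organotrace.segmentation import labelmap_from_masks
from organotrace.synthgen import PlacementError, SceneTruth, round_significant


class TestProtocolArithmetic:
    @pytest.mark.parametrize(
        "stock, factor, steps, sig, expected_last",
        [
            (10_000, 3, 1, 3, 3330.0),
            (10_000, 3, 5, 3, 41.2),
            (10_000, 3, 8, 2, 1.5),
            (10_000, 3, 9, 1, 0.5),
        ],
    )
    def test_dss_dilution_ladder(self, stock, factor, steps, sig, expected_last):
        series = ot.dose_series(stock, factor, steps, sig)
        assert len(series) == steps + 1
        assert series[0] == stock
        assert series[-1] == expected_last

    def test_decade_dilution(self):
        assert ot.dose_series(100, 10, 2, 3) == [100, 10, 1]

    @pytest.mark.parametrize("stock, factor", [(0, 3), (-5, 3), (100, 1), (100, 0.5)])
    def test_dose_series_domain_errors(self, stock, factor):
        with pytest.raises(DomainError):
            ot.dose_series(stock, factor, 3)

    def test_round_significant(self):
        assert round_significant(3333.33, 3) == 3330.0
        assert round_significant(0.508, 1) == 0.5
        assert round_significant(0.0, 4) == 0.0

    @pytest.mark.parametrize(
        "density, volume, expected",
        [(1e6, 50, 50_000), (0, 50, 0), (2e6, 25, 50_000)],
    )
    def test_cells_per_dome(self, density, volume, expected):
        assert ot.cells_per_dome(density, volume) == expected

    def test_cells_per_dome_rejects_negative(self):
        with pytest.raises(DomainError):
            ot.cells_per_dome(-1, 50)


class TestSceneGeneration:
    def test_seed_determinism_bit_identical(self):
        a = ot.generate_scene(3, ot.HEALTHY, seed=7)
        b = ot.generate_scene(3, ot.HEALTHY, seed=7)
        np.testing.assert_array_equal(a.truth_grid, b.truth_grid)
        np.testing.assert_array_equal(a.debris_grid, b.debris_grid)
        assert a.haze_multiplier == b.haze_multiplier
        for ma, mb in zip(a.object_masks, b.object_masks):
            np.testing.assert_array_equal(ma, mb)

    def test_healthy_has_lobes_injured_has_none(self, small_geometry):
        healthy = ot.generate_scene(1, ot.HEALTHY, small_geometry, seed=3)
        assert len(healthy.shapes[0].lobes) >= 2
        effect = ot.ConditionEffect(lobe_suppression=1.0)
        injured = ot.generate_scene(1, ot.INJURED, small_geometry, effect, seed=3)
        assert len(injured.shapes[0].lobes) == 0

    def test_masks_disjoint_and_truth_supported(self, small_geometry):
        scene = ot.generate_scene(1, ot.HEALTHY, small_geometry, seed=5)
        union = np.zeros(scene.truth_grid.shape, dtype=int)
        for mask in scene.object_masks:
            assert mask.sum() >= 1
            union += mask.astype(int)
        assert union.max() <= 1  # pairwise disjoint
        assert np.all(scene.truth_grid[union == 0] == 0)

    def test_multi_organoid_scene_disjoint(self):
        scene = ot.generate_scene(3, ot.HEALTHY, seed=11)
        union = sum(m.astype(int) for m in scene.object_masks)
        assert union.max() <= 1

    def test_body_diameters_within_range(self):
        for seed in range(1, 8):
            scene = ot.generate_scene(1, ot.INJURED, seed=seed)
            assert 400.0 <= 2 * scene.shapes[0].body_radius <= 500.0

    def test_placement_error_names_attempt_limit(self):
        # 220 px at 2 µm/px = 440 µm: cannot hold a 400-500 µm organoid
        tiny = ot.GeometryPriors(canvas_shape=(220, 220), max_attempts=50)
        with pytest.raises(PlacementError):
            ot.generate_scene(1, ot.HEALTHY, tiny, seed=1)
        crowded = ot.GeometryPriors(canvas_shape=(600, 600), max_attempts=25)
        with pytest.raises(PlacementError, match="25"):
            ot.generate_scene(4, ot.HEALTHY, crowded, seed=1)

    def test_rejects_zero_organoids(self):
        with pytest.raises(DomainError):
            ot.generate_scene(0, ot.HEALTHY, seed=1)


class TestRendering:
    def test_identity_optics_returns_truth(self, small_geometry, quiet_optics):
        geometry = ot.GeometryPriors(canvas_shape=(512, 512),
                                     debris_amplitude=(0.0, 0.0))
        scene = ot.generate_scene(1, ot.HEALTHY, geometry, seed=2)
        optics = ot.OpticsModel(infocus_sigma=0.0, haze_sigma=100.0, haze_fraction=0.0,
                                baseline=0.0, photon_gain=0.0, read_noise_sd=0.0,
                                signal_counts=1.0)
        wf = ot.render_widefield(scene, optics, seed=0)
        np.testing.assert_allclose(wf.data, scene.truth_grid, atol=1e-12)

    def test_noiseless_rendering_conserves_mass(self):
        # interior-placed truth, >= 3 haze sigmas from every border
        grid = np.zeros((512, 512))
        yy, xx = np.mgrid[:512, :512]
        mask = (yy - 256) ** 2 + (xx - 256) ** 2 <= 50**2
        grid[mask] = 1.0
        scene = SceneTruth(truth_grid=grid, object_masks=[mask],
                           conditions=[ot.HEALTHY], shapes=[], seed=0, pixel_size=2.0)
        optics = ot.OpticsModel(baseline=7.0, photon_gain=0.0, read_noise_sd=0.0,
                                signal_counts=1.0, haze_fraction=0.4)
        wf = ot.render_widefield(scene, optics, seed=0)
        total = float(np.sum(wf.data - optics.baseline))
        assert abs(total - grid.sum()) <= 1e-3 * grid.sum()

    def test_noisy_render_seed_determinism(self, small_geometry):
        scene = ot.generate_scene(1, ot.INJURED, small_geometry, seed=9)
        a = ot.render_widefield(scene, seed=9)
        b = ot.render_widefield(scene, seed=9)
        np.testing.assert_array_equal(a.data, b.data)

    def test_pixel_size_mismatch_raises(self, small_geometry):
        scene = ot.generate_scene(1, ot.HEALTHY, small_geometry, seed=1)
        with pytest.raises(ot.CalibrationError):
            ot.render_widefield(scene, ot.OpticsModel(pixel_size=1.0), seed=1)


class TestCohortDirection:
    def test_injury_collapses_shape_at_cohort_level(self):
        """Injured cohorts: shorter perimeter, higher circularity, similar area."""
        means = {}
        for condition, base in ((ot.HEALTHY, 1), (ot.INJURED, 101)):
            records = []
            for seed in range(base, base + 20):
                scene = ot.generate_scene(1, condition, seed=seed)
                labels = labelmap_from_masks(scene.object_masks, scene.pixel_size)
                records.append(measure_objects(labels)[0])
            means[condition] = (
                np.mean([r.area for r in records]),
                np.mean([r.perimeter for r in records]),
                np.mean([r.circularity for r in records]),
            )
        h, i = means[ot.HEALTHY], means[ot.INJURED]
        assert h[1] > i[1], "healthy budding outlines must have longer perimeters"
        assert i[2] > h[2], "collapse must raise circularity"
        assert abs(h[0] - i[0]) <= 0.20 * h[0], "areas must remain similar"
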