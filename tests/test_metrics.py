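"""Per-cell metrics: analytic limits, invariances, composition."""

import math

import numpy as np
import pytest

import synquant as sq
from synquant.metrics import MetricError, ZProfile

from conftest import NOISELESS, delta_stack, disk_mask, uniform_stack


class TestAntigenRemaining:
    @staticmethod
    def _bead_only_stack(value=1.0):
        bead = disk_mask((40, 40), 20, 20, 10)
        vox = np.zeros((1, 4, 40, 40))
        vox[0, :, bead] = value
        stack = sq.ImageStack(vox, 0.1, 0.2, {"OVA": 0})
        return stack, bead

    def test_signal_equal_to_reference_zero_extracted(self):
        stack, bead = self._bead_only_stack()
        ref = sq.bead_total_intensity(stack, bead)
        res = sq.antigen_remaining(stack, bead, ref)
        assert res.percent_extracted == pytest.approx(0.0, abs=1e-9)
        assert res.fraction_remaining == pytest.approx(1.0, abs=1e-12)
        assert not res.qc

    def test_half_retained_scene_measures_fifty_percent(self):
        base = dict(seed=21, **NOISELESS)
        full, truth = sq.make_bead_scene(
            sq.SceneConfig(ova_retained_fraction=1.0, **base)
        )
        half, _ = sq.make_bead_scene(sq.SceneConfig(ova_retained_fraction=0.5, **base))
        disk, _ = sq.synapse_disk(full, truth.true_bead_center, 1.5)
        ref = float(full.projection("OVA")[disk].sum())
        res = sq.antigen_remaining(half, disk, ref)
        assert res.percent_extracted == pytest.approx(50.0, abs=1.0)

    def test_brighter_than_reference_clipped_with_flag(self):
        stack, bead = self._bead_only_stack()
        ref = 0.5 * sq.bead_total_intensity(stack, bead)
        res = sq.antigen_remaining(stack, bead, ref)
        assert res.percent_extracted == 0.0
        assert "negative_extraction" in res.qc

    def test_nonpositive_reference_rejected(self):
        stack = uniform_stack(roles=("OVA",))
        with pytest.raises(MetricError):
            sq.antigen_remaining(stack, disk_mask((40, 40), 20, 20, 5), 0.0)


class TestRecruitmentFraction:
    def test_all_signal_inside_disk_is_one(self):
        stack = delta_stack(points=[(20, 20, 5.0)])
        synapse = disk_mask((41, 41), 20, 20, 5)
        cell = disk_mask((41, 41), 20, 20, 15)
        assert sq.recruitment_fraction(stack, "LAMP", synapse, cell) == 1.0

    def test_no_signal_inside_disk_is_zero(self):
        stack = delta_stack(points=[(10, 10, 3.0)])
        synapse = disk_mask((41, 41), 30, 30, 4)
        cell = disk_mask((41, 41), 20, 20, 18)
        assert sq.recruitment_fraction(stack, "LAMP", synapse, cell) == 0.0

    def test_uniform_intensity_gives_area_ratio(self):
        stack = uniform_stack()
        synapse = disk_mask((40, 40), 30, 30, 6)
        cell = disk_mask((40, 40), 18, 18, 12)
        frac = sq.recruitment_fraction(stack, "LAMP", synapse, cell)
        expected = synapse.sum() / (synapse | cell).sum()
        assert frac == pytest.approx(expected, abs=1e-12)

    def test_empty_region_rejected(self):
        stack = uniform_stack()
        with pytest.raises(MetricError):
            sq.recruitment_fraction(
                stack, "LAMP", np.zeros((40, 40), bool), disk_mask((40, 40), 20, 20, 9)
            )


class TestBeadFoldChange:
    @pytest.mark.parametrize("scale,expected", [(1.0, 1.0), (2.0, 2.0), (0.0, 0.0)])
    def test_scaling_against_population_mean(self, scale, expected):
        stack = uniform_stack(value=scale if scale else 1.0, roles=("GEFH1",))
        bead = disk_mask((40, 40), 20, 20, 8)
        ref = float(uniform_stack(roles=("GEFH1",)).projection("GEFH1")[bead].sum())
        if scale == 0.0:
            stack = uniform_stack(value=0.0, roles=("GEFH1",))
        assert sq.bead_fold_change(stack, "GEFH1", bead, ref) == pytest.approx(
            expected, abs=1e-12
        )

    def test_nonpositive_normalizer_rejected(self):
        stack = uniform_stack(roles=("GEFH1",))
        with pytest.raises(MetricError):
            sq.bead_fold_change(stack, "GEFH1", disk_mask((40, 40), 20, 20, 8), 0.0)


class TestPolarityIndex:
    """CL projected on CB over |CB|: 1 polarized, -1 anti-polarized, 0 neutral."""

    def test_com_at_bead_center_is_one(self):
        stack = delta_stack(points=[(20, 30, 1.0)])
        geom = sq.polarity_index(
            stack, "LAMP", None, (2.0, 3.0), cell_center_um=(2.0, 2.0)
        )
        assert geom.index == pytest.approx(1.0, abs=1e-9)
        assert geom.projection_um == pytest.approx(geom.cb_norm_um, abs=1e-9)

    def test_com_at_mirror_point_is_minus_one(self):
        stack = delta_stack(points=[(20, 10, 1.0)])
        geom = sq.polarity_index(
            stack, "LAMP", None, (2.0, 3.0), cell_center_um=(2.0, 2.0)
        )
        assert geom.index == pytest.approx(-1.0, abs=1e-9)

    def test_com_at_cell_center_is_zero(self):
        stack = delta_stack(points=[(20, 20, 1.0)])
        geom = sq.polarity_index(
            stack, "LAMP", None, (2.0, 3.0), cell_center_um=(2.0, 2.0)
        )
        assert geom.index == pytest.approx(0.0, abs=1e-9)

    def test_orthogonal_offset_is_zero(self):
        stack = delta_stack(points=[(30, 20, 1.0)])
        geom = sq.polarity_index(
            stack, "LAMP", None, (2.0, 3.0), cell_center_um=(2.0, 2.0)
        )
        assert geom.index == pytest.approx(0.0, abs=1e-9)

    def test_bead_at_cell_center_rejected(self):
        stack = delta_stack(points=[(20, 20, 1.0)])
        with pytest.raises(MetricError):
            sq.polarity_index(stack, "LAMP", None, (2.0, 2.0), cell_center_um=(2.0, 2.0))

    def test_zero_intensity_rejected(self):
        stack = delta_stack(points=[])
        with pytest.raises(MetricError):
            sq.polarity_index(stack, "LAMP", None, (2.0, 3.0), cell_center_um=(2.0, 2.0))

    def test_bounded_when_com_within_bead_distance(self, bead_scene):
        stack, truth = bead_scene
        mask = disk_mask(stack.shape_zyx[1:], stack.shape_zyx[1] // 2, stack.shape_zyx[2] // 2, 50)
        geom = sq.polarity_index(stack, "LAMP", mask, truth.true_bead_center)
        assert -1 - 1e-9 <= geom.index <= 1 + 1e-9


class TestCentralEnrichment:
    def test_uniform_intensity_is_zero(self):
        stack = uniform_stack()
        cell = disk_mask((40, 40), 20, 20, 15)
        central = disk_mask((40, 40), 20, 20, 8)
        val = sq.central_enrichment(stack, "LAMP", cell, central)
        assert val == pytest.approx(0.0, abs=1e-12)

    def test_all_signal_in_third_area_center_is_two(self):
        # central region holding exactly 1/3 of the footprint pixels
        cell = np.zeros((30, 30), bool)
        cell[0, :30] = True
        central = np.zeros((30, 30), bool)
        central[0, :10] = True
        img = np.zeros((1, 1, 30, 30))
        img[0, 0, 0, :10] = 7.0
        stack = sq.ImageStack(img, 0.1, 0.2, {"LAMP": 0})
        val = sq.central_enrichment(stack, "LAMP", cell, central)
        assert val == pytest.approx(2.0, abs=1e-12)

    def test_empty_center_is_minus_one(self):
        stack = delta_stack(points=[(2, 35, 1.0)])
        cell = np.ones((41, 41), bool)
        central = disk_mask((41, 41), 20, 20, 10)
        val = sq.central_enrichment(stack, "LAMP", cell, central)
        assert val == pytest.approx(-1.0, abs=1e-12)

    def test_empty_central_region_rejected(self):
        stack = uniform_stack()
        with pytest.raises(MetricError):
            sq.central_enrichment(
                stack, "LAMP", disk_mask((40, 40), 20, 20, 10), np.zeros((40, 40), bool)
            )


class TestZProfile:
    def test_uniform_volume_constant_profile(self):
        stack = uniform_stack(value=3.0)
        prof = sq.z_profile(stack, "LAMP", disk_mask((40, 40), 20, 20, 10))
        assert np.allclose(prof.mfi, 3.0)
        assert np.allclose(prof.z_um, np.arange(4) * 0.2)

    def test_noiseless_axial_bias_monotone(self, spreading_scene):
        stack, _ = spreading_scene
        mask = sq.segment_cell(stack)
        prof = sq.z_profile(stack, "LAMP", mask)
        assert np.all(np.diff(prof.mfi) <= 1e-12)

    def test_single_slice_rejected(self):
        stack = uniform_stack(shape=(1, 20, 20))
        with pytest.raises(MetricError):
            sq.z_profile(stack, "LAMP", disk_mask((20, 20), 10, 10, 5))


class TestBottomTopRatio:
    @staticmethod
    def _profile(mfi):
        mfi = np.asarray(mfi, dtype=float)
        idx = np.arange(len(mfi))
        return ZProfile(slice_index=idx, z_um=idx * 0.2, mfi=mfi)

    def test_constant_profile_is_one(self):
        res = sq.bottom_top_ratio(self._profile([2, 2, 2, 2]))
        assert res.ratio == pytest.approx(1.0, abs=1e-12)

    def test_empty_top_half_gives_inf_sentinel(self):
        res = sq.bottom_top_ratio(self._profile([2, 0]))
        assert math.isinf(res.ratio)
        assert "zero_upper_half" in res.qc

    def test_middle_slice_split_equally(self):
        # [3, 1, 1]: middle slice contributes 0.5 to each half -> 3.5/1.5
        res = sq.bottom_top_ratio(self._profile([3, 1, 1]))
        assert res.ratio == pytest.approx(7 / 3, abs=1e-12)

    def test_all_zero_profile_rejected(self):
        with pytest.raises(MetricError):
            sq.bottom_top_ratio(self._profile([0, 0, 0]))


class TestMandersOverlap:
    def test_identical_channels_give_one(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0.5, 2.0, size=(1, 30, 30))
        vox = np.stack([img, img])
        stack = sq.ImageStack(vox, 0.1, 0.2, {"LAMP": 0, "LC3": 1})
        assert sq.manders_overlap(stack, threshold_method="zero") == pytest.approx(1.0)

    def test_disjoint_puncta_give_zero(self):
        a = np.zeros((1, 30, 30))
        b = np.zeros((1, 30, 30))
        a[0, 5, 5] = 1.0
        b[0, 25, 25] = 1.0
        stack = sq.ImageStack(np.stack([a, b]), 0.1, 0.2, {"LAMP": 0, "LC3": 1})
        assert sq.manders_overlap(stack, threshold_method="zero") == 0.0

    def test_overlap_fraction_sweep_monotone(self):
        """Programmed LC3/LAMP co-placement drives M1 up (noiseless scenes)."""
        means = []
        for frac in (0.0, 0.5, 1.0):
            vals = [
                sq.manders_overlap(
                    sq.make_bead_scene(
                        sq.SceneConfig(lc3_overlap_fraction=frac, seed=s, **NOISELESS)
                    )[0]
                )
                for s in range(3)
            ]
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]

    def test_zero_a_intensity_rejected(self):
        vox = np.zeros((2, 1, 10, 10))
        vox[1] = 1.0
        stack = sq.ImageStack(vox, 0.1, 0.2, {"LAMP": 0, "LC3": 1})
        with pytest.raises(MetricError):
            sq.manders_overlap(stack, threshold_method="zero")


class TestInvariances:
    """Spec-level invariances: intensity scale (exact) and rigid motion."""

    def test_intensity_scale_invariance_exact(self, bead_scene):
        stack, truth = bead_scene
        # a power-of-two factor keeps the rescaling bit-exact in float32
        scaled = sq.ImageStack(
            stack.voxels * 4.0,
            stack.pixel_size_um,
            stack.slice_step_um,
            stack.channel_roles,
        )
        mask = disk_mask(stack.shape_zyx[1:], stack.shape_zyx[1] // 2, stack.shape_zyx[2] // 2, 50)
        synapse, _ = sq.synapse_disk(stack, truth.true_bead_center, 1.5)
        assert sq.polarity_index(
            scaled, "LAMP", mask, truth.true_bead_center
        ).index == sq.polarity_index(stack, "LAMP", mask, truth.true_bead_center).index
        assert sq.recruitment_fraction(
            scaled, "LAMP", synapse, mask
        ) == sq.recruitment_fraction(stack, "LAMP", synapse, mask)
        central = sq.central_ellipse(mask)
        assert sq.central_enrichment(
            scaled, "LAMP", mask, central
        ) == sq.central_enrichment(stack, "LAMP", mask, central)

    def test_whole_pixel_translation_invariance(self, bead_scene):
        """Shifting the scene by whole pixels leaves the metrics unchanged."""
        stack, truth = bead_scene
        dy, dx = 4, -6
        shifted = sq.ImageStack(
            np.roll(stack.voxels, (dy, dx), axis=(2, 3)),
            stack.pixel_size_um,
            stack.slice_step_um,
            stack.channel_roles,
        )
        mask = disk_mask(stack.shape_zyx[1:], stack.shape_zyx[1] // 2, stack.shape_zyx[2] // 2, 52)
        mask_s = np.roll(mask, (dy, dx), axis=(0, 1))
        px = stack.pixel_size_um
        bead = truth.true_bead_center
        bead_s = (bead[0] + dy * px, bead[1] + dx * px)
        p0 = sq.polarity_index(stack, "LAMP", mask, bead).index
        p1 = sq.polarity_index(shifted, "LAMP", mask_s, bead_s).index
        assert p1 == pytest.approx(p0, abs=1e-9)
        m0 = sq.manders_overlap(stack, cell_mask=mask)
        m1 = sq.manders_overlap(shifted, cell_mask=mask_s)
        assert m1 == pytest.approx(m0, abs=1e-9)


class TestQuantifyCell:
    def test_noiseless_scene_all_metrics_finite(self, bead_scene):
        stack, truth = bead_scene
        regions = sq.build_regions(stack)
        disk = regions.synapse_mask
        ref = float(stack.projection("OVA")[disk].sum())
        rec = sq.quantify_cell(
            stack, regions, sq.References(t0_bead_ova=ref), cell_id="c1"
        )
        for name in (
            "percent_antigen_extracted",
            "recruitment_fraction",
            "polarity_index",
            "central_enrichment",
            "bottom_top_ratio",
            "manders_m1",
        ):
            assert np.isfinite(getattr(rec, name)), name
        assert "Error" not in rec.qc_flags

    def test_missing_channel_yields_nan_with_flag(self, bead_scene):
        stack, _ = bead_scene
        partial = sq.ImageStack(
            stack.voxels[:2],
            stack.pixel_size_um,
            stack.slice_step_um,
            {"OVA": 0, "LAMP": 1},
        )
        cell = disk_mask(stack.shape_zyx[1:], stack.shape_zyx[1] // 2, stack.shape_zyx[2] // 2, 50)
        regions = sq.build_regions(partial, cell_mask=cell)
        rec = sq.quantify_cell(partial, regions)
        assert math.isnan(rec.manders_m1)
        assert "manders" in rec.qc_flags

    def test_record_round_trips_via_csv(self, tmp_path, bead_scene):
        stack, _ = bead_scene
        regions = sq.build_regions(stack)
        rec = sq.quantify_cell(stack, regions, cell_id="c1", condition="ctrl")
        frame = sq.records_to_frame([rec])
        path = tmp_path / "records.csv"
        frame.to_csv(path, index=False)
        import pandas as pd

        back = pd.read_csv(path)
        assert back.loc[0, "cell_id"] == "c1"
        assert back.loc[0, "polarity_index"] == pytest.approx(
            rec.polarity_index, rel=1e-12
        )
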