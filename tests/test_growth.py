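"""Jacobian growth maps, global normalisation and regional summaries."""

import numpy as np
import pytest

from morphogrowth.core import DisplacementField, LabelVolume
from morphogrowth.errors import GridError
from morphogrowth.growth import (JacobianMap, absolute_growth, global_growth,
                                 global_growth_from_jacobian, jacobian_determinant,
                                 normalize_jacobian, region_growth_summary)


def _field(shape, fn):
    axes = [np.arange(s, dtype=float) for s in shape]
    pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    return DisplacementField(fn(pts))


class TestJacobian:
    def test_zero_field_gives_unity_exactly(self):
        j = jacobian_determinant(_field((8, 8, 8), lambda p: np.zeros_like(p)))
        np.testing.assert_array_equal(j.values, 1.0)

    def test_uniform_scaling_closed_form(self):
        # u(x) = 0.1 x  =>  J = 1.1^3 = 1.331 in the interior
        j = jacobian_determinant(_field((32, 32, 32), lambda p: 0.1 * p))
        interior = j.values[1:-1, 1:-1, 1:-1]
        np.testing.assert_allclose(interior, 1.331, atol=1e-6)

    def test_phantom_truth_matches_fine_grid_oracle(self):
        # numerical differentiation of the analytic field at 1 mm agrees
        # with a half-spacing oracle of the same physical field
        from morphogrowth.fieldops import jacobian_det_array, sample_vectors
        from morphogrowth.synthetic import PhantomSpec, generate_phantom

        s = generate_phantom(PhantomSpec(grid_shape=(32, 32, 32), n_weeks=2, seed=2))
        fld = s.true_fields[0]
        j = jacobian_det_array(fld.vectors, fld.spacing)

        fine_sp = fld.spacing / 2.0
        axes = [fld.origin[d] + fine_sp[d] * np.arange(2 * fld.shape[d] - 1) for d in range(3)]
        pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
        fine = sample_vectors(fld.vectors, fld.spacing, fld.origin, pts)
        j_fine = jacobian_det_array(fine, fine_sp)[::2, ::2, ::2]
        interior = (slice(4, -4),) * 3
        rel = np.abs(j[interior] - j_fine[interior]) / j_fine[interior]
        assert np.median(rel) < 0.01

    def test_degenerate_grid_rejected(self):
        with pytest.raises(GridError):
            jacobian_determinant(DisplacementField(np.zeros((2, 8, 8, 3))))

    def test_agrees_with_simpleitk_oracle(self, rng):
        # independent implementation check on an anisotropic random field
        import SimpleITK as sitk
        from scipy.ndimage import gaussian_filter

        v = np.stack([gaussian_filter(rng.normal(0, 1.5, (14, 16, 18)), 2.0)
                      for _ in range(3)], -1)
        spacing = np.array([1.0, 1.2, 0.8])
        mine = jacobian_determinant(DisplacementField(v, spacing)).values
        img = sitk.GetImageFromArray(np.ascontiguousarray(v.transpose(2, 1, 0, 3)),
                                     isVector=True)
        img.SetSpacing(tuple(spacing))
        ref = sitk.GetArrayFromImage(
            sitk.DisplacementFieldJacobianDeterminant(img)).transpose(2, 1, 0)
        sl = (slice(1, -1),) * 3  # oracle handles the boundary differently
        np.testing.assert_allclose(mine[sl], ref[sl], atol=1e-12)


class TestGlobalGrowth:
    def _labels(self, mask):
        return LabelVolume(mask.astype(np.int32), {"object": 1})

    def test_identical_masks(self):
        m = np.zeros((10, 10, 10), dtype=bool)
        m[2:8, 2:8, 2:8] = True
        assert global_growth(self._labels(m), self._labels(m)) == 1.0

    def test_constructed_count_ratio(self):
        src = np.zeros((12, 12, 12), dtype=bool)
        src[:, :, :] = False
        src.reshape(-1)[:400] = True
        tgt = np.zeros_like(src)
        tgt.reshape(-1)[:436] = True  # exactly 1.09x the voxel count
        assert global_growth(self._labels(src), self._labels(tgt)) == pytest.approx(1.09)

    def test_phantom_pair_recovers_global_growth(self, phantom48):
        r = global_growth(phantom48.labels[0], phantom48.labels[1])
        assert abs(r - 1.06) < 0.02 * 1.06

    def test_empty_mask_rejected(self):
        empty = self._labels(np.zeros((8, 8, 8), dtype=bool))
        full = self._labels(np.ones((8, 8, 8), dtype=bool))
        with pytest.raises(ValueError):
            global_growth(empty, full)

    def test_jacobian_geomean_agrees_with_mask_ratio(self, phantom48):
        # the two normalisation options agree on the phantom within 2 %
        j = jacobian_determinant(phantom48.true_fields[0])
        r_mask = global_growth(phantom48.labels[0], phantom48.labels[1])
        r_geo = global_growth_from_jacobian(j, phantom48.labels[0].mask())
        assert abs(r_geo - r_mask) / r_mask < 0.02


class TestNormalization:
    def test_unit_ratio_is_identity(self):
        j = JacobianMap(np.full((4, 4, 4), 1.09), np.ones(3), np.zeros(3))
        out = normalize_jacobian(j, 1.0)
        np.testing.assert_array_equal(out.values, j.values)

    def test_division_by_ratio(self):
        j = JacobianMap(np.full((4, 4, 4), 1.09), np.ones(3), np.zeros(3))
        out = normalize_jacobian(j, 1.09)
        np.testing.assert_allclose(out.values, 1.0)
        assert out.kind == "normalized" and out.global_ratio == 1.09

    def test_nonpositive_ratio_rejected(self):
        j = JacobianMap(np.ones((4, 4, 4)), np.ones(3), np.zeros(3))
        with pytest.raises(ValueError):
            normalize_jacobian(j, 0.0)


class TestAbsoluteGrowth:
    @pytest.mark.parametrize("j_norm, g, expected", [
        (0.95, 0.09, 3.55),   # the worked normalisation example
        (1.0, 0.0, 0.0),
        (1.1, 0.0, 10.0),     # map-scale reading: 1.1 is 10 % weekly expansion
    ])
    def test_worked_examples(self, j_norm, g, expected):
        assert absolute_growth(j_norm, g) == pytest.approx(expected, abs=1e-9)

    def test_back_composition(self):
        # normalised 0.95 under 9 % global growth is still absolute growth
        pct = absolute_growth(0.95, 0.09)
        assert round(pct, 1) in (3.5, 3.6)
        assert abs(pct - 3.5) <= 0.1


class TestRegionSummary:
    def _uniform(self, value=1.0):
        lab = np.zeros((8, 8, 8), dtype=np.int32)
        lab[1:4] = 1
        lab[5:7] = 2
        labels = LabelVolume(lab, {"a": 1, "b": 2})
        j = JacobianMap(np.full(lab.shape, value), np.ones(3), np.zeros(3))
        return j, labels

    def test_uniform_map_gives_unit_means(self):
        j, labels = self._uniform()
        out = region_growth_summary(j, labels)
        assert (out["mean_j"] == 1.0).all()

    def test_single_voxel_label(self):
        lab = np.zeros((8, 8, 8), dtype=np.int32)
        lab[3, 3, 3] = 1
        j_vals = np.ones(lab.shape)
        j_vals[3, 3, 3] = 1.25
        out = region_growth_summary(JacobianMap(j_vals, np.ones(3), np.zeros(3)),
                                    LabelVolume(lab, {"spot": 1}))
        assert out.loc[out["region"] == "spot", "mean_j"].item() == 1.25

    def test_absent_label_flagged_with_zero_volume(self):
        j, labels = self._uniform()
        labels.label_dict["ghost"] = 9
        out = region_growth_summary(j, labels)
        row = out[out["region"] == "ghost"].iloc[0]
        assert row["missing"] and row["volume_mm3"] == 0.0

    def test_phantom_ranking_puts_opercula_above_insula(self, phantom48):
        j = jacobian_determinant(phantom48.true_fields[0])
        out = region_growth_summary(j, phantom48.labels[0])
        order = list(out["region"])
        for op in ("frontal_operculum", "parietal_operculum", "temporal_operculum"):
            assert order.index(op) < order.index("insula")


class TestVolumeConservation:
    def test_integral_of_raw_j_matches_target_volume(self, phantom48):
        # change of variables: integral of J over the source mask equals the
        # target object volume
        j = jacobian_determinant(phantom48.true_fields[0])
        mask = phantom48.labels[0].mask()
        vox = phantom48.labels[0].voxel_volume
        integral = j.values[mask].sum() * vox
        target = phantom48.labels[1].mask().sum() * phantom48.labels[1].voxel_volume
        assert abs(integral - target) / target < 0.02

    def test_normalized_geometric_mean_is_unity(self, phantom48):
        j = jacobian_determinant(phantom48.true_fields[0])
        r = global_growth(phantom48.labels[0], phantom48.labels[1])
        jn = normalize_jacobian(j, r)
        mask = phantom48.labels[0].mask()
        geo = np.exp(np.mean(np.log(jn.values[mask])))
        assert abs(geo - 1.0) < 0.02
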