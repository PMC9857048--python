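import numpy as np
import pandas as pd
import pytest

from psmalesion import (
    PetVolume,
    PhantomSpec,
    SphereLesion,
    generate_phantom,
    isocontour_segment,
    liver_reference,
    quantify_lesions,
)
from psmalesion.exceptions import DegenerateSignalError, GeometryError
from psmalesion.uptake import read_seed_list, sphere_mask

from oracles import flood_fill_26


def _volume(values, spacing=(4.0, 4.0, 4.0)):
    return PetVolume(values=np.asarray(values, float), spacing=spacing)


class TestIsocontour:
    def test_isolated_maximum(self):
        values = np.full((9, 9, 9), 1.0)
        values[4, 4, 4] = 10.0
        res = isocontour_segment(_volume(values), (slice(None),) * 3, fraction=0.40)
        assert res.suv_max == 10.0
        assert res.suv_mean == 10.0
        assert res.n_voxels == 1
        assert res.mask[4, 4, 4]

    def test_uniform_sphere_on_zero_background(self):
        spec = PhantomSpec(
            shape=(24, 24, 24), spacing=(4.0,) * 3, background_suv=0.0,
            lesions=(SphereLesion((44.0, 44.0, 44.0), 14.0, 8.0),),
        )
        vol, masks, _ = generate_phantom(spec, seed=0)
        res = isocontour_segment(vol, (slice(None),) * 3)
        assert res.suv_max == 8.0
        assert res.suv_mean == 8.0
        np.testing.assert_array_equal(res.mask, masks[0])

    def test_matches_flood_fill_oracle_on_blurred_two_sphere_phantom(self):
        """Component membership equals an independent BFS flood fill, and the
        mask is confined to the hotter sphere when the gap falls below 40%."""
        spec = PhantomSpec(
            shape=(40, 20, 20), spacing=(4.0,) * 3, background_suv=0.2,
            lesions=(
                SphereLesion((40.0, 40.0, 40.0), 12.0, 10.0),
                SphereLesion((116.0, 40.0, 40.0), 10.0, 5.0),
            ),
            psf_fwhm_mm=8.0,
        )
        vol, _, _ = generate_phantom(spec, seed=0)
        res = isocontour_segment(vol, (slice(None),) * 3, fraction=0.40)
        oracle = flood_fill_26(vol.values, res.peak_index, 0.40 * res.suv_max)
        np.testing.assert_array_equal(res.mask, oracle)
        # cold gap: the far sphere's center is not part of the mask
        assert not res.mask[29, 10, 10]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_flood_fill_oracle_on_random_grids(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.gamma(2.0, 1.0, size=(12, 12, 12))
        vol = _volume(values)
        res = isocontour_segment(vol, (slice(2, 10),) * 3, fraction=0.5)
        oracle = flood_fill_26(values, res.peak_index, 0.5 * res.suv_max)
        np.testing.assert_array_equal(res.mask, oracle)

    def test_mask_invariant_under_positive_scaling(self, rng):
        values = rng.random((10, 10, 10)) + 0.1
        region = (slice(None),) * 3
        base = isocontour_segment(_volume(values), region)
        scaled = isocontour_segment(_volume(values * 7.3), region)
        np.testing.assert_array_equal(base.mask, scaled.mask)

    def test_mask_size_non_increasing_in_fraction(self, rng):
        values = rng.random((10, 10, 10)) + 0.1
        region = (slice(None),) * 3
        sizes = [
            isocontour_segment(_volume(values), region, fraction=f).n_voxels
            for f in (0.2, 0.4, 0.6, 0.8)
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_component_grows_beyond_search_region(self):
        values = np.zeros((11, 5, 5))
        values[3:9, 2, 2] = 5.0  # a rod extending past the search box
        res = isocontour_segment(_volume(values), (slice(3, 5), slice(None), slice(None)))
        assert res.n_voxels == 6

    def test_suv_mean_never_exceeds_suv_max(self, rng):
        values = rng.random((8, 8, 8)) + 0.1
        res = isocontour_segment(_volume(values), (slice(None),) * 3)
        assert res.suv_mean <= res.suv_max
        assert np.all(values[res.mask] >= res.fraction * res.suv_max)

    def test_zero_region_raises(self):
        with pytest.raises(DegenerateSignalError):
            isocontour_segment(_volume(np.zeros((5, 5, 5))), (slice(None),) * 3)

    @pytest.mark.parametrize("fraction", [0.0, 1.0, -0.2, 1.5])
    def test_fraction_out_of_range(self, fraction):
        values = np.ones((4, 4, 4))
        with pytest.raises(ValueError):
            isocontour_segment(_volume(values), (slice(None),) * 3, fraction=fraction)

    def test_argmax_tie_broken_by_lowest_linear_index(self):
        values = np.zeros((5, 5, 5))
        values[1, 1, 1] = 3.0
        values[3, 3, 3] = 3.0
        res = isocontour_segment(_volume(values), (slice(None),) * 3)
        assert res.peak_index == (1, 1, 1)


class TestLiverReference:
    def test_uniform_block(self):
        values = np.full((20, 20, 20), 4.0)
        assert liver_reference(_volume(values), (40.0, 40.0, 40.0), 30.0) == 4.0

    def test_center_outside_volume_raises(self):
        values = np.ones((10, 10, 10))
        with pytest.raises(GeometryError):
            liver_reference(_volume(values), (500.0, 20.0, 20.0), 30.0)

    def test_clipped_sphere_raises_rather_than_truncating(self):
        values = np.ones((10, 10, 10))  # extent 36 mm per axis
        with pytest.raises(GeometryError):
            liver_reference(_volume(values), (10.0, 18.0, 18.0), 30.0)

    def test_noisy_block_mean_within_normal_bound(self):
        """30 mm VOI at 4 mm spacing: mean within 4*sigma/sqrt(n) of truth."""
        rng = np.random.default_rng(31)
        values = 4.1 + rng.normal(0.0, 0.2, size=(20, 20, 20))
        vol = _volume(values)
        center = (40.0, 40.0, 40.0)
        n = int(sphere_mask(vol, center, 30.0).sum())
        assert n > 0
        got = liver_reference(vol, center, 30.0)
        assert abs(got - 4.1) < 4 * 0.2 / np.sqrt(n)

    def test_sphere_voxel_count_matches_center_rule(self):
        vol = _volume(np.ones((21, 21, 21)))
        mask = sphere_mask(vol, (40.0, 40.0, 40.0), 30.0)
        # brute-force voxel-center count at 4 mm isotropic spacing
        count = 0
        for i in range(21):
            for j in range(21):
                for k in range(21):
                    d2 = (4 * i - 40) ** 2 + (4 * j - 40) ** 2 + (4 * k - 40) ** 2
                    count += d2 <= 15.0**2
        assert int(mask.sum()) == count


class TestQuantifyLesions:
    @pytest.fixture()
    def three_lesion_phantom(self):
        spec = PhantomSpec(
            shape=(48, 24, 24), spacing=(4.0,) * 3, background_suv=0.5,
            lesions=(
                SphereLesion((36.0, 56.0, 56.0), 16.0, 6.0),
                SphereLesion((92.0, 56.0, 56.0), 16.0, 10.0),
                SphereLesion((152.0, 56.0, 56.0), 16.0, 20.0),
            ),
            liver_box_mm=((12.0, 0.0, 0.0), (176.0, 32.0, 32.0)),
            liver_suv=4.0,
            psf_fwhm_mm=6.0,
        )
        vol, _, truths = generate_phantom(spec, seed=0)
        seeds = pd.DataFrame(
            {
                "lesion_id": ["L1", "L2", "L3"],
                "x_mm": [36.0, 92.0, 152.0],
                "y_mm": [56.0, 56.0, 56.0],
                "z_mm": [56.0, 56.0, 56.0],
                "box_halfwidth_mm": [12.0, 12.0, 12.0],
            }
        )
        return vol, seeds, truths

    def test_empty_seed_list_still_computes_liver(self, three_lesion_phantom):
        vol, seeds, _ = three_lesion_phantom
        table = quantify_lesions(vol, seeds.iloc[:0], (60.0, 16.0, 16.0))
        assert len(table) == 0
        assert list(table.columns)[:3] == ["lesion_id", "suv_max", "suv_mean"]

    def test_suvmax_ordering_preserved_under_blur(self, three_lesion_phantom):
        vol, seeds, truths = three_lesion_phantom
        table = quantify_lesions(vol, seeds, (60.0, 16.0, 16.0))
        assert list(table["suv_max"]) == sorted(table["suv_max"])
        assert (table["liver_mean"] == table["liver_mean"].iloc[0]).all()

    def test_recovery_within_ten_percent_for_large_lesions(self, three_lesion_phantom):
        """16 mm radius >= 2x the 6 mm PSF FWHM: peak recovery within 10%."""
        vol, seeds, truths = three_lesion_phantom
        table = quantify_lesions(vol, seeds, (60.0, 16.0, 16.0))
        for got, truth in zip(table["suv_max"], truths):
            assert got == pytest.approx(truth, rel=0.10)

    def test_error_annotated_with_lesion_id(self, three_lesion_phantom):
        vol, seeds, _ = three_lesion_phantom
        bad = seeds.copy()
        bad.loc[0, "x_mm"] = 1e5
        with pytest.raises(GeometryError, match="L1"):
            quantify_lesions(vol, bad, (60.0, 16.0, 16.0))


class TestVolumeIO:
    def test_nifti_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        vol = PetVolume(values=rng.random((6, 7, 8)), spacing=(2.0, 3.0, 4.0),
                        origin=(1.0, -2.0, 3.0))
        path = tmp_path / "vol.nii.gz"
        vol.to_nifti(path)
        back = PetVolume.from_nifti(path)
        np.testing.assert_allclose(back.values, vol.values, rtol=1e-6)
        assert back.spacing == pytest.approx(vol.spacing)
        assert back.origin == pytest.approx(vol.origin)

    def test_rotated_affine_rejected(self, tmp_path):
        import nibabel as nib

        theta = np.deg2rad(10)
        affine = np.eye(4)
        affine[:2, :2] = [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        path = tmp_path / "rot.nii.gz"
        nib.save(nib.Nifti1Image(np.ones((4, 4, 4), dtype=np.float32), affine), str(path))
        with pytest.raises(GeometryError, match="rotation"):
            PetVolume.from_nifti(path)

    def test_seed_list_schema_enforced(self, tmp_path):
        path = tmp_path / "seeds.csv"
        pd.DataFrame({"lesion_id": ["a"], "x_mm": [0.0]}).to_csv(path, index=False)
        from psmalesion.exceptions import SchemaError

        with pytest.raises(SchemaError, match="box_halfwidth_mm"):
            read_seed_list(path)

    @pytest.mark.parametrize("spacing", [(0.0, 1.0, 1.0), (-1.0, 1.0, 1.0)])
    def test_nonpositive_spacing_rejected(self, spacing):
        with pytest.raises(ValueError):
            PetVolume(values=np.ones((3, 3, 3)), spacing=spacing)
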