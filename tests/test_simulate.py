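"""Phantom generation, stack rendering, tiling and splitting."""

import dataclasses

import numpy as np
import pytest
from scipy.ndimage import label

from ldsefocus.simulate import (
    FocalStack,
    FocalStackSpec,
    PhantomSpec,
    generate_phantom,
    render_defocus_stack,
    split_dataset,
    tile_stack,
    tiles_to_arrays,
)


def variance_of_laplacian(img: np.ndarray) -> float:
    lap = (
        -4 * img[1:-1, 1:-1]
        + img[:-2, 1:-1]
        + img[2:, 1:-1]
        + img[1:-1, :-2]
        + img[1:-1, 2:]
    )
    return float(lap.var())


class TestGeneratePhantom:
    def test_empty_spec_is_uniform(self):
        spec = PhantomSpec(width=64, height=64, n_cells=0, texture_amplitude=0.0, blank_fraction=0.0)
        img = generate_phantom(spec)
        assert np.ptp(img) == 0.0

    def test_deterministic_in_seed(self, small_phantom_spec):
        a = generate_phantom(small_phantom_spec)
        b = generate_phantom(small_phantom_spec)
        assert np.array_equal(a, b)
        c = generate_phantom(dataclasses.replace(small_phantom_spec, seed=12))
        assert not np.array_equal(a, c)

    def test_values_in_unit_interval(self, small_phantom_spec):
        img = generate_phantom(small_phantom_spec)
        assert img.min() >= 0.0 and img.max() <= 1.0

    def test_component_count_bounded_by_cells(self):
        spec = PhantomSpec(width=128, height=128, n_cells=5, cell_radius_range=(5.0, 8.0),
                           texture_amplitude=0.0, blank_fraction=0.0, seed=4)
        img = generate_phantom(spec)
        # cells are darker than the 0.85 background; components may merge
        n_components = label(img < 0.6)[1]
        assert 1 <= n_components <= 5

    def test_blank_band_is_background_only(self, small_phantom_spec):
        img = generate_phantom(small_phantom_spec)
        blank_cols = int(round(small_phantom_spec.width * small_phantom_spec.blank_fraction))
        band = img[:, -blank_cols:]
        # cell rims have soft (sigmoid) edges; their tails into the blank
        # band are far below sensor noise
        assert np.ptp(band) < 1e-8

    def test_unplaceable_cells_rejected(self):
        spec = PhantomSpec(width=32, height=32, n_cells=2, cell_radius_range=(20.0, 30.0))
        with pytest.raises(ValueError, match="do not fit"):
            generate_phantom(spec)


class TestFocalStackSpec:
    def test_default_grid_has_41_frames(self):
        offsets = FocalStackSpec().z_offsets()
        assert len(offsets) == 41
        assert offsets[0] == -10.0 and offsets[-1] == 10.0
        assert np.any(offsets == 0.0)

    def test_grid_must_straddle_focus(self):
        with pytest.raises(ValueError):
            FocalStackSpec(z_min=1.0, z_max=10.0)

    def test_grid_must_contain_focal_plane(self):
        with pytest.raises(ValueError, match="z = 0"):
            FocalStackSpec(z_min=-9.75, z_max=10.0, z_step=0.5)


class TestRenderDefocusStack:
    def test_frame_count_matches_grid(self, coarse_stack):
        assert len(coarse_stack) == 9

    def test_in_focus_frame_is_phantom(self, small_phantom_spec, lens_20x):
        phantom = generate_phantom(small_phantom_spec)
        stack = render_defocus_stack(
            phantom, FocalStackSpec(z_min=-5, z_max=5, z_step=5), lens_20x, noise_sigma=0.0
        )
        i0 = int(np.argmin(np.abs(stack.z_offsets_um)))
        assert np.allclose(stack.frames[i0], phantom)

    def test_focus_measure_peaks_at_zero(self, coarse_stack):
        sharpness = np.array([variance_of_laplacian(f) for f in coarse_stack.frames])
        i0 = int(np.argmin(np.abs(coarse_stack.z_offsets_um)))
        assert sharpness.argmax() == i0
        # non-increasing stepwise away from focus on either side
        assert np.all(np.diff(sharpness[: i0 + 1]) >= 0)
        assert np.all(np.diff(sharpness[i0:]) <= 0)

    def test_gradient_maximal_at_focus_for_absorption_specimen(self, small_phantom_spec, lens_20x):
        """With phase contrast off (pure absorption), blur strictly wins:
        mean absolute gradient peaks at the focal plane.  (With the
        transport-of-intensity term on, slight defocus can *raise* edge
        contrast, as it does for real semi-transparent specimens.)"""
        phantom = generate_phantom(small_phantom_spec)
        stack = render_defocus_stack(
            phantom, FocalStackSpec(z_min=-10, z_max=10, z_step=2.5), lens_20x,
            noise_sigma=0.0, tie_strength=0.0, field_id="absorption", seed=3,
        )
        grads = [np.abs(np.gradient(f)).mean() for f in stack.frames]
        i0 = int(np.argmin(np.abs(stack.z_offsets_um)))
        assert int(np.argmax(grads)) == i0

    def test_roundtrip_through_tiff(self, coarse_stack, tmp_path):
        coarse_stack.save(tmp_path)
        loaded = FocalStack.load(tmp_path, coarse_stack.field_id)
        assert np.allclose(loaded.frames, coarse_stack.frames, atol=1e-7)
        assert np.array_equal(loaded.z_offsets_um, coarse_stack.z_offsets_um)
        assert loaded.magnification_tag == coarse_stack.magnification_tag


class TestTileStack:
    def test_full_resolution_grid_count(self):
        frames = np.zeros((1, 1944, 2592))
        stack = FocalStack(frames=frames, z_offsets_um=np.array([0.0]), field_id="f")
        assert len(tile_stack(stack, tile_size=224)) == 8 * 11

    def test_single_tile_frame(self):
        stack = FocalStack(frames=np.zeros((1, 224, 224)), z_offsets_um=np.array([0.0]), field_id="f")
        assert len(tile_stack(stack, tile_size=224)) == 1

    def test_tiles_inherit_frame_label(self, coarse_stack):
        tiles = tile_stack(coarse_stack, tile_size=64)
        by_z = {}
        for t in tiles:
            by_z.setdefault(t.z_true, 0)
            by_z[t.z_true] += 1
        assert set(by_z) == set(np.asarray(coarse_stack.z_offsets_um, dtype=float))
        assert len(set(by_z.values())) == 1  # label distribution uniform over z

    def test_frame_smaller_than_tile_rejected(self):
        stack = FocalStack(frames=np.zeros((1, 100, 100)), z_offsets_um=np.array([0.0]), field_id="f")
        with pytest.raises(ValueError, match="smaller"):
            tile_stack(stack, tile_size=224)

    def test_tile_content_matches_frame(self, coarse_stack):
        tiles = tile_stack(coarse_stack, tile_size=64)
        t = tiles[3]
        iz = int(np.where(coarse_stack.z_offsets_um == t.z_true)[0][0])
        frame = coarse_stack.frames[iz]
        assert np.array_equal(t.pixels, frame[t.row * 64 : (t.row + 1) * 64, t.col * 64 : (t.col + 1) * 64])


class TestSplitDataset:
    def _tiles(self, n_fields, per_field=4):
        stacks = []
        for i in range(n_fields):
            stacks.append(
                FocalStack(
                    frames=np.zeros((1, 64, 2 * 64 * (per_field // 2))),
                    z_offsets_um=np.array([0.0]),
                    field_id=f"field{i}",
                )
            )
        tiles = []
        for s in stacks:
            tiles.extend(tile_stack(s, tile_size=64))
        return tiles

    def test_nine_to_one_field_split(self):
        tiles = self._tiles(10)
        train, test = split_dataset(tiles, ratio=0.9, seed=0)
        assert len({t.field_id for t in train}) == 9
        assert len({t.field_id for t in test}) == 1

    def test_partition_is_disjoint_and_exhaustive(self):
        tiles = self._tiles(5)
        train, test = split_dataset(tiles, ratio=0.8, seed=1)
        assert len(train) + len(test) == len(tiles)
        assert {t.field_id for t in train}.isdisjoint({t.field_id for t in test})

    def test_split_reproducible(self):
        tiles = self._tiles(6)
        a = split_dataset(tiles, seed=7)
        b = split_dataset(tiles, seed=7)
        assert [t.field_id for t in a[0]] == [t.field_id for t in b[0]]

    def test_single_field_rejected(self):
        tiles = self._tiles(1)
        with pytest.raises(ValueError, match="at least 2 fields"):
            split_dataset(tiles)

    def test_tiles_to_arrays_shapes(self):
        tiles = self._tiles(2)
        x, y = tiles_to_arrays(tiles, channels=3)
        assert x.shape == (len(tiles), 3, 64, 64)
        assert y.shape == (len(tiles),)


class TestMagnificationVariants:
    def test_40x_lens_blurs_faster(self):
        from ldsefocus.optics import blur_radius_from_defocus
        from ldsefocus.simulate import default_lens

        r20 = blur_radius_from_defocus(default_lens("20X"), 5.0)
        r40 = blur_radius_from_defocus(default_lens("40X"), 5.0)
        assert r40 > 2 * r20  # higher NA: much steeper blur growth

    def test_40x_dataset_halves_cell_density(self):
        from ldsefocus.simulate import FocalStackSpec, PhantomSpec, build_dataset

        pspec = PhantomSpec(width=96, height=96, n_cells=8, cell_radius_range=(4, 8),
                            noise_sigma=0.0)
        sspec = FocalStackSpec(z_min=-4, z_max=4, z_step=4, magnification_tag="40X")
        tiles, stacks = build_dataset(1, pspec, sspec, tile_size=32, seed=0)
        assert stacks[0].magnification_tag == "40X"
        # halved density: darker-than-background area is well below the 20X field's
        sspec20 = FocalStackSpec(z_min=-4, z_max=4, z_step=4, magnification_tag="20X")
        _, stacks20 = build_dataset(1, pspec, sspec20, tile_size=32, seed=0)
        dark40 = (stacks[0].frames[1] < 0.6).mean()
        dark20 = (stacks20[0].frames[1] < 0.6).mean()
        assert dark40 < dark20
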