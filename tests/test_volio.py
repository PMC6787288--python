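"""Acquisition geometry, flat-field, stitching, MIP and downsampling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stptquant.volio import (
    AcquisitionSummary,
    OpticalSchedule,
    RawTileGrid,
    SectionImage,
    VolumeStack,
    downsample,
    flat_field_correct,
    make_mip,
    mip_stack,
    plan_acquisition,
    read_stack,
    stitch_tiles,
    write_stack,
)

rng = np.random.default_rng(42)


# ---------------------------------------------------------------------------
# flat-field correction
# ---------------------------------------------------------------------------


class TestFlatField:
    def test_uniform_field_is_noop(self):
        tile = rng.integers(0, 60000, (32, 40)).astype(np.uint16)
        out = flat_field_correct(tile, np.full((32, 40), 3.7))
        np.testing.assert_array_equal(out, tile)

    def test_zero_tile_stays_zero(self):
        field = rng.uniform(0.5, 2.0, (16, 16))
        out = flat_field_correct(np.zeros((16, 16), np.uint16), field)
        assert not out.any()

    def test_vignette_roundtrip_recovers_reference(self):
        # forward-multiply oracle: image * vignette, corrected with the same
        # vignette, recovers the image within 1 intensity unit per pixel
        ref = rng.integers(500, 40000, (48, 48)).astype(np.uint16)
        y, x = np.mgrid[:48, :48]
        vignette = 0.6 + 0.4 * np.cos(np.hypot(y - 24, x - 24) / 30)
        vignette /= vignette.mean()  # unit-mean illumination profile
        observed = np.clip(np.round(ref * vignette), 0, 65535).astype(np.uint16)
        recovered = flat_field_correct(observed, vignette)
        assert np.abs(recovered.astype(int) - ref.astype(int)).max() <= 1

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            flat_field_correct(np.ones((4, 4)), np.ones((4, 5)))

    def test_nonpositive_field_rejected(self):
        field = np.ones((4, 4))
        field[2, 2] = 0.0
        with pytest.raises(ValueError, match="positive"):
            flat_field_correct(np.ones((4, 4)), field)


# ---------------------------------------------------------------------------
# stitching
# ---------------------------------------------------------------------------


def _slice_into_tiles(ref, n_rows, n_cols, overlap):
    h = (ref.shape[0] + (n_rows - 1) * overlap) // n_rows
    w = (ref.shape[1] + (n_cols - 1) * overlap) // n_cols
    tiles = [
        [
            ref[r * (h - overlap) : r * (h - overlap) + h,
                c * (w - overlap) : c * (w - overlap) + w]
            for c in range(n_cols)
        ]
        for r in range(n_rows)
    ]
    return tiles


class TestStitch:
    def test_single_tile_identity(self):
        tile = rng.integers(0, 100, (10, 12)).astype(np.uint16)
        out = stitch_tiles(RawTileGrid([[tile]]))
        np.testing.assert_array_equal(out.pixels, tile)

    def test_2x2_reassembly_no_overlap(self):
        ref = rng.integers(0, 60000, (40, 60)).astype(np.uint16)
        tiles = _slice_into_tiles(ref, 2, 2, 0)
        out = stitch_tiles(RawTileGrid(tiles, overlap_px=0))
        np.testing.assert_array_equal(out.pixels, ref)

    @pytest.mark.parametrize("overlap", [1, 3, 7])
    def test_overlapping_reassembly_bit_exact(self, overlap):
        # first-writer-wins on consistent tiles reproduces the reference
        n_rows, n_cols, h, w = 3, 2, 21, 17
        ref_shape = (n_rows * (h - overlap) + overlap, n_cols * (w - overlap) + overlap)
        ref = rng.integers(0, 60000, ref_shape).astype(np.uint16)
        tiles = [
            [
                ref[r * (h - overlap) : r * (h - overlap) + h,
                    c * (w - overlap) : c * (w - overlap) + w]
                for c in range(n_cols)
            ]
            for r in range(n_rows)
        ]
        out = stitch_tiles(RawTileGrid(tiles, overlap_px=overlap))
        np.testing.assert_array_equal(out.pixels, ref)

    def test_mosaic_shape_9x13(self):
        # a full coronal section is a 9 x 13 mosaic
        tiles = [[np.zeros((8, 6), np.uint16)] * 13 for _ in range(9)]
        out = stitch_tiles(RawTileGrid(tiles, overlap_px=0))
        assert out.pixels.shape == (9 * 8, 13 * 6)

    def test_inconsistent_tiles_rejected(self):
        with pytest.raises(ValueError, match="same shape"):
            RawTileGrid([[np.zeros((4, 4)), np.zeros((4, 5))]])


# ---------------------------------------------------------------------------
# maximum intensity projection
# ---------------------------------------------------------------------------


class TestMip:
    def _planes(self, n, shape=(9, 11)):
        return [
            SectionImage(rng.integers(0, 1000, shape).astype(np.uint16), 1.0)
            for _ in range(n)
        ]

    def test_single_plane_identity(self):
        (p,) = self._planes(1)
        np.testing.assert_array_equal(make_mip([p]).pixels, p.pixels)

    def test_identical_planes(self):
        p = self._planes(1)[0]
        out = make_mip([p, SectionImage(p.pixels.copy(), 1.0), p])
        np.testing.assert_array_equal(out.pixels, p.pixels)

    def test_matches_explicit_triple_loop(self):
        planes = self._planes(3, (6, 7))
        out = make_mip(planes).pixels
        for r in range(6):
            for c in range(7):
                expected = max(p.pixels[r, c] for p in planes)
                assert out[r, c] == expected

    def test_idempotent(self):
        planes = self._planes(3)
        once = make_mip(planes)
        np.testing.assert_array_equal(make_mip([once]).pixels, once.pixels)

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(perm=st.permutations(range(4)))
    def test_permutation_invariant(self, perm):
        planes = [
            SectionImage(np.random.default_rng(i).integers(0, 99, (5, 5)), 1.0)
            for i in range(4)
        ]
        a = make_mip(planes).pixels
        b = make_mip([planes[i] for i in perm]).pixels
        np.testing.assert_array_equal(a, b)

    def test_empty_and_mismatch_rejected(self):
        with pytest.raises(ValueError):
            make_mip([])
        with pytest.raises(ValueError, match="shape"):
            make_mip([SectionImage(np.zeros((3, 3)), 1.0), SectionImage(np.zeros((3, 4)), 1.0)])

    def test_mip_stack_collapses_optical_planes(self):
        sched = OpticalSchedule(75.0, (25.0, 50.0, 75.0), 4, 0.875, ("g",))
        arr = rng.integers(0, 999, (12, 5, 5)).astype(np.uint16)
        raw = VolumeStack.from_array(arr, 0.875, 25.0)
        out = mip_stack(raw, sched)
        assert len(out.sections) == 4
        assert out.axial_spacing_um == 75.0
        np.testing.assert_array_equal(out.sections[0].pixels, arr[:3].max(axis=0))


# ---------------------------------------------------------------------------
# downsampling
# ---------------------------------------------------------------------------


class TestDownsample:
    def test_identity_at_same_spacing(self):
        img = SectionImage(rng.integers(0, 100, (10, 10)).astype(np.uint16), 1.5)
        out = downsample(img, 1.5)
        np.testing.assert_array_equal(out.pixels, img.pixels)

    def test_printed_spacing_arithmetic(self):
        # 1,200 px at 0.875 um -> 700 px at 1.5 um
        img = SectionImage(np.zeros((4, 1200), np.uint16), 0.875)
        out = downsample(img, 1.5)
        assert out.pixels.shape[1] == 700
        assert out.pixel_size_um == 1.5

    def test_constant_preserved_exactly(self):
        img = SectionImage(np.full((37, 53), 123, np.uint16), 0.875)
        out = downsample(img, 1.5)
        assert (out.pixels == 123).all()

    def test_mean_signal_approximately_preserved(self):
        # area interpolation preserves the image mean (hence summed signal
        # after area scaling), unlike decimation
        img = SectionImage(rng.integers(0, 60000, (120, 120)).astype(np.uint16), 1.0)
        out = downsample(img, 2.5)
        assert abs(out.pixels.mean() - img.pixels.mean()) / img.pixels.mean() < 0.01

    def test_upsampling_rejected(self):
        with pytest.raises(ValueError, match=">="):
            downsample(SectionImage(np.zeros((5, 5)), 1.5), 0.875)


# ---------------------------------------------------------------------------
# acquisition planning
# ---------------------------------------------------------------------------


class TestPlanAcquisition:
    def test_whole_brain_schedule(self):
        # 190 physical sections x 3 optical planes = 570 coronal images
        sched = OpticalSchedule(75.0, (25.0, 50.0, 75.0), 190, 0.875)
        out = plan_acquisition(sched)
        assert out == AcquisitionSummary(570, 190, 190 * 75.0)
        assert out.total_images % len(sched.plane_depths_um) == 0

    def test_minimal_schedule(self):
        out = plan_acquisition(OpticalSchedule(75.0, (25.0,), 1, 1.0))
        assert out.total_images == 1

    def test_sampled_depth(self):
        out = plan_acquisition(OpticalSchedule(75.0, (25.0, 50.0, 75.0), 10, 1.0))
        assert out.sampled_depth_um == 750.0

    def test_invalid_schedules_rejected(self):
        with pytest.raises(ValueError):
            OpticalSchedule(75.0, (25.0, 80.0), 1, 1.0)  # deeper than the cut
        with pytest.raises(ValueError):
            OpticalSchedule(75.0, (50.0, 25.0), 1, 1.0)  # not increasing
        with pytest.raises(ValueError):
            OpticalSchedule(75.0, (25.0,), 1, -1.0)


# ---------------------------------------------------------------------------
# I/O round-trip
# ---------------------------------------------------------------------------


def test_stack_tiff_roundtrip(tmp_path):
    arr = rng.integers(0, 60000, (4, 8, 9, 2)).astype(np.uint16)
    stack = VolumeStack.from_array(arr, 1.5, 75.0, "mip", ("red", "green"))
    write_stack(stack, tmp_path / "s.tif")
    back = read_stack(tmp_path / "s.tif")
    np.testing.assert_array_equal(back.as_array(), arr)
    assert back.pixel_size_um == 1.5
    assert back.axial_spacing_um == 75.0
    assert back.provenance == "mip"
    assert back.channels == ("red", "green")
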