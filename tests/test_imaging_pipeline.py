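import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from synergize.imaging_pipeline import (
    RegionMasks,
    TwoChannelImage,
    channel_correlation,
    correct_chromatic_shift,
    extract_regions,
    preprocess,
    richardson_lucy,
    save_masks_tiff,
    track_contour,
)


def _annulus(radius=20.0, size=64, width=1.5, amp=100.0, noise_rng=None):
    yy, xx = np.mgrid[0:size, 0:size]
    r = np.hypot(yy - size / 2, xx - size / 2)
    img = amp * np.exp(-((r - radius) ** 2) / (2 * width**2))
    if noise_rng is not None:
        img = noise_rng.poisson(img + 1.0).astype(float)
    return img


class TestPreprocess:
    def test_identity(self, rng):
        img = rng.uniform(10, 50, (16, 16))
        out, clip = preprocess(img, np.ones_like(img), 0.0)
        np.testing.assert_array_equal(out, img)
        assert clip == 0.0

    def test_uniform_background_subtraction(self):
        img = np.full((8, 8), 30.0)
        out, _ = preprocess(img, background=12.0)
        np.testing.assert_allclose(out, 18.0)

    def test_gradient_flat_field_removed(self):
        yy, xx = np.mgrid[0:32, 0:32]
        ff = 1.0 + 0.5 * xx / 31
        img = 80.0 * ff
        out, _ = preprocess(img, flat_field=ff)
        assert out.std() / out.mean() < 0.01

    def test_overclipping_warns(self):
        with pytest.warns(UserWarning, match="clipped"):
            preprocess(np.full((10, 10), 5.0), background=10.0)

    def test_nonpositive_flat_field_rejected(self):
        with pytest.raises(ValueError):
            preprocess(np.ones((4, 4)), flat_field=np.zeros((4, 4)))


class TestRichardsonLucy:
    def test_delta_psf_is_identity(self, rng):
        img = rng.uniform(5, 50, (24, 24))
        psf = np.zeros((5, 5))
        psf[2, 2] = 1.0
        np.testing.assert_allclose(richardson_lucy(img, psf, 10), img, rtol=1e-6)

    def test_flat_image_is_fixed_point(self):
        psf = np.ones((5, 5)) / 25
        img = np.full((32, 32), 40.0)
        np.testing.assert_allclose(richardson_lucy(img, psf, 25), img, rtol=1e-3)

    def test_recovers_blurred_point_source(self):
        img = np.zeros((41, 41))
        img[20, 20] = 1000.0
        yy, xx = np.mgrid[0:11, 0:11]
        psf = np.exp(-((yy - 5) ** 2 + (xx - 5) ** 2) / (2 * 1.0**2))
        psf /= psf.sum()
        blurred = gaussian_filter(img, 1.0)
        restored = richardson_lucy(blurred, psf, 50)
        assert restored.max() >= 0.8 * img.max()
        assert np.all(restored >= 0)

    def test_unnormalised_psf_warns(self):
        with pytest.warns(UserWarning, match="normalis"):
            richardson_lucy(np.ones((8, 8)), np.ones((3, 3)), 2)


class TestChromaticShift:
    def test_recovers_constructed_shift(self, rng):
        a = rng.poisson(50, (48, 48)).astype(float)
        b = np.zeros_like(a)
        b[1:, 2:] = a[:-1, :-2]       # ch2 displaced by (1, 2)
        shift, fixed = correct_chromatic_shift(a, b, 3)
        assert shift == (1, 2)
        np.testing.assert_array_equal(fixed[:-1, :-2], a[:-1, :-2])

    def test_identical_channels_zero_shift(self, rng):
        a = rng.poisson(50, (32, 32)).astype(float)
        shift, _ = correct_chromatic_shift(a, a.copy(), 3)
        assert shift == (0, 0)

    def test_anticorrelated_synapse_channels(self):
        """Registration must work on mutually excluding channels."""
        from synergize.synthetic_data import generate_bilayer

        cs, cl, tr = generate_bilayer(seed=5)
        cl_shifted = np.roll(cl, (2, 1), axis=(0, 1))
        shift, _ = correct_chromatic_shift(cs, cl_shifted, 3, mask=tr.ci_mask)
        assert shift == (2, 1)

    def test_flat_channel_rejected(self):
        with pytest.raises(ValueError):
            correct_chromatic_shift(np.ones((8, 8)), np.zeros((8, 8)))


class TestTrackContour:
    def test_closed_chain_with_expected_length(self, rng):
        img = _annulus(radius=20, noise_rng=rng)
        chain = track_contour(img, (32, 32), intensity_threshold=20.0)
        # closed and 8-connected
        d = np.abs(np.diff(np.vstack([chain, chain[:1]]), axis=0))
        assert np.all(d.max(axis=1) <= 1)
        # geometric path length (diagonal steps count sqrt(2))
        length = np.where(d.sum(axis=1) == 2, np.sqrt(2), 1.0).sum()
        assert length == pytest.approx(2 * np.pi * 20, rel=0.10)

    def test_orientation_independent_of_seed_point(self, rng):
        img = _annulus(radius=18, noise_rng=rng)

        def signed_area(ch):
            r, c = ch[:, 0].astype(float), ch[:, 1].astype(float)
            return 0.5 * np.sum(c * np.roll(r, -1) - np.roll(c, -1) * r)

        a1 = signed_area(track_contour(img, (30, 30), 20.0))
        a2 = signed_area(track_contour(img, (36, 28), 20.0))
        assert np.sign(a1) == np.sign(a2)
        assert abs(a1) == pytest.approx(np.pi * 18**2, rel=0.15)

    def test_broken_ridge_reports_gap(self):
        img = _annulus(radius=20, width=1.2)
        img[:, 40:] = 0.0   # erase a quadrant
        with pytest.raises(ValueError, match="angle"):
            track_contour(img, (32, 32), intensity_threshold=20.0)

    def test_tracks_generator_stack_membrane(self):
        from synergize.synthetic_data import generate_zstack

        ss, sl, tr = generate_zstack(seed=3)
        mid = tr.extras["mid_slice"]
        img = ss[mid] + sl[mid]
        chain = track_contour(img, (47, 47), intensity_threshold=img.max() * 0.1)
        from scipy.spatial import cKDTree

        d, _ = cKDTree(chain).query(tr.extras["contours"][mid])
        assert (d <= 1.5).mean() >= 0.95


def _truth_annotations(tr):
    anns = []
    for lab in tr.extras["contour_labels"]:
        idx = np.where(lab == "contact")[0]
        if idx.size == 0:
            anns.append(None)
            continue
        gaps = np.where(np.diff(idx) > 1)[0]
        if gaps.size:
            anns.append((int(idx[gaps[0] + 1]), int(idx[gaps[0]])))
        else:
            anns.append((int(idx[0]), int(idx[-1])))
    return anns


@pytest.fixture(scope="module")
def stack_case():
    from synergize.synthetic_data import generate_zstack

    ss, sl, tr = generate_zstack(seed=3)
    masks, transects = extract_regions(ss + sl, tr.extras["contours"],
                                       _truth_annotations(tr))
    return ss, sl, tr, masks, transects


class TestExtractRegions:

    def test_masks_disjoint(self, stack_case):
        _, _, _, masks, _ = stack_case
        assert not np.any(masks.free_surface & masks.contact_interface)

    def test_truth_interface_recovered(self, stack_case):
        _, _, tr, masks, _ = stack_case
        mid = tr.extras["mid_slice"]
        chain = tr.extras["contours"][mid]
        truth_ci = chain[tr.extras["contour_labels"][mid] == "contact"]
        hit = masks.contact_interface[truth_ci[:, 0], truth_ci[:, 1]]
        assert hit.mean() >= 0.95

    def test_transect_offsets_symmetric(self, stack_case):
        _, _, _, _, transects = stack_case
        offs = np.concatenate([t["offsets"] for t in transects])
        assert abs(offs.mean()) < 1e-12

    def test_transect_profile_peaks_on_contour(self, stack_case):
        # per-pixel noise flips individual argmaxes; the mean profile
        # across transects must peak at zero offset
        _, _, _, _, transects = stack_case
        mean_profile = np.mean([t["values"] for t in transects], axis=0)
        assert np.argmax(mean_profile) == len(mean_profile) // 2

    def test_annotation_outside_contour_rejected(self, stack_case):
        ss, sl, tr, _, _ = stack_case
        bad = [(0, 10**6) if c is not None else None
               for c in _truth_annotations(tr)]
        with pytest.raises(ValueError, match="outside"):
            extract_regions(ss + sl, tr.extras["contours"], bad)


class TestChannelCorrelation:
    def test_identical_channels(self, rng):
        a = rng.uniform(0, 1, (16, 16))
        img = TwoChannelImage(small=a, long=a.copy())
        assert channel_correlation(img, np.ones((16, 16), bool)) == pytest.approx(1.0)

    def test_perfect_anticorrelation(self, rng):
        a = rng.uniform(0, 1, (16, 16))
        img = TwoChannelImage(small=a, long=10.0 - a)
        assert channel_correlation(img, np.ones((16, 16), bool)) == pytest.approx(-1.0)

    def test_degenerate_inputs_rejected(self):
        img = TwoChannelImage(small=np.ones((4, 4)), long=np.ones((4, 4)))
        with pytest.raises(ValueError):
            channel_correlation(img, np.ones((4, 4), bool))
        mask = np.zeros((4, 4), bool)
        mask[0, 0] = True
        with pytest.raises(ValueError):
            channel_correlation(img, mask)


class TestContainersAndIo:
    def test_channel_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            TwoChannelImage(small=np.ones((4, 4)), long=np.ones((5, 4)))

    def test_overlapping_masks_rejected(self):
        m = np.ones((4, 4), bool)
        with pytest.raises(ValueError):
            RegionMasks(free_surface=m, contact_interface=m)

    def test_mask_tiff_round_trip(self, tmp_path, rng):
        import tifffile

        fs = rng.uniform(size=(12, 12)) > 0.6
        ci = ~fs & (rng.uniform(size=(12, 12)) > 0.5)
        masks = RegionMasks(free_surface=fs, contact_interface=ci)
        path = tmp_path / "masks.tif"
        save_masks_tiff(masks, path)
        arr = tifffile.imread(path)
        np.testing.assert_array_equal(arr[0].astype(bool), fs)
        np.testing.assert_array_equal(arr[1].astype(bool), ci)

    def test_pipeline_determinism(self, rng):
        img = _annulus(radius=15, noise_rng=np.random.default_rng(4))
        out1, _ = preprocess(img, background=1.0)
        out2, _ = preprocess(img, background=1.0)
        np.testing.assert_array_equal(out1, out2)
        c1 = track_contour(out1, (32, 32), 10.0)
        c2 = track_contour(out2, (32, 32), 10.0)
        np.testing.assert_array_equal(c1, c2)
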