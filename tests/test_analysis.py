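"""Segmentation, morphometrics, droplet counting, and PSF fitting."""

import math

import numpy as np
import pytest

from viffi import (
    CellRecord,
    ChannelLayout,
    cell_features,
    count_droplets,
    droplet_area_stats,
    enclosing_box_ratio,
    export_crops,
    export_features,
    fit_psf,
    min_area_rect,
    segment,
    split_channels,
)


def brute_force_min_rect(mask, step_deg=0.1):
    """Exhaustive rotation search over the pixel-corner point set [px²]."""
    ys, xs = np.nonzero(mask)
    pts = np.concatenate([
        np.stack([xs, ys], 1), np.stack([xs + 1, ys], 1),
        np.stack([xs, ys + 1], 1), np.stack([xs + 1, ys + 1], 1),
    ]).astype(float)
    best = np.inf
    for ang in np.arange(0.0, 90.0, step_deg):
        t = math.radians(ang)
        c, s = math.cos(t), math.sin(t)
        xr = pts[:, 0] * c - pts[:, 1] * s
        yr = pts[:, 0] * s + pts[:, 1] * c
        area = (xr.max() - xr.min()) * (yr.max() - yr.min())
        best = min(best, area)
    return best


def random_blob_mask(rng, shape=(48, 48), max_disks=4):
    m = np.zeros(shape, dtype=bool)
    yy, xx = np.ogrid[:shape[0], :shape[1]]
    cy, cx = shape[0] // 2, shape[1] // 2
    for _ in range(rng.integers(1, max_disks + 1)):
        r0 = rng.integers(cy - 10, cy + 10)
        c0 = rng.integers(cx - 10, cx + 10)
        rad = rng.integers(3, 9)
        m |= (yy - r0) ** 2 + (xx - c0) ** 2 <= rad**2
    return m


class TestSplitChannels:
    def test_round_trip_of_disjoint_halves(self):
        frame = np.arange(32 * 64, dtype=np.uint16).reshape(32, 64)
        layout = ChannelLayout(regions=[(0, 0, 32, 32), (0, 32, 32, 32)])
        a, b = split_channels(frame, layout)
        assert a.shape == b.shape == (32, 32)
        np.testing.assert_array_equal(np.hstack([a, b]), frame)

    def test_symmetric_frame_gives_identical_channels(self):
        half = np.random.default_rng(0).integers(0, 100, (16, 20)).astype(np.uint16)
        frame = np.hstack([half, half])
        layout = ChannelLayout(regions=[(0, 0, 16, 20), (0, 20, 16, 20)])
        a, b = split_channels(frame, layout)
        np.testing.assert_array_equal(a, b)

    def test_one_pixel_registration_shift(self):
        rng = np.random.default_rng(1)
        frame = rng.integers(0, 1000, (20, 40)).astype(float)
        base = ChannelLayout(regions=[(2, 3, 10, 10)])
        shifted = ChannelLayout(regions=[(2, 3, 10, 10)], shifts=[(0, 1)])
        a = split_channels(frame, base)[0]
        b = split_channels(frame, shifted)[0]
        np.testing.assert_array_equal(b[:, :-1], a[:, 1:])

    def test_out_of_bounds_layout_rejected(self):
        frame = np.zeros((10, 10))
        with pytest.raises(ValueError, match="outside frame"):
            split_channels(frame, ChannelLayout(regions=[(5, 5, 10, 10)]))


class TestSegment:
    def test_blank_image_zero_components(self):
        seg = segment(np.zeros((32, 32)))
        assert seg.n_components == 0 and not seg.mask.any()

    def test_disk_area_within_5_percent(self):
        yy, xx = np.ogrid[:64, :64]
        img = ((yy - 32) ** 2 + (xx - 32) ** 2 <= 15**2) * 100.0
        seg = segment(img + np.random.default_rng(2).normal(0, 1, img.shape))
        assert seg.n_components == 1
        area = list(seg.counts.values())[0]
        assert area == pytest.approx(math.pi * 15**2, rel=0.05)

    def test_two_separated_disks_two_labels(self):
        yy, xx = np.ogrid[:64, :64]
        img = (((yy - 16) ** 2 + (xx - 16) ** 2 <= 8**2)
               | ((yy - 48) ** 2 + (xx - 48) ** 2 <= 8**2)) * 100.0
        assert segment(img).n_components == 2

    def test_labels_contiguous_from_one(self):
        yy, xx = np.ogrid[:64, :64]
        img = (((yy - 16) ** 2 + (xx - 16) ** 2 <= 8**2)
               | ((yy - 48) ** 2 + (xx - 48) ** 2 <= 8**2)) * 100.0
        seg = segment(img)
        assert sorted(seg.counts) == [1, 2]


class TestEnclosingBox:
    def test_full_rectangle_scores_one(self):
        m = np.zeros((30, 50), dtype=bool)
        m[5:25, 10:40] = True
        assert enclosing_box_ratio(m) == pytest.approx(1.0, abs=1e-9)

    def test_large_disk_approaches_pi_over_4(self):
        yy, xx = np.ogrid[:260, :260]
        m = (yy - 130) ** 2 + (xx - 130) ** 2 <= 120**2
        assert enclosing_box_ratio(m) == pytest.approx(math.pi / 4, abs=0.01)

    def test_matches_brute_force_rotation_search(self):
        """Rotating-calipers result equals exhaustive 0.1°-step search."""
        rng = np.random.default_rng(42)
        for _ in range(50):
            m = random_blob_mask(rng)
            fast = min_area_rect(m)
            brute = brute_force_min_rect(m)
            assert fast == pytest.approx(brute, rel=1e-3, abs=1e-6)

    def test_rotation_invariance_of_ratio(self):
        from scipy.ndimage import rotate

        yy, xx = np.ogrid[:120, :120]
        m = ((yy - 60) ** 2 / 35**2 + (xx - 60) ** 2 / 18**2) <= 1.0
        base = enclosing_box_ratio(m)
        for ang in (17.0, 45.0, 73.0):
            mr = rotate(m.astype(float), ang, reshape=True, order=1) > 0.5
            assert abs(enclosing_box_ratio(mr) - base) < 0.02

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            enclosing_box_ratio(np.zeros((5, 5), dtype=bool))


class TestCountDroplets:
    @staticmethod
    def spots_image(positions, amp=200.0, sigma=1.5, shape=(80, 80)):
        yy, xx = np.mgrid[:shape[0], :shape[1]]
        img = np.zeros(shape)
        for r, c in positions:
            img += amp * np.exp(-((yy - r) ** 2 + (xx - c) ** 2) / (2 * sigma**2))
        return img

    def test_blank_image_zero(self):
        assert count_droplets(np.zeros((40, 40)), 5, 10.0) == (0, [])

    def test_exact_recovery_of_separated_spots(self):
        true = [(20, 20), (20, 60), (60, 40), (50, 15), (65, 70)]
        img = self.spots_image(true)
        n, pos = count_droplets(img, 5, 100.0)
        assert n == len(true)
        for r, c in true:
            assert min(math.hypot(r - a, c - b) for a, b in pos) <= 1.0

    def test_sub_threshold_spots_ignored(self):
        img = self.spots_image([(20, 20), (60, 60)], amp=80.0)
        assert count_droplets(img, 5, 100.0)[0] == 0

    def test_offset_invariance(self):
        true = [(20, 20), (60, 60)]
        img = self.spots_image(true)
        n0, _ = count_droplets(img, 5, 100.0)
        n1, _ = count_droplets(img + 500.0, 5, 100.0)
        assert n0 == n1 == 2

    def test_amplitude_monotonicity(self):
        """Counts never decrease as amplitude grows past the threshold."""
        true = [(20, 20), (60, 60), (30, 55)]
        counts = [count_droplets(self.spots_image(true, amp=a), 5, 100.0)[0]
                  for a in (50.0, 110.0, 400.0)]
        assert counts == sorted(counts)

    def test_plateau_resolved_to_centroid(self):
        img = np.zeros((30, 30))
        img[10:13, 10:13] = 50.0  # 3x3 flat plateau
        n, pos = count_droplets(img, 5, 10.0)
        assert n == 1
        assert pos[0] == pytest.approx((11.0, 11.0))


class TestCellFeatures:
    def test_disk_area_and_units(self):
        yy, xx = np.ogrid[:64, :64]
        m = (yy - 32) ** 2 + (xx - 32) ** 2 <= 20**2
        f = cell_features(m, pixel_size=0.325)
        assert f["area_um2"] == pytest.approx(math.pi * 6.5**2, rel=0.05)

    def test_square_aspect_ratio_unity(self):
        m = np.zeros((40, 40), dtype=bool)
        m[10:30, 10:30] = True
        assert cell_features(m, 1.0)["aspect_ratio"] == pytest.approx(1.0, abs=1e-6)

    def test_scaling_laws(self):
        yy, xx = np.ogrid[:128, :128]
        m1 = (yy - 64) ** 2 + (xx - 64) ** 2 <= 15**2
        m2 = (yy - 64) ** 2 + (xx - 64) ** 2 <= 30**2
        f1, f2 = cell_features(m1, 1.0), cell_features(m2, 1.0)
        assert f2["area_um2"] == pytest.approx(4 * f1["area_um2"], rel=0.05)
        assert f2["perimeter_um"] == pytest.approx(2 * f1["perimeter_um"], rel=0.05)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            cell_features(np.zeros((5, 5), dtype=bool), 1.0)


class TestDropletAreaStats:
    def test_single_droplet_mean_is_its_area(self):
        lbl = np.zeros((20, 20), dtype=int)
        lbl[5:8, 5:8] = 1  # 9 px
        s = droplet_area_stats(lbl, pixel_size=0.5)
        assert s["droplet_count"] == 1
        assert s["mean_droplet_area_um2"] == pytest.approx(9 * 0.25)

    def test_two_droplets_arithmetic_mean(self):
        lbl = np.zeros((20, 20), dtype=int)
        lbl[2:4, 2:4] = 1   # 4 px
        lbl[10:14, 10:14] = 2  # 16 px
        s = droplet_area_stats(lbl, 1.0)
        assert s["mean_droplet_area_um2"] == pytest.approx(10.0)

    def test_zero_droplets_mean_undefined_not_zero(self):
        s = droplet_area_stats(np.zeros((10, 10), dtype=int), 1.0)
        assert s["droplet_count"] == 0
        assert math.isnan(s["mean_droplet_area_um2"])


class TestFitPsf:
    def test_noiseless_gaussian_identity(self):
        yy, xx = np.mgrid[:31, :31]
        crop = 50 + 500 * np.exp(-(((yy - 15) ** 2) + (xx - 15) ** 2) / (2 * 1.0**2))
        est = fit_psf(crop, pixel_size=1.0)
        assert est.converged
        assert est.fwe1m_x_um == pytest.approx(2 * math.sqrt(2), abs=1e-3)
        assert est.fwe1m_y_um == pytest.approx(2 * math.sqrt(2), abs=1e-3)
        # FWe1M identity with the fitted sigma
        assert est.fwe1m_x_um == pytest.approx(2 * math.sqrt(2) * est.sigma_x_um)

    def test_anisotropic_widths_recovered(self):
        yy, xx = np.mgrid[:41, :41]
        crop = 10 + 300 * np.exp(-((yy - 20) ** 2) / (2 * 2.0**2)
                                 - ((xx - 20) ** 2) / (2 * 1.2**2))
        est = fit_psf(crop, pixel_size=0.325)
        assert est.sigma_x_um == pytest.approx(1.2 * 0.325, rel=1e-3)
        assert est.sigma_y_um == pytest.approx(2.0 * 0.325, rel=1e-3)

    def test_flat_crop_flagged_not_raised(self):
        est = fit_psf(np.full((15, 15), 7.0), 1.0)
        assert not est.converged

    def test_center_recovery_on_rendered_beads(self, design, modes, noise):
        """Median localization error < 0.2 px at SNR > 10 on simulated beads."""
        from viffi import render_bead_field

        f = render_bead_field(80, design, modes["VIFFI"], noise, seed=17,
                              bead_rate=10.0)
        px = f.pixel_size_um
        img = f.channels[0].astype(float)
        errs = []
        for x, y in f.ground_truth["bead_positions_um"]:
            c = int(round(x / px - 0.5))
            r = int(round(y / px - 0.5))
            if r < 8 or c < 8 or r + 9 > img.shape[0] or c + 9 > img.shape[1]:
                continue
            est = fit_psf(img[r - 8:r + 9, c - 8:c + 9], px)
            if est.converged:
                ex = est.center_x_um - (x - (c - 8) * px)
                ey = est.center_y_um - (y - (r - 8) * px)
                errs.append(math.hypot(ex, ey))
        assert len(errs) >= 50
        assert np.median(errs) < 0.2 * px


class TestExport:
    @staticmethod
    def records():
        return [
            CellRecord(cell_id=0, frame=0, x_um=10.0, y_um=5.0, area_um2=100.0,
                       perimeter_um=35.0, aspect_ratio=1.1,
                       nucleus_area_um2=40.0, box_area_um2=50.0, box_ratio=0.8,
                       droplet_count=2, mean_droplet_area_um2=0.5),
            CellRecord(cell_id=1, frame=0, x_um=20.0, y_um=6.0, area_um2=90.0,
                       perimeter_um=33.0, aspect_ratio=1.4,
                       nucleus_area_um2=30.0, box_area_um2=60.0, box_ratio=0.5,
                       droplet_count=0),
        ]

    def test_csv_round_trip(self, tmp_path):
        import pandas as pd

        path = tmp_path / "features.csv"
        df = export_features(self.records(), path)
        back = pd.read_csv(path)
        pd.testing.assert_frame_equal(back, df)

    def test_row_and_column_contract(self, tmp_path):
        path = tmp_path / "features.csv"
        df = export_features(self.records(), path)
        assert len(df) == 2
        assert list(df.columns) == [
            "frame", "cell_id", "x_um", "y_um", "area_um2", "perimeter_um",
            "aspect_ratio", "nucleus_area_um2", "box_area_um2", "box_ratio",
            "droplet_count", "mean_droplet_area_um2"]
        assert path.read_text().count("\n") == 3  # header + 2 rows

    def test_crop_centered_on_centroid(self, tmp_path):
        import tifffile

        frame = np.zeros((80, 80), dtype=np.uint16)
        frame[40, 30] = 999  # bright pixel at the known centroid
        rec = CellRecord(cell_id=0, x_um=30.0, y_um=40.0)
        paths = export_crops(frame, [rec], pixel_size=1.0, out_dir=tmp_path,
                             crop_px=16)
        crop = tifffile.imread(paths[0])
        peak = np.unravel_index(np.argmax(crop), crop.shape)
        assert abs(peak[0] - 8) <= 1 and abs(peak[1] - 8) <= 1

    def test_empty_records_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            export_features([], tmp_path / "x.csv")
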