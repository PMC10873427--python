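"""Thresholding, particle counting and per-group summaries for field images."""

import numpy as np
import pandas as pd
import pytest

from retinaggr import fields
from retinaggr.synth import make_field_image


def _field(pixels, pixel_size=1.0):
    pixels = np.asarray(pixels, float)
    h, w = pixels.shape
    return fields.FieldImage(
        pixels=pixels, pixel_size=pixel_size,
        field_size=(w * pixel_size, h * pixel_size),
    )


def _disk_grid(n_disks, radius=5, spacing=20, shape=(120, 120)):
    """Disjoint disks on a regular lattice; returns the boolean grid."""
    grid = np.zeros(shape, dtype=bool)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    placed = 0
    for row in range(10, shape[0] - 10, spacing):
        for col in range(10, shape[1] - 10, spacing):
            if placed >= n_disks:
                return grid
            grid |= (yy - row) ** 2 + (xx - col) ** 2 <= radius**2
            placed += 1
    assert placed >= n_disks, "fixture lattice too small"
    return grid


class TestBinarize:
    def test_constant_below_threshold(self):
        binary, _ = fields.binarize(_field(np.full((8, 8), 5.0) + np.eye(8)), threshold=50.0)
        assert not binary.any()

    def test_threshold_at_minimum_selects_all(self):
        img = _field(np.arange(64, dtype=float).reshape(8, 8))
        binary, _ = fields.binarize(img, threshold=0.0)
        assert binary.all()

    def test_auto_threshold_separates_modes(self):
        rng = np.random.default_rng(0)
        low = rng.normal(20, 3, 2000)
        high = rng.normal(200, 3, 2000)
        img = _field(np.concatenate([low, high]).reshape(80, 50), pixel_size=1.0)
        _, thr = fields.binarize(img, "auto")
        # the threshold lands in the inter-mode gap: it cleanly splits the
        # two populations
        assert (low >= thr).mean() < 0.01
        assert (high >= thr).mean() > 0.99

    def test_out_of_range_threshold_selects_all_or_nothing(self):
        img = _field(np.eye(8) + 1.0)
        all_true, _ = fields.binarize(img, threshold=-5.0)
        none_true, _ = fields.binarize(img, threshold=99.0)
        assert all_true.all() and not none_true.any()

    def test_non_finite_threshold_rejected(self):
        with pytest.raises(fields.FieldError):
            fields.binarize(_field(np.eye(8)), threshold=float("nan"))


class TestCountParticles:
    def test_twelve_disjoint_disks(self):
        binary = _disk_grid(12, radius=5)
        res = fields.count_particles(binary, pixel_size=1.0, min_area=10.0)
        assert res.count == 12

    def test_empty_grid(self):
        res = fields.count_particles(np.zeros((32, 32), dtype=bool), pixel_size=1.0)
        assert res.count == 0

    def test_min_area_excludes_small_disks(self):
        # 7 big disks (r=5, area ~78 px) + 3 single pixels
        binary = _disk_grid(7, radius=5)
        binary[2, 2] = binary[2, 110] = binary[110, 2] = True
        res = fields.count_particles(binary, pixel_size=1.0, min_area=10.0)
        assert res.count == 7

    def test_connectivity_agnostic_on_disjoint_disks(self):
        binary = _disk_grid(9, radius=4)
        c4 = fields.count_particles(binary, 1.0, connectivity=4).count
        c8 = fields.count_particles(binary, 1.0, connectivity=8).count
        assert c4 == c8 == 9

    def test_count_monotone_in_min_area(self):
        img, _ = make_field_image(12, radius_range=(2, 6), seed=3)
        binary, _ = fields.binarize(img, "auto")
        counts = [
            fields.count_particles(binary, img.pixel_size, min_area=a).count
            for a in (1.0, 10.0, 40.0, 120.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_count_monotone_in_threshold(self):
        """On a noise-free tiered-brightness field, raising the threshold
        removes whole objects and can never raise the count."""
        img = np.zeros((80, 80))
        yy, xx = np.mgrid[0:80, 0:80]
        for row, col, level in [(15, 15, 50), (15, 55, 100), (55, 15, 150), (55, 55, 200)]:
            img[(yy - row) ** 2 + (xx - col) ** 2 <= 16] = level
        field = _field(img)
        counts = []
        for thr in (25.0, 75.0, 125.0, 175.0):
            binary, _ = fields.binarize(field, thr)
            counts.append(fields.count_particles(binary, 1.0, min_area=5.0).count)
        assert counts == [4, 3, 2, 1]

    def test_background_offset_invariance(self):
        img, _ = make_field_image(10, seed=5)
        res0 = fields.count_field(img, threshold=100.0)
        shifted = fields.FieldImage(
            pixels=img.pixels + 10.0, pixel_size=img.pixel_size,
            field_size=img.field_size,
        )
        res1 = fields.count_field(shifted, threshold=110.0)
        assert res0.count == res1.count


class TestGeneratedFields:
    def test_counts_match_ground_truth(self):
        for seed in range(10):
            img, manifest = make_field_image(12, seed=seed)
            res = fields.count_field(img)
            assert res.count == manifest.parameters["n_particles"]

    def test_blank_field(self):
        img, _ = make_field_image(0, seed=0)
        assert fields.count_field(img).count == 0


class TestCountsSummary:
    def test_group_mean_and_sd(self):
        df = fields.counts_summary({("TUNEL", "superior", 0.5, "het"): [3, 5]})
        row = df.iloc[0]
        assert row["mean"] == 4.0
        assert row["sd"] == pytest.approx(np.sqrt(2))
        assert row["n"] == 2

    def test_single_member_sd_flagged(self):
        df = fields.counts_summary({("TUNEL", "superior", 0.5, "het"): [3]})
        assert df.iloc[0]["n"] == 1
        assert pd.isna(df.iloc[0]["sd"])

    def test_ordering(self):
        df = fields.counts_summary(
            {
                ("TUNEL", "superior", 0.75, "het"): [3],
                ("PROTEOSTAT", "inferior", 0.5, "homo"): [9],
                ("PROTEOSTAT", "inferior", 0.5, "het"): [4],
            }
        )
        keys = list(zip(df["stain"], df["region"], df["age"], df["genotype"]))
        assert keys == sorted(keys)

    def test_poisson_cohort_mean(self):
        """n = 4 mice with Poisson(20) counts: group mean within 3 SE of 20."""
        rng = np.random.default_rng(11)
        counts = rng.poisson(20, size=4).tolist()
        df = fields.counts_summary({("TUNEL", "superior", 0.5, "het"): counts})
        se = np.sqrt(20 / 4)
        assert abs(df.iloc[0]["mean"] - 20) < 3 * se
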