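"""Descriptor suite: closed forms, invariances, and the Feret oracle."""

import math

import numpy as np
import pytest

from myoshape.shapes import (
    compute_shape_profile,
    neighbor_distances,
    profile_objects,
    summarize_image,
)

from conftest import random_blob, rectangle_mask, sweep_feret


class TestDiskDescriptors:
    def test_circle_normalisations(self, disk50):
        p = compute_shape_profile(disk50, 1)
        assert p.compactness == pytest.approx(1.0, rel=0.02)
        assert p.form_factor == pytest.approx(1.0, rel=0.02)
        assert p.eccentricity < 0.05

    def test_disk_sizes(self, disk50):
        p = compute_shape_profile(disk50, 1)
        assert p.area_shape == np.count_nonzero(disk50)
        assert p.equivalent_diameter == pytest.approx(100.0, rel=0.01)
        assert p.major_axis_length == pytest.approx(100.0, rel=0.01)
        assert p.maximum_radius == pytest.approx(50.0, abs=1.0)
        assert p.max_feret_diameter == pytest.approx(101.0, rel=0.01)


@pytest.mark.parametrize("w,h", [(30, 4), (20, 10), (15, 15)])
def test_rectangle_closed_forms(w, h):
    p = compute_shape_profile(rectangle_mask(w, h), 1)
    assert p.area_shape == w * h
    assert p.bounding_box_area == w * h
    assert p.extent == 1.0
    assert p.solidity == pytest.approx(1.0, rel=0.01)
    assert p.min_feret_diameter == pytest.approx(min(w, h), abs=1.0)
    assert p.max_feret_diameter == pytest.approx(math.hypot(w, h), abs=1.0)


def test_square_major_axis_is_moment_based():
    # 10x10 square: eigenvalue (99+1)/12 -> axis length 4*sqrt(100/12)
    p = compute_shape_profile(rectangle_mask(10, 10), 1)
    assert p.major_axis_length == pytest.approx(4 * math.sqrt(100 / 12), rel=1e-6)
    assert p.minor_axis_length == pytest.approx(p.major_axis_length, rel=1e-6)


def test_single_pixel_is_finite():
    m = np.zeros((5, 5), dtype=np.int32)
    m[2, 2] = 1
    p = compute_shape_profile(m, 1)
    assert p.major_axis_length == pytest.approx(4 * math.sqrt(1 / 12))
    assert p.min_feret_diameter == pytest.approx(1.0)
    assert p.maximum_radius == 1.0


def test_missing_label_raises(disk50):
    with pytest.raises(ValueError, match="not present"):
        compute_shape_profile(disk50, 7)


def test_feret_matches_rotation_sweep_oracle():
    rng = np.random.default_rng(11)
    for _ in range(20):
        blob = random_blob(rng)
        p = compute_shape_profile(blob, 1)
        coords = np.column_stack(np.nonzero(blob == 1)).astype(float)
        lo, hi = sweep_feret(coords)
        assert p.min_feret_diameter == pytest.approx(lo, rel=0.005)
        assert p.max_feret_diameter == pytest.approx(hi, rel=0.005)


def test_isodiametric_bound_on_random_blobs():
    rng = np.random.default_rng(4)
    for _ in range(25):
        p = compute_shape_profile(random_blob(rng), 1)
        assert p.equivalent_diameter <= p.max_feret_diameter + 1e-9
        assert p.min_feret_diameter <= p.max_feret_diameter
        assert p.minor_axis_length <= p.major_axis_length
        assert 0 <= p.eccentricity < 1
        assert 0 < p.extent <= 1
        assert 0 < p.solidity <= 1 + 1e-9


def test_translation_invariance_exact():
    rng = np.random.default_rng(7)
    blob = random_blob(rng)
    shifted = np.zeros((blob.shape[0] + 13, blob.shape[1] + 9), dtype=np.int32)
    shifted[13:, 9:] = blob
    a = compute_shape_profile(blob, 1)
    b = compute_shape_profile(shifted, 1)
    for field in (
        "area_shape", "bounding_box_area", "compactness", "eccentricity",
        "equivalent_diameter", "extent", "form_factor", "major_axis_length",
        "max_feret_diameter", "maximum_radius", "mean_radius", "median_radius",
        "min_feret_diameter", "minor_axis_length", "perimeter", "solidity",
    ):
        assert getattr(a, field) == pytest.approx(getattr(b, field), rel=1e-12)
    assert b.centroid[0] == pytest.approx(a.centroid[0] + 13)


def test_quarter_rotation_invariance():
    rng = np.random.default_rng(9)
    blob = random_blob(rng)
    rotated = np.rot90(blob).copy()
    a = compute_shape_profile(blob, 1)
    b = compute_shape_profile(rotated, 1)
    for field in (
        "area_shape", "perimeter", "min_feret_diameter", "max_feret_diameter",
        "maximum_radius", "mean_radius", "median_radius", "solidity",
        "major_axis_length", "minor_axis_length", "eccentricity",
    ):
        assert getattr(a, field) == pytest.approx(getattr(b, field), rel=1e-9)


def test_elongation_monotonicity():
    # fixed area 240, growing aspect ratio
    shapes = [(20, 12), (30, 8), (40, 6), (60, 4)]
    profs = [compute_shape_profile(rectangle_mask(w, h), 1) for w, h in shapes]
    ecc = [p.eccentricity for p in profs]
    fmax = [p.max_feret_diameter for p in profs]
    ff = [p.form_factor for p in profs]
    assert all(x < y for x, y in zip(ecc, ecc[1:]))
    assert all(x < y for x, y in zip(fmax, fmax[1:]))
    assert all(x > y for x, y in zip(ff, ff[1:]))


class TestNeighborDistances:
    def _mask_with_points(self, points, size=64):
        m = np.zeros((size, size), dtype=np.int32)
        for k, (r, c) in enumerate(points, start=1):
            m[r - 1 : r + 2, c - 1 : c + 2] = k
        return m

    def test_collinear_triplet(self):
        m = self._mask_with_points([(5, 5), (5, 15), (5, 30)])
        profs = profile_objects(m)
        first = profs.set_index("label")["first_closest_distance"]
        second = profs.set_index("label")["second_closest_distance"]
        assert first[1] == pytest.approx(10.0)
        assert second[1] == pytest.approx(25.0)

    def test_singleton_undefined(self):
        m = self._mask_with_points([(5, 5)])
        profs = profile_objects(m)
        assert np.isnan(profs["first_closest_distance"]).all()
        assert np.isnan(profs["second_closest_distance"]).all()

    def test_pair_symmetry(self):
        m = self._mask_with_points([(5, 5), (20, 25)])
        profs = profile_objects(m)
        d = profs["first_closest_distance"]
        assert d.iloc[0] == pytest.approx(d.iloc[1])
        assert np.isnan(profs["second_closest_distance"]).all()


class TestSummarizeImage:
    def test_totals_and_means(self):
        from skimage.morphology import disk as _disk

        m = np.zeros((120, 220), dtype=np.int32)
        d1, d2 = _disk(10), _disk(20)
        m[10 : 10 + d1.shape[0], 10 : 10 + d1.shape[1]] = d1
        m[30 : 30 + d2.shape[0], 120 : 120 + d2.shape[1]] = d2 * 2
        s = summarize_image(m)
        a1, a2 = d1.sum(), d2.sum()
        assert s.n_objects == 2
        assert s.total_area_occupied == a1 + a2
        assert s.means["area_shape"] == pytest.approx((a1 + a2) / 2)

    def test_single_object_sd_flagged(self, disk50):
        s = summarize_image(disk50)
        assert s.n_objects == 1
        assert np.isnan(s.sds["area_shape"])
        assert s.means["area_shape"] == np.count_nonzero(disk50)

    def test_relabel_invariance(self):
        rng = np.random.default_rng(3)
        blob = random_blob(rng)
        blob2 = np.where(blob > 0, 9, 0).astype(np.int32)
        s1, s2 = summarize_image(blob), summarize_image(blob2)
        assert s1.total_area_occupied == s2.total_area_occupied
        assert np.allclose(
            s1.means.fillna(0).values, s2.means.fillna(0).values
        )

    def test_empty_mask(self):
        s = summarize_image(np.zeros((10, 10), dtype=np.int32))
        assert s.n_objects == 0
        assert s.total_area_occupied == 0
        assert np.isnan(s.means["area_shape"])
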