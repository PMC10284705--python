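"""Segmentation, track linking, geometry and response classification."""

import itertools

import numpy as np
import pytest

import stamparray as sa
from stamparray.segment import SegmentationError, feret_diameter


class TestSegmentFrame:
    def test_blank_frame_yields_no_objects(self):
        lab = sa.segment_frame(np.zeros((64, 64)))
        assert lab.max() == 0

    def test_segmentation_is_deterministic(self, static_mixed_render):
        series, _ = static_mixed_render
        frame = series.frame("tumour", 0)
        np.testing.assert_array_equal(sa.segment_frame(frame), sa.segment_frame(frame))

    def test_recovers_rendered_blobs_with_accurate_areas(self, static_mixed_truth, static_mixed_render):
        series, labels = static_mixed_render
        seg = sa.segment_frame(series.frame("tumour", 0))
        assert seg.max() == static_mixed_truth.n_tumours
        px_mm2 = (series.pixel_size_um / 1000.0) ** 2
        for t in static_mixed_truth.tumours:
            gt_mask = labels[0] == t.tumour_id + 1
            seg_ids, counts = np.unique(seg[gt_mask], return_counts=True)
            seg_id = seg_ids[counts.argmax()]
            assert seg_id > 0
            area = (seg == seg_id).sum() * px_mm2
            assert area == pytest.approx(t.area_seq[0], rel=0.10)


class TestGeometry:
    def test_square_area_and_feret_match_brute_force(self):
        """100x100 px solid square at 10 µm/px: 1 mm² area; Feret equals
        the exhaustive max pairwise distance over boundary pixels."""
        mask = np.zeros((120, 120), dtype=bool)
        mask[10:110, 10:110] = True
        m = sa.measure_mask(mask, 10.0)
        assert m["area_mm2"] == pytest.approx(1.0)
        # independent oracle: all pairwise distances over boundary pixels
        eroded = np.zeros_like(mask)
        eroded[11:109, 11:109] = True
        pts = np.argwhere(mask & ~eroded).astype(float)
        best = max(float(np.hypot(*(a - b))) for a, b in itertools.combinations(pts, 2))
        assert m["feret_um"] == pytest.approx(best * 10.0, abs=1e-9)
        assert m["feret_um"] == pytest.approx(99 * np.sqrt(2) * 10.0)

    def test_random_blob_feret_matches_exhaustive_pairs(self):
        rng = np.random.default_rng(0)
        mask = np.zeros((40, 40), dtype=bool)
        pts = rng.integers(8, 32, size=(30, 2))
        mask[pts[:, 0], pts[:, 1]] = True
        from scipy.ndimage import binary_erosion
        boundary = np.argwhere(mask & ~binary_erosion(mask)).astype(float)
        oracle = max(
            float(np.hypot(*(a - b))) for a, b in itertools.combinations(boundary, 2)
        )
        assert feret_diameter(mask, 1.0) == pytest.approx(oracle, abs=1e-12)

    def test_single_pixel(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 2] = True
        m = sa.measure_mask(mask, 10.0)
        assert m["area_mm2"] == pytest.approx(1e-4)
        assert m["feret_um"] == 0.0

    def test_empty_mask_flagged(self):
        m = sa.measure_mask(np.zeros((5, 5), dtype=bool), 10.0)
        assert m["area_mm2"] == 0.0
        assert np.isnan(m["feret_um"])


def _disc_labels(centres_by_frame, shape=(80, 80), radius=5):
    out = []
    for centres in centres_by_frame:
        lab = np.zeros(shape, dtype=int)
        for k, (cy, cx) in enumerate(centres):
            yy, xx = np.mgrid[: shape[0], : shape[1]]
            lab[np.hypot(yy - cy, xx - cx) <= radius] = k + 1
        out.append(lab)
    return np.stack(out)


class TestLinking:
    def test_static_blobs_give_one_full_track_each(self):
        frames = _disc_labels([[(20, 20), (60, 60)]] * 5)
        tracks = sa.link_tracks(frames, days=[1, 2, 3, 4, 5], pixel_size_um=10)
        assert len(tracks) == 2
        for t in tracks:
            assert t.days == [1, 2, 3, 4, 5]

    def test_vanishing_blob_ends_its_track(self):
        frames = _disc_labels([[(20, 20), (60, 60)]] * 2 + [[(20, 20)]] * 2)
        tracks = sa.link_tracks(frames, days=[1, 2, 3, 4], pixel_size_um=10)
        assert len(tracks) == 2
        last = sorted(t.last_detected_day for t in tracks)
        assert last == [2, 4]

    def test_mutual_nearest_equals_min_total_distance_on_crossing(self):
        """Two approaching blobs: the mutual-nearest assignment coincides
        with the exhaustive minimum-total-distance matching over both
        permutations, so no identity swap occurs."""
        f0 = [(30, 20), (30, 60)]
        f1 = [(30, 30), (30, 50)]
        frames = _disc_labels([f0, f1])
        tracks = sa.link_tracks(frames, days=[1, 2], pixel_size_um=10, max_displacement_um=400)
        # brute-force matching oracle
        d = np.array([[np.hypot(a[0] - b[0], a[1] - b[1]) for b in f1] for a in f0])
        perms = [(0, 1), (1, 0)]
        best = min(perms, key=lambda p: d[0, p[0]] + d[1, p[1]])
        assert len(tracks) == 2
        for i, t in enumerate(sorted(tracks, key=lambda t: t.centroid[1][1])):
            assert t.centroid[2][1] == pytest.approx(f1[best[i]][1], abs=0.5)

    def test_linking_invariant_to_label_permutation(self):
        frames = _disc_labels([[(20, 20), (60, 60)]] * 3)
        swapped = frames.copy()
        swapped[1][frames[1] == 1] = 99
        swapped[1][frames[1] == 2] = 1
        swapped[1][swapped[1] == 99] = 2
        a = sa.link_tracks(frames, [1, 2, 3], 10)
        b = sa.link_tracks(swapped, [1, 2, 3], 10)
        cen_a = sorted(tuple(t.centroid[d] for d in t.days) for t in a)
        cen_b = sorted(tuple(t.centroid[d] for d in t.days) for t in b)
        assert cen_a == cen_b


class TestResponse:
    @pytest.mark.parametrize(
        "areas, detected, expected",
        [
            ([1, 2, 3], [1, 1, 1], "SD/PD"),
            ([1, 4, 3], [1, 1, 1], "PR"),            # (4-3)/4 = 25% >= 20%
            ([1, 2, 0, 0], [1, 1, 0, 0], "CR"),
            ([1, 1.05, 1.1], [1, 1, 1], "SD/PD"),
        ],
    )
    def test_response_rules(self, areas, detected, expected):
        assert sa.classify_response(areas, detected) == expected

    def test_single_frame_dropout_is_not_cr(self):
        assert sa.classify_response([1, 2, 0], [1, 1, 0]) != "CR"

    def test_sd_pd_split_flag(self):
        assert sa.classify_response([1, 1.5, 1.6], [1, 1, 1], split_sd_pd=True) == "PD"
        assert sa.classify_response([1, 1.05, 1.1], [1, 1, 1], split_sd_pd=True) == "SD"

    def test_never_detected_rejected(self):
        with pytest.raises(SegmentationError):
            sa.classify_response([0, 0], [0, 0])
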