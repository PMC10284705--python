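"""Phenotype rule set: ratiometric calls, cohort references, precedence,
timeline encoding, and end-to-end soundness on noise-free renders."""

import numpy as np
import pandas as pd
import pytest

import stamparray as sa
from stamparray.classify import RULE_TAGS
from stamparray.profiles import RadialProfile


def profile_from(values):
    values = np.asarray(values, dtype=float)
    return RadialProfile(np.linspace(0, 1, len(values) + 1), values)


class TestRatiometricCall:
    def test_inner_bins_at_max_is_inflamed(self):
        prof = profile_from([1, 1, 1, 1, 1, 0.2, 0.2, 0.2])  # 8 bins, inner 2 = max
        assert sa.ratiometric_call(prof) == "inflamed"

    def test_inner_bins_at_tenth_of_max_is_excluded(self):
        prof = profile_from([0.1, 0.1, 0.1, 0.1, 0.1, 0.3, 0.8, 1.0])
        assert sa.ratiometric_call(prof) == "excluded"

    def test_inner_bins_at_half_max_is_indeterminate(self):
        prof = profile_from([0.5, 0.5, 0.5, 0.5, 0.5, 0.7, 0.9, 1.0])
        assert sa.ratiometric_call(prof) == "indeterminate"

    def test_all_zero_profile_is_indeterminate(self):
        prof = profile_from([0.0, 0.0, 0.0, 1e-12])
        prof.median_intensity[:] = 0.0
        assert sa.ratiometric_call(prof) == "indeterminate"

    def test_call_invariant_to_per_tumour_rescaling(self):
        vals = [0.1, 0.1, 0.1, 0.1, 0.5, 0.8, 1.0, 0.9]
        assert sa.ratiometric_call(profile_from(vals)) == sa.ratiometric_call(
            profile_from([37.0 * v for v in vals])
        )


class TestCohortRefs:
    def test_linear_interpolation_percentile(self):
        assert sa.desert_threshold([1, 2, 3, 4]) == pytest.approx(1.75)

    def test_identical_cohort_gives_common_value(self):
        assert sa.desert_threshold([2.5] * 6) == pytest.approx(2.5)

    def test_single_tumour_cohort(self):
        assert sa.desert_threshold([3.2]) == pytest.approx(3.2)


class TestDailyPrecedence:
    def test_excluded_with_hot_core_reclassified_inflamed(self):
        code, tag = sa.classify_day("excluded", 9.0, 5.0, 1.0, 4.0, prev_code=None)
        assert (code, tag) == (3, "reclassified")

    def test_excluded_with_cold_core_stays_excluded(self):
        code, tag = sa.classify_day("excluded", 1.0, 5.0, 1.0, 4.0, prev_code=None)
        assert (code, tag) == (2, "excluded-rule")

    def test_indeterminate_below_threshold_is_desert(self):
        code, tag = sa.classify_day("indeterminate", 1.0, 0.5, 1.0, None, prev_code=2)
        assert (code, tag) == (1, "desert-rule")

    def test_indeterminate_above_threshold_propagates(self):
        code, tag = sa.classify_day("indeterminate", 1.0, 5.0, 1.0, None, prev_code=2)
        assert (code, tag) == (2, "propagated")

    def test_first_day_indeterminate_defaults_excluded(self):
        code, tag = sa.classify_day("indeterminate", 1.0, 5.0, 1.0, None, prev_code=None)
        assert (code, tag) == (2, "first-day-default")

    def test_reclassification_disabled_without_inflamed_reference(self):
        code, tag = sa.classify_day("excluded", 9.0, 5.0, 1.0, None, prev_code=None)
        assert (code, tag) == (2, "excluded-rule")


class TestEncodeTimeline:
    def test_resolution_pads_with_fives(self):
        codes, tags = sa.encode_timeline([1, 2, 3, 3, 3], [1, 1, 1, 0, 0])
        assert list(codes) == [1, 2, 3, 5, 5]
        assert tags[3] == tags[4] == "resolved"

    def test_death_pads_with_zeros(self):
        codes, tags = sa.encode_timeline([2, 2, 2, 2], [1, 1, 1, 1], death_from_index=2)
        assert list(codes) == [2, 2, 0, 0]
        assert tags[2] == "death"

    def test_no_events_leaves_codes_unchanged(self):
        codes, tags = sa.encode_timeline([1, 2, 3], [1, 1, 1])
        assert list(codes) == [1, 2, 3]
        assert all(t == "" for t in tags)

    def test_death_wins_same_day_conflict(self):
        codes, _ = sa.encode_timeline([2, 2, 2, 2], [1, 1, 0, 0], death_from_index=2)
        assert list(codes) == [2, 2, 0, 0]

    def test_single_frame_dropout_not_resolved(self):
        codes, _ = sa.encode_timeline([2, 2, 2], [1, 1, 0])
        assert list(codes) == [2, 2, 2]


def _cohort_day_table():
    """Hand-built classifier inputs exercising every provenance tag."""
    rows = [
        # day 1: fix the desert threshold via medians {0, 4, 5, 6} -> 25th pct = 3
        (0, 1, True, "indeterminate", 0.0, 0.0),   # desert-rule
        (1, 1, True, "excluded", 0.5, 4.0),        # excluded-rule
        (2, 1, True, "inflamed", 8.0, 5.0),        # inflamed-rule
        (3, 1, True, "indeterminate", 5.0, 6.0),   # first-day-default
        # day 2
        (0, 2, True, "indeterminate", 0.0, 0.5),   # desert-rule again
        (1, 2, True, "excluded", 9.0, 4.0),        # hot core -> reclassified
        (2, 2, True, "inflamed", 8.0, 5.0),
        (3, 2, True, "indeterminate", 5.0, 6.0),   # propagated (2)
        # day 3: tumour 2 undetected from here on (-> resolved); 3 dies
        (0, 3, True, "indeterminate", 0.0, 0.5),
        (1, 3, True, "inflamed", 9.0, 6.0),
        (2, 3, False, np.nan, np.nan, np.nan),
        (3, 3, True, "indeterminate", 5.0, 6.0),
        (0, 4, True, "indeterminate", 0.0, 0.5),
        (1, 4, True, "inflamed", 9.0, 6.0),
        (2, 4, False, np.nan, np.nan, np.nan),
        (3, 4, True, "indeterminate", 5.0, 6.0),
    ]
    return pd.DataFrame(
        rows, columns=["tumour_id", "day", "detected", "call", "core_intensity", "median_tcell"]
    )


class TestCohortClassification:
    def test_every_provenance_tag_is_exercised(self):
        timelines, refs = sa.classify_cohort(_cohort_day_table(), death_day={3: 3})
        assert refs.desert_threshold == pytest.approx(3.0)
        tags = set(timelines["rule_tag"])
        assert tags == {
            "desert-rule", "excluded-rule", "inflamed-rule", "reclassified",
            "propagated", "first-day-default", "resolved", "death",
        }
        assert set(tags) <= set(RULE_TAGS)

    def test_codes_follow_rules_and_absorbing_overlays(self):
        timelines, _ = sa.classify_cohort(_cohort_day_table(), death_day={3: 3})
        by = {
            tid: grp.sort_values("day")["code"].tolist()
            for tid, grp in timelines.groupby("tumour_id")
        }
        assert by[0] == [1, 1, 1, 1]
        assert by[1] == [2, 3, 3, 3]
        assert by[2] == [3, 3, 5, 5]
        assert by[3] == [2, 2, 0, 0]

    def test_tag_counts_reconcile_with_tumour_days(self):
        timelines, _ = sa.classify_cohort(_cohort_day_table(), death_day={3: 3})
        assert timelines["rule_tag"].value_counts().sum() == len(timelines) == 16

    def test_classification_is_deterministic(self):
        a, _ = sa.classify_cohort(_cohort_day_table(), death_day={3: 3})
        b, _ = sa.classify_cohort(_cohort_day_table(), death_day={3: 3})
        assert a.equals(b)


class TestRenderSoundness:
    def test_noise_free_renders_classified_perfectly(self, static_mixed_truth, static_mixed_render):
        """Desert/excluded/inflamed renders are recovered on 100% of days
        with no propagation needed."""
        series, labels = static_mixed_render
        res = sa.analyze_series(series)
        timelines = res["timelines"]
        # match tracks to truth tumours via day-1 ground-truth labels
        gt_of_track = {}
        for tr in res["tracks"]:
            lbl = tr.label_by_frame[0]
            seg_mask = res["label_stack"][0] == lbl
            ids, counts = np.unique(labels[0][seg_mask], return_counts=True)
            gt_of_track[tr.tumour_id] = int(ids[counts.argmax()]) - 1
        n_days_checked = 0
        for tid, grp in timelines.groupby("tumour_id"):
            want = static_mixed_truth.tumours[gt_of_track[tid]].phenotype_seq
            got = grp.sort_values("day")["code"].to_numpy()
            np.testing.assert_array_equal(got, want)
            assert not (grp["rule_tag"] == "propagated").any()
            n_days_checked += len(grp)
        assert n_days_checked == static_mixed_truth.n_tumours * 4
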