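"""End-to-end image analysis: segment, track, profile, classify.

This module chains the single-purpose operations into the daily analysis
a tumour-array experiment needs: per-frame segmentation of the tumour
channel, cross-day track linking, radial T-cell profiling of every
tumour-day, and cohort-referenced phenotype classification into coded
timelines.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .classify import classify_cohort, ratiometric_call
from .profiles import core_median, median_intensity, radial_profile
from .segment import SegmentationParams, TumorTrack, classify_response, link_tracks, segment_frame
from .series import ImageSeries


def segment_series(series: ImageSeries, params: SegmentationParams = SegmentationParams()) -> np.ndarray:
    """Segment the tumour channel of every frame; returns (T, y, x) labels."""
    tum = series.channel("tumour")
    return np.stack([segment_frame(tum[t], params) for t in range(series.n_frames)])


def tracks_table(tracks: list[TumorTrack], days) -> pd.DataFrame:
    """Long-form per-track-day geometry table over the full day grid."""
    rows = []
    for tr in tracks:
        for d in days:
            d = int(d)
            det = d in tr.area_mm2
            rows.append((
                tr.tumour_id, d, det,
                tr.area_mm2.get(d, 0.0),
                *(tr.centroid.get(d, (np.nan, np.nan))),
                tr.feret_um.get(d, np.nan),
            ))
    return pd.DataFrame(
        rows, columns=["tumour_id", "day", "detected", "area_mm2", "centroid_y", "centroid_x", "feret_um"]
    )


def build_day_table(
    series: ImageSeries,
    label_stack: np.ndarray,
    tracks: list[TumorTrack],
    *,
    n_bins: int = 20,
    core_fraction: float = 0.25,
) -> pd.DataFrame:
    """Per-tumour-day classifier inputs: ratiometric call, core intensity
    and median T-cell intensity (NaN/undetected rows included)."""
    tcell = series.channel("tcell")
    frame_of_day = {int(d): f for f, d in enumerate(series.days)}
    rows = []
    for tr in tracks:
        for d in series.days:
            d = int(d)
            f = frame_of_day[d]
            lbl = tr.label_by_frame.get(f)
            if lbl is None:
                rows.append((tr.tumour_id, d, False, np.nan, np.nan, np.nan))
                continue
            mask = label_stack[f] == lbl
            prof = radial_profile(tcell[f], mask, n_bins, tumour_id=tr.tumour_id, day=d)
            call = ratiometric_call(prof, core_fraction=core_fraction)
            rows.append((
                tr.tumour_id, d, True, call,
                core_median(tcell[f], mask, core_fraction),
                median_intensity(tcell[f], mask),
            ))
    df = pd.DataFrame(
        rows, columns=["tumour_id", "day", "detected", "call", "core_intensity", "median_tcell"]
    )
    return df


def analyze_series(
    series: ImageSeries,
    *,
    seg_params: SegmentationParams = SegmentationParams(),
    max_displacement_um: float = 300.0,
    death_day: dict[int, int] | None = None,
    label_stack: np.ndarray | None = None,
) -> dict:
    """Run the full pipeline on one image series.

    Returns a dict with the label stack, tracks, geometry table, per-day
    classifier inputs, coded phenotype timelines, cohort references and
    per-track response calls.  A precomputed ``label_stack`` (e.g. ground
    truth) bypasses segmentation.
    """
    if label_stack is None:
        label_stack = segment_series(series, seg_params)
    tracks = link_tracks(label_stack, series.days, series.pixel_size_um,
                         max_displacement_um=max_displacement_um)
    geometry = tracks_table(tracks, series.days)
    day_table = build_day_table(series, label_stack, tracks)
    timelines, refs = classify_cohort(day_table, death_day=death_day)
    responses = {
        tr.tumour_id: classify_response(
            geometry.loc[geometry["tumour_id"] == tr.tumour_id, "area_mm2"].to_numpy(),
            geometry.loc[geometry["tumour_id"] == tr.tumour_id, "detected"].to_numpy(),
        )
        for tr in tracks
    }
    return {
        "label_stack": label_stack,
        "tracks": tracks,
        "geometry": geometry,
        "day_table": day_table,
        "timelines": timelines,
        "refs": refs,
        "responses": responses,
    }
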