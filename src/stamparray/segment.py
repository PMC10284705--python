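"""Tumour segmentation, cross-day track linking, geometry and response.

Segmentation is a classical, pluggable pipeline (Gaussian smoothing,
Otsu or fixed thresholding, small-object removal, connected components).
Tracks link objects across days by a greedy mutual-nearest-centroid rule
under a maximum displacement; the rule prevents label swaps between
nearby tumours because both partners must agree on the match.  Response
calls follow the standard per-lesion criteria: complete response (CR)
when the tumour becomes durably undetectable, partial response (PR) on a
>= 20% decrease from the maximum area, otherwise stable/progressive
disease (SD/PD).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_erosion
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as cc_label, regionprops


class SegmentationError(ValueError):
    """Invalid input to segmentation or tracking."""


@dataclass(frozen=True)
class SegmentationParams:
    """Classical segmenter settings.

    ``method`` is "otsu" or "fixed" (using ``threshold``); Otsu falls back
    to the fixed threshold on near-constant frames.  ``min_area_px``
    removes speckle below the area floor.
    """

    smooth_sigma: float = 1.0
    method: str = "otsu"
    threshold: float | None = None
    min_area_px: int = 20

    def __post_init__(self):
        if self.method not in ("otsu", "fixed"):
            raise SegmentationError("method must be 'otsu' or 'fixed'")
        if self.method == "fixed" and self.threshold is None:
            raise SegmentationError("fixed method requires a threshold")


def segment_frame(frame: np.ndarray, params: SegmentationParams = SegmentationParams()) -> np.ndarray:
    """Segment one tumour-channel frame into a label image (0 background,
    objects labelled 1..n in scan order); deterministic."""
    img = np.asarray(frame, dtype=float)
    if img.ndim != 2:
        raise SegmentationError("frame must be 2-D")
    if params.smooth_sigma > 0:
        img = gaussian(img, sigma=params.smooth_sigma, preserve_range=True)
    if params.method == "otsu":
        if np.ptp(img) == 0:
            if params.threshold is None:
                return np.zeros(img.shape, dtype=int)
            thr = params.threshold
        else:
            thr = threshold_otsu(img)
    else:
        thr = params.threshold
    mask = img > thr
    lab = cc_label(mask, connectivity=2)
    if params.min_area_px > 1 and lab.max() > 0:
        sizes = np.bincount(lab.ravel())
        lab[np.isin(lab, np.flatnonzero(sizes < params.min_area_px))] = 0
        lab = cc_label(lab > 0, connectivity=2)
    return lab


def feret_diameter(mask: np.ndarray, pixel_size_um: float = 1.0) -> float:
    """Maximum pairwise distance between boundary-pixel centres (µm).

    Boundary pixels are the mask minus its erosion; the maximum distance
    is attained on the convex hull of those pixel centres.  A single
    pixel has Feret diameter 0.
    """
    mask = np.asarray(mask, dtype=bool)
    coords = np.argwhere(mask & ~binary_erosion(mask)).astype(float)
    if len(coords) < 2:
        return 0.0
    if len(coords) > 4:
        try:
            coords = coords[ConvexHull(coords).vertices]
        except Exception:  # degenerate (collinear) point sets
            pass
    return float(pdist(coords).max()) * pixel_size_um


def measure_mask(mask: np.ndarray, pixel_size_um: float) -> dict:
    """Geometry of one boolean mask: area (mm²), centroid (row, col, px)
    and Feret diameter (µm, max caliper distance).

    An empty mask has area 0 and undefined (NaN) geometry.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return {"area_mm2": 0.0, "centroid": (float("nan"), float("nan")), "feret_um": float("nan")}
    yy, xx = np.nonzero(mask)
    area_mm2 = float(mask.sum()) * (pixel_size_um / 1000.0) ** 2
    feret = feret_diameter(mask, pixel_size_um)
    return {"area_mm2": area_mm2, "centroid": (float(yy.mean()), float(xx.mean())), "feret_um": feret}


@dataclass
class TumorTrack:
    """One tumour followed across days."""

    tumour_id: int
    days: list[int] = field(default_factory=list)          # days where detected
    label_by_frame: dict[int, int] = field(default_factory=dict)
    area_mm2: dict[int, float] = field(default_factory=dict)
    centroid: dict[int, tuple[float, float]] = field(default_factory=dict)
    feret_um: dict[int, float] = field(default_factory=dict)

    @property
    def first_day(self) -> int:
        return min(self.days)

    @property
    def last_detected_day(self) -> int:
        return max(self.days)

    def detected_flags(self, all_days) -> np.ndarray:
        return np.array([int(d) in set(self.days) for d in all_days], dtype=bool)

    def area_series(self, all_days) -> np.ndarray:
        return np.array([self.area_mm2.get(int(d), 0.0) for d in all_days], dtype=float)


def _frame_objects(labels: np.ndarray, pixel_size_um: float):
    out = []
    for p in regionprops(labels):
        out.append({
            "label": int(p.label),
            "centroid": np.asarray(p.centroid, dtype=float),
            "area_mm2": float(p.area) * (pixel_size_um / 1000.0) ** 2,
            "feret_um": feret_diameter(p.image, pixel_size_um),
        })
    return out


def link_tracks(
    label_series: np.ndarray,
    days,
    pixel_size_um: float,
    *,
    max_displacement_um: float = 300.0,
) -> list[TumorTrack]:
    """Link per-frame label images into tracks.

    Greedy mutual-nearest matching between each active track's last known
    centroid and the next frame's objects, under ``max_displacement_um``.
    Unmatched objects start new tracks; unmatched tracks stay active (the
    tumour is simply not detected that day) and may re-link later.
    """
    label_series = np.asarray(label_series)
    if label_series.ndim != 3 or label_series.shape[0] != len(days):
        raise SegmentationError("label_series must be (n_frames, y, x) matching days")
    max_disp_px = max_displacement_um / pixel_size_um
    tracks: list[TumorTrack] = []
    active: list[TumorTrack] = []

    for f, day in enumerate(days):
        objs = _frame_objects(label_series[f], pixel_size_um)
        assigned = set()
        if active and objs:
            prev_pos = np.array([t.centroid[t.last_detected_day] for t in active])
            new_pos = np.array([o["centroid"] for o in objs])
            d = np.linalg.norm(prev_pos[:, None, :] - new_pos[None, :, :], axis=2)
            nearest_new = d.argmin(axis=1)
            nearest_prev = d.argmin(axis=0)
            for i, t in enumerate(active):
                j = nearest_new[i]
                if nearest_prev[j] == i and d[i, j] <= max_disp_px:
                    _append_obs(t, int(day), f, objs[j])
                    assigned.add(j)
        for j, o in enumerate(objs):
            if j not in assigned:
                t = TumorTrack(tumour_id=len(tracks))
                _append_obs(t, int(day), f, o)
                tracks.append(t)
                active.append(t)
    return tracks


def _append_obs(track: TumorTrack, day: int, frame: int, obj: dict) -> None:
    track.days.append(day)
    track.label_by_frame[frame] = obj["label"]
    track.area_mm2[day] = obj["area_mm2"]
    track.centroid[day] = tuple(obj["centroid"])
    track.feret_um[day] = obj["feret_um"]


def classify_response(
    areas,
    detected,
    *,
    pr_drop: float = 0.20,
    sd_band: float = 0.20,
    min_undetected: int = 2,
    split_sd_pd: bool = False,
) -> str:
    """Classify one track's response from its area series and per-day
    detectability flags.

    CR: a terminal undetected run of at least ``min_undetected`` days
    after at least one detection.  PR: final detected area at least
    ``pr_drop`` below the maximum.  Otherwise SD/PD (split at
    ±``sd_band`` of the initial area when ``split_sd_pd``).
    """
    areas = np.asarray(areas, dtype=float)
    detected = np.asarray(detected, dtype=bool)
    if areas.shape != detected.shape or areas.size < 2:
        raise SegmentationError("need >= 2 timepoints with matching detectability flags")
    if not detected.any():
        raise SegmentationError("track was never detected")

    if not detected[-1]:
        j = len(detected)
        while j > 0 and not detected[j - 1]:
            j -= 1
        if len(detected) - j >= min_undetected and detected[:j].any():
            return "CR"

    obs = areas[detected]
    a_max, a_final, a_init = obs.max(), obs[-1], obs[0]
    if a_max > 0 and (a_max - a_final) / a_max >= pr_drop:
        return "PR"
    if not split_sd_pd:
        return "SD/PD"
    if a_final >= (1.0 + sd_band) * a_init:
        return "PD"
    return "SD"
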