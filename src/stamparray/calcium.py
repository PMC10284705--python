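"""Calcium and propidium-iodide (PI) influx indices.

Cytotoxic T-cell attack opens calcium-permeable pores in the tumour cell
membrane; the GCaMP6 sensor reports these events as transient
fluorescence flashes.  The indices below quantify flashing activity from
minute-scale time-lapse movies, normalising against either a structural
reporter channel (mTagBFP2) or the movie's own mean intensity so that
the result is invariant to overall brightness.

Movies are represented as per-frame in-mask pixel matrices of shape
``(n_frames, n_pixels)``: a fixed tumour mask applied to every frame.
"""

from __future__ import annotations

import numpy as np


class CalciumError(ValueError):
    """Invalid input to an influx-index computation."""


def _as_movie(x) -> np.ndarray:
    m = np.asarray(x, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2:
        raise CalciumError("movie must be (n_frames >= 2, n_pixels)")
    return m


def _normalised_delta_sum(movie: np.ndarray) -> float:
    """Mean |Δ| of the per-frame intensity sum, normalised by the movie's
    mean in-mask MFI."""
    s = movie.sum(axis=1)
    d = float(np.mean(np.abs(np.diff(s))))
    mfi = float(movie.mean())
    if mfi == 0.0:
        return float("nan")
    return d / mfi


def ca_index_epifluorescence(gcamp, reference) -> float:
    """Epifluorescence calcium influx index.

    For each channel the per-frame sum of in-mask intensities S(t) is
    taken; the mean absolute consecutive difference of S is normalised by
    the channel's across-frame mean pixel intensity; the index is the
    GCaMP normalised delta divided by the reference (mTagBFP2) normalised
    delta.  NaN when the reference channel is degenerate.
    """
    g, r = _as_movie(gcamp), _as_movie(reference)
    n_ref = _normalised_delta_sum(r)
    if not np.isfinite(n_ref) or n_ref == 0.0:
        return float("nan")
    n_g = _normalised_delta_sum(g)
    if not np.isfinite(n_g):
        return float("nan")
    return n_g / n_ref


def ca_index_two_photon(gcamp, reference, *, ddof: int = 0) -> float:
    """Two-photon calcium influx index: the epifluorescence-style ratio
    (value1) multiplied by the ratio of mean per-pixel temporal standard
    deviations GCaMP/reference (value2)."""
    g, r = _as_movie(gcamp), _as_movie(reference)
    value1 = ca_index_epifluorescence(g, r)
    sd_ref = float(r.std(axis=0, ddof=ddof).mean())
    if not np.isfinite(value1) or sd_ref == 0.0:
        return float("nan")
    value2 = float(g.std(axis=0, ddof=ddof).mean()) / sd_ref
    return value1 * value2


def median_mfi_series(frames, cell_labels) -> np.ndarray:
    """Per-frame median of per-cell MFIs.

    ``frames`` is (n_frames, y, x); ``cell_labels`` an integer label image
    of cell isosurfaces (0 = background).  For each frame the MFI of every
    labelled cell is computed and their median taken.
    """
    frames = np.asarray(frames, dtype=float)
    labels = np.asarray(cell_labels)
    ids = np.unique(labels)
    ids = ids[ids > 0]
    if frames.ndim != 3 or ids.size == 0:
        raise CalciumError("frames must be (T, y, x) with a non-empty label image")
    out = np.empty(frames.shape[0])
    cell_masks = [labels == i for i in ids]
    for t in range(frames.shape[0]):
        out[t] = np.median([frames[t][m].mean() for m in cell_masks])
    return out


def _delta_over_mean(series) -> float:
    m = np.asarray(series, dtype=float)
    if m.ndim != 1 or m.size < 2:
        raise CalciumError("need >= 2 timepoints")
    denom = float(m.mean())
    if denom == 0.0:
        return float("nan")
    return float(np.mean(np.abs(np.diff(m)))) / denom


def ca_index_confocal(gcamp_frames=None, cell_labels=None, *, median_series=None) -> float:
    """Spinning-disk confocal calcium influx index.

    M(t) is the per-frame median GCaMP MFI over cell isosurfaces (supply
    either raw frames plus a cell label image, or a precomputed
    ``median_series``); the index is mean |ΔM| divided by the across-frame
    mean of M.
    """
    if median_series is None:
        median_series = median_mfi_series(gcamp_frames, cell_labels)
    return _delta_over_mean(median_series)


def pi_influx_index(pi_frames=None, cell_labels=None, *, median_series=None) -> float:
    """PI influx index: identical construction to :func:`ca_index_confocal`
    applied to the propidium-iodide channel (reports membrane rupture
    rather than calcium influx)."""
    if median_series is None:
        median_series = median_mfi_series(pi_frames, cell_labels)
    return _delta_over_mean(median_series)
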