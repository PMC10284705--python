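"""Per-tumour T-cell spatial statistics.

All statistics are computed from the T-cell fluorescence channel within
(or around) a tumour mask derived from the tumour-reporter channel:

* :func:`radial_profile` — per-bin median T-cell intensity as a function
  of normalised radial distance from the tumour centroid, where the
  normalising length is the equivalent radius sqrt(area / pi);
* :func:`abundance_index` — median over days of the in-mask mean
  fluorescence intensity (MFI);
* :func:`infiltration_index` — centre/periphery MFI ratio, with the
  centre holding the inner 50% of the mask area and the periphery the
  out-of-mask shell up to 50 µm from the tumour border;
* :func:`infiltration_ratio` — median core intensity (inner 25% of the
  normalised radius) divided by the maximum of the median radial profile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage


class ProfileError(ValueError):
    """Invalid input to a spatial-profile computation."""


@dataclass
class RadialProfile:
    """Median radial fluorescence profile of one tumour on one day."""

    bin_edges: np.ndarray        # length n_bins + 1, covering [0, 1]
    median_intensity: np.ndarray  # length n_bins; NaN for empty bins
    tumour_id: int | None = None
    day: int | None = None

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.median_intensity = np.asarray(self.median_intensity, dtype=float)
        if self.bin_edges.ndim != 1 or len(self.bin_edges) != len(self.median_intensity) + 1:
            raise ProfileError("bin_edges must have one more entry than median_intensity")
        if np.all(np.isnan(self.median_intensity)):
            raise ProfileError("profile has no non-empty bin")

    @property
    def max_value(self) -> float:
        return float(np.nanmax(self.median_intensity))

    def inner_values(self, core_fraction: float = 0.25) -> np.ndarray:
        """Median intensities of the bins wholly inside the core
        (bin upper edge <= core_fraction), empty bins dropped."""
        sel = self.bin_edges[1:] <= core_fraction + 1e-12
        vals = self.median_intensity[sel]
        return vals[~np.isnan(vals)]


def _normalised_radius(mask: np.ndarray, centroid: tuple[float, float] | None = None):
    """Per-pixel normalised radius (distance to centroid / equivalent
    radius), clipped to [0, 1], plus the pixel index arrays."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ProfileError("mask is empty")
    yy, xx = np.nonzero(mask)
    if centroid is None:
        cy, cx = yy.mean(), xx.mean()
    else:
        cy, cx = centroid
    r_eq = np.sqrt(mask.sum() / np.pi)
    r = np.hypot(yy - cy, xx - cx) / r_eq
    return np.clip(r, 0.0, 1.0), yy, xx


def radial_profile(
    tcell_image: np.ndarray,
    mask: np.ndarray,
    n_bins: int = 20,
    *,
    centroid: tuple[float, float] | None = None,
    tumour_id: int | None = None,
    day: int | None = None,
) -> RadialProfile:
    """Median radial T-cell fluorescence profile over equal-width bins of
    the normalised radius."""
    if n_bins < 1:
        raise ProfileError("n_bins must be >= 1")
    r, yy, xx = _normalised_radius(mask, centroid)
    vals = np.asarray(tcell_image, dtype=float)[yy, xx]
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    # right-inclusive last bin so r == 1 lands in the outermost bin
    idx = np.minimum(np.searchsorted(edges, r, side="right") - 1, n_bins - 1)
    medians = np.full(n_bins, np.nan)
    for b in range(n_bins):
        sel = idx == b
        if sel.any():
            medians[b] = np.median(vals[sel])
    return RadialProfile(edges, medians, tumour_id=tumour_id, day=day)


def core_median(
    tcell_image: np.ndarray,
    mask: np.ndarray,
    core_fraction: float = 0.25,
    *,
    centroid: tuple[float, float] | None = None,
) -> float:
    """Median T-cell intensity over in-mask pixels with normalised radius
    <= ``core_fraction``; NaN if the core contains no pixel."""
    r, yy, xx = _normalised_radius(mask, centroid)
    sel = r <= core_fraction
    if not sel.any():
        return float("nan")
    return float(np.median(np.asarray(tcell_image, dtype=float)[yy[sel], xx[sel]]))


def median_intensity(tcell_image: np.ndarray, mask: np.ndarray) -> float:
    """Median T-cell intensity over all in-mask pixels."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ProfileError("mask is empty")
    return float(np.median(np.asarray(tcell_image, dtype=float)[mask]))


def abundance_index(tcell_images, masks) -> float:
    """Median over days of the per-day in-mask mean T-cell intensity."""
    mfis = []
    for img, mask in zip(tcell_images, masks):
        mask = np.asarray(mask, dtype=bool)
        if mask.any():
            mfis.append(float(np.asarray(img, dtype=float)[mask].mean()))
    if not mfis:
        raise ProfileError("no day with a non-empty mask")
    return float(np.median(mfis))


def infiltration_index(
    tcell_images,
    masks,
    pixel_size_um: float,
    *,
    periphery_um: float = 50.0,
    centre_area_fraction: float = 0.5,
    exclude_masks=None,
) -> float:
    """Centre/periphery MFI ratio.

    The centre is the inner ``centre_area_fraction`` of the mask *area*
    (normalised radius <= sqrt(fraction)); the periphery is the out-of-mask
    shell within ``periphery_um`` of the mask border, minus any pixels in
    ``exclude_masks`` (e.g. neighbouring tumours).  Per-day MFIs are taken
    in each region and the index is the ratio of their across-day medians.
    Returns NaN (with a warning) when the periphery median is zero.
    """
    r_cut = np.sqrt(centre_area_fraction)
    centre_mfis, peri_mfis = [], []
    if exclude_masks is None:
        exclude_masks = [None] * len(masks)
    for img, mask, excl in zip(tcell_images, masks, exclude_masks):
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            continue
        img = np.asarray(img, dtype=float)
        r, yy, xx = _normalised_radius(mask)
        sel = r <= r_cut
        if not sel.any():
            continue
        centre_mfis.append(img[yy[sel], xx[sel]].mean())
        dist = ndimage.distance_transform_edt(~mask) * pixel_size_um
        peri = (~mask) & (dist <= periphery_um) & (dist > 0)
        if excl is not None:
            peri &= ~np.asarray(excl, dtype=bool)
        if peri.any():
            peri_mfis.append(img[peri].mean())
    if not centre_mfis or not peri_mfis:
        raise ProfileError("no day with valid centre and periphery regions")
    denom = float(np.median(peri_mfis))
    if denom == 0.0:
        warnings.warn("periphery median MFI is zero; infiltration index undefined")
        return float("nan")
    return float(np.median(centre_mfis)) / denom


def infiltration_ratio(
    tcell_image: np.ndarray,
    mask: np.ndarray,
    *,
    n_bins: int = 20,
    core_fraction: float = 0.25,
    centroid: tuple[float, float] | None = None,
) -> float:
    """Core-median / profile-maximum ratio (in [0, ~1]).

    The numerator is the median T-cell intensity over in-mask pixels with
    normalised radius <= ``core_fraction``; the denominator is the maximum
    of the median radial profile.  A zero denominator yields 0 by
    convention (flat, empty profile).
    """
    prof = radial_profile(tcell_image, mask, n_bins, centroid=centroid)
    denom = prof.max_value
    if denom == 0.0:
        return 0.0
    num = core_median(tcell_image, mask, core_fraction, centroid=centroid)
    if np.isnan(num):
        return 0.0
    return float(num / denom)
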