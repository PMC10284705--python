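"""Render synthetic cohorts into multi-channel image stacks.

The renderer turns a :class:`~stamparray.simulate.CohortTruth` into the
stack a fluorescence stereoscope would record, one frame per acquisition
day:

* **tumour** channel — flat-top radial blobs whose half-maximum radius
  equals the equivalent radius of the true area, so segmented areas match
  ground truth;
* **tcell** channel — phenotype-dependent: nothing for desert tumours, an
  annulus centred on the mask boundary for excluded tumours (width 20% of
  the equivalent radius), a filled disc for inflamed tumours, and a
  residual T-cell cluster for resolved lesions;
* **gcamp** channel — a baseline inside each live tumour plus transient
  single-frame flash events, Poisson-distributed with a per-phenotype
  rate.

Ground-truth label images (tumour_id + 1 inside each true disc) are
emitted alongside.  Noise (Gaussian read noise, optional Poisson shot
noise) is applied last.
"""

from __future__ import annotations

import numpy as np

from .config import ArrayLayout, ImagingParams, ConfigError
from .series import ImageSeries
from .simulate import CohortTruth
from .states import DESERT, EXCLUDED, INFLAMED, RESOLVED


class LayoutError(ConfigError):
    """Array geometry cannot accommodate the cohort."""


def _radius_px(area_mm2: float, pixel_size_um: float) -> float:
    return np.sqrt(area_mm2 * 1e6 / np.pi) / pixel_size_um


def _stamp(canvas: np.ndarray, cy: float, cx: float, radius: float, fn) -> None:
    """Apply ``fn(r)`` additively on a local window around (cy, cx)."""
    if radius <= 0:
        return
    r_ext = int(np.ceil(radius * 1.6)) + 2
    y0, y1 = max(0, int(cy) - r_ext), min(canvas.shape[0], int(cy) + r_ext + 1)
    x0, x1 = max(0, int(cx) - r_ext), min(canvas.shape[1], int(cx) + r_ext + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    r = np.hypot(yy - cy, xx - cx)
    canvas[y0:y1, x0:x1] += fn(r)


def render_timelapse(
    truth: CohortTruth,
    layout: ArrayLayout | None = None,
    imaging: ImagingParams = ImagingParams(),
    *,
    channels: tuple[str, ...] = ("tumour", "tcell", "gcamp"),
    seed: int | None = None,
) -> tuple[ImageSeries, np.ndarray]:
    """Render a cohort; returns (series, ground-truth label stack)."""
    cfg = truth.config
    if layout is None:
        side = int(np.ceil(np.sqrt(truth.n_tumours)))
        layout = ArrayLayout(n_rows=side, n_cols=side)
    if layout.n_sites < truth.n_tumours:
        raise LayoutError(f"layout has {layout.n_sites} sites for {truth.n_tumours} tumours")

    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed if seed is None else seed, 1)))
    if not layout.positions:
        layout = layout.realise(rng)
    pos_um = np.asarray(layout.positions, dtype=float)[: truth.n_tumours]

    px = imaging.pixel_size_um
    max_area = max(float(np.nanmax(t.area_seq)) for t in truth.tumours)
    max_r_um = np.sqrt(max_area * 1e6 / np.pi)
    if truth.n_tumours > 1:
        d = np.linalg.norm(pos_um[:, None] - pos_um[None, :], axis=2)
        np.fill_diagonal(d, np.inf)
        if d.min() <= 2.0 * max_r_um * (1.0 + imaging.annulus_width_frac):
            raise LayoutError(
                f"minimum pore distance {d.min():.0f} µm cannot hold blobs of radius {max_r_um:.0f} µm"
            )

    origin = imaging.margin_um
    pos_px = (pos_um + origin) / px
    shape = (
        int(np.ceil((pos_um[:, 0].max() + 2 * origin) / px)) + 1,
        int(np.ceil((pos_um[:, 1].max() + 2 * origin) / px)) + 1,
    )

    n_t = cfg.n_timepoints
    roles = {c: i for i, c in enumerate(channels)}
    data = np.full((n_t, len(channels), *shape), imaging.background, dtype=np.float32)
    labels = np.zeros((n_t, *shape), dtype=np.int32)
    sharp = imaging.blob_sharpness
    ln2 = np.log(2.0)

    for t in range(n_t):
        for tum in truth.tumours:
            code = int(tum.phenotype_seq[t])
            cy, cx = pos_px[tum.tumour_id]
            r_eq = _radius_px(float(tum.area_seq[t]), px)
            amp_t = imaging.tcell_amp * float(np.nan_to_num(tum.abundance_seq[t]))

            if tum.detected[t] and r_eq > 0:
                if "tumour" in roles:
                    _stamp(
                        data[t, roles["tumour"]], cy, cx, r_eq,
                        lambda r: imaging.tumour_amp * np.exp(-ln2 * (r / r_eq) ** sharp),
                    )
                _stamp(labels[t], cy, cx, r_eq,
                       lambda r: (r <= r_eq).astype(np.int32) * (tum.tumour_id + 1))
                if "gcamp" in roles:
                    ch = data[t, roles["gcamp"]]
                    _stamp(ch, cy, cx, r_eq,
                           lambda r: imaging.gcamp_baseline * (r <= r_eq))
                    rate = cfg.flash_rates.get(code, 0.0)
                    for _ in range(rng.poisson(rate)):
                        off = rng.uniform(-0.5, 0.5, size=2) * r_eq
                        _stamp(ch, cy + off[0], cx + off[1], 0.35 * r_eq,
                               lambda r, rr=0.35 * r_eq: imaging.gcamp_flash_amp * (r <= rr))

            if "tcell" in roles:
                ch = data[t, roles["tcell"]]
                if code == EXCLUDED and tum.detected[t] and r_eq > 0:
                    half_w = 0.5 * imaging.annulus_width_frac * r_eq
                    _stamp(ch, cy, cx, r_eq * (1 + imaging.annulus_width_frac),
                           lambda r: amp_t * (np.abs(r - r_eq) <= half_w))
                    _stamp(ch, cy, cx, r_eq,
                           lambda r: imaging.diffuse_frac * amp_t * (r <= r_eq))
                elif code == INFLAMED and tum.detected[t] and r_eq > 0:
                    _stamp(ch, cy, cx, r_eq, lambda r: amp_t * (r <= r_eq))
                elif code == RESOLVED:
                    r_res = max(4.0, 0.5 * _radius_px(cfg.growth.K / 4, px))
                    _stamp(ch, cy, cx, r_res, lambda r: amp_t * (r <= r_res))
                # desert: background only

    if cfg.noise.poisson_gain > 0:
        data = rng.poisson(np.clip(data, 0, None) / cfg.noise.poisson_gain) * cfg.noise.poisson_gain
        data = data.astype(float)
    if cfg.noise.gaussian_sd > 0:
        data += rng.normal(0.0, cfg.noise.gaussian_sd, size=data.shape)
    data = np.clip(data, 0.0, None)

    series = ImageSeries(
        data=data, channel_roles=roles, pixel_size_um=px, days=[int(d) for d in truth.days]
    )
    return series, labels
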