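"""Ground-truthed synthetic cohorts of arrayed microtumours.

`simulate_cohort` realises, for every tumour in the array:

* a per-day immune-phenotype sequence drawn from the archetype's Markov
  chain over {desert, excluded, inflamed, resolved, death};
* a logistic area curve (per-tumour lognormal growth rate) that switches
  to exponential decay once the chain enters the resolved state, with the
  tumour leaving the detectability set below a configurable area floor;
* per-day emissions of the two trajectory features — T-cell abundance and
  core infiltration ratio — drawn from per-phenotype distributions.

Randomness is organised as one root seed split into per-tumour
substreams (``numpy.random.SeedSequence.spawn``), so simulating a larger
cohort reproduces the smaller cohort's tumours exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ScenarioConfig, ConfigError, GrowthParams
from .states import STATE_ORDER, RESOLVED, DEATH, ABSORBING


@dataclass
class TumourTruth:
    """Ground truth for one simulated tumour."""

    tumour_id: int
    archetype_class: str
    phenotype_seq: np.ndarray          # int codes, length n_timepoints
    rejection_day: int | None          # acquisition day of first code 5
    death_day: int | None              # acquisition day of first code 0
    growth_params: GrowthParams
    area_seq: np.ndarray               # mm², length n_timepoints
    detected: np.ndarray               # bool, length n_timepoints
    abundance_seq: np.ndarray          # a.u., NaN after death
    core_ratio_seq: np.ndarray         # [0, 1], NaN after death


@dataclass
class CohortTruth:
    """Ground truth for a whole simulated cohort."""

    config: ScenarioConfig
    days: np.ndarray
    tumours: list[TumourTruth] = field(default_factory=list)

    @property
    def n_tumours(self) -> int:
        return len(self.tumours)

    def trajectory_table(self) -> pd.DataFrame:
        """Long-form per-tumour-day table (the canonical CSV output)."""
        rows = []
        for t in self.tumours:
            for j, day in enumerate(self.days):
                rows.append(
                    (t.tumour_id, int(day), t.archetype_class, float(t.area_seq[j]),
                     int(t.phenotype_seq[j]), bool(t.detected[j]),
                     float(t.abundance_seq[j]), float(t.core_ratio_seq[j]))
                )
        return pd.DataFrame(
            rows,
            columns=["tumour_id", "day", "archetype", "area_mm2",
                     "phenotype_code", "detected", "abundance", "core_ratio"],
        )


def logistic_area(t: np.ndarray, growth: GrowthParams, r: float | None = None) -> np.ndarray:
    """Logistic growth a(t) = K a0 e^{rt} / (K + a0 (e^{rt} - 1)), t in days."""
    r = growth.r if r is None else r
    e = np.exp(r * np.asarray(t, dtype=float))
    return growth.K * growth.a0 * e / (growth.K + growth.a0 * (e - 1.0))


def _draw_growth_rate(rng: np.random.Generator, growth: GrowthParams) -> float:
    if growth.r_cv == 0:
        return growth.r
    sigma2 = np.log1p(growth.r_cv ** 2)
    return growth.r * rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2))


def _simulate_chain(rng: np.random.Generator, arch, n_timepoints: int) -> tuple[np.ndarray, int | None]:
    """Realise one phenotype sequence; returns (codes, switch_day_index)."""
    states = np.array(STATE_ORDER)
    switch = None
    if arch.switch_day_range is not None:
        lo, hi = arch.switch_day_range
        switch = int(rng.integers(lo, hi + 1))
    codes = np.empty(n_timepoints, dtype=int)
    state_idx = rng.choice(5, p=np.asarray(arch.initial_dist, dtype=float))
    codes[0] = states[state_idx]
    for t in range(1, n_timepoints):
        if codes[t - 1] in ABSORBING:
            codes[t] = codes[t - 1]
            continue
        P = arch.matrix_for_day(t - 1, switch)
        state_idx = rng.choice(5, p=P[state_idx])
        codes[t] = states[state_idx]
    return codes, switch


def simulate_cohort(config: ScenarioConfig, n_tumours: int) -> CohortTruth:
    """Simulate ``n_tumours`` tumours under ``config``; fully seeded."""
    if n_tumours < 1:
        raise ConfigError("n_tumours must be >= 1")
    days = config.days
    n_t = config.n_timepoints
    weights = config.weights
    root = np.random.SeedSequence(config.seed)
    truth = CohortTruth(config=config, days=days)

    for i, child in enumerate(root.spawn(n_tumours)):
        rng = np.random.default_rng(child)
        arch = config.archetypes[rng.choice(len(weights), p=weights)]
        codes, _ = _simulate_chain(rng, arch, n_t)

        rej = np.flatnonzero(codes == RESOLVED)
        dth = np.flatnonzero(codes == DEATH)
        rejection_day = int(days[rej[0]]) if rej.size else None
        death_day = int(days[dth[0]]) if dth.size else None

        r_i = _draw_growth_rate(rng, config.growth)
        growth_i = GrowthParams(r=r_i, K=config.growth.K, a0=config.growth.a0, r_cv=0.0)
        t_rel = days - days[0]
        area = logistic_area(t_rel, growth_i)
        if rejection_day is not None:
            j0 = rej[0]
            a_rej = area[j0]
            area = area.copy()
            area[j0:] = a_rej * np.exp(-config.rejection_decay * (days[j0:] - rejection_day))
        detected = area >= config.detect_floor_mm2
        if death_day is not None:
            detected[dth[0]:] = False

        # per-day emissions; archetype trend ramps the abundance multiplier
        trend = np.linspace(arch.abundance_trend[0], arch.abundance_trend[1], n_t)
        abundance = np.full(n_t, np.nan)
        core_ratio = np.full(n_t, np.nan)
        for j in range(n_t):
            code = int(codes[j])
            if code == DEATH:
                continue
            em = config.emissions[code]
            a = em.abundance_mean + rng.normal(0.0, em.abundance_sd) if em.abundance_sd else em.abundance_mean
            c = em.core_ratio_mean + rng.normal(0.0, em.core_ratio_sd) if em.core_ratio_sd else em.core_ratio_mean
            abundance[j] = max(a, 0.0) * trend[j]
            core_ratio[j] = float(np.clip(c, 0.0, 1.0))

        truth.tumours.append(
            TumourTruth(
                tumour_id=i,
                archetype_class=arch.name,
                phenotype_seq=codes,
                rejection_day=rejection_day,
                death_day=death_day,
                growth_params=growth_i,
                area_seq=area,
                detected=detected,
                abundance_seq=abundance,
                core_ratio_seq=core_ratio,
            )
        )
    return truth


def resolved_fraction_by_day(truth: CohortTruth, day: int) -> float:
    """Fraction of tumours whose timeline reaches code 5 on or before ``day``."""
    n = truth.n_tumours
    hit = sum(
        1 for t in truth.tumours
        if t.rejection_day is not None and t.rejection_day <= day
    )
    return hit / n


# ---------------------------------------------------------------------------
# calcium movies


def simulate_calcium_movie(
    *,
    n_frames: int = 60,
    n_pixels: int = 400,
    flash_rate: float = 0.3,
    flash_amp: float = 1500.0,
    flash_fraction: float = 0.15,
    gcamp_baseline: float = 100.0,
    ref_level: float = 500.0,
    ref_jitter: float = 5.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Minute-scale in-mask pixel movie for calcium-index studies.

    Returns ``(gcamp, ref)``, each of shape (n_frames, n_pixels).  Per
    frame, a Poisson number of transient flash events (rate ``flash_rate``)
    each light up a random ``flash_fraction`` of the pixels for that frame
    only, on top of a constant GCaMP baseline.  The reference channel is a
    constant structural reporter with small Gaussian jitter.
    """
    rng = np.random.default_rng(seed)
    gcamp = np.full((n_frames, n_pixels), gcamp_baseline, dtype=float)
    k_flash = max(1, int(round(flash_fraction * n_pixels)))
    for t in range(n_frames):
        for _ in range(rng.poisson(flash_rate)):
            idx = rng.choice(n_pixels, size=k_flash, replace=False)
            gcamp[t, idx] += flash_amp
    ref = ref_level + rng.normal(0.0, ref_jitter, size=(n_frames, n_pixels))
    return gcamp, np.clip(ref, 0.0, None)
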