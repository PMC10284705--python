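"""Shared fixtures: hand-built static cohorts and noise-free renders."""

from __future__ import annotations

import numpy as np
import pytest

from stamparray import (
    ArrayLayout,
    CohortTruth,
    GrowthParams,
    ImagingParams,
    TumourTruth,
    default_immunocompetent,
    render_timelapse,
    simulate_cohort,
)
from stamparray.config import DEFAULT_EMISSIONS
from stamparray.states import DEATH


def make_static_truth(codes_per_tumour, *, n_days=4, area_mm2=0.30, seed=0):
    """A cohort whose tumours hold fixed phenotypes with constant area and
    noise-free per-phenotype emissions — the ground truth for classifier
    soundness checks."""
    cfg = default_immunocompetent(seed=seed, n_timepoints=n_days)
    days = cfg.days
    truth = CohortTruth(config=cfg, days=days)
    for i, codes in enumerate(codes_per_tumour):
        codes = np.broadcast_to(np.asarray(codes, dtype=int), (n_days,)).copy()
        area = np.full(n_days, area_mm2)
        detected = np.ones(n_days, dtype=bool)
        abundance = np.array([
            np.nan if c == DEATH else DEFAULT_EMISSIONS[int(c)].abundance_mean for c in codes
        ])
        ratio = np.array([
            np.nan if c == DEATH else DEFAULT_EMISSIONS[int(c)].core_ratio_mean for c in codes
        ])
        truth.tumours.append(TumourTruth(
            tumour_id=i, archetype_class="fixture", phenotype_seq=codes,
            rejection_day=None, death_day=None,
            growth_params=GrowthParams(r=0.0, r_cv=0.0),
            area_seq=area, detected=detected,
            abundance_seq=abundance, core_ratio_seq=ratio,
        ))
    return truth


@pytest.fixture(scope="session")
def static_mixed_truth():
    """Nine static tumours: 2 desert, 4 excluded, 3 inflamed."""
    return make_static_truth([[1], [1], [2], [2], [2], [2], [3], [3], [3]], n_days=4)


@pytest.fixture(scope="session")
def static_mixed_render(static_mixed_truth):
    series, labels = render_timelapse(
        static_mixed_truth, ArrayLayout(n_rows=3, n_cols=3), ImagingParams(), seed=42
    )
    return series, labels


@pytest.fixture(scope="session")
def small_default_truth():
    return simulate_cohort(default_immunocompetent(seed=123), 60)
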