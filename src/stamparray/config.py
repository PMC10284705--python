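"""Scenario configuration for synthetic microtumour-array cohorts.

A :class:`ScenarioConfig` fully determines one simulated cohort: the
Markov chain over immune phenotypes, logistic tumour growth, per-phenotype
emission distributions for the two trajectory features (T-cell abundance
and core infiltration ratio), calcium flash rates and imaging noise.

Cohorts are mixtures of *archetypes* — trajectory classes with their own
initial phenotype distribution and (possibly time-switched) transition
matrix.  The three default archetypes mirror the trajectory classes seen
in longitudinal tumour-array experiments:

* class I   — tumours that recruit T cells but remain immune-excluded and
  progress;
* class II  — tumours that pass through an excluded state and reach an
  inflamed phenotype late;
* class III — tumours that convert early to an inflamed phenotype with a
  high infiltration ratio, and are frequently rejected.

The default immunocompetent mixture is calibrated so that roughly 30% of
tumours resolve (reach code 5) by day 14, the headline spontaneous
rejection rate in immunocompetent hosts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .states import STATE_ORDER, DESERT, EXCLUDED, INFLAMED, RESOLVED, DEATH


class ConfigError(ValueError):
    """Invalid scenario, layout or imaging configuration."""


def _check_stochastic(matrix: np.ndarray, *, atol: float = 1e-9) -> np.ndarray:
    m = np.asarray(matrix, dtype=float)
    if m.shape != (5, 5):
        raise ConfigError(f"transition matrix must be 5x5 in state order {STATE_ORDER}, got {m.shape}")
    if (m < -atol).any():
        raise ConfigError("transition matrix has negative entries")
    rows = m.sum(axis=1)
    if not np.allclose(rows, 1.0, atol=atol):
        raise ConfigError(f"transition matrix rows must sum to 1, got {rows}")
    # resolved (index 3) and death (index 4) are absorbing
    for idx, code in ((3, RESOLVED), (4, DEATH)):
        if not np.isclose(m[idx, idx], 1.0, atol=atol):
            raise ConfigError(f"state {code} must be absorbing (row {idx} self-probability 1)")
    return m


@dataclass(frozen=True)
class GrowthParams:
    """Logistic growth parameters.

    r is the per-day intrinsic growth rate, K the carrying capacity and a0
    the seeded area, both in mm².  ``r_cv`` is the coefficient of variation
    of the per-tumour lognormal spread of r.
    """

    r: float = 0.35
    K: float = 0.5
    a0: float = 0.05
    r_cv: float = 0.2

    def __post_init__(self):
        if self.r < 0 or self.K <= 0 or self.a0 <= 0 or self.r_cv < 0:
            raise ConfigError("growth parameters must be positive (r, r_cv >= 0)")


@dataclass(frozen=True)
class EmissionParams:
    """Per-phenotype emission of (abundance, core infiltration ratio).

    ``abundance_mean`` is in arbitrary fluorescence units (the T-cell
    channel is only meaningful up to scale); ``core_ratio_mean`` is the
    dimensionless core/max radial-profile ratio in [0, 1].
    """

    abundance_mean: float
    core_ratio_mean: float
    abundance_sd: float = 0.0
    core_ratio_sd: float = 0.0

    def __post_init__(self):
        if min(self.abundance_mean, self.core_ratio_mean, self.abundance_sd, self.core_ratio_sd) < 0:
            raise ConfigError("emission parameters must be non-negative")


DEFAULT_EMISSIONS: dict[int, EmissionParams] = {
    DESERT: EmissionParams(0.04, 0.05, 0.015, 0.03),
    EXCLUDED: EmissionParams(0.45, 0.12, 0.08, 0.05),
    INFLAMED: EmissionParams(1.00, 0.85, 0.12, 0.06),
    # a dense T-cell cluster remains after rejection, so the resolved
    # state emits near-inflamed abundance with a fully infiltrated ratio
    RESOLVED: EmissionParams(0.95, 0.90, 0.10, 0.05),
}

#: calcium flash events per movie frame, by phenotype — inflamed tumours
#: flash an order of magnitude more than excluded ones
DEFAULT_FLASH_RATES: dict[int, float] = {
    DESERT: 0.0,
    EXCLUDED: 0.02,
    INFLAMED: 0.30,
    RESOLVED: 0.05,
}


@dataclass(frozen=True)
class ArchetypeSpec:
    """One trajectory class of the cohort mixture.

    ``initial_dist`` is the day-one phenotype distribution over
    ``STATE_ORDER``.  ``transition_matrix`` drives daily transitions; if
    ``switch_day_range`` is set, a per-tumour switch day is drawn uniformly
    from the inclusive range and ``switch_matrix`` is used from that day
    onward (this models the delayed excluded-to-inflamed conversion of
    late-inflaming tumours).  ``abundance_trend`` linearly ramps a
    multiplicative factor on the abundance emission from the first to the
    last day.
    """

    name: str
    weight: float
    initial_dist: tuple[float, ...]
    transition_matrix: tuple[tuple[float, ...], ...]
    switch_day_range: tuple[int, int] | None = None
    switch_matrix: tuple[tuple[float, ...], ...] | None = None
    abundance_trend: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self):
        if self.weight < 0:
            raise ConfigError("archetype weight must be >= 0")
        p = np.asarray(self.initial_dist, dtype=float)
        if p.shape != (5,) or (p < 0).any() or not np.isclose(p.sum(), 1.0, atol=1e-9):
            raise ConfigError("initial_dist must be a length-5 distribution over STATE_ORDER")
        _check_stochastic(np.asarray(self.transition_matrix))
        if (self.switch_day_range is None) != (self.switch_matrix is None):
            raise ConfigError("switch_day_range and switch_matrix must be given together")
        if self.switch_matrix is not None:
            _check_stochastic(np.asarray(self.switch_matrix))
        if min(self.abundance_trend) < 0:
            raise ConfigError("abundance_trend factors must be >= 0")

    def matrix_for_day(self, day_index: int, switch_day: int | None) -> np.ndarray:
        """Transition matrix applying to the step leaving ``day_index`` (0-based)."""
        if switch_day is not None and self.switch_matrix is not None and day_index >= switch_day:
            return np.asarray(self.switch_matrix, dtype=float)
        return np.asarray(self.transition_matrix, dtype=float)


@dataclass(frozen=True)
class NoiseParams:
    """Detector noise applied after rendering: additive Gaussian with the
    given sd (counts) plus optional Poisson shot noise with the given gain
    (counts per photon; 0 disables)."""

    gaussian_sd: float = 0.0
    poisson_gain: float = 0.0

    def __post_init__(self):
        if self.gaussian_sd < 0 or self.poisson_gain < 0:
            raise ConfigError("noise parameters must be >= 0")


@dataclass(frozen=True)
class ScenarioConfig:
    """Full specification of a synthetic cohort; see module docstring."""

    archetypes: tuple[ArchetypeSpec, ...]
    growth: GrowthParams = GrowthParams()
    rejection_decay: float = 1.2          # 1/day exponential area decay once resolved
    detect_floor_mm2: float = 0.01        # area below which a tumour is undetectable
    emissions: dict[int, EmissionParams] = field(default_factory=lambda: dict(DEFAULT_EMISSIONS))
    flash_rates: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_FLASH_RATES))
    noise: NoiseParams = NoiseParams()
    n_timepoints: int = 21
    first_day: int = 1
    seed: int = 0

    def __post_init__(self):
        if not self.archetypes:
            raise ConfigError("at least one archetype is required")
        total = sum(a.weight for a in self.archetypes)
        if total <= 0:
            raise ConfigError("archetype weights must sum to a positive value")
        if self.rejection_decay < 0:
            raise ConfigError("rejection_decay must be >= 0")
        if self.n_timepoints < 1:
            raise ConfigError("n_timepoints must be >= 1")
        if any(v < 0 for v in self.flash_rates.values()):
            raise ConfigError("flash rates must be >= 0")

    @property
    def days(self) -> np.ndarray:
        """Acquisition days: a uniform daily grid starting at ``first_day``."""
        return np.arange(self.first_day, self.first_day + self.n_timepoints)

    @property
    def weights(self) -> np.ndarray:
        w = np.array([a.weight for a in self.archetypes], dtype=float)
        return w / w.sum()

    # -- serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["emissions"] = {int(k): asdict(v) for k, v in self.emissions.items()}
        d["flash_rates"] = {int(k): float(v) for k, v in self.flash_rates.items()}
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        d["archetypes"] = tuple(
            ArchetypeSpec(**{
                **a,
                "initial_dist": tuple(a["initial_dist"]),
                "transition_matrix": tuple(map(tuple, a["transition_matrix"])),
                "switch_day_range": tuple(a["switch_day_range"]) if a.get("switch_day_range") else None,
                "switch_matrix": tuple(map(tuple, a["switch_matrix"])) if a.get("switch_matrix") else None,
                "abundance_trend": tuple(a.get("abundance_trend", (1.0, 1.0))),
            })
            for a in d["archetypes"]
        )
        d["growth"] = GrowthParams(**d.get("growth", {}))
        d["noise"] = NoiseParams(**d.get("noise", {}))
        d["emissions"] = {int(k): EmissionParams(**v) for k, v in d.get("emissions", {}).items()} or dict(DEFAULT_EMISSIONS)
        d["flash_rates"] = {int(k): float(v) for k, v in d.get("flash_rates", {}).items()} or dict(DEFAULT_FLASH_RATES)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _m(rows: list[list[float]]) -> tuple[tuple[float, ...], ...]:
    return tuple(tuple(float(x) for x in r) for r in rows)


_ABSORB = [[0, 0, 0, 1, 0], [0, 0, 0, 0, 1]]  # resolved, death rows


def default_immunocompetent(*, seed: int = 0, n_timepoints: int = 21) -> ScenarioConfig:
    """Default wild-type scenario: three-archetype mixture calibrated so
    that ~30% of tumours are resolved by day 14.

    Per-day mouse-loss (code 0) hazard is a shared 0.005; resolution
    hazards differ sharply between archetypes, which is what creates the
    class structure of outcomes.
    """
    class_i = ArchetypeSpec(
        name="I",
        weight=0.40,
        initial_dist=(0.20, 0.80, 0.0, 0.0, 0.0),
        transition_matrix=_m([
            [0.930, 0.065, 0.000, 0.000, 0.005],
            [0.015, 0.970, 0.005, 0.005, 0.005],
            [0.000, 0.050, 0.930, 0.015, 0.005],
        ] + _ABSORB),
        abundance_trend=(0.30, 2.2),
    )
    class_ii = ArchetypeSpec(
        name="II",
        weight=0.32,
        initial_dist=(0.05, 0.95, 0.0, 0.0, 0.0),
        transition_matrix=_m([
            [0.850, 0.145, 0.000, 0.000, 0.005],
            [0.020, 0.965, 0.005, 0.005, 0.005],
            [0.000, 0.020, 0.915, 0.060, 0.005],
        ] + _ABSORB),
        switch_day_range=(8, 8),    # 0-based day index; excluded->inflamed opens here
        switch_matrix=_m([
            [0.600, 0.395, 0.000, 0.000, 0.005],
            [0.000, 0.290, 0.700, 0.005, 0.005],
            [0.000, 0.020, 0.915, 0.060, 0.005],
        ] + _ABSORB),
        abundance_trend=(0.55, 0.85),
    )
    class_iii = ArchetypeSpec(
        name="III",
        weight=0.28,
        initial_dist=(0.00, 0.30, 0.70, 0.0, 0.0),
        transition_matrix=_m([
            [0.700, 0.295, 0.000, 0.000, 0.005],
            [0.000, 0.450, 0.540, 0.005, 0.005],
            [0.000, 0.010, 0.865, 0.120, 0.005],
        ] + _ABSORB),
        abundance_trend=(1.20, 1.50),
    )
    return ScenarioConfig(
        archetypes=(class_i, class_ii, class_iii),
        n_timepoints=n_timepoints,
        seed=seed,
    )


def single_matrix_scenario(
    transition_matrix,
    initial_dist=(0.25, 0.50, 0.25, 0.0, 0.0),
    *,
    seed: int = 0,
    n_timepoints: int = 21,
    **kwargs,
) -> ScenarioConfig:
    """Scenario with one homogeneous Markov chain — the configuration used
    for transition-matrix parameter-recovery studies."""
    arch = ArchetypeSpec(
        name="all",
        weight=1.0,
        initial_dist=tuple(initial_dist),
        transition_matrix=tuple(map(tuple, np.asarray(transition_matrix, dtype=float))),
    )
    return ScenarioConfig(archetypes=(arch,), n_timepoints=n_timepoints, seed=seed, **kwargs)


# ---------------------------------------------------------------------------
# array geometry and imaging


@dataclass(frozen=True)
class ArrayLayout:
    """Regular grid of pore positions (µm) with per-pore jitter."""

    n_rows: int = 8
    n_cols: int = 8
    pitch_um: float = 1200.0
    jitter_um: float = 40.0
    positions: tuple[tuple[float, float], ...] = ()

    def __post_init__(self):
        if self.n_rows < 1 or self.n_cols < 1 or self.pitch_um <= 0 or self.jitter_um < 0:
            raise ConfigError("invalid layout geometry")

    @property
    def n_sites(self) -> int:
        return self.n_rows * self.n_cols

    def realise(self, rng: np.random.Generator) -> "ArrayLayout":
        """Return a copy with jittered (y, x) positions drawn for every
        pore site; the original layout is left untouched."""
        import dataclasses

        yy, xx = np.meshgrid(
            np.arange(self.n_rows) * self.pitch_um,
            np.arange(self.n_cols) * self.pitch_um,
            indexing="ij",
        )
        pos = np.stack([yy.ravel(), xx.ravel()], axis=1).astype(float)
        pos += rng.uniform(-self.jitter_um, self.jitter_um, size=pos.shape)
        pos -= pos.min(axis=0)
        return dataclasses.replace(self, positions=tuple(map(tuple, pos)))


@dataclass(frozen=True)
class ImagingParams:
    """Rendering parameters for the synthetic microscope.

    Channel amplitudes are 16-bit counts.  ``blob_sharpness`` is the
    exponent of the flat-top radial intensity profile used for tumour
    blobs (higher = harder edge; the half-maximum radius always equals the
    equivalent radius of the true area).  ``annulus_width_frac`` is the
    width of the excluded-phenotype T-cell annulus as a fraction of the
    equivalent radius.
    """

    pixel_size_um: float = 20.0
    margin_um: float = 600.0
    tumour_amp: float = 1000.0
    tcell_amp: float = 800.0
    gcamp_baseline: float = 100.0
    gcamp_flash_amp: float = 1500.0
    blob_sharpness: float = 8.0
    annulus_width_frac: float = 0.20
    #: diffuse in-mask T-cell signal of an excluded tumour, as a fraction
    #: of its rim amplitude — excluded lesions are not T-cell free, they
    #: spatially confine T cells to the rim
    diffuse_frac: float = 0.08
    background: float = 0.0

    def __post_init__(self):
        if self.pixel_size_um <= 0:
            raise ConfigError("pixel_size_um must be positive")
        if self.blob_sharpness <= 0 or not 0 < self.annulus_width_frac < 1:
            raise ConfigError("invalid blob rendering parameters")
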