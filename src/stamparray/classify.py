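"""Rule-based per-day tumour immune phenotype (TIP) classification.

The classifier turns each tumour-day's median radial T-cell profile into
one of the integer-coded phenotypes, using a cohort-referenced rule set:

1. *Inflamed* (code 3) if every radial-profile bin in the inner 25% of the
   normalised radius exceeds 60% of the profile maximum.
2. *Excluded* (code 2) if every inner bin is below 40% of the maximum —
   unless the core intensity exceeds the median core intensity of the
   tumours called inflamed that day, in which case the tumour is
   *reclassified* as inflamed.
3. *Desert* (code 1) if the call is indeterminate, the tumour's median
   T-cell intensity is below the cohort desert threshold (25th percentile
   of all tumours' first-imaging-day median intensities, frozen after day
   one) and the profile does not show an excluded pattern.
4. Otherwise the previous day's phenotype is propagated forward.

Timelines are then padded with the absorbing codes: 5 from the first day
a tumour is durably undetectable (complete response), 0 from mouse
death/euthanasia onward.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .profiles import RadialProfile
from .states import DESERT, EXCLUDED, INFLAMED, RESOLVED, DEATH


INFLAMED_CUT = 0.60
EXCLUDED_CUT = 0.40

#: provenance tags a per-day code may carry
RULE_TAGS = (
    "inflamed-rule", "excluded-rule", "desert-rule", "reclassified",
    "propagated", "first-day-default", "resolved", "death",
)


def ratiometric_call(
    profile: RadialProfile,
    *,
    core_fraction: float = 0.25,
    inflamed_cut: float = INFLAMED_CUT,
    excluded_cut: float = EXCLUDED_CUT,
    consistency: float = 1.0,
) -> str:
    """Classify a radial profile as ``"inflamed"``, ``"excluded"`` or
    ``"indeterminate"`` by the ratiometric cut-offs.

    "Consistently" above/below the cut-off is read strictly: the required
    fraction of inner-core bins (default all of them) must satisfy it.
    An all-zero or core-less profile is indeterminate.
    """
    inner = profile.inner_values(core_fraction)
    mx = profile.max_value
    if inner.size == 0 or mx <= 0.0:
        return "indeterminate"
    if np.mean(inner > inflamed_cut * mx) >= consistency:
        return "inflamed"
    if np.mean(inner < excluded_cut * mx) >= consistency:
        return "excluded"
    return "indeterminate"


@dataclass
class CohortRefs:
    """Cohort-level reference intensities for the classifier.

    ``desert_threshold`` is frozen from the first imaging day;
    ``inflamed_core_median`` is recomputed each day from the tumours whose
    ratiometric call that day is inflamed (None when no tumour qualifies,
    which disables the reclassification rule for that day).
    """

    desert_threshold: float
    inflamed_core_median: dict[int, float | None] = field(default_factory=dict)

    def __post_init__(self):
        if self.desert_threshold < 0:
            raise ValueError("desert_threshold must be >= 0")


def desert_threshold(first_day_medians, *, percentile: float = 25.0) -> float:
    """25th percentile (linear interpolation) of the cohort's first-day
    median T-cell intensities."""
    vals = np.asarray(list(first_day_medians), dtype=float)
    if vals.size == 0:
        raise ValueError("no first-day median intensities supplied")
    return float(np.percentile(vals, percentile, method="linear"))


def classify_day(
    call: str,
    core_intensity: float,
    median_tcell: float,
    desert_thr: float,
    inflamed_core_median: float | None,
    prev_code: int | None,
    *,
    first_day_default: int = EXCLUDED,
) -> tuple[int, str]:
    """Apply the daily rule precedence to one tumour; returns (code, tag)."""
    if call == "inflamed":
        return INFLAMED, "inflamed-rule"
    if call == "excluded":
        if (
            inflamed_core_median is not None
            and np.isfinite(core_intensity)
            and core_intensity > inflamed_core_median
        ):
            return INFLAMED, "reclassified"
        return EXCLUDED, "excluded-rule"
    # indeterminate: desert rule, then propagation
    if np.isfinite(median_tcell) and median_tcell < desert_thr:
        return DESERT, "desert-rule"
    if prev_code is not None:
        return prev_code, "propagated"
    return first_day_default, "first-day-default"


def encode_timeline(
    codes,
    detected,
    *,
    death_from_index: int | None = None,
    min_undetected: int = 2,
) -> tuple[np.ndarray, list[str]]:
    """Overlay the absorbing conventions on a per-day code sequence.

    ``codes`` are the daily classifier outputs (ignored where overridden);
    ``detected`` the per-day detectability flags.  From the first day of a
    terminal undetected run of at least ``min_undetected`` days, codes
    become 5 (resolved).  From ``death_from_index`` onward codes become 0;
    death wins when it occurs first (and on a same-day tie).
    """
    codes = np.asarray(codes, dtype=int).copy()
    detected = np.asarray(detected, dtype=bool)
    n = len(codes)
    tags = ["" for _ in range(n)]

    resolved_from: int | None = None
    if n and not detected[-1]:
        j = n
        while j > 0 and not detected[j - 1]:
            j -= 1
        run = n - j
        has_prior_detection = detected[:j].any()
        if run >= min_undetected and has_prior_detection:
            resolved_from = j

    if death_from_index is not None and (resolved_from is None or death_from_index <= resolved_from):
        codes[death_from_index:] = DEATH
        for k in range(death_from_index, n):
            tags[k] = "death"
    elif resolved_from is not None:
        codes[resolved_from:] = RESOLVED
        for k in range(resolved_from, n):
            tags[k] = "resolved"
    return codes, tags


def classify_cohort(
    day_table: pd.DataFrame,
    *,
    death_day: dict[int, int] | None = None,
    first_day_default: int = EXCLUDED,
    min_undetected: int = 2,
) -> tuple[pd.DataFrame, CohortRefs]:
    """Classify every tumour-day of a cohort.

    ``day_table`` must have one row per (tumour_id, day) with columns
    ``call`` (ratiometric call string, or NaN when undetected),
    ``core_intensity``, ``median_tcell`` and ``detected``.  Days must be
    shared across tumours (undetected days still need a row).  Returns a
    timelines table (tumour_id, day, code, rule_tag) plus the cohort
    references used.
    """
    required = {"tumour_id", "day", "call", "core_intensity", "median_tcell", "detected"}
    missing = required - set(day_table.columns)
    if missing:
        raise ValueError(f"day_table missing columns: {sorted(missing)}")
    death_day = death_day or {}
    days = np.sort(day_table["day"].unique())

    first = day_table[(day_table["day"] == days[0]) & day_table["detected"]]
    refs = CohortRefs(desert_threshold=desert_threshold(first["median_tcell"]))

    # two passes per day: ratiometric calls define the day's inflamed
    # reference, then the full precedence (incl. reclassification) runs
    for day in days:
        sub = day_table[(day_table["day"] == day) & day_table["detected"]]
        inflamed_cores = sub.loc[sub["call"] == "inflamed", "core_intensity"].to_numpy(dtype=float)
        inflamed_cores = inflamed_cores[np.isfinite(inflamed_cores)]
        refs.inflamed_core_median[int(day)] = (
            float(np.median(inflamed_cores)) if inflamed_cores.size else None
        )

    out_rows = []
    for tid, grp in day_table.sort_values("day").groupby("tumour_id"):
        grp = grp.set_index("day").reindex(days)
        codes = np.zeros(len(days), dtype=int)
        tags: list[str] = []
        prev: int | None = None
        for j, day in enumerate(days):
            row = grp.loc[day]
            if not bool(row["detected"]) or not isinstance(row["call"], str):
                # undetected days carry the previous code until the
                # absorbing overlay decides their fate
                codes[j] = prev if prev is not None else first_day_default
                tags.append("propagated")
                continue
            code, tag = classify_day(
                row["call"], float(row["core_intensity"]), float(row["median_tcell"]),
                refs.desert_threshold, refs.inflamed_core_median[int(day)], prev,
                first_day_default=first_day_default,
            )
            codes[j] = code
            tags.append(tag)
            prev = code
        detected = grp["detected"].fillna(False).to_numpy(dtype=bool)
        death_idx = None
        if tid in death_day:
            hits = np.flatnonzero(days >= death_day[tid])
            death_idx = int(hits[0]) if hits.size else None
        codes, overlay = encode_timeline(
            codes, detected, death_from_index=death_idx, min_undetected=min_undetected
        )
        tags = [o if o else t for t, o in zip(tags, overlay)]
        for j, day in enumerate(days):
            out_rows.append((tid, int(day), int(codes[j]), tags[j]))

    timelines = pd.DataFrame(out_rows, columns=["tumour_id", "day", "code", "rule_tag"])
    return timelines, refs
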