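"""Per-tumour survival analysis.

Each tumour contributes one record: the event is tumour rejection (the
timeline entering the resolved state, or a complete response), censoring
occurs at mouse death or at the end of follow-up.  Estimation and testing
use the standard product-limit machinery (Kaplan–Meier with Greenwood
variance and log-log confidence band; log-rank tests pairwise against a
reference group), with tumours — not mice — as the survival unit.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

from .states import RESOLVED, DEATH


def build_records(
    timelines: pd.DataFrame,
    *,
    horizon: int | None = None,
    group: dict[int, str] | str | None = None,
) -> pd.DataFrame:
    """Build survival records from a timelines table.

    ``timelines`` has columns (tumour_id, day, code).  Event time is the
    first day with code 5 (event=1).  A timeline entering code 0 first is
    censored at the last pre-death day; otherwise censoring is at
    ``horizon`` (default: last observed day).  ``group`` may be a constant
    label or a per-tumour mapping.
    """
    records = []
    for tid, grp in timelines.sort_values("day").groupby("tumour_id"):
        days = grp["day"].to_numpy()
        codes = grp["code"].to_numpy()
        res = np.flatnonzero(codes == RESOLVED)
        dth = np.flatnonzero(codes == DEATH)
        end = horizon if horizon is not None else int(days[-1])
        if res.size and (not dth.size or res[0] < dth[0]):
            time, event = int(days[res[0]]), 1
        elif dth.size:
            j = dth[0]
            time = int(days[j - 1]) if j > 0 else int(days[0])
            event = 0
        else:
            time, event = end, 0
        if isinstance(group, dict):
            label = group.get(tid)
        else:
            label = group
        records.append((tid, time, event, label))
    df = pd.DataFrame(records, columns=["tumour_id", "time", "event", "group"])
    if (df["time"] <= 0).any():
        raise ValueError("event/censoring times must be positive")
    return df


def km_estimate(records: pd.DataFrame, *, alpha: float = 0.05) -> pd.DataFrame:
    """Kaplan–Meier curve with 95% log-log (exponential Greenwood)
    confidence band.

    Returns a step-function table with columns (time, S, lo, hi, at_risk),
    including the t=0 row where S=1.
    """
    if len(records) == 0:
        raise ValueError("no records")
    kmf = KaplanMeierFitter(alpha=alpha)
    kmf.fit(records["time"], event_observed=records["event"])
    surv = kmf.survival_function_
    ci = kmf.confidence_interval_
    at_risk = kmf.event_table["at_risk"].reindex(surv.index)
    out = pd.DataFrame({
        "time": surv.index.to_numpy(dtype=float),
        "S": surv.iloc[:, 0].to_numpy(),
        "lo": ci.iloc[:, 0].to_numpy(),
        "hi": ci.iloc[:, 1].to_numpy(),
        "at_risk": at_risk.to_numpy(),
    })
    return out.reset_index(drop=True)


def logrank(records: pd.DataFrame, *, reference: str) -> pd.DataFrame:
    """Pairwise log-rank tests of every group against ``reference``.

    Returns one row per comparison with the chi-square statistic and
    p-value; empty groups are skipped with a warning.
    """
    if "group" not in records.columns:
        raise ValueError("records need a 'group' column")
    groups = [g for g in records["group"].dropna().unique() if g != reference]
    ref = records[records["group"] == reference]
    if len(ref) == 0:
        raise ValueError(f"reference group {reference!r} is empty")
    rows = []
    for g in groups:
        other = records[records["group"] == g]
        if len(other) == 0:
            warnings.warn(f"group {g!r} is empty; skipped")
            continue
        res = logrank_test(
            ref["time"], other["time"],
            event_observed_A=ref["event"], event_observed_B=other["event"],
        )
        rows.append((g, reference, float(res.test_statistic), float(res.p_value)))
    return pd.DataFrame(rows, columns=["group", "reference", "statistic", "p"])
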