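"""Per-tumour survival grouped by landmark-day immune phenotype.

Simulates a cohort, groups tumours by their phenotype on day 8 (the
landmark used when phenotyping arrays by imaging), builds per-tumour
rejection records, and compares Kaplan–Meier curves with log-rank tests
referenced to the excluded group — inflamed tumours reject far more.
"""


from stamparray import (
    build_records,
    default_immunocompetent,
    km_estimate,
    logrank,
    simulate_cohort,
)
from stamparray.states import STATE_NAMES

LANDMARK = 8
truth = simulate_cohort(default_immunocompetent(seed=6), 400)
tl = truth.trajectory_table()[["tumour_id", "day", "phenotype_code"]]
tl = tl.rename(columns={"phenotype_code": "code"})

phen_at_landmark = {
    t.tumour_id: int(t.phenotype_seq[list(truth.days).index(LANDMARK)])
    for t in truth.tumours
}
group = {
    tid: STATE_NAMES[c] for tid, c in phen_at_landmark.items() if c in (1, 2, 3)
}
records = build_records(tl, group=group)
records = records.dropna(subset=["group"])

for name, grp in records.groupby("group"):
    km = km_estimate(grp)
    final = km["S"].iloc[-1]
    print(f"{name:9s}: n={len(grp):3d}, events={int(grp['event'].sum()):3d}, "
          f"S(day {int(km['time'].iloc[-1])}) = {final:.2f} [{km['lo'].iloc[-1]:.2f}, {km['hi'].iloc[-1]:.2f}]")

tests = logrank(records, reference="excluded")
print("\nlog-rank vs excluded (chi-square, p):")
for _, row in tests.iterrows():
    print(f"  {row['group']:9s} chi2 = {row['statistic']:7.2f}, p = {row['p']:.2e}")
print("tumours inflamed at the landmark day reject more and survive less "
      "as lesions; deserts rarely reject")
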