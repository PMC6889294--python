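"""Kaplan-Meier estimation and the 4-group log-rank test.

Reads the reference cohort's survival table (exponential disease-free
survival times with group medians 55.40 / 38.33 / 34.43 / 27.70 months,
~15% censoring), prints each group's KM median and the log-rank result.
A small p-value indicates the four biotypes separate prognostically.
"""

from ecsubtype.fixture import build_reference_fixture
from ecsubtype.stats import km_estimate, logrank_test, survival_records_from_frame

cohort, _ = build_reference_fixture(seed=0)
records = survival_records_from_frame(cohort.survival, endpoint="DFS")

for group in ("POLE", "MSI", "CNL", "CNH"):
    sub = [r for r in records if r.group == group]
    km = km_estimate(sub)
    median = "not reached" if km.median is None else f"{km.median:.1f} months"
    print(f"{group:<5} n={len(sub):>2}  KM median DFS: {median}")

res = logrank_test(records)
print(f"\nlog-rank: statistic {res.statistic:.3f}, df {res.df}, p {res.p:.4f}")
print("The statistic compares observed vs expected events per group under "
      "the shared-hazard null.")
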