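"""Build a cause-stratified life table from raw death/population counts.

Cause-specific expected rates are the anchor of partitioned excess-hazard
analysis: every stratum of the model needs its own background rate by
attained age, sex and calendar year.
"""

import pandas as pd

from flexcess import SWEDISH_CVD_SCHEME, build_from_counts, classify_cause

# raw cells: deaths from the cause stratum, total deaths, population
counts = pd.DataFrame({
    "age":     [60, 61, 62, 60, 61, 62],
    "sex":     ["female"] * 6,
    "year":    [1980, 1980, 1980, 1981, 1981, 1981],
    "d_cause": [12, 15, 13, 11, 14, 16],
    "d_total": [55, 60, 58, 50, 61, 63],
    "N":       [11000, 10800, 10500, 11100, 10900, 10600],
})

table = build_from_counts(counts, cause_label="cvd", residual_label="other")
r_cvd = table.lookup(61.4, "female", 1980, "cvd")
r_other = table.lookup(61.4, "female", 1980, "other")
print(f"expected rate, age 61, 1980, cvd:   {r_cvd:.5f} per person-year")
print(f"expected rate, age 61, 1980, other: {r_other:.5f} per person-year")
print("-> a 61-year-old woman free of the disease under study had a "
      f"{1000 * r_cvd:.2f}/1000 py background cardiovascular mortality rate")

# ICD codes are classified into strata revision-by-revision
for code, year in [("410", 1990), ("I21", 2000), ("C50", 2000)]:
    stratum = classify_cause(code, year, SWEDISH_CVD_SCHEME)
    print(f"ICD {code!r} coded in {year} -> stratum {stratum!r}")
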