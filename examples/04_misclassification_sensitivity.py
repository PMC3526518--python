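"""How robust is the partition to miscoded causes of death?

The excess count of cause-specific deaths (observed minus expected) drives
the partitioned model.  This analysis asks what fraction of the observed
cause-specific deaths would have to be coded erroneously to shrink the
excess by 10, 15 or 20% — a small required fraction would mean the
conclusions lean heavily on coding quality.

The worked input is the published table of observed and expected
cardiovascular deaths among Swedish breast cancer patients diagnosed
1973-1992, by age group and diagnosis period.
"""

from flexcess import load_reference_counts, sensitivity_table

counts = load_reference_counts()
out = sensitivity_table(counts, reductions=(0.10, 0.15, 0.20))

cols = ["year_band", "age_band", "at_risk", "observed", "expected",
        "excess_deaths", "misclass_10", "misclass_15", "misclass_20"]
print(out[cols].to_string(index=False))

lo, hi = out["misclass_10"].min(), out["misclass_10"].max()
print(f"\n-> across every covariate pattern, miscoding {lo:.1f}-{hi:.1f}% of "
      "the observed CVD deaths would be needed to cut the excess CVD deaths "
      "by 10% — the partition is not fragile to plausible coding error")
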