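"""Classify county-day winds into Beaufort exposure categories.

Exposure begins at gale force (34 kt) and hurricane force at 64 kt,
both inclusive.  The summary mirrors the descriptive statistics used
for a national exposure dataset: totals, per-month and per-state
counts, and the hurricane-force share.
"""

import stormlag as sl

config = sl.SimConfig(n_counties=100, start_year=1999, end_year=2014, seed=1)
panel, _ = sl.simulate_panel(config)

exposure = sl.make_exposure_panel(
    panel[["county_id", "date", "wind_knots"]], panel[["county_id", "date"]]
)
summ = sl.summarize_exposure(exposure)

print(f"total exposure days: {summ.total_days}")
print(f"exposed counties:    {summ.n_exposed_counties}")
print(
    "per-county days:     "
    f"min={summ.county_min:g} median={summ.county_median:g} "
    f"mean={summ.county_mean:.2f} max={summ.county_max:g}"
)
print(f"hurricane force:     {summ.hurricane_days} ({100 * summ.hurricane_share:.1f}%)")
print(f"September share:     {100 * summ.september_share:.1f}%")
print("\nper-month counts (all fall in May-October by construction):")
print(summ.per_month)
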