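"""Simulate a synthetic county-day hospitalization panel with known truth.

Builds a small 10-county, 4-year panel with a strong lag-1 exposure
effect, and prints the panel head plus the planted exposure calendar.
"""

import stormlag as sl

config = sl.SimConfig(
    n_counties=10,
    start_year=2000,
    end_year=2003,
    true_beta_lags=(0.0, 0.2, 0.1, 0.0, 0.0, 0.0, 0.0, 0.0),
    exposure_rate=1.0,  # ~1 exposure day per county-year, May-October only
    seed=42,
)
panel, truth = sl.simulate_panel(config)

print(panel.head())
print(f"\nrows: {len(panel)}, counties: {panel['county_id'].nunique()}")
print(f"planted exposure days: {len(truth.exposure_calendar)}")
print(truth.exposure_calendar.head())
print("\ntrue lag coefficients (log rate ratios):")
print(truth.true_beta)
# Counts average population * baseline_rate / 10,000 per day, modulated by
# season, weekday, temperature, and the lagged exposure effects above.
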