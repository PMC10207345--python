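#!/usr/bin/env python
"""Descriptive trends: classify country trajectories and average by region.

Reads the simulated panel from step 01, labels each country's gender-gap
trajectory (interior peak / increasing / decreasing), tabulates peak
values, and computes the unweighted per-region mean series.
"""

import argparse
from pathlib import Path

import pandas as pd

from stgap.io import stamp_lines, write_scores
from stgap.panel import read_panel_csv
from stgap.trends import classify_panel, peak_value_table, region_average

parser = argparse.ArgumentParser()
parser.add_argument("--sim-dir", type=Path, default=Path("results/sim"))
parser.add_argument("--out", type=Path, default=Path("results/trends"))
args = parser.parse_args()

panel = read_panel_csv(args.sim_dir / "panel.csv")
classes = classify_panel(panel)
args.out.mkdir(parents=True, exist_ok=True)
stamp = stamp_lines()

rows = [
    {"country_id": cid, "label": c.label, "peak_year": c.peak_year,
     "peak_value": c.peak_value, "slope_per_decade": c.slope_estimate}
    for cid, c in classes.items()
]
write_scores(pd.DataFrame(rows), args.out / "trends.csv", header_lines=stamp)
peaks = peak_value_table(classes)
write_scores(peaks, args.out / "peaks.csv", header_lines=stamp)
regions = region_average(panel)
write_scores(regions, args.out / "region_averages.csv", header_lines=stamp)

counts = pd.Series([c.label for c in classes.values()]).value_counts()
print(f"classified {len(classes)} countries:")
for label in ("peak", "increasing", "decreasing"):
    print(f"  {label:10s} {counts.get(label, 0)}")
if len(peaks):
    top = peaks.iloc[0]
    print(f"highest peak: {top['country_id']} at {int(top['peak_year'])} "
          f"({top['peak_value']:.2f} years)")
print("region-average series (last year):")
last = regions[regions["year"] == regions["year"].max()]
for _, row in last.iterrows():
    print(f"  {row['region']:22s} {row['mean']:+.3f} "
          f"(n={int(row['n_countries'])})")
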