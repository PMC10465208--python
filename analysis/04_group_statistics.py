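#!/usr/bin/env python
"""Phase contrasts: Mann-Whitney tiers and onset/offset AUC tables.

Reads results/features.csv (from 03_extract_features.py), writes the
mean +- sd table, the significance-tier table (contrasts A: baseline vs
1st min, B: 1st vs 2nd min, C: 2nd min vs recovery) and the AUC table
(contrasts A and C, 0.8 flagged), then prints the headline findings.
"""
from pathlib import Path

import pandas as pd

from ppgstress.pipeline import analyze_features_csv

OUT = Path(__file__).resolve().parents[1] / "results"
features_csv = OUT / "features.csv"
if not features_csv.exists():
    raise SystemExit("run analysis/03_extract_features.py first")

tables = analyze_features_csv(features_csv, OUT)

t4 = tables.table4
a_total = t4[(t4.feature == "total_sampen") & (t4.contrast == "A")]
print("TotalSampEn onset detection (contrast A) AUC by cell:")
print(a_total.pivot_table(index="wavelength", columns="stressor",
                          values="auc").round(2))
print(f"flagged (AUC >= 0.8): {int(a_total.flagged.sum())}/{len(a_total)} cells")

t12 = tables.table1_2
avg = t12[t12.feature == "avg_sampen"].pivot_table(
    index="wavelength", columns="phase", values="mean")
print("\nAvgSampEn cohort means by phase:")
print(avg[["baseline", "min1", "min2", "recovery"]].round(3))

features = pd.read_csv(features_csv)
total = t12[t12.feature == "total_sampen"].pivot_table(
    index="wavelength", columns="phase", values="mean")
print("\nTotalSampEn cohort means by phase:")
print(total[["baseline", "min1", "min2", "recovery"]].round(1))
print("\ntables written:", ", ".join(
    str(OUT / n) for n in ("table1_2.csv", "table3.csv", "table4.csv")))
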