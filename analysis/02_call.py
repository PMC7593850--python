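#!/usr/bin/env python
"""Validate bisulfite calls against the site catalog; global summaries.

Ingests every sample's per-context bedGraphs, applies the >= 20X coverage and
catalog-membership filter, and reports per-sample called-site counts and
methylation fractions, per-context cross-sample means, the genome-wide
percent methylation, and the methylation-ratio histogram of one control
sample (ratios below 0.05 excluded, 0.1 bins).
"""

from pathlib import Path

import pandas as pd

from picomethyl import calling, pipeline

ROOT = Path(__file__).resolve().parents[1]
EXP = ROOT / "scratch" / "experiment"
OUT = ROOT / "scratch" / "calling"
RESULTS = ROOT / "results"

pipeline.run_call(EXP, OUT)
summary = pd.read_csv(OUT / "global_summary.tsv", sep="\t")
summary.to_csv(RESULTS / "global_methylation_summary.tsv", sep="\t", index=False)

frac = summary[["frac_CpG", "frac_CHG", "frac_CHH"]]
print("per-context mean methylation fraction across samples:")
print((100 * frac.mean()).round(1).to_string())

catalog, profiles, gnm, _ = pipeline.load_experiment(EXP)
d4c1 = profiles["D4_control_1"]
cpg = d4c1.calls_in_context("CpG")["ratio"]
hist = calling.ratio_histogram(cpg)
hist.to_csv(RESULTS / "cpg_ratio_histogram_D4_control_1.tsv", sep="\t")
shares = calling.bimodality_summary(cpg)
print(f"\nD4_control_1: {len(cpg)} called CpG sites, mean ratio {cpg.mean():.3f}")
print(f"bimodality: {100*shares['unmethylated']:.1f}% < 0.2, "
      f"{100*shares['moderate']:.1f}% in [0.4,0.6], {100*shares['methylated']:.1f}% > 0.8")
print(f"ratio histogram written to {RESULTS / 'cpg_ratio_histogram_D4_control_1.tsv'}")
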