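#!/usr/bin/env python
"""Reporting tables: Manhattan data and per-sex cohort summaries.

Writes manhattan.tsv (-log10 nominal p by mitochondrial position with the
per-chip Bonferroni significance line) and cohort_summary.tsv (per-chip,
per-sex lipid means +/- SD), and prints the per-chip significance
thresholds.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import CONFIG_PATH, RESULTS

from mtgwas.cli import _load_config, _report_stage, _selected_chips

cfg = _load_config(str(CONFIG_PATH))
chips = _selected_chips(cfg, ())
_report_stage(cfg, RESULTS, chips, float(cfg["association"]["alpha"]))

manhattan = pd.read_csv(RESULTS / "manhattan.tsv", sep="\t")
for chip, thr in manhattan.groupby("chip_name").threshold.first().items():
    print(f"{chip}: -log10 significance line at {thr:.3f}")
top = manhattan.sort_values("neglog10_p", ascending=False).head(5)
print("\ntop signals:")
print(top.to_string(index=False))
print(f"\ntables in {RESULTS}/")
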