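#!/usr/bin/env python
"""Per-chip association scan of the lipid traits.

Fits, for every kept probe and each of TC/HDL/LDL/TG, the linear model
y ~ centered log2(A/B) + sex + centered age, applies the Wald test and the
per-chip Bonferroni correction, and attaches cross-chip nominal p-values
at shared positions.  Prints the significant hits (the planted HDL effect
should surface on the largest chip) and writes results.tsv.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import CONFIG_PATH, RESULTS

from mtgwas.cli import _associate_stage, _load_config, _selected_chips

cfg = _load_config(str(CONFIG_PATH))
chips = _selected_chips(cfg, ())
alpha = float(cfg["association"]["alpha"])
phenos = tuple(cfg["association"]["phenotypes"])
results = _associate_stage(cfg, RESULTS, chips, alpha, phenos)

sig = results[results.significant]
print(f"{len(results)} probe x phenotype tests; {len(sig)} significant after Bonferroni")
if len(sig):
    cols = ["chip_name", "phenotype", "position_bp", "gene", "beta_snp",
            "p_nominal", "p_adjusted", "minor_allele_increases_trait"]
    print(sig[cols].to_string(index=False))
print(f"full table in {RESULTS/'results.tsv'}")
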