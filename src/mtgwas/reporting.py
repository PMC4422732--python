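"""Manhattan-style scan summaries over the mitochondrial genome.

The plot data carry one row per association record with -log10 nominal p,
plus one per-chip dashed threshold line at -log10(0.05 / m), m being the
number of probes tested on that chip.  Rendering is optional; the tables
are the contract.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .association import AssociationRecord


@dataclass
class ManhattanData:
    rows: pd.DataFrame             # position_bp, phenotype, chip, neglog10_p, gene
    threshold_lines: dict[str, float]  # chip -> -log10(alpha / m)

    def to_tsv(self, path) -> None:
        df = self.rows.copy()
        df["threshold"] = df["chip_name"].map(self.threshold_lines)
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def significance_threshold(m: int, alpha: float = 0.05) -> float:
    """Pointwise -log10 significance line for an m-probe chip."""
    return -math.log10(alpha / m)


def make_manhattan(records: list[AssociationRecord], alpha: float = 0.05) -> ManhattanData:
    """Tabulate -log10(p_nominal) by genome position, phenotype and chip."""
    if not records:
        raise ValueError("no association records to plot")
    rows = pd.DataFrame(
        {
            "position_bp": [r.position_bp for r in records],
            "phenotype": [r.phenotype_name for r in records],
            "chip_name": [r.chip_name for r in records],
            "p_nominal": [r.fit.p_nominal for r in records],
            "gene": [r.gene_symbol for r in records],
        }
    )
    return manhattan_from_frame(rows, alpha)


def manhattan_from_frame(results: pd.DataFrame, alpha: float = 0.05) -> ManhattanData:
    """Build Manhattan data from a results table.

    Requires columns chip_name, phenotype, position_bp, p_nominal and
    (optionally) gene.
    """
    rows = results.copy()
    if "gene" not in rows.columns:
        rows["gene"] = ""
    rows["neglog10_p"] = -np.log10(rows["p_nominal"].to_numpy(dtype=float))
    rows = rows.sort_values(
        ["phenotype", "chip_name", "position_bp"], kind="stable"
    ).reset_index(drop=True)
    rows = rows[["position_bp", "phenotype", "chip_name", "neglog10_p", "gene"]]
    # m per (chip, phenotype) can differ if probes were skipped; the line per
    # chip uses the maximum tested count across phenotypes (the chip's m)
    m_by_chip: dict[str, int] = {}
    counts = rows.groupby(["chip_name", "phenotype"]).size()
    for (chip, _), n in counts.items():
        m_by_chip[chip] = max(m_by_chip.get(chip, 0), int(n))
    thresholds = {chip: significance_threshold(m, alpha) for chip, m in m_by_chip.items()}
    return ManhattanData(rows=rows, threshold_lines=thresholds)


def plot_manhattan(data: ManhattanData, path) -> None:
    """Optional figure rendering (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    phenos = sorted(data.rows["phenotype"].unique())
    fig, axes = plt.subplots(len(phenos), 1, figsize=(9, 2.4 * len(phenos)), sharex=True)
    if len(phenos) == 1:
        axes = [axes]
    for ax, ph in zip(axes, phenos):
        sub = data.rows[data.rows["phenotype"] == ph]
        for chip, chunk in sub.groupby("chip_name"):
            ax.scatter(chunk["position_bp"], chunk["neglog10_p"], s=6, label=chip)
            ax.axhline(data.threshold_lines[chip], ls="--", lw=0.8)
        ax.set_ylabel(f"{ph}\n-log10 p")
        ax.legend(fontsize=6)
    axes[-1].set_xlabel("mtDNA position (bp, rCRS)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
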