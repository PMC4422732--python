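"""Design constants of the published four-chip mitochondrial lipid scan.

These numbers describe the study whose analysis chain this package
implements: per-chip probe totals before QC, probes removed by the
upper-bound (saturation) rule and by Build-38 unmappability, the per-chip
sample sizes, replicate intensity measures per allele (I_SNP), and the
number of intensity ratios flagged as outliers.  They are used as *inputs*
when rebuilding the QC bookkeeping on synthetic data of the same design;
kept-probe counts and I_tot are always recomputed, never stored.
"""

from __future__ import annotations

from dataclasses import dataclass

from .chip_model import total_intensity_measures


@dataclass(frozen=True)
class StudyChipDesign:
    chip_name: str
    n_probes_total: int          # mitochondrial probes on the chip before QC
    n_excluded_upper_bound: int  # removed by the saturation (upper-bound) rule
    n_excluded_no_build38: int   # removed because unmappable on Build 38
    sample_size: int             # individuals passing genotyping QC on this chip
    n_measures: int              # replicate intensity measures per allele (I_SNP)
    n_outlier_ratios: int        # log2-ratio values flagged by outlier detection

    @property
    def n_probes_kept(self) -> int:
        return self.n_probes_total - self.n_excluded_upper_bound - self.n_excluded_no_build38

    @property
    def i_tot(self) -> int:
        return total_intensity_measures(self.n_measures, self.sample_size, self.n_probes_kept)


STUDY_CHIPS: tuple[StudyChipDesign, ...] = (
    StudyChipDesign("Affy6.0", 465, 0, 54, 1647, 3, 230),
    StudyChipDesign("Axiom", 252, 37, 0, 2731, 4, 42),
    StudyChipDesign("Exome", 226, 0, 0, 2721, 1, 128),
    StudyChipDesign("Metabochip", 135, 0, 9, 2815, 1, 98),
)

PHENOTYPES = ("tc", "hdl", "ldl", "tg")
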