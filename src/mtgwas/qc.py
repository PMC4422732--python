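"""Intensity quality control for heteroplasmy-aware association scans.

The chain, in fixed order, mirrors how raw microarray allele intensities are
prepared before the log-ratio regression:

1. probe exclusions (Build-38 unmappable; saturation "upper bound" rule),
2. per-individual background subtraction (5% quantile of the individual's
   pooled measures),
3. quantile normalization across individuals (Bolstad rank-mean method),
4. per-probe log2 intensity ratios z = log2((A + eps) / (B + eps)) over
   replicate means, with A the major- and B the minor-allele channel,
5. iterative robust outlier masking (median / scaled MAD),
6. per-probe centering of the unmasked ratios.

:func:`run_qc` enforces the order and produces the bookkeeping report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .chip_model import ChipManifest, total_intensity_measures
from .simulate import RawIntensityTensor

logger = logging.getLogger(__name__)

MAD_SCALE = 1.4826  # consistency factor: scaled MAD estimates sigma under normality


@dataclass
class QCParams:
    background_quantile: float = 0.05
    epsilon: float = 1.0            # added to both channels inside the log ratio
    outlier_k: float = 5.0          # mask |z - median| > k * scaled MAD
    outlier_max_iter: int = 10
    outlier_abs_tol: float = 1e-8   # degenerate (MAD = 0) probes
    saturation_fraction_cutoff: float = 0.05


@dataclass
class LogRatioMatrix:
    """Per-individual, per-probe log2(A/B) with an outlier mask.

    Masked entries are excluded from every downstream statistic.  Probes
    dropped during QC (all entries masked, or fewer than two unmasked
    values at centering) are recorded in ``dropped_probes``.
    """

    z: np.ndarray            # (n_individuals, n_probes)
    mask: np.ndarray         # bool, same shape; True = outlier / excluded
    individual_ids: list[str]
    probe_ids: list[str]
    chip_name: str
    centered: bool = False
    dropped_probes: list[str] = field(default_factory=list)

    @property
    def n_outliers(self) -> int:
        return int(self.mask.sum())

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(
            np.where(self.mask, np.nan, self.z),
            index=pd.Index(self.individual_ids, name="individual_id"),
            columns=self.probe_ids,
        )
        df.to_csv(path, sep="\t", float_format="%.10g")

    @classmethod
    def from_tsv(cls, path, chip_name: str, centered: bool = True) -> "LogRatioMatrix":
        df = pd.read_csv(path, sep="\t", index_col="individual_id")
        z = df.to_numpy(dtype=float)
        mask = np.isnan(z)
        return cls(
            np.nan_to_num(z), mask, [str(i) for i in df.index], list(df.columns),
            chip_name, centered=centered,
        )


@dataclass
class ExclusionResult:
    excluded_upper_bound: list[str]
    excluded_no_build38: list[str]

    @property
    def n_excluded_upper_bound(self) -> int:
        return len(self.excluded_upper_bound)

    @property
    def n_excluded_no_build38(self) -> int:
        return len(self.excluded_no_build38)

    def to_frame(self) -> pd.DataFrame:
        rows = [(p, "no_B38") for p in self.excluded_no_build38]
        rows += [(p, "UB") for p in self.excluded_upper_bound]
        return pd.DataFrame(rows, columns=["probe_id", "reason"])


@dataclass
class QCReport:
    """Bookkeeping of one chip's QC, including the I_tot identity."""

    chip_name: str
    n_probes_input: int
    n_excluded_upper_bound: int
    n_excluded_no_build38: int
    n_probes_kept: int
    sample_size: int
    n_measures: int
    i_tot: int
    n_outlier_ratios: int
    outlier_fraction: float

    def __post_init__(self) -> None:
        assert self.n_probes_kept == (
            self.n_probes_input - self.n_excluded_upper_bound - self.n_excluded_no_build38
        ), "kept-probe identity violated"
        assert self.i_tot == total_intensity_measures(
            self.n_measures, self.sample_size, self.n_probes_kept
        ), "I_tot identity violated"

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def to_text(self) -> str:
        return (
            f"chip {self.chip_name}: {self.n_probes_input} probes, "
            f"excluded UB={self.n_excluded_upper_bound} no_B38={self.n_excluded_no_build38}, "
            f"kept {self.n_probes_kept}; sample {self.sample_size}, I_SNP={self.n_measures}, "
            f"I_tot={self.i_tot}; outlier ratios {self.n_outlier_ratios} "
            f"({100 * self.outlier_fraction:.3f}%)"
        )


def build_qc_report(
    chip_name: str,
    n_probes_input: int,
    n_excluded_upper_bound: int,
    n_excluded_no_build38: int,
    sample_size: int,
    n_measures: int,
    n_outlier_ratios: int,
) -> QCReport:
    kept = n_probes_input - n_excluded_upper_bound - n_excluded_no_build38
    n_ratios = sample_size * kept
    return QCReport(
        chip_name=chip_name,
        n_probes_input=n_probes_input,
        n_excluded_upper_bound=n_excluded_upper_bound,
        n_excluded_no_build38=n_excluded_no_build38,
        n_probes_kept=kept,
        sample_size=sample_size,
        n_measures=n_measures,
        i_tot=total_intensity_measures(n_measures, sample_size, kept),
        n_outlier_ratios=n_outlier_ratios,
        outlier_fraction=(n_outlier_ratios / n_ratios) if n_ratios else 0.0,
    )


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------

def apply_probe_exclusions(
    manifest: ChipManifest,
    tensor: RawIntensityTensor,
    saturation_fraction_cutoff: float = 0.05,
) -> tuple[ChipManifest, RawIntensityTensor, ExclusionResult]:
    """Remove unmappable probes and probes saturating the vendor ceiling.

    Applied to the *raw* tensor, before any transformation.  A probe is
    removed by the upper-bound rule when more than ``saturation_fraction_cutoff``
    of its raw measures sit at or above the chip's saturation cap.  A probe
    failing both rules is counted once, as unmappable.
    """
    if list(manifest.probe_ids) != list(tensor.probe_ids):
        raise ValueError("manifest and tensor probe lists disagree")
    sat_frac = (tensor.values >= manifest.saturation_cap).mean(axis=(0, 2, 3))
    no_b38, upper = [], []
    keep = []
    for j, probe in enumerate(manifest.probes):
        if not probe.mappable_build38:
            no_b38.append(probe.probe_id)
        elif sat_frac[j] > saturation_fraction_cutoff:
            upper.append(probe.probe_id)
        else:
            keep.append(probe.probe_id)
    result = ExclusionResult(excluded_upper_bound=upper, excluded_no_build38=no_b38)
    logger.info(
        "%s: excluded %d upper-bound, %d no-Build38 of %d probes",
        manifest.chip_name, len(upper), len(no_b38), manifest.n_probes,
    )
    return manifest.subset(keep), tensor.subset_probes(keep), result


def subtract_background(
    tensor: RawIntensityTensor, quantile: float = 0.05, floor: float = 0.0
) -> RawIntensityTensor:
    """Per individual: subtract the 5% quantile of all pooled measures.

    The quantile pools every measure of that individual on the chip (all
    probes, both allele channels, all replicates) and uses linear
    interpolation between order statistics; results are clamped at ``floor``.
    """
    flat = tensor.values.reshape(tensor.n_individuals, -1)
    if flat.shape[1] == 0:
        logger.warning("individuals with zero measures; background subtraction skipped")
        return tensor
    q = np.quantile(flat, quantile, axis=1, method="linear")
    values = np.maximum(tensor.values - q[:, None, None, None], floor)
    return RawIntensityTensor(values, list(tensor.individual_ids), list(tensor.probe_ids), tensor.chip_name)


def quantile_normalize(tensor: RawIntensityTensor) -> RawIntensityTensor:
    """Bolstad quantile normalization across individuals within one chip.

    Each individual's pooled measure vector is sorted, the mean at each rank
    across individuals forms the reference distribution, and every measure
    is mapped to the reference value at its rank.  Ties take the average of
    their ranks' reference values (fractional ranks are interpolated, as in
    limma's implementation).  After normalization, every individual's sorted
    vector is identical.
    """
    n_ind = tensor.n_individuals
    if n_ind <= 1:
        return tensor
    flat = tensor.values.reshape(n_ind, -1)
    ref = np.sort(flat, axis=1).mean(axis=0)
    m = flat.shape[1]
    out = np.empty_like(flat)
    grid = np.arange(1.0, m + 1.0)
    for i in range(n_ind):
        ranks = rankdata(flat[i], method="average")
        out[i] = np.interp(ranks, grid, ref)
    return RawIntensityTensor(
        out.reshape(tensor.values.shape), list(tensor.individual_ids),
        list(tensor.probe_ids), tensor.chip_name,
    )


def compute_log_ratio(
    tensor: RawIntensityTensor, manifest: ChipManifest, epsilon: float = 1.0
) -> LogRatioMatrix:
    """z = log2((mean A + eps) / (mean B + eps)) over replicate measures.

    A is the major-allele channel, B the minor-allele channel; ``epsilon``
    guards zeros symmetrically so equal channels give z = 0 exactly.
    """
    if list(manifest.probe_ids) != list(tensor.probe_ids):
        raise ValueError("manifest and tensor probe lists disagree")
    a_bar = tensor.values[:, :, 0, :].mean(axis=2)
    b_bar = tensor.values[:, :, 1, :].mean(axis=2)
    z = np.log2((a_bar + epsilon) / (b_bar + epsilon))
    return LogRatioMatrix(
        z, np.zeros_like(z, dtype=bool), list(tensor.individual_ids),
        list(tensor.probe_ids), tensor.chip_name,
    )


def detect_outliers(
    z: LogRatioMatrix, k: float = 5.0, max_iter: int = 10, abs_tol: float = 1e-8
) -> LogRatioMatrix:
    """Iterative per-probe robust outlier masking.

    Per probe, until stable (at most ``max_iter`` rounds): compute the
    median and the scaled MAD (1.4826 * median |z - median|) of the
    unmasked values; mask values with |z - median| > k * scaled MAD.
    Probes whose unmasked values have zero MAD mask only values differing
    from the median by more than ``abs_tol``.  Probes ending fully masked
    are dropped.  Idempotent: re-running adds no masks.
    """
    if z.centered:
        raise ValueError("outlier detection must run before centering")
    mask = z.mask.copy()
    for _ in range(max_iter):
        work = np.where(mask, np.nan, z.z)
        with np.errstate(all="ignore"):
            med = np.nanmedian(work, axis=0)
            mad = np.nanmedian(np.abs(work - med), axis=0)
        dev = np.abs(z.z - med)
        cut = np.where(mad > 0, k * MAD_SCALE * mad, abs_tol)
        new_mask = (dev > cut) & ~np.isnan(dev)
        new_mask |= mask
        if (new_mask == mask).all():
            break
        mask = new_mask
    dropped = [p for j, p in enumerate(z.probe_ids) if mask[:, j].all()]
    if dropped:
        logger.warning("%s: %d probes fully masked by outlier detection: %s",
                       z.chip_name, len(dropped), dropped[:10])
    logger.info("%s: %d outlier ratios masked", z.chip_name, int(mask.sum()))
    return LogRatioMatrix(
        z.z.copy(), mask, list(z.individual_ids), list(z.probe_ids), z.chip_name,
        centered=False, dropped_probes=sorted(set(z.dropped_probes) | set(dropped)),
    )


def center(z: LogRatioMatrix) -> LogRatioMatrix:
    """Subtract the per-probe mean of unmasked ratios (mean 0 within 1e-9).

    Probes with fewer than two unmasked values are dropped.  Idempotent.
    """
    work = np.where(z.mask, np.nan, z.z)
    counts = (~z.mask).sum(axis=0)
    with np.errstate(all="ignore"):
        means = np.nanmean(work, axis=0)
    means = np.where(counts > 0, means, 0.0)
    out = z.z - means
    low = counts < 2
    dropped = [p for j, p in enumerate(z.probe_ids) if low[j]]
    if dropped:
        logger.warning("%s: %d probes with <2 unmasked ratios dropped at centering",
                       z.chip_name, len(dropped))
    return LogRatioMatrix(
        out, z.mask.copy(), list(z.individual_ids), list(z.probe_ids), z.chip_name,
        centered=True, dropped_probes=sorted(set(z.dropped_probes) | set(dropped)),
    )


def center_vector(x: np.ndarray) -> np.ndarray:
    """Center a covariate vector (e.g. age) on its mean."""
    x = np.asarray(x, dtype=float)
    return x - (x.mean() if x.size else 0.0)


def run_qc(
    tensor: RawIntensityTensor, manifest: ChipManifest, params: QCParams | None = None
) -> tuple[LogRatioMatrix, ChipManifest, QCReport, ExclusionResult]:
    """Full QC chain in the fixed order; returns centered ratios + report."""
    p = params or QCParams()
    kept_manifest, kept_tensor, excl = apply_probe_exclusions(
        manifest, tensor, p.saturation_fraction_cutoff
    )
    bg = subtract_background(kept_tensor, p.background_quantile)
    qn = quantile_normalize(bg)
    z = compute_log_ratio(qn, kept_manifest, p.epsilon)
    z = detect_outliers(z, p.outlier_k, p.outlier_max_iter, p.outlier_abs_tol)
    z = center(z)
    report = build_qc_report(
        chip_name=manifest.chip_name,
        n_probes_input=manifest.n_probes,
        n_excluded_upper_bound=excl.n_excluded_upper_bound,
        n_excluded_no_build38=excl.n_excluded_no_build38,
        sample_size=tensor.n_individuals,
        n_measures=tensor.n_measures,
        n_outlier_ratios=z.n_outliers,
    )
    return z, kept_manifest, report, excl
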