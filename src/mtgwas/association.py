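"""Per-chip linear-model association scan on centered log intensity ratios.

For each kept probe and each lipid phenotype, ordinary least squares of

    y = b0 + b_snp * z + b_sex * 1[female] + b_age * age_centered + error

where z is the centered log2(A/B) intensity ratio (A = major allele,
B = minor allele).  Significance of b_snp comes from a Wald test against a
Student-t reference with n - 4 degrees of freedom, two-sided, followed by
per-chip Bonferroni correction with the number of probes tested on that
chip.  Because z falls as the minor-allele fraction rises, b_snp < 0 means
the minor allele is associated with a *higher* trait value.

Each chip is scanned separately (different vendors measure intensities on
incomparable scales); cross-chip agreement is reported as an overlap of
nominal p-values at shared genomic positions, never pooled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .chip_model import ChipManifest, annotate_position
from .qc import LogRatioMatrix, center_vector

logger = logging.getLogger(__name__)


class RankDeficientError(ValueError):
    """Design matrix not full rank (e.g. constant log ratio)."""


class DomainError(ValueError):
    pass


@dataclass
class ModelFit:
    beta_snp: float
    se_snp: float
    beta_sex: float
    se_sex: float
    beta_age: float
    se_age: float
    intercept: float
    n_used: int
    wald_stat: float
    p_nominal: float


@dataclass
class AssociationRecord:
    probe_id: str
    chip_name: str
    phenotype_name: str
    position_bp: int
    rs_id: str | None
    allele_major: str
    allele_minor: str
    fit: ModelFit
    p_adjusted: float
    significant: bool
    minor_allele_increases_trait: bool
    gene_symbol: str
    overlap: list[tuple[str, float]] = field(default_factory=list)


def fit_lipid_model(y, z, sex, age_centered) -> ModelFit:
    """OLS of y on {1, z, female indicator, centered age} with Wald t-test.

    ``sex`` is the female indicator (male = 0 baseline).  The p-value uses
    a Student-t reference with n - 4 degrees of freedom, two-sided.
    """
    y, z, sex, age_centered = (np.asarray(v, dtype=float) for v in (y, z, sex, age_centered))
    n = y.size
    if not (z.size == sex.size == age_centered.size == n):
        raise ValueError("design vectors have unequal lengths")
    if n <= 4:
        raise RankDeficientError(f"n={n} too small for a 4-parameter model")
    X = np.column_stack([np.ones(n), z, sex, age_centered])
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < 4:
        raise RankDeficientError("design matrix is rank deficient")
    resid = y - X @ beta
    df = n - 4
    sigma2 = float(resid @ resid) / df
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se  # se = 0 only for an exact fit; p then underflows to the clamp
    p = 2.0 * stats.t.sf(np.abs(t[1]), df)
    return ModelFit(
        beta_snp=float(beta[1]), se_snp=float(se[1]),
        beta_sex=float(beta[2]), se_sex=float(se[2]),
        beta_age=float(beta[3]), se_age=float(se[3]),
        intercept=float(beta[0]), n_used=int(n),
        wald_stat=float(t[1]), p_nominal=float(max(p, np.nextafter(0.0, 1.0))),
    )


def bonferroni(p_nominal: float, m: int) -> float:
    """Family-wise adjustment: min(1, m * p)."""
    if m < 1:
        raise DomainError(f"correction factor m must be >= 1, got {m}")
    if not (0.0 < p_nominal <= 1.0):
        raise DomainError(f"p_nominal {p_nominal} outside (0, 1]")
    return min(1.0, m * p_nominal)


def scan_chip(
    z_matrix: LogRatioMatrix,
    phenotypes: pd.DataFrame,
    manifest: ChipManifest,
    alpha: float = 0.05,
    phenotype_names: tuple[str, ...] = ("tc", "hdl", "ldl", "tg"),
    n_min: int = 30,
) -> list[AssociationRecord]:
    """One association record per kept probe x phenotype, sorted by position.

    ``phenotypes`` must already have eligibility applied (no diabetics).
    Individuals are matched by id between the ratio matrix and the
    phenotype table; age is centered on the matched chip sample.  Probes
    with fewer than ``n_min`` usable ratios, or a degenerate design, are
    skipped with a log entry.  The Bonferroni factor is the number of
    probes actually tested for that phenotype on this chip.
    """
    if not z_matrix.centered:
        raise ValueError("log-ratio matrix must be centered before scanning")
    pheno = phenotypes.set_index("individual_id")
    shared = [i for i in z_matrix.individual_ids if i in pheno.index]
    if not shared:
        logger.warning("%s: no individuals shared with phenotype table", z_matrix.chip_name)
        return []
    row_of = {ind: i for i, ind in enumerate(z_matrix.individual_ids)}
    rows = np.array([row_of[i] for i in shared])
    sub = pheno.loc[shared]
    female = (sub["sex"].to_numpy() == "female").astype(float)
    age_c = center_vector(sub["age_years"].to_numpy(dtype=float))
    dropped = set(z_matrix.dropped_probes)
    probe_info = {p.probe_id: p for p in manifest.probes}

    records: list[AssociationRecord] = []
    for ph in phenotype_names:
        y_all = sub[ph].to_numpy(dtype=float)
        fits: list[tuple[str, ModelFit]] = []
        for j, pid in enumerate(z_matrix.probe_ids):
            if pid in dropped:
                continue
            use = ~z_matrix.mask[rows, j] & ~np.isnan(y_all)
            if use.sum() < n_min:
                logger.info("%s/%s: probe %s skipped (n=%d < %d)",
                            z_matrix.chip_name, ph, pid, int(use.sum()), n_min)
                continue
            try:
                fit = fit_lipid_model(
                    y_all[use], z_matrix.z[rows, j][use], female[use], age_c[use]
                )
            except RankDeficientError:
                logger.info("%s/%s: probe %s skipped (degenerate design)",
                            z_matrix.chip_name, ph, pid)
                continue
            fits.append((pid, fit))
        m = len(fits)
        if m == 0:
            logger.warning("%s/%s: no probes tested", z_matrix.chip_name, ph)
            continue
        for pid, fit in fits:
            p_adj = bonferroni(fit.p_nominal, m)
            probe = probe_info[pid]
            records.append(
                AssociationRecord(
                    probe_id=pid,
                    chip_name=z_matrix.chip_name,
                    phenotype_name=ph,
                    position_bp=probe.position_bp,
                    rs_id=probe.rs_id,
                    allele_major=probe.allele_major,
                    allele_minor=probe.allele_minor,
                    fit=fit,
                    p_adjusted=p_adj,
                    significant=p_adj <= alpha,
                    minor_allele_increases_trait=fit.beta_snp < 0,
                    gene_symbol=annotate_position(probe.position_bp),
                )
            )
    records.sort(key=lambda r: (r.phenotype_name, r.position_bp, r.probe_id))
    return records


def cross_chip_lookup(records_by_chip: dict[str, list[AssociationRecord]]) -> None:
    """Fill ``overlap`` on significant records with other chips' nominal p.

    Probes are matched across chips by genomic position and allele pair
    (vendor probe ids differ); a record never lists its own chip.  Modifies
    records in place.
    """
    index: dict[tuple[int, str, str, str], dict[str, float]] = {}
    for chip, records in records_by_chip.items():
        for r in records:
            key = (r.position_bp, r.allele_major, r.allele_minor, r.phenotype_name)
            index.setdefault(key, {})[chip] = r.fit.p_nominal
    for chip, records in records_by_chip.items():
        for r in records:
            if not r.significant:
                continue
            key = (r.position_bp, r.allele_major, r.allele_minor, r.phenotype_name)
            r.overlap = sorted(
                (other, p) for other, p in index.get(key, {}).items() if other != chip
            )


def records_to_frame(records: list[AssociationRecord]) -> pd.DataFrame:
    """Flatten association records into the results table."""
    return pd.DataFrame(
        {
            "chip_name": [r.chip_name for r in records],
            "phenotype": [r.phenotype_name for r in records],
            "position_bp": [r.position_bp for r in records],
            "probe_id": [r.probe_id for r in records],
            "rs_id": [r.rs_id or "" for r in records],
            "alleles": [f"{r.allele_major}>{r.allele_minor}" for r in records],
            "gene": [r.gene_symbol for r in records],
            "beta_snp": [r.fit.beta_snp for r in records],
            "se_snp": [r.fit.se_snp for r in records],
            "beta_sex": [r.fit.beta_sex for r in records],
            "beta_age": [r.fit.beta_age for r in records],
            "n_used": [r.fit.n_used for r in records],
            "p_nominal": [r.fit.p_nominal for r in records],
            "p_adjusted": [r.p_adjusted for r in records],
            "significant": [r.significant for r in records],
            "minor_allele_increases_trait": [r.minor_allele_increases_trait for r in records],
            "overlap": [
                ";".join(f"{c}:{p:.3g}" for c, p in r.overlap) for r in records
            ],
        }
    )
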