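"""Lipid phenotype derivation, eligibility exclusions and cohort summaries.

Phenotype tables are plain pandas DataFrames with columns ``individual_id``,
``sex`` (male/female), ``age_years``, ``hdl``, ``ldl``, ``tg``,
``diabetes_t2`` and the derived ``tc``.  All lipids are in mg/dL.  Total
cholesterol is always the Friedewald-style combination
``TC = HDL + LDL + 0.2 * TG``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LIPID_COLUMNS = ("hdl", "ldl", "tg")
REQUIRED_COLUMNS = ("individual_id", "sex", "age_years", "hdl", "ldl", "tg", "diabetes_t2")


class PhenotypeError(ValueError):
    """Invalid phenotype data."""


def derive_tc(hdl, ldl, tg):
    """Total cholesterol in mg/dL: TC = HDL + LDL + 0.2 * TG.

    Accepts scalars or arrays; inputs must be nonnegative.
    """
    hdl, ldl, tg = (np.asarray(x, dtype=float) for x in (hdl, ldl, tg))
    for name, v in (("hdl", hdl), ("ldl", ldl), ("tg", tg)):
        if np.any(v[~np.isnan(v)] < 0):
            raise PhenotypeError(f"negative {name} value")
    tc = hdl + ldl + 0.2 * tg
    return float(tc) if tc.ndim == 0 else tc


def load_phenotypes(path) -> pd.DataFrame:
    """Read a phenotype TSV; derive ``tc``, or validate it if present."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise PhenotypeError(f"phenotype table missing columns: {missing}")
    return attach_tc(df)


def attach_tc(df: pd.DataFrame) -> pd.DataFrame:
    """Derive ``tc`` (or check a present ``tc`` column against the formula)."""
    df = df.copy()
    expected = derive_tc(df["hdl"], df["ldl"], df["tg"])
    if "tc" in df.columns:
        ok = np.isnan(expected) | np.isclose(df["tc"].to_numpy(dtype=float), expected, atol=1e-6)
        if not np.all(ok):
            raise PhenotypeError(
                f"{int((~ok).sum())} rows violate TC = HDL + LDL + 0.2*TG"
            )
    df["tc"] = expected
    return df


def apply_eligibility(table: pd.DataFrame, trait: str | None = None) -> pd.DataFrame:
    """Drop type-2-diabetes individuals and, if ``trait`` given, rows missing it.

    Idempotent; logs removal counts.
    """
    n0 = len(table)
    out = table.loc[~table["diabetes_t2"].astype(bool)].copy()
    n_diabetes = n0 - len(out)
    n_missing = 0
    if trait is not None:
        keep = out[trait].notna()
        n_missing = int((~keep).sum())
        out = out.loc[keep].copy()
    logger.info(
        "eligibility: removed %d diabetic, %d missing-%s of %d rows",
        n_diabetes, n_missing, trait, n0,
    )
    return out.reset_index(drop=True)


def cohort_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per-sex n and mean +/- SD of age and lipids (sample SD, 0 for n=1)."""
    rows = []
    for sex in ("male", "female"):
        sub = table.loc[table["sex"] == sex]
        row: dict[str, object] = {"sex": sex, "n": len(sub)}
        for col in ("age_years", "tc", "hdl", "ldl", "tg"):
            vals = sub[col].dropna().to_numpy(dtype=float) if len(sub) else np.array([])
            if vals.size == 0:
                row[f"{col}_mean"], row[f"{col}_sd"] = np.nan, np.nan
            else:
                row[f"{col}_mean"] = float(vals.mean())
                row[f"{col}_sd"] = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)
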