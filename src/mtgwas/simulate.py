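"""Synthetic cohorts, heteroplasmy fractions, replicate allele intensities
and lipid phenotypes.

The generator emulates the statistical structure the downstream analysis
assumes.  For each individual and mitochondrial probe, a minor-allele
fraction ``h`` (heteroplasmy) is drawn: with probability ``maf`` the
individual carries the minor allele and ``h ~ Beta(a, b)`` (optionally
forced to full homoplasmy h=1), otherwise ``h = 0``.  Each of the chip's
replicate measures then reports

    A channel (major):  background + brightness * (1 - h)
    B channel (minor):  background + brightness * h

times a multiplicative log-normal noise factor with coefficient of
variation ``noise_cv`` (unit mean), clipped to the vendor saturation cap;
with probability ``outlier_rate`` a measure is replaced by a gross
corruption uniform on [0, cap].

Lipid phenotypes follow the linear model the scan fits: per phenotype,
``intercept + beta_z * z_true + beta_sex * 1[female] + beta_age *
(age - mean age) + N(0, residual_sd)``, where ``z_true`` is the noise- and
background-free log2 intensity ratio implied by ``h`` (same epsilon floor
as the QC stage, so the generative effect scale is the fitted covariate
scale).  Total cholesterol is always derived as TC = HDL + LDL + 0.2*TG,
never simulated independently.

Default phenotype parameters mimic a middle-aged central-European
population cohort (lipids in mg/dL, ages 31-85): HDL higher in females,
TG higher in males and with age.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .chip_model import ChipManifest, ProbeRecord, MT_GENOME_LENGTH
from .phenotype import derive_tc

SIM_PHENOTYPES = ("hdl", "ldl", "tg")

# fixed per-stage tags so partial pipelines replay identically
_STAGE = {"cohort": 11, "heteroplasmy": 12, "intensities": 13, "phenotypes": 14, "manifest": 15}


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class CausalEffect:
    probe_id: str
    phenotype: str
    beta: float  # phenotype units per unit log2-ratio


@dataclass
class SimulationConfig:
    seed: int
    n_individuals: int
    manifest: ChipManifest
    maf: float | list[float] = 0.01  # scalar or per-probe carrier frequency
    het_beta_a: float = 2.0
    het_beta_b: float = 2.0
    p_full_homoplasmy: float = 0.0
    brightness: float = 1000.0
    background_level: float = 50.0
    noise_cv: float = 0.1
    outlier_rate: float = 0.0
    causal_effects: list[CausalEffect] = field(default_factory=list)
    beta_sex: dict[str, float] = field(
        default_factory=lambda: {"hdl": 11.2, "ldl": -4.0, "tg": -33.0}
    )
    beta_age: dict[str, float] = field(
        default_factory=lambda: {"hdl": 0.0, "ldl": 0.3, "tg": 0.5}
    )
    intercepts: dict[str, float] = field(
        default_factory=lambda: {"hdl": 51.0, "ldl": 139.0, "tg": 145.0}
    )
    residual_sd: dict[str, float] = field(
        default_factory=lambda: {"hdl": 13.0, "ldl": 34.0, "tg": 85.0}
    )
    diabetes_rate: float = 0.07
    epsilon: float = 1.0  # matches the QC log-ratio floor

    def validate(self) -> None:
        for name in ("p_full_homoplasmy", "outlier_rate", "diabetes_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name}={v} outside [0, 1]")
        maf = np.asarray(self.maf, dtype=float)
        if np.any(maf < 0) or np.any(maf > 1):
            raise ConfigError("maf values must lie in [0, 1]")
        if maf.ndim not in (0, 1) or (maf.ndim == 1 and maf.size != self.manifest.n_probes):
            raise ConfigError("maf must be a scalar or one value per probe")
        if self.n_individuals < 0:
            raise ConfigError("n_individuals must be >= 0")
        if self.het_beta_a <= 0 or self.het_beta_b <= 0:
            raise ConfigError("Beta shape parameters must be > 0")
        if self.noise_cv < 0:
            raise ConfigError("noise_cv must be >= 0")
        if not (self.brightness > self.background_level >= 0.0):
            raise ConfigError("need brightness > background_level >= 0")
        for ph, sd in self.residual_sd.items():
            if sd <= 0:
                raise ConfigError(f"residual_sd[{ph}] must be > 0")
        ids = set(self.manifest.probe_ids)
        for ce in self.causal_effects:
            if ce.probe_id not in ids:
                raise ConfigError(f"causal effect references unknown probe {ce.probe_id!r}")
            if ce.phenotype not in SIM_PHENOTYPES:
                raise ConfigError(f"causal effect on non-simulated phenotype {ce.phenotype!r}")

    def _rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng([_STAGE[stage], int(self.seed)])

    # -- config file round trip (manifest travels as its own TSV) ----------
    def to_yaml(self, path, manifest_path) -> None:
        d = dataclasses.asdict(self)
        d.pop("manifest")
        if not np.isscalar(d["maf"]):
            d["maf"] = [float(x) for x in np.asarray(d["maf"], dtype=float)]
        d["manifest_tsv"] = str(manifest_path)
        d["saturation_cap"] = self.manifest.saturation_cap
        d["causal_effects"] = [dataclasses.asdict(ce) for ce in self.causal_effects]
        self.manifest.to_tsv(manifest_path)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        manifest = ChipManifest.from_tsv(
            d.pop("manifest_tsv"), saturation_cap=float(d.pop("saturation_cap", 65535.0))
        )
        d["causal_effects"] = [CausalEffect(**ce) for ce in d.get("causal_effects", [])]
        return cls(manifest=manifest, **d)


@dataclass
class HeteroplasmyMatrix:
    """Minor-allele fraction per individual x probe; non-carriers are exactly 0."""

    values: np.ndarray  # (n_individuals, n_probes), in [0, 1]
    individual_ids: list[str]
    probe_ids: list[str]


@dataclass
class RawIntensityTensor:
    """Raw allele intensities, (individual, probe, allele channel, replicate).

    Channel 0 is the major (A) allele, channel 1 the minor (B) allele.
    """

    values: np.ndarray  # (n_ind, n_probe, 2, n_measures), all >= 0
    individual_ids: list[str]
    probe_ids: list[str]
    chip_name: str

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_probes(self) -> int:
        return self.values.shape[1]

    @property
    def n_measures(self) -> int:
        return self.values.shape[3]

    def subset_probes(self, probe_ids: list[str]) -> "RawIntensityTensor":
        index = {p: i for i, p in enumerate(self.probe_ids)}
        idx = [index[p] for p in probe_ids]
        return RawIntensityTensor(
            self.values[:, idx, :, :].copy(), list(self.individual_ids), list(probe_ids), self.chip_name
        )

    def to_long_frame(self) -> pd.DataFrame:
        n_i, n_p, _, n_r = self.values.shape
        ii, pp, aa, rr = np.meshgrid(
            np.arange(n_i), np.arange(n_p), np.arange(2), np.arange(n_r), indexing="ij"
        )
        return pd.DataFrame(
            {
                "individual_id": np.asarray(self.individual_ids, dtype=object)[ii.ravel()],
                "probe_id": np.asarray(self.probe_ids, dtype=object)[pp.ravel()],
                "allele": np.where(aa.ravel() == 0, "A", "B"),
                "replicate": rr.ravel() + 1,
                "intensity": self.values.ravel(),
            }
        )

    def to_tsv(self, path) -> None:
        self.to_long_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_long_frame(cls, df: pd.DataFrame, chip_name: str) -> "RawIntensityTensor":
        individuals = list(pd.unique(df["individual_id"]))
        probes = list(pd.unique(df["probe_id"]))
        n_r = int(df["replicate"].max())
        values = np.full((len(individuals), len(probes), 2, n_r), np.nan)
        i_idx = df["individual_id"].map({v: i for i, v in enumerate(individuals)}).to_numpy()
        p_idx = df["probe_id"].map({v: i for i, v in enumerate(probes)}).to_numpy()
        a_idx = (df["allele"].to_numpy() == "B").astype(int)
        r_idx = df["replicate"].to_numpy() - 1
        values[i_idx, p_idx, a_idx, r_idx] = df["intensity"].to_numpy()
        if np.isnan(values).any():
            raise ValueError("long-format intensity table is not a complete tensor")
        return cls(values, individuals, probes, chip_name)

    @classmethod
    def from_tsv(cls, path, chip_name: str) -> "RawIntensityTensor":
        return cls.from_long_frame(pd.read_csv(path, sep="\t"), chip_name)


def make_synthetic_manifest(
    chip_name: str,
    n_probes: int,
    n_measures: int,
    seed: int,
    n_unmappable: int = 0,
    saturation_cap: float = 65535.0,
) -> ChipManifest:
    """Random chip manifest: unique positions, random distinct allele pairs.

    The last ``n_unmappable`` probes (in probe-id order) are flagged as not
    mappable on Build 38.
    """
    rng = np.random.default_rng([_STAGE["manifest"], int(seed)])
    positions = rng.choice(np.arange(1, MT_GENOME_LENGTH + 1), size=n_probes, replace=False)
    positions.sort()
    nts = np.array(list("ACGT"))
    probes = []
    for i, pos in enumerate(positions):
        major, minor = rng.choice(nts, size=2, replace=False)
        probes.append(
            ProbeRecord(
                probe_id=f"{chip_name}_p{i:04d}",
                position_bp=int(pos),
                allele_major=str(major),
                allele_minor=str(minor),
                n_measures=n_measures,
                mappable_build38=i < n_probes - n_unmappable,
            )
        )
    return ChipManifest(chip_name, probes, saturation_cap)


def simulate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Individuals with sex, age and diabetes status (no lipid values yet)."""
    config.validate()
    rng = config._rng("cohort")
    n = config.n_individuals
    return pd.DataFrame(
        {
            "individual_id": [f"ind{i:06d}" for i in range(n)],
            "sex": np.where(rng.random(n) < 0.5, "female", "male"),
            "age_years": rng.integers(31, 86, size=n),
            "diabetes_t2": rng.random(n) < config.diabetes_rate,
        }
    )


def simulate_heteroplasmy(config: SimulationConfig) -> HeteroplasmyMatrix:
    config.validate()
    rng = config._rng("heteroplasmy")
    n, p = config.n_individuals, config.manifest.n_probes
    maf = np.broadcast_to(np.asarray(config.maf, dtype=float), (p,))
    carrier = rng.random((n, p)) < maf
    h = rng.beta(config.het_beta_a, config.het_beta_b, size=(n, p))
    if config.p_full_homoplasmy > 0:
        h = np.where(rng.random((n, p)) < config.p_full_homoplasmy, 1.0, h)
    h = np.where(carrier, h, 0.0)
    return HeteroplasmyMatrix(
        h, [f"ind{i:06d}" for i in range(n)], list(config.manifest.probe_ids)
    )


def simulate_intensities(config: SimulationConfig, H: HeteroplasmyMatrix) -> RawIntensityTensor:
    config.validate()
    n, p = H.values.shape
    if (n, p) != (config.n_individuals, config.manifest.n_probes):
        raise ValueError(
            f"heteroplasmy matrix {H.values.shape} does not match cohort x manifest "
            f"({config.n_individuals}, {config.manifest.n_probes})"
        )
    rng = config._rng("intensities")
    n_r = config.manifest.n_measures
    cap = config.manifest.saturation_cap
    h = H.values[:, :, None, None]
    mean = np.concatenate(
        [
            config.background_level + config.brightness * (1.0 - h),
            config.background_level + config.brightness * h,
        ],
        axis=2,
    )  # (n, p, 2, 1)
    mean = np.broadcast_to(mean, (n, p, 2, n_r)).copy()
    if config.noise_cv > 0:
        # log-normal factor with unit mean and sd = noise_cv
        sigma2 = np.log1p(config.noise_cv**2)
        noise = np.exp(rng.normal(-0.5 * sigma2, np.sqrt(sigma2), size=mean.shape))
        mean *= noise
    if config.outlier_rate > 0:
        gross = rng.random(mean.shape) < config.outlier_rate
        mean = np.where(gross, rng.uniform(0.0, cap, size=mean.shape), mean)
    values = np.clip(mean, 0.0, cap)
    return RawIntensityTensor(values, list(H.individual_ids), list(H.probe_ids), config.manifest.chip_name)


def true_log_ratio(config: SimulationConfig, H: HeteroplasmyMatrix) -> np.ndarray:
    """Noise- and background-free log2 intensity ratio implied by h."""
    eps = config.epsilon
    a = config.brightness * (1.0 - H.values)
    b = config.brightness * H.values
    return np.log2((a + eps) / (b + eps))


def simulate_phenotypes(
    config: SimulationConfig, H: HeteroplasmyMatrix, cohort: pd.DataFrame
) -> pd.DataFrame:
    """Attach hdl/ldl/tg (and derived tc) to the cohort table."""
    config.validate()
    if len(cohort) != H.values.shape[0]:
        raise ValueError("cohort and heteroplasmy matrix disagree on n_individuals")
    rng = config._rng("phenotypes")
    z_true = true_log_ratio(config, H)
    probe_index = {p: j for j, p in enumerate(H.probe_ids)}
    female = (cohort["sex"].to_numpy() == "female").astype(float)
    age_c = cohort["age_years"].to_numpy(dtype=float)
    age_c = age_c - (age_c.mean() if len(age_c) else 0.0)

    out = cohort.copy()
    for ph in SIM_PHENOTYPES:
        y = np.full(len(cohort), config.intercepts[ph])
        y += config.beta_sex[ph] * female + config.beta_age[ph] * age_c
        for ce in config.causal_effects:
            if ce.phenotype == ph:
                y = y + ce.beta * z_true[:, probe_index[ce.probe_id]]
        y += rng.normal(0.0, config.residual_sd[ph], size=len(cohort))
        # lipid concentrations cannot be negative; truncation is negligible
        # at default parameters (means several SDs above zero)
        out[ph] = np.maximum(y, 0.0)
    out["tc"] = derive_tc(out["hdl"].to_numpy(), out["ldl"].to_numpy(), out["tg"].to_numpy())
    return out


def simulate_all(config: SimulationConfig) -> tuple[pd.DataFrame, HeteroplasmyMatrix, RawIntensityTensor]:
    """Cohort with phenotypes, heteroplasmy matrix and raw intensity tensor."""
    cohort = simulate_cohort(config)
    H = simulate_heteroplasmy(config)
    tensor = simulate_intensities(config, H)
    phenotypes = simulate_phenotypes(config, H, cohort)
    return phenotypes, H, tensor
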