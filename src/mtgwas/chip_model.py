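"""Genotyping-chip manifests, the rCRS gene map, and intensity bookkeeping.

The mitochondrial genome is the 16,569 bp revised Cambridge Reference
Sequence (rCRS, GenBank J01415.2); all coordinates in this package are
1-based positions on that sequence.  A chip manifest describes the
mitochondrial probes of one genotyping array: position, major/minor allele,
the number of replicate intensity measures per allele the vendor chemistry
produces (``n_measures``), and whether the probe position is mappable on
genome Build 38.

The bookkeeping identity ``I_tot = I_SNP * 2 * sample_size * n_probes``
(two allele channels per probe) is exposed as
:func:`total_intensity_measures` and used by the QC report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

MT_GENOME_LENGTH = 16569
_NUCLEOTIDES = frozenset("ACGT")


class CoordinateError(ValueError):
    """Position outside the mitochondrial genome [1, 16569]."""


class DomainError(ValueError):
    """Argument outside the operation's domain."""


@dataclass(frozen=True)
class ProbeRecord:
    """One mitochondrial probe on a genotyping chip.

    ``n_measures`` is the number of replicate intensity measures per allele
    channel (vendor-specific; constant within one chip).
    """

    probe_id: str
    position_bp: int
    allele_major: str
    allele_minor: str
    n_measures: int
    mappable_build38: bool = True
    rs_id: str | None = None


@dataclass
class ChipManifest:
    """Ordered probe list for one chip plus the vendor intensity ceiling."""

    chip_name: str
    probes: list[ProbeRecord]
    saturation_cap: float = 65535.0

    @property
    def n_probes(self) -> int:
        return len(self.probes)

    @property
    def probe_ids(self) -> list[str]:
        return [p.probe_id for p in self.probes]

    @property
    def positions(self) -> list[int]:
        return [p.position_bp for p in self.probes]

    @property
    def n_measures(self) -> int:
        """Replicate measures per allele; must be constant across probes."""
        counts = {p.n_measures for p in self.probes}
        if len(counts) != 1:
            raise DomainError(
                f"chip {self.chip_name!r}: n_measures not constant: {sorted(counts)}"
            )
        return counts.pop()

    def sorted_by_position(self) -> "ChipManifest":
        return ChipManifest(
            self.chip_name,
            sorted(self.probes, key=lambda p: (p.position_bp, p.probe_id)),
            self.saturation_cap,
        )

    def subset(self, probe_ids: list[str]) -> "ChipManifest":
        keep = set(probe_ids)
        return ChipManifest(
            self.chip_name,
            [p for p in self.probes if p.probe_id in keep],
            self.saturation_cap,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chip_name": self.chip_name,
                "probe_id": [p.probe_id for p in self.probes],
                "position_bp": [p.position_bp for p in self.probes],
                "allele_major": [p.allele_major for p in self.probes],
                "allele_minor": [p.allele_minor for p in self.probes],
                "n_measures": [p.n_measures for p in self.probes],
                "mappable_build38": [p.mappable_build38 for p in self.probes],
                "rs_id": [p.rs_id if p.rs_id is not None else "" for p in self.probes],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, saturation_cap: float = 65535.0) -> "ChipManifest":
        df = pd.read_csv(path, sep="\t", dtype={"rs_id": str}, keep_default_na=False)
        names = df["chip_name"].unique()
        if len(names) != 1:
            raise DomainError(f"manifest TSV must describe one chip, found {list(names)}")
        probes = [
            ProbeRecord(
                probe_id=str(r.probe_id),
                position_bp=int(r.position_bp),
                allele_major=str(r.allele_major),
                allele_minor=str(r.allele_minor),
                n_measures=int(r.n_measures),
                mappable_build38=_as_bool(r.mappable_build38),
                rs_id=str(r.rs_id) or None,
            )
            for r in df.itertuples(index=False)
        ]
        return cls(str(names[0]), probes, saturation_cap)


def _as_bool(x) -> bool:
    if isinstance(x, str):
        return x.strip().lower() in {"true", "1", "yes"}
    return bool(x)


# --------------------------------------------------------------------------
# rCRS gene map
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneInterval:
    gene_symbol: str
    start_bp: int
    end_bp: int
    product_class: str  # protein | tRNA | rRNA | control-region


# Standard rCRS annotation (J01415.2): 13 protein genes, 22 tRNAs, 2 rRNAs
# and the two hypervariable segments of the control region.  1-based closed
# intervals on the heavy-strand coordinate system; light-strand genes are
# listed by their genomic footprint.  Several pairs genuinely overlap
# (MT-TI/MT-TQ, MT-ATP8/MT-ATP6, MT-ND4L/MT-ND4, single-bp abutments).
_RCRS_GENES: list[tuple[str, int, int, str]] = [
    ("HVR2", 57, 372, "control-region"),
    ("MT-TF", 577, 647, "tRNA"),
    ("MT-RNR1", 648, 1601, "rRNA"),
    ("MT-TV", 1602, 1670, "tRNA"),
    ("MT-RNR2", 1671, 3229, "rRNA"),
    ("MT-TL1", 3230, 3304, "tRNA"),
    ("MT-ND1", 3307, 4262, "protein"),
    ("MT-TI", 4263, 4331, "tRNA"),
    ("MT-TQ", 4329, 4400, "tRNA"),
    ("MT-TM", 4402, 4469, "tRNA"),
    ("MT-ND2", 4470, 5511, "protein"),
    ("MT-TW", 5512, 5579, "tRNA"),
    ("MT-TA", 5587, 5655, "tRNA"),
    ("MT-TN", 5657, 5729, "tRNA"),
    ("MT-TC", 5761, 5826, "tRNA"),
    ("MT-TY", 5826, 5891, "tRNA"),
    ("MT-CO1", 5904, 7445, "protein"),
    ("MT-TS1", 7446, 7514, "tRNA"),
    ("MT-TD", 7518, 7585, "tRNA"),
    ("MT-CO2", 7586, 8269, "protein"),
    ("MT-TK", 8295, 8364, "tRNA"),
    ("MT-ATP8", 8366, 8572, "protein"),
    ("MT-ATP6", 8527, 9207, "protein"),
    ("MT-CO3", 9207, 9990, "protein"),
    ("MT-TG", 9991, 10058, "tRNA"),
    ("MT-ND3", 10059, 10404, "protein"),
    ("MT-TR", 10405, 10469, "tRNA"),
    ("MT-ND4L", 10470, 10766, "protein"),
    ("MT-ND4", 10760, 12137, "protein"),
    ("MT-TH", 12138, 12206, "tRNA"),
    ("MT-TS2", 12207, 12265, "tRNA"),
    ("MT-TL2", 12266, 12336, "tRNA"),
    ("MT-ND5", 12337, 14148, "protein"),
    ("MT-ND6", 14149, 14673, "protein"),
    ("MT-TE", 14674, 14742, "tRNA"),
    ("MT-CYB", 14747, 15887, "protein"),
    ("MT-TT", 15888, 15953, "tRNA"),
    ("MT-TP", 15956, 16023, "tRNA"),
    ("HVR1", 16024, 16383, "control-region"),
]

INTERGENIC = "intergenic"


@dataclass
class MitoGeneMap:
    """Position -> gene lookup over rCRS intervals.

    Lookup is total: positions outside every interval return ``intergenic``.
    Where intervals overlap, the interval that starts first in genome order
    wins; :meth:`annotate_all` exposes every hit.
    """

    entries: list[GeneInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        for e in self.entries:
            if not (1 <= e.start_bp <= e.end_bp <= MT_GENOME_LENGTH):
                raise CoordinateError(
                    f"{e.gene_symbol}: interval [{e.start_bp}, {e.end_bp}] "
                    f"outside [1, {MT_GENOME_LENGTH}]"
                )
        self.entries = sorted(self.entries, key=lambda e: (e.start_bp, e.end_bp))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.gene_symbol, e.start_bp, e.end_bp, e.product_class) for e in self.entries],
            columns=["gene_symbol", "start_bp", "end_bp", "product_class"],
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "MitoGeneMap":
        df = pd.read_csv(path, sep="\t")
        return cls(
            [
                GeneInterval(str(r.gene_symbol), int(r.start_bp), int(r.end_bp), str(r.product_class))
                for r in df.itertuples(index=False)
            ]
        )


def default_gene_map() -> MitoGeneMap:
    """The built-in rCRS gene interval table."""
    return MitoGeneMap([GeneInterval(*row) for row in _RCRS_GENES])


_DEFAULT_MAP = default_gene_map()


def annotate_position(position_bp: int, gene_map: MitoGeneMap | None = None) -> str:
    """Gene symbol whose interval contains ``position_bp`` (first in genome order)."""
    if not (1 <= position_bp <= MT_GENOME_LENGTH):
        raise CoordinateError(f"position {position_bp} outside [1, {MT_GENOME_LENGTH}]")
    gm = gene_map if gene_map is not None else _DEFAULT_MAP
    for e in gm.entries:
        if e.start_bp <= position_bp <= e.end_bp:
            return e.gene_symbol
    return INTERGENIC


def annotate_all(position_bp: int, gene_map: MitoGeneMap | None = None) -> list[str]:
    """All gene symbols overlapping ``position_bp`` (exhaustive lookup)."""
    if not (1 <= position_bp <= MT_GENOME_LENGTH):
        raise CoordinateError(f"position {position_bp} outside [1, {MT_GENOME_LENGTH}]")
    gm = gene_map if gene_map is not None else _DEFAULT_MAP
    return [e.gene_symbol for e in gm.entries if e.start_bp <= position_bp <= e.end_bp]


# --------------------------------------------------------------------------
# Bookkeeping and validation
# --------------------------------------------------------------------------

def total_intensity_measures(n_measures: int, sample_size: int, n_probes: int) -> int:
    """Total intensity measures on a chip: n_measures * 2 * sample_size * n_probes.

    Two allele channels per probe; ``n_measures`` replicate measures per channel.
    """
    for name, v in (("n_measures", n_measures), ("sample_size", sample_size), ("n_probes", n_probes)):
        if v < 0:
            raise DomainError(f"{name} must be >= 0, got {v}")
    return int(n_measures) * 2 * int(sample_size) * int(n_probes)


def validate_manifest(manifest: ChipManifest) -> list[str]:
    """Check probe-level invariants; returns human-readable violations (empty = valid)."""
    violations: list[str] = []
    seen: dict[str, int] = {}
    counts = set()
    for p in manifest.probes:
        seen[p.probe_id] = seen.get(p.probe_id, 0) + 1
        counts.add(p.n_measures)
        if not (1 <= p.position_bp <= MT_GENOME_LENGTH):
            violations.append(f"{p.probe_id}: position_bp {p.position_bp} outside [1, {MT_GENOME_LENGTH}]")
        if p.allele_major == p.allele_minor:
            violations.append(f"{p.probe_id}: major and minor allele identical ({p.allele_major})")
        for which, a in (("major", p.allele_major), ("minor", p.allele_minor)):
            if a not in _NUCLEOTIDES:
                violations.append(f"{p.probe_id}: {which} allele {a!r} not a nucleotide")
        if p.n_measures < 1:
            violations.append(f"{p.probe_id}: n_measures {p.n_measures} < 1")
    for pid, n in seen.items():
        if n > 1:
            violations.append(f"{pid}: probe_id duplicated {n} times")
    if len(counts) > 1:
        violations.append(f"chip {manifest.chip_name}: n_measures not constant across probes: {sorted(counts)}")
    return violations
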