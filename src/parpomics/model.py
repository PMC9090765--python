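"""Core domain types for the multi-omic PARPi-response pipeline.

The pipeline operates on five substrates: allele-specific copy-number
segment profiles (scar scores), somatic variant tables (consensus
filtering, TMB, catalogs), 96-channel trinucleotide mutation catalogs
(signature refitting), expression matrices plus gene-set collections
(ranking, GSEA, signature scores), and clinical cohort records
(response labels, composite classifier).

Coordinate convention: segments are 1-based, inclusive at both ends.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CALLER_UNIVERSE",
    "CHANNELS",
    "SUBSTITUTIONS",
    "CohortRecord",
    "ExpressionMatrix",
    "GeneSetCollection",
    "MutationCatalog",
    "ResponseLabel",
    "Segment",
    "SegmentProfile",
    "SignatureMatrix",
    "VariantRecord",
    "CONSEQUENCE_CLASSES",
    "validate_variant_table",
    "variant_table",
]

#: The six somatic SNV callers whose consensus defines the variant set.
CALLER_UNIVERSE = frozenset(
    {"MuSE", "MuTect", "MuTect2", "SomaticSniper", "Strelka2", "VarScan2"}
)

CONSEQUENCE_CLASSES = frozenset(
    {
        "nonsynonymous",
        "synonymous",
        "intronic",
        "intergenic",
        "noncoding",
        "splicing",
        "other",
    }
)

#: Pyrimidine-centred single-base substitution types, COSMIC order.
SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: The 96 trinucleotide channels, lexicographic in (substitution, 5', 3').
CHANNELS = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in "ACGT"
    for three in "ACGT"
)

_CHANNEL_INDEX = {c: i for i, c in enumerate(CHANNELS)}

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


class ResponseLabel(enum.Enum):
    """Dichotomised pathologic response after neoadjuvant PARPi.

    SENSITIVE corresponds to pCR or RCB-I, RESISTANT to RCB-II or
    RCB-III (residual cancer burden classes).
    """

    SENSITIVE = "SENSITIVE"
    RESISTANT = "RESISTANT"


@dataclass(frozen=True)
class Segment:
    """One allele-specific copy-number segment (1-based, inclusive)."""

    chromosome: str
    start: int
    end: int
    major_cn: int
    minor_cn: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"segment {self.chromosome}:{self.start}-{self.end}: start > end"
            )
        if self.minor_cn < 0:
            raise ValueError("minor_cn must be >= 0")
        if self.major_cn < self.minor_cn:
            raise ValueError(
                f"segment {self.chromosome}:{self.start}-{self.end}: "
                f"major_cn ({self.major_cn}) < minor_cn ({self.minor_cn})"
            )

    @property
    def total_cn(self) -> int:
        return self.major_cn + self.minor_cn

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def allele_profile(self) -> tuple[int, int]:
        return (self.major_cn, self.minor_cn)


@dataclass
class SegmentProfile:
    """Ordered, per-chromosome non-overlapping segments of one sample."""

    sample_id: str
    segments: list[Segment] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.segments = sorted(
            self.segments, key=lambda s: (s.chromosome, s.start, s.end)
        )
        prev: dict[str, Segment] = {}
        for seg in self.segments:
            p = prev.get(seg.chromosome)
            if p is not None and seg.start <= p.end:
                raise ValueError(
                    f"sample {self.sample_id}, chromosome {seg.chromosome}: "
                    f"overlapping segments [{p.start}-{p.end}] and "
                    f"[{seg.start}-{seg.end}]"
                )
            prev[seg.chromosome] = seg

    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for seg in self.segments:
            seen.setdefault(seg.chromosome, None)
        return list(seen)

    def segments_for(self, chromosome: str) -> list[Segment]:
        return [s for s in self.segments if s.chromosome == chromosome]


@dataclass(frozen=True)
class VariantRecord:
    """One somatic SNV with multi-caller support evidence."""

    chromosome: str
    position: int
    ref: str
    alt: str
    gene: str
    consequence_class: str
    depth: int
    alt_reads: int
    vaf: float
    callers: frozenset[str]
    trinucleotide_context: Optional[str] = None

    def __post_init__(self) -> None:
        if self.consequence_class not in CONSEQUENCE_CLASSES:
            raise ValueError(
                f"variant {self.chromosome}:{self.position}: unknown "
                f"consequence_class {self.consequence_class!r}"
            )
        if self.alt_reads > self.depth:
            raise ValueError(
                f"variant {self.chromosome}:{self.position}: alt_reads "
                f"({self.alt_reads}) > depth ({self.depth})"
            )
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError("vaf must lie in [0, 1]")
        if self.depth > 0 and abs(self.vaf - self.alt_reads / self.depth) > 0.01:
            raise ValueError(
                f"variant {self.chromosome}:{self.position}: stored vaf "
                f"{self.vaf} inconsistent with alt_reads/depth "
                f"{self.alt_reads}/{self.depth}"
            )


_VARIANT_COLUMNS = [
    "chromosome",
    "position",
    "ref",
    "alt",
    "gene",
    "consequence_class",
    "depth",
    "alt_reads",
    "vaf",
    "callers",
    "trinucleotide_context",
]


def variant_table(records: Iterable[VariantRecord]) -> pd.DataFrame:
    """Build a validated variant table (one row per :class:`VariantRecord`)."""
    rows = [
        {
            "chromosome": r.chromosome,
            "position": r.position,
            "ref": r.ref,
            "alt": r.alt,
            "gene": r.gene,
            "consequence_class": r.consequence_class,
            "depth": r.depth,
            "alt_reads": r.alt_reads,
            "vaf": r.vaf,
            "callers": r.callers,
            "trinucleotide_context": r.trinucleotide_context,
        }
        for r in records
    ]
    df = pd.DataFrame(rows, columns=_VARIANT_COLUMNS)
    return df


def validate_variant_table(
    df: pd.DataFrame, caller_universe: frozenset[str] = CALLER_UNIVERSE
) -> pd.DataFrame:
    """Validate a variant table against the VariantRecord invariants.

    Raises ``ValueError`` naming the offending row. Returns the table
    unchanged on success (empty tables are valid).
    """
    missing = [c for c in _VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"variant table missing columns: {missing}")
    for i, row in df.iterrows():
        where = f"row {i} ({row['chromosome']}:{row['position']})"
        if row["consequence_class"] not in CONSEQUENCE_CLASSES:
            raise ValueError(
                f"{where}: unknown consequence_class {row['consequence_class']!r}"
            )
        if row["alt_reads"] > row["depth"]:
            raise ValueError(f"{where}: alt_reads > depth")
        if row["depth"] > 0 and abs(row["vaf"] - row["alt_reads"] / row["depth"]) > 0.01:
            raise ValueError(f"{where}: vaf inconsistent with alt_reads/depth")
        extra = set(row["callers"]) - set(caller_universe)
        if extra:
            raise ValueError(f"{where}: unknown callers {sorted(extra)}")
    return df


class MutationCatalog:
    """96-channel pyrimidine-centred substitution counts for one sample."""

    def __init__(self, counts, sample_id: str = "") -> None:
        arr = np.asarray(counts, dtype=float)
        if arr.shape != (96,):
            raise ValueError(f"catalog must have 96 channels, got {arr.shape}")
        if np.any(arr < 0):
            raise ValueError("catalog counts must be nonnegative")
        self.counts = arr
        self.sample_id = sample_id

    @classmethod
    def from_mapping(cls, counts: Mapping[str, float], sample_id: str = "") -> "MutationCatalog":
        arr = np.zeros(96)
        for channel, n in counts.items():
            if channel not in _CHANNEL_INDEX:
                raise ValueError(f"unknown channel {channel!r}")
            arr[_CHANNEL_INDEX[channel]] = n
        return cls(arr, sample_id=sample_id)

    def to_series(self) -> pd.Series:
        return pd.Series(self.counts, index=list(CHANNELS), name=self.sample_id)

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def __getitem__(self, channel: str) -> float:
        return float(self.counts[_CHANNEL_INDEX[channel]])

    def __eq__(self, other: object) -> bool:
        return isinstance(other, MutationCatalog) and np.array_equal(
            self.counts, other.counts
        )


def channel_index(channel: str) -> int:
    return _CHANNEL_INDEX[channel]


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


class SignatureMatrix:
    """Named reference signature profiles over the 96 channels.

    Each profile is nonnegative and sums to 1 (tolerance 1e-6).
    """

    def __init__(self, names: Sequence[str], profiles) -> None:
        profiles = np.asarray(profiles, dtype=float)
        if profiles.ndim != 2 or profiles.shape[1] != 96:
            raise ValueError("profiles must be (k, 96)")
        if len(names) != profiles.shape[0]:
            raise ValueError("names/profiles length mismatch")
        if len(set(names)) != len(names):
            raise ValueError("duplicate signature names")
        if np.any(profiles < 0):
            raise ValueError("signature profiles must be nonnegative")
        sums = profiles.sum(axis=1)
        bad = np.where(np.abs(sums - 1.0) > 1e-6)[0]
        if bad.size:
            raise ValueError(
                f"signature {names[bad[0]]!r} profile sums to {sums[bad[0]]}, not 1"
            )
        self.names = list(names)
        self.profiles = profiles

    def __len__(self) -> int:
        return len(self.names)

    def profile(self, name: str) -> np.ndarray:
        return self.profiles[self.names.index(name)]

    def reordered(self, names: Sequence[str]) -> "SignatureMatrix":
        idx = [self.names.index(n) for n in names]
        return SignatureMatrix(list(names), self.profiles[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.profiles.T, index=list(CHANNELS), columns=self.names
        )


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values, tagged with their scale.

    ``scale`` is either ``"counts"`` (raw counts; ``gene_lengths`` in bp
    required for TPM conversion) or ``"log2tpm"``.
    """

    values: pd.DataFrame
    scale: str
    gene_lengths: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        if self.scale not in ("counts", "log2tpm"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate gene id {dup!r}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id {dup!r}")
        if (self.values.values < 0).any() and self.scale == "counts":
            raise ValueError("counts must be nonnegative")
        if self.gene_lengths is not None:
            missing = self.values.index.difference(self.gene_lengths.index)
            if len(missing):
                raise ValueError(f"gene_lengths missing for {list(missing)[:5]}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. a GMT file) with free-text provenance."""

    sets: dict[str, list[str]]
    provenance: str = ""

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if len(members) < 1:
                raise ValueError(f"gene set {name!r} is empty")
            deduped = list(dict.fromkeys(members))
            self.sets[name] = deduped

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()


_RCB_CLASSES = ("pCR", "RCB-I", "RCB-II", "RCB-III")


@dataclass
class CohortRecord:
    """One patient's clinical annotation (germline gene, receptors, RCB)."""

    sample_id: str
    germline_gene: str
    er_status: str
    tp53: str
    rcb: str
    tnbc_subtype: str = ""
    mutations_per_mb: float = 0.0
    purity: float = 0.0
    ploidy: float = 0.0
    analyzed: bool = True

    def __post_init__(self) -> None:
        if self.germline_gene not in ("BRCA1", "BRCA2"):
            raise ValueError(
                f"sample {self.sample_id}: germline gene must be BRCA1 or "
                f"BRCA2, got {self.germline_gene!r}"
            )
        if self.rcb not in _RCB_CLASSES:
            raise ValueError(
                f"sample {self.sample_id}: unknown RCB class {self.rcb!r}"
            )
        if self.mutations_per_mb < 0:
            raise ValueError("mutations_per_mb must be >= 0")
        if not 0.0 <= self.purity <= 1.0:
            raise ValueError("purity must lie in [0, 1]")

    @property
    def tnbc(self) -> bool:
        return self.er_status.strip().upper() == "TNBC"

    @property
    def er_positive(self) -> bool:
        """Any nonzero ER positivity counts as ER+ (including weak staining)."""
        status = self.er_status
        if self.tnbc:
            return False
        if "ER+" in status.replace(" ", ""):
            return True
        import re

        m = re.search(r"ER\s*(\d+)\s*%", status)
        return bool(m and int(m.group(1)) > 0)

    @property
    def tp53_mutant(self) -> bool:
        return self.tp53.strip().lower() not in ("", "wt")
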