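"""Genome builds: chromosome lengths, centromeres, acrocentric p-arms.

Scar scores need to know where chromosomes end (telomeric imbalance),
where centromeres sit (an imbalanced run must stop before the
centromere to count), and which p-arms to ignore (the acrocentric
chromosomes 13, 14, 15 and 22 have no exome coverage on the p-arm).

Two builds ship with the package: ``"toy"`` (three 200 Mb chromosomes,
centromere at 90-100 Mb, chromosome 3 flagged acrocentric) used by the
simulators and oracles, and ``"hg19-like"`` (the 22 autosomes plus X
with standard UCSC lengths and centromere gap intervals).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Union

import pandas as pd

__all__ = ["ChromosomeInfo", "GenomeBuild", "load_genome_build", "write_genome_build"]

_BUILTIN = {"toy": "toy_build.tsv", "hg19-like": "hg19_like_build.tsv"}


@dataclass(frozen=True)
class ChromosomeInfo:
    name: str
    length: int
    centromere_start: int
    centromere_end: int

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"chromosome {self.name}: nonpositive length")
        if not 0 < self.centromere_start < self.centromere_end < self.length:
            raise ValueError(
                f"chromosome {self.name}: centromere "
                f"[{self.centromere_start}, {self.centromere_end}] does not "
                f"lie strictly inside (0, {self.length})"
            )


class GenomeBuild:
    """Ordered chromosome table with centromeres and acrocentric flags."""

    def __init__(
        self,
        chromosomes: list[ChromosomeInfo],
        acrocentric_p_arms: set[str] | None = None,
        name: str = "",
    ) -> None:
        if not chromosomes:
            raise ValueError("a genome build needs at least one chromosome")
        names = [c.name for c in chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        self.chromosomes = {c.name: c for c in chromosomes}
        self.acrocentric_p_arms = set(
            acrocentric_p_arms if acrocentric_p_arms is not None else set()
        )
        unknown = self.acrocentric_p_arms - set(names)
        if unknown:
            raise ValueError(f"acrocentric chromosomes not in build: {unknown}")
        self.name = name

    def __contains__(self, chromosome: str) -> bool:
        return chromosome in self.chromosomes

    def __getitem__(self, chromosome: str) -> ChromosomeInfo:
        try:
            return self.chromosomes[chromosome]
        except KeyError:
            raise KeyError(f"chromosome {chromosome!r} not in build {self.name!r}")

    @property
    def autosomes(self) -> list[str]:
        """Chromosome names identifiable as autosomes 1-22 (optionally chr-prefixed)."""
        out = []
        for name in self.chromosomes:
            bare = name[3:] if name.lower().startswith("chr") else name
            if bare.isdigit() and 1 <= int(bare) <= 22:
                out.append(name)
        return out

    def is_autosome(self, chromosome: str) -> bool:
        return chromosome in set(self.autosomes)

    def is_acrocentric(self, chromosome: str) -> bool:
        return chromosome in self.acrocentric_p_arms

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "chromosome": c.name,
                "length": c.length,
                "centromere_start": c.centromere_start,
                "centromere_end": c.centromere_end,
                "acrocentric": int(c.name in self.acrocentric_p_arms),
            }
            for c in self.chromosomes.values()
        ]
        return pd.DataFrame(rows)


def _from_frame(df: pd.DataFrame, name: str) -> GenomeBuild:
    required = {"chromosome", "length", "centromere_start", "centromere_end"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"build config missing columns: {sorted(missing)}")
    chroms = [
        ChromosomeInfo(
            name=str(r["chromosome"]),
            length=int(r["length"]),
            centromere_start=int(r["centromere_start"]),
            centromere_end=int(r["centromere_end"]),
        )
        for _, r in df.iterrows()
    ]
    acro = set()
    if "acrocentric" in df.columns:
        acro = {
            str(r["chromosome"]) for _, r in df.iterrows() if int(r["acrocentric"])
        }
    return GenomeBuild(chroms, acrocentric_p_arms=acro, name=name)


def load_genome_build(name_or_path: Union[str, Path]) -> GenomeBuild:
    """Load a builtin build (``"toy"``, ``"hg19-like"``) or a TSV config."""
    key = str(name_or_path)
    if key in _BUILTIN:
        ref = resources.files("parpomics.data").joinpath(_BUILTIN[key])
        with resources.as_file(ref) as path:
            df = pd.read_csv(path, sep="\t", dtype=str).astype(
                {
                    "length": int,
                    "centromere_start": int,
                    "centromere_end": int,
                    "acrocentric": int,
                }
            )
        return _from_frame(df, name=key)
    path = Path(name_or_path)
    if not path.exists():
        raise FileNotFoundError(
            f"{name_or_path!r} is neither a builtin build "
            f"({sorted(_BUILTIN)}) nor an existing file"
        )
    df = pd.read_csv(path, sep="\t")
    return _from_frame(df, name=path.stem)


def write_genome_build(build: GenomeBuild, path: Union[str, Path]) -> None:
    build.to_frame().to_csv(path, sep="\t", index=False)
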