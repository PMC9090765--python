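"""Consensus variant filtering, tumor mutation burden, and catalogs.

The consensus filter keeps somatic SNVs supported by at least 2 of the
6 callers, 20 reads of depth and 5% variant allele frequency, and (for
the mutation-burden path) restricts to nonsynonymous changes. The
signature-analysis path applies the same support thresholds but keeps
all consequence classes. TMB is the surviving nonsynonymous count per
megabase of unique exome target. Catalogs fold every SNV into the
pyrimidine-centred 96-channel trinucleotide frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import CHANNELS, MutationCatalog, channel_index, reverse_complement

__all__ = ["ConsensusThresholds", "consensus_filter", "tmb", "build_catalog"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConsensusThresholds:
    """Support thresholds of the consensus filter."""

    min_callers: int = 2
    min_depth: int = 20
    min_vaf: float = 0.05
    require_nonsynonymous: bool = True

    def __post_init__(self) -> None:
        if self.min_callers < 1:
            raise ValueError("min_callers must be >= 1")
        if not 0.0 <= self.min_vaf <= 1.0:
            raise ValueError("min_vaf must lie in [0, 1]")


def consensus_filter(
    variants: pd.DataFrame,
    thresholds: ConsensusThresholds = ConsensusThresholds(),
) -> pd.DataFrame:
    """Apply the multi-caller consensus filter; row order is preserved.

    The VAF used for thresholding is recomputed as alt_reads/depth
    (callers disagree on VAF definitions; the stored column is only
    validated at read time).
    """
    if len(variants) == 0:
        return variants.copy()
    n_callers = variants["callers"].map(len)
    vaf = variants["alt_reads"] / variants["depth"].clip(lower=1)
    mask = (
        (n_callers >= thresholds.min_callers)
        & (variants["depth"] >= thresholds.min_depth)
        & (vaf >= thresholds.min_vaf)
    )
    if thresholds.require_nonsynonymous:
        mask &= variants["consequence_class"] == "nonsynonymous"
    return variants[mask].copy()


def tmb(variants: pd.DataFrame, target_mb: float) -> float:
    """Mutations per megabase of targeted exome.

    ``variants`` should already be consensus-filtered with the
    nonsynonymous restriction applied.
    """
    if target_mb <= 0:
        raise ValueError("target_mb must be positive")
    return len(variants) / target_mb


_PYRIMIDINES = {"C", "T"}
_BASES = set("ACGT")


def build_catalog(variants: pd.DataFrame, sample_id: str = "") -> MutationCatalog:
    """Fold SNVs into a pyrimidine-centred 96-channel catalog.

    Purine-reference variants are reverse-complemented into the
    pyrimidine frame, so e.g. A[G>T]C lands in the G[C>A]T channel.
    Non-SNVs are skipped with a logged count. A trinucleotide context
    whose middle base disagrees with the reference base raises an error
    naming the record.
    """
    counts = np.zeros(96)
    skipped = 0
    for i, row in variants.iterrows():
        ref, alt = str(row["ref"]), str(row["alt"])
        if len(ref) != 1 or len(alt) != 1 or ref not in _BASES or alt not in _BASES:
            skipped += 1
            continue
        context = row["trinucleotide_context"]
        if context is None or (isinstance(context, float) and np.isnan(context)):
            raise ValueError(
                f"row {i} ({row['chromosome']}:{row['position']}): SNV lacks "
                "a trinucleotide context"
            )
        context = str(context).upper()
        if len(context) != 3 or set(context) - _BASES:
            raise ValueError(
                f"row {i} ({row['chromosome']}:{row['position']}): malformed "
                f"trinucleotide context {context!r}"
            )
        if context[1] != ref:
            raise ValueError(
                f"row {i} ({row['chromosome']}:{row['position']}): context "
                f"{context!r} inconsistent with ref base {ref!r}"
            )
        if ref not in _PYRIMIDINES:
            context = reverse_complement(context)
            ref = reverse_complement(ref)
            alt = reverse_complement(alt)
        channel = f"{context[0]}[{ref}>{alt}]{context[2]}"
        counts[channel_index(channel)] += 1
    if skipped:
        logger.info("build_catalog: skipped %d non-SNV records", skipped)
    return MutationCatalog(counts, sample_id=sample_id)
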