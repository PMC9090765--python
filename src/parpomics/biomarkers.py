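"""Response dichotomization, group statistics and the composite
resistance classifier.

Pathologic response after six months of neoadjuvant PARPi is graded on
the residual-cancer-burden (RCB) scale; the pipeline dichotomizes pCR
and RCB-I as SENSITIVE and RCB-II/III as RESISTANT (with an alternate
pCR-vs-non-pCR mode). The composite classifier predicts RESISTANT for
any sample showing at least one of three pre-treatment biomarkers:
concomitant SHLD2 copy-number loss and low SHLD2 expression (shieldin
loss restores end resection and thus HR in BRCA1-mutant tumors), a
high hypoxia signature score, or a high EMT/stem-cell signature score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genome import GenomeBuild
from .model import CohortRecord, ResponseLabel, SegmentProfile
from .scars import median_total_cn

__all__ = [
    "BiomarkerCall",
    "GroupComparison",
    "dichotomize_response",
    "group_compare",
    "shld2_cn_loss",
    "shld2_loss_call",
    "composite_resistance_call",
    "cohort_summary",
]

logger = logging.getLogger(__name__)


@dataclass
class BiomarkerCall:
    """Per-sample biomarker flags and the disjunction-rule prediction."""

    sample_id: str
    shld2_loss: bool
    hypoxia_high: bool
    emt_stem_high: bool
    predicted: ResponseLabel
    observed: Optional[ResponseLabel] = None

    def __post_init__(self) -> None:
        expected = (
            ResponseLabel.RESISTANT
            if (self.shld2_loss or self.hypoxia_high or self.emt_stem_high)
            else ResponseLabel.SENSITIVE
        )
        if self.predicted != expected:
            raise ValueError(
                f"sample {self.sample_id}: predicted label inconsistent with "
                "the three-flag disjunction rule"
            )


@dataclass
class GroupComparison:
    """Pooled-variance two-sided t comparison of two response groups."""

    t_statistic: float
    p_value: float
    fold_change: float  # mean(SENSITIVE) / mean(RESISTANT), linear scale
    group_means: tuple[float, float]
    degenerate: bool = False


def dichotomize_response(rcb: str, pcr_only: bool = False) -> ResponseLabel:
    """SENSITIVE for pCR/RCB-I, RESISTANT for RCB-II/III.

    ``pcr_only=True`` switches to the pCR-vs-non-pCR dichotomy, in
    which only pCR counts as SENSITIVE.
    """
    if rcb not in ("pCR", "RCB-I", "RCB-II", "RCB-III"):
        raise ValueError(f"unknown RCB class {rcb!r}")
    if pcr_only:
        return ResponseLabel.SENSITIVE if rcb == "pCR" else ResponseLabel.RESISTANT
    if rcb in ("pCR", "RCB-I"):
        return ResponseLabel.SENSITIVE
    return ResponseLabel.RESISTANT


def group_compare(
    values: dict[str, float], labels: dict[str, ResponseLabel]
) -> GroupComparison:
    """Unpaired two-sided Student's t test (pooled variance).

    The fold change is reported on the linear scale as
    mean(SENSITIVE)/mean(RESISTANT); its reciprocal gives the "x-fold
    lower in resistant tumors" phrasing. Zero pooled variance flags
    the comparison degenerate with p undefined (NaN).
    """
    a = np.array(
        [v for s, v in values.items() if labels.get(s) == ResponseLabel.SENSITIVE]
    )
    b = np.array(
        [v for s, v in values.items() if labels.get(s) == ResponseLabel.RESISTANT]
    )
    if len(a) < 2 or len(b) < 2:
        raise ValueError(
            f"need >= 2 samples per group, got {len(a)} sensitive / {len(b)} resistant"
        )
    mean_a, mean_b = float(a.mean()), float(b.mean())
    pooled = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / (
        len(a) + len(b) - 2
    )
    if pooled == 0:
        if mean_a == mean_b:
            return GroupComparison(0.0, 1.0, _safe_ratio(mean_a, mean_b), (mean_a, mean_b))
        return GroupComparison(
            np.inf if mean_a > mean_b else -np.inf,
            np.nan,
            _safe_ratio(mean_a, mean_b),
            (mean_a, mean_b),
            degenerate=True,
        )
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return GroupComparison(
        t_statistic=float(t),
        p_value=float(p),
        fold_change=_safe_ratio(mean_a, mean_b),
        group_means=(mean_a, mean_b),
    )


def _safe_ratio(a: float, b: float) -> float:
    return a / b if b != 0 else np.nan


def shld2_cn_loss(
    profile: SegmentProfile,
    build: GenomeBuild,
    locus_chromosome: str,
    locus_start: int,
    locus_end: int,
) -> Optional[bool]:
    """Copy-number loss at a gene locus relative to the sample median.

    True when the segment overlapping the locus (maximal overlap if
    several) has total_cn below the sample's median total copy number.
    Returns None ("unknown") when no segment covers the locus.
    """
    overlapping = [
        s
        for s in profile.segments_for(locus_chromosome)
        if s.start <= locus_end and s.end >= locus_start
    ]
    if not overlapping:
        logger.info(
            "sample %s: locus %s:%d-%d not covered by any segment",
            profile.sample_id,
            locus_chromosome,
            locus_start,
            locus_end,
        )
        return None
    best = max(
        overlapping,
        key=lambda s: min(s.end, locus_end) - max(s.start, locus_start),
    )
    return best.total_cn < median_total_cn(profile, build)


def shld2_loss_call(
    cn_loss: Optional[bool], expression_z: float, z_cutoff: float = -1.0
) -> Optional[bool]:
    """Shieldin loss requires concomitant CN loss AND low expression."""
    if cn_loss is None:
        return None
    return bool(cn_loss and expression_z < z_cutoff)


def composite_resistance_call(
    sample_id: str,
    shld2_loss: Optional[bool],
    hypoxia_high: Optional[bool],
    emt_stem_high: Optional[bool],
    observed: Optional[ResponseLabel] = None,
) -> Optional[BiomarkerCall]:
    """Predict RESISTANT iff any of the three biomarker flags is set.

    Any unresolved (None) flag excludes the sample, with a log line.
    """
    flags = (shld2_loss, hypoxia_high, emt_stem_high)
    if any(f is None for f in flags):
        logger.info("sample %s: unresolved biomarker flag, excluded", sample_id)
        return None
    predicted = (
        ResponseLabel.RESISTANT if any(flags) else ResponseLabel.SENSITIVE
    )
    return BiomarkerCall(
        sample_id=sample_id,
        shld2_loss=bool(shld2_loss),
        hypoxia_high=bool(hypoxia_high),
        emt_stem_high=bool(emt_stem_high),
        predicted=predicted,
        observed=observed,
    )


def _percent(x: float) -> int:
    """Nearest-integer percent (round half away from zero)."""
    return int(np.floor(100 * x + 0.5))


def cohort_summary(records: list[CohortRecord]) -> dict:
    """Cohort descriptive statistics over analyzed records.

    Reports counts by germline gene, TNBC and TP53-mutant fractions,
    ER+ fractions stratified by germline gene, RCB class fractions and
    the median mutation burden; every fraction also as a
    nearest-integer percent.
    """
    if not records:
        raise ValueError("empty cohort")
    n = len(records)
    by_gene = {g: [r for r in records if r.germline_gene == g] for g in ("BRCA1", "BRCA2")}
    rcb_counts = {c: sum(r.rcb == c for r in records) for c in ("pCR", "RCB-I", "RCB-II", "RCB-III")}
    tnbc = sum(r.tnbc for r in records) / n
    tp53 = sum(r.tp53_mutant for r in records) / n
    out = {
        "n": n,
        "n_brca1": len(by_gene["BRCA1"]),
        "n_brca2": len(by_gene["BRCA2"]),
        "tnbc_fraction": tnbc,
        "tnbc_percent": _percent(tnbc),
        "tp53_mutant_fraction": tp53,
        "tp53_mutant_percent": _percent(tp53),
        "median_mutations_per_mb": float(
            np.median([r.mutations_per_mb for r in records])
        ),
    }
    for gene, recs in by_gene.items():
        if recs:
            frac = sum(r.er_positive for r in recs) / len(recs)
        else:
            frac = np.nan
        key = gene.lower()
        out[f"{key}_er_positive_fraction"] = frac
        out[f"{key}_er_positive_percent"] = _percent(frac) if recs else None
    for cls, count in rcb_counts.items():
        key = cls.lower().replace("-", "")
        out[f"{key}_fraction"] = count / n
        out[f"{key}_percent"] = _percent(count / n)
    return out
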