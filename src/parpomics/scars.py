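"""Copy-number scar scores: weighted GII, LST and TAI.

All three statistics summarize homologous-recombination-deficiency
"scarring" of an allele-specific copy-number profile:

* **wGII** — per autosome, the fraction of the segmented length whose
  total copy number deviates from the sample's (length-weighted) median
  copy number, averaged over autosomes so long chromosomes do not
  dominate.
* **LST** (large-scale state transitions) — the number of long
  (>= 10 Mb) segments lying within 3 Mb of an adjacent long segment
  with a different allele profile, after merging identical neighbours
  and dropping short (< 3 Mb) segments outright.
* **TAI** (telomeric allelic imbalance) — the number of chromosome ends
  whose terminal run of segments has unequal major/minor copy number,
  provided the run stops before the centromere. The p-termini of the
  acrocentric chromosomes (13, 14, 15, 22 in the human build) are
  skipped because exome capture has no coverage there.

Sex chromosomes are retained in profiles but excluded from all three
scores (wGII is defined on chromosomes 1-22; LST/TAI follow the same
restriction for symmetry). The terminal segment of a chromosome's
profile is treated as reaching the telomere: exome segmentation never
reaches literal chromosome ends.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genome import GenomeBuild
from .model import Segment, SegmentProfile

__all__ = [
    "ScarScoreSet",
    "median_total_cn",
    "weighted_gii",
    "lst_score",
    "tai_score",
    "score_profile",
]


@dataclass(frozen=True)
class ScarScoreSet:
    """The three scar statistics of one sample."""

    sample_id: str
    wgii: float
    lst: int
    tai: int
    median_total_cn: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.wgii <= 1.0:
            raise ValueError("wgii must lie in [0, 1]")
        if self.lst < 0 or self.tai < 0:
            raise ValueError("lst and tai must be nonnegative")


def _autosomal_segments(
    profile: SegmentProfile, build: GenomeBuild
) -> list[Segment]:
    autosomes = set(build.autosomes)
    return [s for s in profile.segments if s.chromosome in autosomes]


def median_total_cn(profile: SegmentProfile, build: GenomeBuild) -> int:
    """Length-weighted median total copy number over autosomal segments.

    When the weight splits evenly between two copy-number states the
    lower of the two is returned (lower-median tie rule).
    """
    segments = _autosomal_segments(profile, build)
    if not segments:
        raise ValueError(
            f"sample {profile.sample_id}: no autosomal segments to take a "
            "median over"
        )
    by_cn: dict[int, int] = {}
    for seg in segments:
        by_cn[seg.total_cn] = by_cn.get(seg.total_cn, 0) + seg.length
    total = sum(by_cn.values())
    half = total / 2
    cum = 0
    for cn in sorted(by_cn):
        cum += by_cn[cn]
        if cum >= half:
            return cn
    raise AssertionError("unreachable")


def weighted_gii(profile: SegmentProfile, build: GenomeBuild) -> float:
    """Mean per-autosome fraction of segmented length off the median CN.

    Averaging per chromosome (rather than pooling) keeps the index from
    being biased by chromosome length. Only autosomes present in the
    profile enter the average; the denominator of each fraction is that
    chromosome's segmented length (capture data leaves gaps).
    """
    segments = _autosomal_segments(profile, build)
    if not segments:
        raise ValueError(f"sample {profile.sample_id}: no autosomal segments")
    median = median_total_cn(profile, build)
    altered: dict[str, int] = {}
    covered: dict[str, int] = {}
    for seg in segments:
        covered[seg.chromosome] = covered.get(seg.chromosome, 0) + seg.length
        if seg.total_cn != median:
            altered[seg.chromosome] = altered.get(seg.chromosome, 0) + seg.length
    fractions = [
        altered.get(chrom, 0) / covered[chrom] for chrom in covered
    ]
    return sum(fractions) / len(fractions)


def _merge_identical(segments: list[Segment]) -> list[Segment]:
    """Merge consecutive segments with the same (major, minor) profile."""
    merged: list[Segment] = []
    for seg in segments:
        if merged and merged[-1].allele_profile == seg.allele_profile:
            prev = merged[-1]
            merged[-1] = Segment(
                chromosome=prev.chromosome,
                start=prev.start,
                end=seg.end,
                major_cn=prev.major_cn,
                minor_cn=prev.minor_cn,
            )
        else:
            merged.append(seg)
    return merged


def _split_at_centromere(
    segments: list[Segment], build: GenomeBuild
) -> list[Segment]:
    out: list[Segment] = []
    for seg in segments:
        info = build[seg.chromosome]
        mid = info.centromere_start
        if seg.start < mid <= seg.end:
            out.append(
                Segment(seg.chromosome, seg.start, mid - 1, seg.major_cn, seg.minor_cn)
            )
            out.append(
                Segment(seg.chromosome, mid, seg.end, seg.major_cn, seg.minor_cn)
            )
        else:
            out.append(seg)
    return out


def lst_score(
    profile: SegmentProfile,
    build: GenomeBuild,
    min_segment: int = 10_000_000,
    max_gap: int = 3_000_000,
    min_keep: int = 3_000_000,
    per_arm: bool = False,
    drop_before_merge: bool = False,
) -> int:
    """Count large-scale state transitions over the autosomes.

    Per chromosome: merge adjacent segments with identical allele
    profiles, drop segments shorter than ``min_keep`` entirely, re-merge
    identical neighbours, then count every segment of length
    >= ``min_segment`` that has an adjacent neighbour of length
    >= ``min_segment`` with a different allele profile whose gap
    (``start_next - end_prev - 1``) is <= ``max_gap``. Both members of a
    qualifying pair count; a segment flanked by qualifying neighbours on
    both sides still counts once.

    ``per_arm=True`` splits segments at the centromere first so no pair
    spans arms. ``drop_before_merge=True`` applies the short-segment
    drop before the initial merge (the alternative processing order).
    """
    score = 0
    for chrom in profile.chromosomes():
        if not build.is_autosome(chrom):
            continue
        segments = profile.segments_for(chrom)
        if per_arm:
            segments = _split_at_centromere(segments, build)
            info = build[chrom]
            arms = [
                [s for s in segments if s.end < info.centromere_start],
                [s for s in segments if s.start >= info.centromere_start],
            ]
        else:
            arms = [segments]
        for arm in arms:
            if drop_before_merge:
                arm = [s for s in arm if s.length >= min_keep]
            arm = _merge_identical(arm)
            arm = [s for s in arm if s.length >= min_keep]
            arm = _merge_identical(arm)
            for i, seg in enumerate(arm):
                if seg.length < min_segment:
                    continue
                qualifies = False
                for j in (i - 1, i + 1):
                    if j < 0 or j >= len(arm):
                        continue
                    other = arm[j]
                    if other.length < min_segment:
                        continue
                    if other.allele_profile == seg.allele_profile:
                        continue
                    left, right = (other, seg) if j < i else (seg, other)
                    gap = right.start - left.end - 1
                    if gap <= max_gap:
                        qualifies = True
                        break
                if qualifies:
                    score += 1
    return score


def tai_score(profile: SegmentProfile, build: GenomeBuild) -> int:
    """Count telomeric allelic-imbalance events over the autosomes.

    For each chromosome end (skipping acrocentric p-termini) take the
    maximal run of consecutive segments, starting at the terminal
    segment, in which major_cn != minor_cn. The end scores 1 if the run
    is non-empty and its inner boundary stops before the centromere; a
    run crossing or touching the centromere contributes 0 at both ends.
    """
    score = 0
    for chrom in profile.chromosomes():
        if not build.is_autosome(chrom):
            continue
        segments = profile.segments_for(chrom)
        if not segments:
            continue
        info = build[chrom]
        # p-terminal run
        if not build.is_acrocentric(chrom):
            run_end = None
            for seg in segments:
                if seg.major_cn != seg.minor_cn:
                    run_end = seg.end
                else:
                    break
            if run_end is not None and run_end < info.centromere_start:
                score += 1
        # q-terminal run
        run_start = None
        for seg in reversed(segments):
            if seg.major_cn != seg.minor_cn:
                run_start = seg.start
            else:
                break
        if run_start is not None and run_start > info.centromere_end:
            score += 1
    return score


def score_profile(
    profile: SegmentProfile,
    build: GenomeBuild,
    min_segment: int = 10_000_000,
    max_gap: int = 3_000_000,
    min_keep: int = 3_000_000,
    per_arm: bool = False,
) -> ScarScoreSet:
    """All three scar scores of one profile."""
    return ScarScoreSet(
        sample_id=profile.sample_id,
        wgii=weighted_gii(profile, build),
        lst=lst_score(
            profile,
            build,
            min_segment=min_segment,
            max_gap=max_gap,
            min_keep=min_keep,
            per_arm=per_arm,
        ),
        tai=tai_score(profile, build),
        median_total_cn=median_total_cn(profile, build),
    )
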