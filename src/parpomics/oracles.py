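"""Naive brute-force reimplementations of the scar scores.

These exist to cross-check the production implementations in
:mod:`parpomics.scars` and to attach verifiable ground truth to
simulated profiles. They are deliberately written as plain enumeration:
the wGII oracle expands profiles per base (only feasible on mini
builds) or walks segments in a separate pure-Python loop; the LST
oracle enumerates all segment pairs; the TAI oracle enumerates all
candidate terminal runs.
"""

from __future__ import annotations

import numpy as np

from .genome import GenomeBuild
from .model import Segment, SegmentProfile

__all__ = [
    "wgii_oracle_perbase",
    "wgii_oracle_segments",
    "lst_oracle",
    "tai_oracle",
]

_PERBASE_LIMIT = 50_000_000  # total bp above which per-base expansion refuses


def wgii_oracle_perbase(profile: SegmentProfile, build: GenomeBuild) -> float:
    """Per-base wGII: expand every autosomal segment into base-level CN."""
    autosomes = set(build.autosomes)
    segs = [s for s in profile.segments if s.chromosome in autosomes]
    if not segs:
        raise ValueError("no autosomal segments")
    total_len = sum(s.length for s in segs)
    if total_len > _PERBASE_LIMIT:
        raise ValueError(
            f"per-base oracle limited to {_PERBASE_LIMIT} segmented bases"
        )
    all_cn = np.concatenate([np.full(s.length, s.total_cn) for s in segs])
    all_cn.sort()
    median = all_cn[(len(all_cn) - 1) // 2]  # lower median
    fractions = []
    for chrom in sorted({s.chromosome for s in segs}):
        cn = np.concatenate(
            [np.full(s.length, s.total_cn) for s in segs if s.chromosome == chrom]
        )
        fractions.append(float(np.mean(cn != median)))
    return float(np.mean(fractions))


def wgii_oracle_segments(profile: SegmentProfile, build: GenomeBuild) -> float:
    """Loop-based wGII for builds too large to expand per base."""
    autosomes = set(build.autosomes)
    segs = [s for s in profile.segments if s.chromosome in autosomes]
    if not segs:
        raise ValueError("no autosomal segments")
    weighted = sorted((s.total_cn, s.length) for s in segs)
    half = sum(w for _, w in weighted) / 2
    cum = 0
    median = weighted[-1][0]
    for cn, w in weighted:
        cum += w
        if cum >= half:
            median = cn
            break
    fractions = []
    for chrom in sorted({s.chromosome for s in segs}):
        here = [s for s in segs if s.chromosome == chrom]
        altered = sum(s.length for s in here if s.total_cn != median)
        fractions.append(altered / sum(s.length for s in here))
    return sum(fractions) / len(fractions)


def _preprocess_lst(segments: list[Segment], min_keep: int) -> list[Segment]:
    def merge(segs: list[Segment]) -> list[Segment]:
        out: list[Segment] = []
        for s in segs:
            if out and (out[-1].major_cn, out[-1].minor_cn) == (s.major_cn, s.minor_cn):
                last = out.pop()
                out.append(
                    Segment(last.chromosome, last.start, s.end, last.major_cn, last.minor_cn)
                )
            else:
                out.append(s)
        return out

    segs = merge(sorted(segments, key=lambda s: s.start))
    segs = [s for s in segs if s.end - s.start + 1 >= min_keep]
    return merge(segs)


def lst_oracle(
    profile: SegmentProfile,
    build: GenomeBuild,
    min_segment: int = 10_000_000,
    max_gap: int = 3_000_000,
    min_keep: int = 3_000_000,
) -> int:
    """All-pairs enumeration of large-scale state transitions."""
    autosomes = set(build.autosomes)
    total = 0
    for chrom in sorted({s.chromosome for s in profile.segments} & autosomes):
        segs = _preprocess_lst(profile.segments_for(chrom), min_keep)
        for i, a in enumerate(segs):
            if a.length < min_segment:
                continue
            hit = False
            for j, b in enumerate(segs):
                if j == i or b.length < min_segment:
                    continue
                if (b.major_cn, b.minor_cn) == (a.major_cn, a.minor_cn):
                    continue
                left, right = (a, b) if a.start < b.start else (b, a)
                between = [
                    c
                    for c in segs
                    if c.start > left.start and c.start < right.start
                ]
                if between:
                    continue  # not adjacent in the surviving list
                if right.start - left.end - 1 <= max_gap:
                    hit = True
            if hit:
                total += 1
    return total


def tai_oracle(profile: SegmentProfile, build: GenomeBuild) -> int:
    """Run enumeration of telomeric allelic imbalance events."""
    autosomes = set(build.autosomes)
    total = 0
    for chrom in sorted({s.chromosome for s in profile.segments} & autosomes):
        segs = sorted(profile.segments_for(chrom), key=lambda s: s.start)
        info = build[chrom]
        imbalanced = [s.major_cn != s.minor_cn for s in segs]
        # enumerate every prefix; keep the maximal fully imbalanced one
        p_runs = [
            segs[:k]
            for k in range(1, len(segs) + 1)
            if all(imbalanced[:k]) and (k == len(segs) or not imbalanced[k])
        ]
        q_runs = [
            segs[k:]
            for k in range(len(segs))
            if all(imbalanced[k:]) and (k == 0 or not imbalanced[k - 1]) and segs[k:]
        ]
        if not build.is_acrocentric(chrom):
            for run in p_runs:
                if run[-1].end < info.centromere_start:
                    total += 1
        for run in q_runs:
            if run[0].start > info.centromere_end:
                total += 1
    return total
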