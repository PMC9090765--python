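"""Seeded generators for every input the pipeline consumes.

Each generator is a pure function of (parameters, seed) and attaches
ground truth that is re-verified against the package's naive oracles
before being returned, so downstream tests can trust the planted
structure. The default substrate is the ``"toy"`` genome build (three
200 Mb chromosomes, centromere at 90-100 Mb, chromosome 3 acrocentric),
chosen so the enumeration oracles stay tractable.

What is emulated: segmented allele-specific copy-number profiles with
planted large-scale-transition pairs and telomeric imbalance runs;
96-channel catalogs drawn multinomially from signature mixtures;
log2-scale expression with Gaussian noise and planted differential
pathways; per-variant caller-support/depth/VAF structure; and cohorts
whose resistant samples each carry at least one of the three
biomarkers of the composite resistance model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genome import GenomeBuild, load_genome_build
from .model import (
    CALLER_UNIVERSE,
    CHANNELS,
    ExpressionMatrix,
    MutationCatalog,
    ResponseLabel,
    Segment,
    SegmentProfile,
    SignatureMatrix,
    reverse_complement,
    validate_variant_table,
)
from .oracles import lst_oracle, tai_oracle, wgii_oracle_segments
from .variants import ConsensusThresholds

__all__ = [
    "SimulationTruth",
    "PlantedSet",
    "simulate_profile",
    "random_profile",
    "simulate_catalog",
    "simulate_expression_cohort",
    "simulate_variant_table",
    "expected_survival_fraction",
    "simulate_biomarker_cohort",
    "BiomarkerCohort",
]


@dataclass
class SimulationTruth:
    """Planted ground truth attached to a simulated object."""

    lst_truth: Optional[int] = None
    tai_truth: Optional[int] = None
    wgii_truth: Optional[float] = None
    exposures: Optional[dict[str, float]] = None
    planted_sets: Optional[dict[str, "PlantedSet"]] = None
    resistant: Optional[dict[str, bool]] = None
    biomarker_flags: Optional[dict[str, dict[str, bool]]] = None
    noise_sd: Optional[float] = None
    effect_log2: Optional[float] = None
    extra: dict = field(default_factory=dict)


@dataclass
class PlantedSet:
    """A differential gene set planted into an expression cohort."""

    name: str
    genes: list[str]
    direction: str  # "resistance" or "sensitivity"
    effect_log2: float


# -- copy-number profiles --------------------------------------------------

_PAIR_PROFILES = ((2, 1), (3, 1))  # allele profiles of a planted LST pair
_TAI_PROFILE = (2, 0)  # imbalanced but copy-neutral (LOH) terminal run


def simulate_profile(
    build: GenomeBuild | str = "toy",
    n_lst_pairs: int = 0,
    n_tai_runs: int = 0,
    seed: int = 0,
    sample_id: str = "sim",
) -> tuple[SegmentProfile, SimulationTruth]:
    """A baseline-diploid profile with planted scar events.

    Every planted LST pair is two abutting 12 Mb segments with distinct
    allele profiles, isolated from neighbours by >3 Mb unsegmented
    gaps, so it contributes exactly 2 to the LST score. Every planted
    TAI run is a terminal copy-neutral LOH segment ending before the
    centromere, contributing exactly 1. Truths are recomputed with the
    naive oracles and checked against the planted counts.
    """
    if isinstance(build, str):
        build = load_genome_build(build)
    rng = np.random.default_rng(seed)
    autosomes = build.autosomes
    pair_slots = [(c, arm) for c in autosomes for arm in ("p", "q")]
    tai_slots = [
        (c, arm)
        for c in autosomes
        for arm in ("p", "q")
        if not (arm == "p" and build.is_acrocentric(c))
    ]
    if n_lst_pairs > len(pair_slots):
        raise ValueError(
            f"{n_lst_pairs} LST pairs do not fit on {len(pair_slots)} arm "
            "slots; use a larger build"
        )
    if n_tai_runs > len(tai_slots):
        raise ValueError(
            f"{n_tai_runs} TAI runs do not fit on {len(tai_slots)} eligible "
            "chromosome ends; use a larger build"
        )
    chosen_pairs = {
        tuple(pair_slots[i]) for i in rng.choice(len(pair_slots), n_lst_pairs, replace=False)
    }
    chosen_tai = {
        tuple(tai_slots[i]) for i in rng.choice(len(tai_slots), n_tai_runs, replace=False)
    }

    segments: list[Segment] = []
    for chrom in autosomes:
        info = build[chrom]
        cen_s, cen_e = info.centromere_start, info.centromere_end
        length = info.length
        p_need = 47_000_000 if (chrom, "p") in chosen_pairs else 18_000_000
        q_need = 51_000_000 if (chrom, "q") in chosen_pairs else 23_000_000
        if cen_s < p_need or length - cen_e < q_need:
            raise ValueError(
                f"chromosome {chrom}: arms too short to host the planted "
                "events; use a larger build"
            )
        jitter = int(rng.integers(0, 2_000_000))
        # p arm: terminal 10 Mb, optional pair, baseline up to the centromere
        term_profile = _TAI_PROFILE if (chrom, "p") in chosen_tai else (1, 1)
        segments.append(Segment(chrom, 1, 10_000_000, *term_profile))
        cursor = 14_000_001 + jitter
        if (chrom, "p") in chosen_pairs:
            a, b = _PAIR_PROFILES
            segments.append(Segment(chrom, cursor, cursor + 11_999_999, *a))
            segments.append(
                Segment(chrom, cursor + 12_000_000, cursor + 23_999_999, *b)
            )
            cursor += 28_000_000
        segments.append(Segment(chrom, cursor, cen_s - 1, 1, 1))
        # q arm: baseline, optional pair, terminal segment
        q_term_start = length - 18_000_000 + 1
        q_term_profile = _TAI_PROFILE if (chrom, "q") in chosen_tai else (1, 1)
        if (chrom, "q") in chosen_pairs:
            pair_end = q_term_start - 4_000_001
            pair_start = pair_end - 23_999_999
            segments.append(Segment(chrom, cen_e + 1, pair_start - 4_000_001, 1, 1))
            a, b = _PAIR_PROFILES
            segments.append(Segment(chrom, pair_start, pair_start + 11_999_999, *a))
            segments.append(Segment(chrom, pair_start + 12_000_000, pair_end, *b))
        else:
            segments.append(Segment(chrom, cen_e + 1, q_term_start - 4_000_001, 1, 1))
        segments.append(Segment(chrom, q_term_start, length, *q_term_profile))

    profile = SegmentProfile(sample_id, segments)
    truth = SimulationTruth(
        lst_truth=lst_oracle(profile, build),
        tai_truth=tai_oracle(profile, build),
        wgii_truth=wgii_oracle_segments(profile, build),
    )
    if truth.lst_truth != 2 * n_lst_pairs:
        raise AssertionError(
            f"planted {n_lst_pairs} LST pairs but oracle counts {truth.lst_truth}"
        )
    if truth.tai_truth != n_tai_runs:
        raise AssertionError(
            f"planted {n_tai_runs} TAI runs but oracle counts {truth.tai_truth}"
        )
    return profile, truth


def random_profile(
    build: GenomeBuild,
    seed: int,
    mean_breaks: float = 6.0,
    gap_prob: float = 0.3,
    sample_id: str = "rand",
) -> SegmentProfile:
    """An unstructured random profile for oracle-equivalence testing.

    Random breakpoints per chromosome, random allele profiles from a
    small state set, and random unsegmented gaps between segments.
    """
    rng = np.random.default_rng(seed)
    states = [(1, 1), (1, 0), (2, 1), (2, 0), (2, 2), (3, 1), (3, 2), (4, 2)]
    segments: list[Segment] = []
    for chrom in build.chromosomes:
        length = build[chrom].length
        n_breaks = int(rng.poisson(mean_breaks))
        cuts = np.sort(rng.integers(1, length, size=n_breaks))
        prev = 1
        for bound in list(cuts) + [length]:
            if bound < prev:
                continue
            start, end = prev, int(bound)
            prev = int(bound) + 1
            if rng.random() < gap_prob:
                continue  # unsegmented gap
            major, minor = states[rng.integers(len(states))]
            segments.append(Segment(chrom, start, end, major, minor))
    # fallback so every profile is scoreable
    if not any(build.is_autosome(s.chromosome) for s in segments):
        chrom = build.autosomes[0]
        segments.append(Segment(chrom, 1, build[chrom].length, 1, 1))
    return SegmentProfile(sample_id, segments)


# -- mutation catalogs -----------------------------------------------------


def simulate_catalog(
    signatures: SignatureMatrix,
    exposures: dict[str, float],
    n_mutations: int,
    seed: int = 0,
    sample_id: str = "sim",
) -> tuple[MutationCatalog, SimulationTruth]:
    """Multinomial catalog from a mixture of reference signatures."""
    if n_mutations < 0:
        raise ValueError("n_mutations must be >= 0")
    weights = np.array([exposures.get(n, 0.0) for n in signatures.names])
    if abs(weights.sum() - 1.0) > 1e-6:
        raise ValueError(
            f"exposures must sum to 1 (got {weights.sum():.8f})"
        )
    unknown = set(exposures) - set(signatures.names)
    if unknown:
        raise ValueError(f"exposures name unknown signatures: {sorted(unknown)}")
    mixture = weights @ signatures.profiles
    mixture = mixture / mixture.sum()
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_mutations, mixture)
    catalog = MutationCatalog(counts.astype(float), sample_id=sample_id)
    assert catalog.total == n_mutations
    return catalog, SimulationTruth(exposures=dict(exposures))


# -- expression cohorts ----------------------------------------------------


def simulate_expression_cohort(
    n_genes: int,
    labels: dict[str, ResponseLabel],
    planted_sets: list[PlantedSet],
    noise_sd: float = 1.0,
    seed: int = 0,
    baseline_mean: float = 8.0,
    baseline_sd: float = 2.0,
) -> tuple[ExpressionMatrix, SimulationTruth]:
    """Log2-scale expression with planted differential pathways.

    Background genes are ``G0001``... with per-gene baselines drawn
    once and shared across samples; planted-set genes are additionally
    shifted by their effect (in log2 units) in RESISTANT samples for
    resistance-associated sets and in SENSITIVE samples for
    sensitivity-associated sets. Noise is Gaussian on the log2 scale.
    """
    planted_genes = [g for ps in planted_sets for g in ps.genes]
    if len(set(planted_genes)) != len(planted_genes):
        raise ValueError("planted sets must be pairwise disjoint")
    if len(planted_genes) > n_genes:
        raise ValueError("planted sets larger than n_genes")
    rng = np.random.default_rng(seed)
    n_background = n_genes - len(planted_genes)
    genes = [f"G{i:04d}" for i in range(1, n_background + 1)] + planted_genes
    samples = list(labels)
    baseline = rng.normal(baseline_mean, baseline_sd, size=len(genes))
    values = baseline[:, None] + rng.normal(0, noise_sd, size=(len(genes), len(samples)))
    gene_index = {g: i for i, g in enumerate(genes)}
    for ps in planted_sets:
        target = (
            ResponseLabel.RESISTANT
            if ps.direction == "resistance"
            else ResponseLabel.SENSITIVE
        )
        cols = [j for j, s in enumerate(samples) if labels[s] == target]
        rows = [gene_index[g] for g in ps.genes]
        values[np.ix_(rows, cols)] += ps.effect_log2
    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples),
        scale="log2tpm",
    )
    truth = SimulationTruth(
        planted_sets={ps.name: ps for ps in planted_sets},
        resistant={s: labels[s] == ResponseLabel.RESISTANT for s in samples},
        noise_sd=noise_sd,
    )
    return matrix, truth


# -- variant tables --------------------------------------------------------

_PYRIMIDINE_REFS = ("C", "T")


def _random_snv(rng: np.random.Generator) -> tuple[str, str, str]:
    """(ref, alt, context) with the context consistent with ref."""
    ref = _PYRIMIDINE_REFS[rng.integers(2)]
    alt = rng.choice([b for b in "ACGT" if b != ref])
    context = rng.choice(list("ACGT")) + ref + rng.choice(list("ACGT"))
    if rng.random() < 0.5:  # present half the records on the purine strand
        context = reverse_complement(context)
        ref, alt = reverse_complement(ref), reverse_complement(alt)
    return ref, str(alt), context


def simulate_variant_table(
    n_variants: int,
    caller_support_prob: float = 0.5,
    depth_mean: float = 40.0,
    vaf_params: tuple[float, float] = (2.0, 5.0),
    fraction_nonsynonymous: float = 0.7,
    seed: int = 0,
    channel_mixture: np.ndarray | None = None,
) -> pd.DataFrame:
    """Somatic SNVs with independent caller support, depth and VAF.

    Each of the six callers supports a variant independently with
    ``caller_support_prob``; depth is Poisson(``depth_mean``) floored
    at 1; the latent VAF is Beta(``vaf_params``) with alt_reads the
    rounded product (the stored vaf column is alt_reads/depth); the
    consequence class is nonsynonymous with ``fraction_nonsynonymous``
    else synonymous. When ``channel_mixture`` (a 96-simplex vector in
    the documented channel order) is given, substitutions and contexts
    are drawn from it instead of uniformly, so the downstream catalog
    reflects a chosen signature mixture.
    """
    for p in (caller_support_prob, fraction_nonsynonymous):
        if not 0.0 <= p <= 1.0:
            raise ValueError("probabilities must lie in [0, 1]")
    if depth_mean <= 0 or min(vaf_params) <= 0:
        raise ValueError("depth_mean and vaf_params must be positive")
    rng = np.random.default_rng(seed)
    callers = sorted(CALLER_UNIVERSE)
    rows = []
    for i in range(n_variants):
        support = frozenset(
            c for c in callers if rng.random() < caller_support_prob
        )
        depth = max(1, int(rng.poisson(depth_mean)))
        vaf_true = rng.beta(*vaf_params)
        alt_reads = int(np.clip(np.rint(vaf_true * depth), 0, depth))
        if channel_mixture is not None:
            channel = CHANNELS[int(rng.choice(96, p=channel_mixture))]
            ref, alt = channel[2], channel[4]
            context = channel[0] + ref + channel[6]
            if rng.random() < 0.5:
                context = reverse_complement(context)
                ref, alt = reverse_complement(ref), reverse_complement(alt)
        else:
            ref, alt, context = _random_snv(rng)
        rows.append(
            {
                "chromosome": str(1 + i % 3),
                "position": 1_000 + i * 100,
                "ref": ref,
                "alt": alt,
                "gene": f"GENE{i:05d}",
                "consequence_class": (
                    "nonsynonymous"
                    if rng.random() < fraction_nonsynonymous
                    else "synonymous"
                ),
                "depth": depth,
                "alt_reads": alt_reads,
                "vaf": alt_reads / depth,
                "callers": support,
                "trinucleotide_context": context,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "chromosome", "position", "ref", "alt", "gene",
            "consequence_class", "depth", "alt_reads", "vaf",
            "callers", "trinucleotide_context",
        ],
    )
    if len(df):
        validate_variant_table(df)
    return df


def expected_survival_fraction(
    caller_support_prob: float,
    depth_mean: float,
    vaf_params: tuple[float, float],
    fraction_nonsynonymous: float,
    thresholds: ConsensusThresholds = ConsensusThresholds(),
    depth_tail: int = 400,
) -> float:
    """Analytic probability that a simulated variant survives the filter.

    Closed form by independence: P(>= min_callers of 6 supporting) x
    P(depth >= min_depth and round(V*depth)/depth >= min_vaf), the
    latter summed over the Poisson depth distribution with the Beta
    VAF tail evaluated at the rounding-aware threshold, x the
    nonsynonymous fraction. This is the independent oracle for the
    generator's surviving-fraction check.
    """
    p = caller_support_prob
    n_callers = 6
    p_callers = float(
        1.0
        - sum(
            sps.binom.pmf(k, n_callers, p) for k in range(thresholds.min_callers)
        )
    )
    a, b = vaf_params
    p_depth_vaf = 0.0
    pois = sps.poisson(depth_mean)
    for d in range(max(1, thresholds.min_depth), depth_tail):
        # smallest alt count m with m/d >= min_vaf; rint(v*d) >= m iff
        # v*d > m - 0.5 (ties have measure zero under a continuous Beta)
        m = int(np.ceil(thresholds.min_vaf * d - 1e-12))
        v_threshold = max(0.0, (m - 0.5) / d)
        p_depth_vaf += pois.pmf(d) * float(sps.beta.sf(v_threshold, a, b))
    frac = p_callers * p_depth_vaf
    if thresholds.require_nonsynonymous:
        frac *= fraction_nonsynonymous
    return frac


# -- biomarker cohorts (the composite-resistance model) --------------------

HYPOXIA_SET = "HYPOXIA_RESPONSE"
EMT_STEM_SET = "EMT_STEM_PROGRAM"
SHLD2_GENE = "SHLD2"
SHLD2_LOCUS = ("2", 115_000_001, 125_000_000)  # on the toy build


@dataclass
class BiomarkerCohort:
    """A synthetic cohort realizing the three-biomarker disjunction model."""

    labels: dict[str, ResponseLabel]
    rcb: dict[str, str]
    expression: ExpressionMatrix
    profiles: dict[str, SegmentProfile]
    gene_sets: dict[str, list[str]]
    truth: SimulationTruth


def simulate_biomarker_cohort(
    n_samples: int = 13,
    n_resistant: int = 6,
    seed: int = 0,
    effect_log2: float = 2.0,
    shld2_effect_log2: float = -4.0,
    noise_sd: float = 0.5,
    n_background_genes: int = 540,
    set_size: int = 30,
    extra_flag_prob: float = 0.25,
) -> BiomarkerCohort:
    """Cohort in which every resistant sample carries >= 1 biomarker.

    Resistant samples are assigned one primary biomarker each, cycling
    through shieldin loss, hypoxia and EMT/stem so every biomarker has
    at least one carrier (two when n_resistant >= 6 in the default
    layout), plus occasional extra hypoxia/EMT flags. Shieldin loss is
    planted as a copy-number deletion spanning the SHLD2 locus together
    with strongly reduced SHLD2 expression; hypoxia and EMT/stem as
    upward shifts of their 30-gene signature sets. Sensitive samples
    carry no planted biomarker.
    """
    if n_resistant >= n_samples:
        raise ValueError("need at least one sensitive sample")
    rng = np.random.default_rng(seed)
    samples = [f"S{i:02d}" for i in range(1, n_samples + 1)]
    resistant_idx = set(rng.choice(n_samples, n_resistant, replace=False).tolist())
    labels = {
        s: ResponseLabel.RESISTANT if i in resistant_idx else ResponseLabel.SENSITIVE
        for i, s in enumerate(samples)
    }
    rcb = {
        s: (
            str(rng.choice(["RCB-II", "RCB-III"]))
            if labels[s] == ResponseLabel.RESISTANT
            else str(rng.choice(["pCR", "RCB-I"]))
        )
        for s in samples
    }

    flags = {s: {"shld2_loss": False, "hypoxia_high": False, "emt_stem_high": False} for s in samples}
    resistant_samples = [s for s in samples if labels[s] == ResponseLabel.RESISTANT]
    order = rng.permutation(len(resistant_samples))
    primaries = ["shld2_loss", "hypoxia_high", "emt_stem_high"]
    for rank, idx in enumerate(order):
        flags[resistant_samples[idx]][primaries[rank % 3]] = True
    for s in resistant_samples:  # extra flags, never shieldin (single-gene
        for extra in ("hypoxia_high", "emt_stem_high"):  # z-scores saturate)
            if not flags[s][extra] and rng.random() < extra_flag_prob:
                flags[s][extra] = True

    hypoxia_genes = [f"HYP{i:03d}" for i in range(1, set_size + 1)]
    emt_genes = [f"EMT{i:03d}" for i in range(1, set_size + 1)]
    genes = (
        [f"G{i:04d}" for i in range(1, n_background_genes + 1)]
        + hypoxia_genes
        + emt_genes
        + [SHLD2_GENE]
    )
    baseline = rng.normal(8.0, 2.0, size=len(genes))
    values = baseline[:, None] + rng.normal(0, noise_sd, size=(len(genes), len(samples)))
    frame = pd.DataFrame(values, index=genes, columns=samples)
    for j, s in enumerate(samples):
        if flags[s]["hypoxia_high"]:
            frame.loc[hypoxia_genes, s] += effect_log2
        if flags[s]["emt_stem_high"]:
            frame.loc[emt_genes, s] += effect_log2
        if flags[s]["shld2_loss"]:
            frame.loc[SHLD2_GENE, s] += shld2_effect_log2
    expression = ExpressionMatrix(values=frame, scale="log2tpm")

    build = load_genome_build("toy")
    chrom_locus, locus_start, locus_end = SHLD2_LOCUS
    profiles = {}
    for s in samples:
        segments = []
        for chrom in build.autosomes:
            info = build[chrom]
            if chrom == chrom_locus and flags[s]["shld2_loss"]:
                segments += [
                    Segment(chrom, 1, info.centromere_start - 1, 1, 1),
                    Segment(chrom, info.centromere_end + 1, locus_start - 1, 1, 1),
                    Segment(chrom, locus_start, locus_end, 1, 0),
                    Segment(chrom, locus_end + 1, info.length, 1, 1),
                ]
            else:
                segments += [
                    Segment(chrom, 1, info.centromere_start - 1, 1, 1),
                    Segment(chrom, info.centromere_end + 1, info.length, 1, 1),
                ]
        profiles[s] = SegmentProfile(s, segments)

    truth = SimulationTruth(
        resistant={s: labels[s] == ResponseLabel.RESISTANT for s in samples},
        biomarker_flags=flags,
        effect_log2=effect_log2,
        noise_sd=noise_sd,
    )
    for s in samples:  # the disjunction model: resistant => >= 1 flag
        if truth.resistant[s]:
            assert any(flags[s].values())
        else:
            assert not any(flags[s].values())
    return BiomarkerCohort(
        labels=labels,
        rcb=rcb,
        expression=expression,
        profiles=profiles,
        gene_sets={HYPOXIA_SET: hypoxia_genes, EMT_STEM_SET: emt_genes},
        truth=truth,
    )
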