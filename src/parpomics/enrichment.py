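"""Expression normalization, gene ranking, preranked GSEA, scoring.

The transcriptomic arm of the pipeline: convert counts to log2 TPM,
rank genes by a Welch t statistic between response groups, run a
preranked gene-set enrichment analysis with a gene-label permutation
null, extract leading-edge genes, test over-representation of a gene
list against a background, and compute per-sample mean-z signature
scores.

The GSEA enrichment score is the classic weighted Kolmogorov-Smirnov
running sum: walking down the ranking, in-set genes ("hits") increment
the sum by |statistic|^p normalized by the in-set total, out-of-set
genes decrement by 1/(N - |S|); the ES is the running-sum value of
maximal absolute deviation. The null distribution permutes gene labels
(equivalently, draws the set's positions at random), NES divides the
ES by the mean |null ES| of matching sign, and the nominal p-value is
the matching-sign tail frequency with +1 smoothing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .model import ExpressionMatrix, GeneSetCollection, ResponseLabel

__all__ = [
    "RankedGeneList",
    "EnrichmentResult",
    "log2_tpm",
    "rank_genes",
    "enrichment_score",
    "gsea_preranked",
    "leading_edge",
    "benjamini_hochberg",
    "overrepresentation_test",
    "signature_score",
]

logger = logging.getLogger(__name__)


@dataclass
class RankedGeneList:
    """Genes sorted by descending statistic, ties broken by gene id."""

    genes: list[str]
    statistic: np.ndarray

    def __post_init__(self) -> None:
        self.statistic = np.asarray(self.statistic, dtype=float)
        if len(self.genes) != len(self.statistic):
            raise ValueError("genes/statistic length mismatch")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes in ranking")
        order = sorted(
            range(len(self.genes)), key=lambda i: (-self.statistic[i], self.genes[i])
        )
        self.genes = [self.genes[i] for i in order]
        self.statistic = self.statistic[order]

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class EnrichmentResult:
    set_name: str
    es: float
    nes: float
    p_nominal: float
    p_adjusted: float
    leading_edge: list[str] = field(default_factory=list)
    size: int = 0
    peak_index: int = -1


def log2_tpm(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Convert raw counts to log2(TPM + 1).

    Per sample: rate_g = count_g / (length_g in kb), TPM_g =
    rate_g / sum(rates) * 1e6. Doubling all counts of a sample leaves
    its TPM vector unchanged.
    """
    if matrix.scale != "counts":
        raise ValueError("log2_tpm expects a counts-scale matrix")
    if matrix.gene_lengths is None:
        raise ValueError("TPM conversion requires gene_lengths (bp)")
    lengths_kb = matrix.gene_lengths.reindex(matrix.values.index) / 1000.0
    rates = matrix.values.div(lengths_kb, axis=0)
    totals = rates.sum(axis=0)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0][0]
        raise ValueError(f"sample {bad!r} has zero total rate")
    tpm = rates.div(totals, axis=1) * 1e6
    return ExpressionMatrix(values=np.log2(tpm + 1), scale="log2tpm")


def rank_genes(
    matrix: ExpressionMatrix, groups: dict[str, ResponseLabel]
) -> RankedGeneList:
    """Welch t statistic per gene, SENSITIVE minus RESISTANT.

    Genes with zero variance in both groups get statistic 0 rather
    than an error.
    """
    if matrix.scale != "log2tpm":
        raise ValueError("rank_genes expects log2 TPM values")
    sens = [s for s in matrix.sample_ids if groups.get(s) == ResponseLabel.SENSITIVE]
    res = [s for s in matrix.sample_ids if groups.get(s) == ResponseLabel.RESISTANT]
    if len(sens) < 2 or len(res) < 2:
        raise ValueError(
            f"need >= 2 samples per group, got {len(sens)} sensitive / "
            f"{len(res)} resistant"
        )
    a = matrix.values[sens].to_numpy()
    b = matrix.values[res].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        t, _ = sps.ttest_ind(a, b, axis=1, equal_var=False)
    t = np.nan_to_num(t, nan=0.0, posinf=0.0, neginf=0.0)
    return RankedGeneList(genes=matrix.gene_ids, statistic=t)


def _es_from_sorted_positions(
    positions: np.ndarray, weights: np.ndarray, n_genes: int
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized ES for rows of sorted hit positions.

    ``positions`` is (m, k) with each row the sorted 0-based ranking
    positions of the set's genes; ``weights`` is the |statistic|^p of
    every ranking position. Returns (es, peak_position) per row. The
    running sum attains its extrema only immediately after a hit
    (maxima) or immediately before one (minima), so those candidates
    suffice.
    """
    m, k = positions.shape
    n_miss = n_genes - k
    hit_w = weights[positions]
    totals = hit_w.sum(axis=1, keepdims=True)
    # degenerate: all weights zero -> flat increments
    flat = totals[:, 0] == 0
    cum = np.where(
        flat[:, None],
        np.arange(1, k + 1) / k,
        np.cumsum(hit_w, axis=1) / np.where(totals == 0, 1, totals),
    )
    idx = np.arange(k)
    miss_before = (positions - idx) / n_miss if n_miss > 0 else np.zeros_like(
        positions, dtype=float
    )
    dev_after = cum - miss_before
    dev_before = np.concatenate(
        [np.zeros((m, 1)), cum[:, :-1]], axis=1
    ) - miss_before
    cand = np.concatenate([dev_after, dev_before], axis=1)
    best = np.argmax(np.abs(cand), axis=1)
    es = cand[np.arange(m), best]
    peak = positions[np.arange(m), best % k]
    return es, peak


def enrichment_score(
    ranked: RankedGeneList, members: list[str], weight_exponent: float = 1.0
) -> tuple[float, int]:
    """Observed ES and the ranking position of the running-sum extremum."""
    index = {g: i for i, g in enumerate(ranked.genes)}
    pos = np.array(sorted(index[g] for g in members if g in index))
    if pos.size == 0:
        raise ValueError("gene set does not intersect the ranking")
    n = len(ranked)
    if pos.size == n:
        return 1.0, n - 1  # every gene is a hit: the sum climbs monotonically
    weights = np.abs(ranked.statistic) ** weight_exponent
    es, peak = _es_from_sorted_positions(pos[None, :], weights, n)
    return float(es[0]), int(peak[0])


def gsea_preranked(
    ranked: RankedGeneList,
    sets: GeneSetCollection,
    n_perm: int = 1000,
    seed: int | None = None,
    weight_exponent: float = 1.0,
    min_size: int = 5,
) -> list[EnrichmentResult]:
    """Preranked GSEA with a shared gene-label permutation null.

    One label permutation per iteration is drawn and evaluated against
    every set, then per-set NES, nominal p (matching-sign tail, +1
    smoothing) and Benjamini-Hochberg adjusted p across scored sets
    are computed. Fixed seed implies bit-identical output.
    """
    if n_perm < 100:
        logger.warning("n_perm=%d < 100: p-values will be coarse", n_perm)
    rng = np.random.default_rng(seed)
    n = len(ranked)
    index = {g: i for i, g in enumerate(ranked.genes)}
    weights = np.abs(ranked.statistic) ** weight_exponent

    scored: list[tuple[str, np.ndarray]] = []
    for name, members in sets.items():
        pos = np.array(sorted(index[g] for g in members if g in index))
        if pos.size == 0:
            logger.info("set %s: empty intersection with ranking, skipped", name)
            continue
        if pos.size < min_size:
            logger.info(
                "set %s: only %d genes in ranking (< %d), skipped",
                name,
                pos.size,
                min_size,
            )
            continue
        scored.append((name, pos))
    if not scored:
        return []

    # position of each gene under every permutation of the gene labels
    keys = rng.random((n_perm, n))
    pos_of_gene = np.argsort(np.argsort(keys, axis=1), axis=1)

    results: list[EnrichmentResult] = []
    p_values = []
    for name, pos in scored:
        es_obs, peak = _es_from_sorted_positions(pos[None, :], weights, n)
        es_obs, peak = float(es_obs[0]), int(peak[0])
        null_pos = np.sort(pos_of_gene[:, pos], axis=1)
        null_es, _ = _es_from_sorted_positions(null_pos, weights, n)
        same_sign = null_es * np.sign(es_obs) > 0 if es_obs != 0 else null_es >= 0
        n_same = int(same_sign.sum())
        if n_same > 0:
            mean_abs = float(np.abs(null_es[same_sign]).mean())
            nes = es_obs / mean_abs if mean_abs > 0 else 0.0
            exceed = int((np.abs(null_es[same_sign]) >= abs(es_obs)).sum())
            p_nom = (1 + exceed) / (1 + n_same)
        else:
            nes, p_nom = 0.0, 1.0
        lead = leading_edge(
            ranked, [g for g in sets[name] if g in index], es_obs, peak
        )
        results.append(
            EnrichmentResult(
                set_name=name,
                es=es_obs,
                nes=nes,
                p_nominal=p_nom,
                p_adjusted=np.nan,
                leading_edge=lead,
                size=len(pos),
                peak_index=peak,
            )
        )
        p_values.append(p_nom)
    adjusted = benjamini_hochberg(p_values)
    for r, padj in zip(results, adjusted):
        r.p_adjusted = float(padj)
    return results


def leading_edge(
    ranked: RankedGeneList,
    members: list[str],
    es: float,
    peak_index: int | None = None,
) -> list[str]:
    """In-set genes at/before the running-sum peak (positive ES) or
    at/after the trough (negative ES), in ranking order."""
    index = {g: i for i, g in enumerate(ranked.genes)}
    in_set = sorted((index[g] for g in members if g in index))
    if peak_index is None:
        _, peak_index = enrichment_score(ranked, members)
    if es >= 0:
        chosen = [i for i in in_set if i <= peak_index]
    else:
        chosen = [i for i in in_set if i >= peak_index]
    return [ranked.genes[i] for i in chosen]


def benjamini_hochberg(p_values) -> np.ndarray:
    """Standard BH step-up adjustment, capped at 1."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def overrepresentation_test(
    query: list[str],
    sets: GeneSetCollection,
    background_size: int,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation with BH FDR.

    ``query`` is assumed drawn from a background of
    ``background_size`` genes that contains every set. A set with zero
    achievable overlap below the observed one gets p = 1.
    """
    query_set = set(query)
    if background_size < len(query_set):
        raise ValueError("background smaller than query")
    rows = []
    for name, members in sets.items():
        k = len(query_set & set(members))
        p = float(
            sps.hypergeom.sf(k - 1, background_size, len(members), len(query_set))
        )
        rows.append({"set_name": name, "overlap": k, "p_value": min(p, 1.0)})
    df = pd.DataFrame(rows)
    df["fdr"] = benjamini_hochberg(df["p_value"])
    return df


def signature_score(matrix: ExpressionMatrix, members: list[str]) -> pd.Series:
    """Per-sample mean of row-wise z-scored expression over set genes.

    Zero-variance genes contribute 0 by convention, so a constant
    matrix scores 0 everywhere.
    """
    if len(matrix.sample_ids) < 2:
        raise ValueError("signature_score needs >= 2 samples")
    present = [g for g in members if g in set(matrix.gene_ids)]
    if not present:
        raise ValueError("gene set does not intersect the expression matrix")
    sub = matrix.values.loc[present]
    means = sub.mean(axis=1)
    sds = sub.std(axis=1, ddof=1)
    z = sub.sub(means, axis=0).div(sds.replace(0, np.nan), axis=0).fillna(0.0)
    return z.mean(axis=0)
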