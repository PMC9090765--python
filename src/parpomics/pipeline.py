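"""End-to-end cohort pipeline: from input files to biomarker calls.

``run_cohort_pipeline`` wires the whole analysis together: read the
genome build, cohort table, segments, variants, expression, gene sets,
signature reference and target BED; compute per-sample scar scores,
consensus-filtered mutation burden, signature exposures, signature
scores and biomarker flags; apply the composite resistance rule; run
the group comparisons and preranked GSEA; and write a wide per-sample
TSV plus summary tables. Deterministic given the configured seed.

``write_cohort_inputs`` emits a complete synthetic input bundle (plus
ground truth) that the pipeline can consume directly.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .biomarkers import (
    composite_resistance_call,
    dichotomize_response,
    group_compare,
    shld2_cn_loss,
    shld2_loss_call,
)
from .enrichment import gsea_preranked, rank_genes, signature_score
from .genome import load_genome_build
from .model import CohortRecord, GeneSetCollection, ResponseLabel
from .scars import score_profile
from .signatures import refit_exposures, signature_fraction, synthetic_reference
from .simulate import (
    EMT_STEM_SET,
    HYPOXIA_SET,
    SHLD2_GENE,
    SHLD2_LOCUS,
    simulate_biomarker_cohort,
    simulate_variant_table,
)
from .variants import ConsensusThresholds, build_catalog, consensus_filter, tmb

__all__ = ["run_cohort_pipeline", "write_cohort_inputs"]

logger = logging.getLogger(__name__)

_SAMPLE_COLUMNS = [
    "sample_id", "observed", "predicted", "shld2_loss", "hypoxia_high",
    "emt_stem_high", "wgii", "lst", "tai", "median_total_cn", "tmb",
    "hypoxia_score", "emt_stem_score", "shld2_z", "signature_fraction",
    "residual_error",
]


def run_cohort_pipeline(config) -> dict:
    """Run the full analysis described by a config mapping or YAML path.

    Returns ``{"samples": DataFrame, "gsea": DataFrame, "summary":
    DataFrame, "calls": list}`` and, when ``out_dir`` is configured,
    writes samples.tsv, gsea.tsv and summary.tsv there.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    required = ["build", "cohort", "segments", "variants", "expression", "gene_sets"]
    for key in required:
        if key not in config:
            raise ValueError(f"config missing required key {key!r}")
        if key != "build" and not Path(config[key]).exists():
            raise FileNotFoundError(f"{key} file not found: {config[key]}")

    build = load_genome_build(config["build"])
    cohort = [r for r in pio.read_cohort(config["cohort"]) if r.analyzed]
    profiles = pio.read_segments(config["segments"])
    variants = pio.read_variants(config["variants"])
    expression = pio.read_expression(
        config["expression"], scale=config.get("expression_scale", "log2tpm")
    )
    gene_sets = pio.read_gmt(config["gene_sets"])
    reference = (
        pio.read_signature_matrix(config["signature_reference"])
        if "signature_reference" in config
        else None
    )
    target_mb = (
        pio.read_target_size(config["targets_bed"])
        if "targets_bed" in config
        else float(config.get("target_mb", 40.0))
    )
    thresholds = ConsensusThresholds(
        **config.get("consensus_thresholds", {})
    )
    score_cutoff = float(config.get("score_cutoff", 0.0))
    shld2_cfg = config.get("shld2", {})
    shld2_gene = shld2_cfg.get("gene", SHLD2_GENE)
    sig_name = config.get("signature_of_interest")
    pcr_only = bool(config.get("pcr_only", False))

    sample_ids = [r.sample_id for r in cohort]
    for sid in sample_ids:
        if sid not in profiles:
            raise ValueError(f"segments file missing cohort sample {sid!r}")
        if sid not in expression.sample_ids:
            raise ValueError(f"expression file missing cohort sample {sid!r}")
    if "sample" not in variants.columns:
        raise ValueError("cohort variant table needs a 'sample' column")

    labels = {r.sample_id: dichotomize_response(r.rcb, pcr_only=pcr_only) for r in cohort}

    hypoxia_name = config.get("hypoxia_set", HYPOXIA_SET)
    emt_name = config.get("emt_stem_set", EMT_STEM_SET)
    hypoxia_scores = signature_score(expression, gene_sets[hypoxia_name])
    emt_scores = signature_score(expression, gene_sets[emt_name])
    shld2_z = (
        signature_score(expression, [shld2_gene])
        if shld2_gene in expression.gene_ids
        else None
    )

    rows, calls = [], []
    for record in cohort:
        sid = record.sample_id
        profile = profiles[sid]
        scars = score_profile(profile, build)
        sample_variants = variants[variants["sample"] == sid]
        nonsyn = consensus_filter(sample_variants, thresholds)
        sample_tmb = tmb(nonsyn, target_mb)
        all_conseq = consensus_filter(
            sample_variants,
            ConsensusThresholds(
                min_callers=thresholds.min_callers,
                min_depth=thresholds.min_depth,
                min_vaf=thresholds.min_vaf,
                require_nonsynonymous=False,
            ),
        )
        sig_frac = np.nan
        residual = np.nan
        if reference is not None and len(all_conseq):
            catalog = build_catalog(all_conseq, sample_id=sid)
            if catalog.total >= 1:
                exposure = refit_exposures(catalog, reference)
                residual = exposure.residual_error
                if sig_name:
                    sig_frac = signature_fraction(exposure, sig_name)

        cn_loss = (
            shld2_cn_loss(
                profile,
                build,
                shld2_cfg.get("chromosome", SHLD2_LOCUS[0]),
                int(shld2_cfg.get("start", SHLD2_LOCUS[1])),
                int(shld2_cfg.get("end", SHLD2_LOCUS[2])),
            )
            if shld2_cfg.get("enabled", True)
            else False
        )
        z = float(shld2_z[sid]) if shld2_z is not None else np.nan
        shld2 = shld2_loss_call(
            cn_loss, z, z_cutoff=float(shld2_cfg.get("z_cutoff", -1.0))
        )
        hypoxia_high = bool(hypoxia_scores[sid] > score_cutoff)
        emt_high = bool(emt_scores[sid] > score_cutoff)
        call = composite_resistance_call(
            sid, shld2, hypoxia_high, emt_high, observed=labels[sid]
        )
        if call is not None:
            calls.append(call)
        rows.append(
            {
                "sample_id": sid,
                "observed": labels[sid].value,
                "predicted": call.predicted.value if call else "",
                "shld2_loss": shld2,
                "hypoxia_high": hypoxia_high,
                "emt_stem_high": emt_high,
                "wgii": scars.wgii,
                "lst": scars.lst,
                "tai": scars.tai,
                "median_total_cn": scars.median_total_cn,
                "tmb": sample_tmb,
                "hypoxia_score": float(hypoxia_scores[sid]),
                "emt_stem_score": float(emt_scores[sid]),
                "shld2_z": z,
                "signature_fraction": sig_frac,
                "residual_error": residual,
            }
        )
    samples = pd.DataFrame(rows, columns=_SAMPLE_COLUMNS)

    gsea_df = pd.DataFrame()
    n_sens = sum(1 for v in labels.values() if v == ResponseLabel.SENSITIVE)
    n_res = len(labels) - n_sens
    if n_sens >= 2 and n_res >= 2:
        ranking = rank_genes(expression, labels)
        results = gsea_preranked(
            ranking,
            gene_sets,
            n_perm=int(config.get("n_perm", 1000)),
            seed=int(config.get("seed", 0)),
            min_size=int(config.get("min_set_size", 5)),
        )
        gsea_df = pd.DataFrame(
            [
                {
                    "set_name": r.set_name,
                    "es": r.es,
                    "nes": r.nes,
                    "p_nominal": r.p_nominal,
                    "p_adjusted": r.p_adjusted,
                    "size": r.size,
                    "leading_edge": ";".join(r.leading_edge),
                }
                for r in results
            ]
        )

    summary_rows = []
    if calls:
        truly_resistant = [c for c in calls if c.observed == ResponseLabel.RESISTANT]
        truly_sensitive = [c for c in calls if c.observed == ResponseLabel.SENSITIVE]
        if truly_resistant:
            sens = np.mean(
                [c.predicted == ResponseLabel.RESISTANT for c in truly_resistant]
            )
            summary_rows.append({"metric": "classifier_sensitivity", "value": float(sens)})
        if truly_sensitive:
            spec = np.mean(
                [c.predicted == ResponseLabel.SENSITIVE for c in truly_sensitive]
            )
            summary_rows.append({"metric": "classifier_specificity", "value": float(spec)})
    if n_sens >= 2 and n_res >= 2:
        for column in ("tmb", "wgii", "lst", "tai", "signature_fraction"):
            values = dict(zip(samples["sample_id"], samples[column]))
            if any(np.isnan(list(values.values()))):
                continue
            comparison = group_compare(values, labels)
            summary_rows.append(
                {
                    "metric": f"{column}_t",
                    "value": comparison.t_statistic,
                    "p_value": comparison.p_value,
                }
            )
    summary = pd.DataFrame(summary_rows)

    out_dir = config.get("out_dir")
    if out_dir:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        samples.to_csv(out / "samples.tsv", sep="\t", index=False)
        gsea_df.to_csv(out / "gsea.tsv", sep="\t", index=False)
        summary.to_csv(out / "summary.tsv", sep="\t", index=False)
    return {"samples": samples, "gsea": gsea_df, "summary": summary, "calls": calls}


def write_cohort_inputs(
    out_dir,
    seed: int = 0,
    n_samples: int = 13,
    n_resistant: int = 6,
    n_variants_per_sample: int = 150,
) -> Path:
    """Emit a complete synthetic input bundle plus truth; return the
    config path that :func:`run_cohort_pipeline` can consume."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    cohort_sim = simulate_biomarker_cohort(
        n_samples=n_samples, n_resistant=n_resistant, seed=seed
    )
    samples = list(cohort_sim.labels)

    pio.write_segments(cohort_sim.profiles, out / "segments.tsv")
    pio.write_expression(cohort_sim.expression, out / "expression.tsv")

    sets = dict(cohort_sim.gene_sets)
    background = [g for g in cohort_sim.expression.gene_ids if g.startswith("G")]
    for i in range(3):  # a few null sets so GSEA has competitors
        members = rng.choice(background, size=30, replace=False)
        sets[f"NULL_SET_{i + 1}"] = sorted(members.tolist())
    pio.write_gmt(GeneSetCollection(sets, provenance="synthetic"), out / "gene_sets.gmt")

    reference = synthetic_reference(4)
    pio.write_signature_matrix(reference, out / "signatures.tsv")

    mixture = 0.6 * reference.profiles[0] + 0.4 * reference.profiles[1]
    frames = []
    for i, sid in enumerate(samples):
        table = simulate_variant_table(
            n_variants_per_sample,
            caller_support_prob=0.8,
            depth_mean=60.0,
            vaf_params=(8.0, 12.0),
            fraction_nonsynonymous=0.7,
            seed=int(rng.integers(2**31)),
            channel_mixture=mixture / mixture.sum(),
        )
        table.insert(0, "sample", sid)
        frames.append(table)
    pio.write_variants(pd.concat(frames, ignore_index=True), out / "variants.tsv")

    with open(out / "targets.bed", "w") as fh:
        for chrom in ("1", "2", "3"):
            fh.write(f"{chrom}\t0\t13333333\n")  # 40 Mb of unique target

    records = []
    for sid in samples:
        gene = "BRCA1" if rng.random() < 0.75 else "BRCA2"
        records.append(
            CohortRecord(
                sample_id=sid,
                germline_gene=gene,
                er_status="TNBC" if rng.random() < 0.7 else "ER+, PR+, HER2-",
                tp53="R175H" if rng.random() < 0.8 else "wt",
                rcb=cohort_sim.rcb[sid],
                mutations_per_mb=0.0,
                purity=float(rng.uniform(0.2, 0.8)),
                ploidy=2.0,
            )
        )
    pio.write_cohort(records, out / "cohort.tsv")

    truth_rows = [
        {
            "sample_id": sid,
            "resistant": int(cohort_sim.truth.resistant[sid]),
            **{k: int(v) for k, v in cohort_sim.truth.biomarker_flags[sid].items()},
        }
        for sid in samples
    ]
    pd.DataFrame(truth_rows).to_csv(out / "truth.tsv", sep="\t", index=False)

    config = {
        "build": "toy",
        "cohort": str(out / "cohort.tsv"),
        "segments": str(out / "segments.tsv"),
        "variants": str(out / "variants.tsv"),
        "expression": str(out / "expression.tsv"),
        "expression_scale": "log2tpm",
        "gene_sets": str(out / "gene_sets.gmt"),
        "signature_reference": str(out / "signatures.tsv"),
        "targets_bed": str(out / "targets.bed"),
        "signature_of_interest": reference.names[0],
        "hypoxia_set": HYPOXIA_SET,
        "emt_stem_set": EMT_STEM_SET,
        "shld2": {
            "gene": SHLD2_GENE,
            "chromosome": SHLD2_LOCUS[0],
            "start": SHLD2_LOCUS[1],
            "end": SHLD2_LOCUS[2],
            "z_cutoff": -1.0,
        },
        "seed": int(seed),
        "n_perm": 200,
        "out_dir": str(out / "results"),
    }
    config_path = out / "config.yaml"
    with open(config_path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
    return config_path
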