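"""End-to-end pipeline orchestration.

Stages: ingest or simulate -> well QC -> detection filter -> replicate
handling -> quantile (or rank) normalization -> per-phenotype association ->
sex stratification -> permutation FDR -> fetal association -> annotation
cross-reference -> report bundle. Every stage writes a plain-TSV artifact so
any step can be inspected or re-entered, and deterministic stages rerun
bit-identically from the same config and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import association, crossref, permutation_fdr, preprocess, report, synthetic
from .data_model import (
    Cohort,
    join_cohort,
    read_annotations,
    read_ct_matrix,
    read_fetal_table,
    read_sample_table,
    read_well_qc,
    write_ct_matrix,
    write_sample_table,
    write_well_qc,
)

logger = logging.getLogger(__name__)

PHENOTYPE_DEFAULTS = ("fev1_fvc", "fev1_pct", "fvc_pct")


@dataclass
class PipelineConfig:
    """Everything a full run needs; unset input paths trigger simulation."""

    outdir: str = "results/pipeline"
    ct_path: str | None = None
    qc_path: str | None = None
    samples_path: str | None = None
    fetal_ct_path: str | None = None
    fetal_table_path: str | None = None
    literature_path: str | None = None
    targets_path: str | None = None
    gwas_path: str | None = None
    qc_thresholds: preprocess.QCThresholds = field(default_factory=preprocess.QCThresholds)
    alpha: float = 0.05
    n_iter: int = 10_000
    seed: int = 0
    replicate_mode: str = "keep_all"
    normalization: str = "quantile"   # quantile | rank | none
    phenotypes: tuple[str, ...] = PHENOTYPE_DEFAULTS
    synthetic_params: synthetic.SyntheticParams | None = None
    run_fetal: bool = True
    run_permutation: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.normalization not in ("quantile", "rank", "none"):
            raise ValueError("normalization must be quantile, rank, or none")

    def digest(self) -> str:
        payload = {k: v for k, v in asdict(self).items()}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def bundled_annotation_path(name: str) -> Path:
    """Path to one of the annotation TSVs shipped with the package."""
    return Path(resources.files("mirlung.data") / name)


def _default_annotations():
    return read_annotations(
        literature_path=bundled_annotation_path("literature.tsv"),
        targets_path=bundled_annotation_path("targets_gwas_linked.tsv"),
        gwas_path=bundled_annotation_path("gwas_traits.tsv"),
    )


def preprocess_cohort(
    ct, qc_rows, samples, config: PipelineConfig
) -> tuple[Cohort, pd.DataFrame]:
    """QC -> detection filter -> replicate handling -> normalization."""
    ct = preprocess.apply_well_qc(ct, qc_rows, config.qc_thresholds)
    cohort = join_cohort(ct, samples)
    filtered, qc_report = preprocess.detection_filter(
        cohort.ct, config.qc_thresholds, cohort.samples
    )
    cohort = Cohort(filtered, cohort.samples)
    cohort = preprocess.collapse_replicates(cohort, config.replicate_mode)
    if config.normalization == "quantile":
        cohort = Cohort(
            preprocess.quantile_normalize_to_mean(cohort.ct), cohort.samples
        )
    elif config.normalization == "rank":
        vals = cohort.ct.values.copy()
        for i in range(vals.shape[0]):
            if np.isfinite(vals[i]).any():
                vals[i] = preprocess.rank_normalize(vals[i])
        cohort = Cohort(
            type(cohort.ct)(list(cohort.ct.feature_ids),
                            list(cohort.ct.sample_ids), vals),
            cohort.samples,
        )
    return cohort, qc_report


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every configured stage and write the report bundle.

    Returns a dict of in-memory results keyed by stage. Any stage failure
    propagates with the stage name prefixed.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"config_digest": config.digest(), "seed": config.seed}
    logger.info("pipeline start: config digest %s seed %d",
                bundle["config_digest"], config.seed)

    stage = "ingest"
    try:
        if config.ct_path is None:
            params = config.synthetic_params or synthetic.SyntheticParams(
                seed=config.seed)
            ct, qc_rows, samples, truth = synthetic.generate_cohort(params)
            truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
            write_ct_matrix(ct, outdir / "raw_ct.tsv")
            write_well_qc(qc_rows, outdir / "well_qc.tsv")
            write_sample_table(samples, outdir / "samples.tsv")
        else:
            ct = read_ct_matrix(config.ct_path)
            qc_rows = read_well_qc(config.qc_path) if config.qc_path else []
            samples = read_sample_table(config.samples_path)

        stage = "preprocess"
        cohort, qc_report = preprocess_cohort(ct, qc_rows, samples, config)
        qc_report.to_csv(outdir / "qc_report.tsv", sep="\t", index=False)
        write_ct_matrix(cohort.ct, outdir / "normalized_ct.tsv")
        bundle["cohort"] = cohort

        stage = "replicate_concordance"
        if (samples.frame.groupby("subject_id").size() > 1).any() \
                and config.replicate_mode == "keep_all":
            conc = preprocess.replicate_concordance(cohort)
            conc.to_csv(outdir / "replicate_concordance.tsv", sep="\t", index=False)
            bundle["replicate_concordance"] = conc

        stage = "associate"
        assoc_frames = {}
        for pheno in config.phenotypes:
            results = association.associate_all(cohort, pheno, config.alpha)
            frame = association.results_to_frame(results)
            report.round_association_frame(frame).to_csv(
                outdir / f"associations_{pheno}.tsv", sep="\t", index=False)
            assoc_frames[pheno] = frame
        bundle["associations"] = assoc_frames

        primary = config.phenotypes[0]
        significant = sorted(
            assoc_frames[primary].loc[assoc_frames[primary]["significant"],
                                      "feature_id"])
        bundle["significant"] = significant

        stage = "stratify"
        strat = association.stratify_by_sex(
            cohort, significant, primary, config.alpha)
        strat_frame = pd.DataFrame([
            {"feature_id": c.feature_id,
             "male_significant": c.male_significant, "male_p": c.male_p,
             "female_significant": c.female_significant, "female_p": c.female_p,
             "class": c.call_class}
            for c in strat
        ])
        strat_frame.to_csv(outdir / "stratified.tsv", sep="\t", index=False)
        bundle["stratified"] = strat

        stage = "permute"
        if config.run_permutation:
            null = permutation_fdr.permutation_null(
                cohort, primary, n_iter=config.n_iter, alpha=config.alpha,
                seed=config.seed, observed_significant=len(significant),
            )
            np.savetxt(outdir / "permutation_counts.txt", null.counts, fmt="%d")
            summary = {
                "n_iter": null.n_iter, "seed": null.seed,
                "median_fp": null.median_fp, "mean_fp": null.mean_fp,
                "observed_significant": null.observed_significant,
                "fdr_from_median": null.fdr_from_median,
                "fdr_from_mean": null.fdr_from_mean,
                "fdr_from_median_display": report.format_fdr(null.fdr_from_median),
                "fdr_from_mean_display": report.format_fdr(null.fdr_from_mean),
            }
            (outdir / "permutation_summary.json").write_text(
                json.dumps(summary, indent=2))
            bundle["permutation"] = null

        stage = "fetal"
        fetal_set: set[str] = set()
        if config.run_fetal:
            if config.fetal_ct_path:
                fetal_ct = read_ct_matrix(config.fetal_ct_path)
                fetal_table = read_fetal_table(config.fetal_table_path)
            else:
                fparams = synthetic.FetalParams(seed=config.seed + 1)
                fetal_ct, fetal_table, _ = synthetic.generate_fetal(fparams)
            fetal_results = association.fetal_age_association(
                fetal_ct, fetal_table, alpha=config.alpha)
            fetal_frame = association.results_to_frame(fetal_results)
            report.round_association_frame(fetal_frame).to_csv(
                outdir / "fetal_associations.tsv", sep="\t", index=False)
            fetal_set = {r.feature_id for r in fetal_results if r.significant}
            bundle["fetal"] = fetal_results

        stage = "crossref"
        if not significant:
            logger.warning("no significant features; skipping crossref stage")
            (outdir / "overlap.json").write_text(json.dumps(
                {"n_significant": 0, "regions": {}, "counts": {},
                 "percentages": {}}, indent=2))
            return bundle
        annotations = _default_annotations()
        flags = crossref.literature_flags(significant, annotations.literature)
        joined = crossref.gwas_target_join(
            significant, annotations.targets, annotations.gwas_traits)
        male_only = {c.feature_id for c in strat if c.call_class == "male_only"}
        female_only = {c.feature_id for c in strat if c.call_class == "female_only"}
        overlap = crossref.overlap_sets(
            set(significant), male_only, female_only, fetal_set & set(significant))
        bundle["overlap"] = overlap
        annot_frame = pd.DataFrame([
            {"feature_id": f, "lit_flag": flags[f],
             "fetal": f in fetal_set,
             "target_genes": ",".join(sorted(joined[f].target_genes)),
             "gwas_genes": ",".join(sorted(joined[f].gwas_genes))}
            for f in significant
        ])
        annot_frame.to_csv(outdir / "annotations.tsv", sep="\t", index=False)

        stage = "report"
        overlap_out = {
            "n_significant": overlap.n_significant,
            "regions": overlap.regions,
            "counts": overlap.counts,
            "percentages": {k: report.percent(len(v), overlap.n_significant)
                            for k, v in overlap.regions.items()},
        }
        # self-consistency audit: percentages must re-derive from memberships
        for k, v in overlap_out["percentages"].items():
            assert v == report.percent(overlap_out["counts"][k],
                                       overlap.n_significant)
        (outdir / "overlap.json").write_text(json.dumps(overlap_out, indent=2))
    except Exception as exc:  # noqa: BLE001 - annotate the failing stage
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    logger.info("pipeline complete; artifacts in %s", outdir)
    return bundle
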