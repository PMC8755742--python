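"""End-to-end orchestration: run the stages in order and write result tables.

Stage order is normalize -> cohort -> de -> pca -> modules -> enrich ->
tissues -> concord.  Each stage writes its tables into the output
directory; a run manifest records the configuration, seed, and library
versions.  Stages can be skipped; a stage whose prerequisite output is
missing raises with the stage name.
"""

from __future__ import annotations

import json
import logging

import numpy as np
import pandas as pd

from . import __version__
from .cohort import summarize_cohort
from .concordance import concordance, harmonize_ids
from .datatypes import (
    GROUP_MIDTRIMESTER,
    GROUP_TERM,
    LOG2,
    RAW,
    AbundanceMatrix,
    AnalyteAnnotation,
    Config,
    SampleMetadata,
    ValidationError,
)
from .diffabund import run_differential_abundance, run_midtrimester_contrast
from .enrich import hypergeometric_enrichment, map_analytes_to_genes
from .io import ensure_dir, write_abundance_matrix, write_table
from .network import (
    bicor_matrix,
    detect_modules,
    loess_profile,
    module_eigenprofiles,
    select_hubs,
    signed_adjacency,
    topological_overlap,
)
from .normalize import normalize_chain
from .pca import compute_pca, pc_trait_correlation
from .tissues import (
    build_tissue_signatures,
    compare_tissue_scores,
    score_tissue_signatures,
)

logger = logging.getLogger(__name__)

ALL_STAGES = (
    "normalize",
    "cohort",
    "de",
    "pca",
    "modules",
    "enrich",
    "tissues",
    "concord",
)


class StageError(RuntimeError):
    """A stage failed; carries the stage name."""


def _require(inputs: dict, key: str, stage: str):
    if key not in inputs or inputs[key] is None:
        raise StageError(f"stage {stage!r}: required input {key!r} missing")
    return inputs[key]


def run_pipeline(
    config: Config,
    inputs: dict,
    outdir,
    stages=ALL_STAGES,
) -> dict:
    """Execute the requested stages and write their tables under ``outdir``.

    ``inputs`` holds the loaded objects: ``matrix`` (AbundanceMatrix),
    ``metadata`` (SampleMetadata), ``annotation`` (AnalyteAnnotation), and
    optionally ``gene_sets``, ``atlas``, ``prior``, ``control_reference``,
    ``calibrator_reference``, ``calibrators``.  Returns the in-memory
    results keyed by stage.
    """
    outdir = ensure_dir(outdir)
    results: dict = {}
    matrix: AbundanceMatrix = _require(inputs, "matrix", "pipeline")
    metadata: SampleMetadata = _require(inputs, "metadata", "pipeline")
    annotation: AnalyteAnnotation = _require(inputs, "annotation", "pipeline")

    for stage in stages:
        if stage not in ALL_STAGES:
            raise ValidationError(f"unknown stage {stage!r}")

    try:
        if "normalize" in stages:
            if matrix.scale != RAW:
                raise StageError("stage 'normalize': matrix is not raw-scale")
            matrix, factors = normalize_chain(
                matrix,
                annotation,
                control_reference=inputs.get("control_reference"),
                calibrator_reference=inputs.get("calibrator_reference"),
                plate_ids=metadata.table.get("plate_id"),
                calibrators=inputs.get("calibrators"),
                steps=inputs.get("normalize_steps", ("hyb", "median", "plate")),
                log2=True,
            )
            write_abundance_matrix(matrix, f"{outdir}/normalized_log2.tsv")
            for name, f in factors.items():
                table = f.to_frame() if isinstance(f, pd.Series) else f
                write_table(table, f"{outdir}/factors_{name}.tsv", index_label="id")
            results["normalize"] = {"matrix": matrix, "factors": factors}
        elif matrix.scale == RAW:
            raise StageError(
                "downstream stages need a log2 matrix; include 'normalize' "
                "or provide log2 input"
            )

        assay = annotation.assay_ids
        log2_assay = matrix.subset(analytes=[a for a in assay if a in matrix.data.columns])

        if "cohort" in stages:
            summary = summarize_cohort(metadata)
            write_table(summary, f"{outdir}/cohort_summary.tsv", index_label="variable")
            results["cohort"] = summary

        if "de" in stages:
            de_main = run_differential_abundance(
                log2_assay,
                metadata,
                covariates=config.covariates,
                fc_min=config.fc_min,
                q_de=config.q_de,
            )
            de_mid = run_midtrimester_contrast(
                log2_assay,
                metadata,
                boundary=config.midtrimester_boundary,
                covariates=config.covariates,
                fc_min=config.fc_min,
                q_de=config.q_de,
            )
            write_table(de_main, f"{outdir}/de_term_vs_mid.tsv", index_label="analyte_id")
            write_table(de_mid, f"{outdir}/de_late_vs_early.tsv", index_label="analyte_id")
            results["de"] = {"term_vs_mid": de_main, "late_vs_early": de_mid}

        if "pca" in stages:
            n_comp = min(5, matrix.n_samples - 1, log2_assay.n_analytes)
            pca = compute_pca(log2_assay, n_components=n_comp)
            r, p = pc_trait_correlation(
                pca.scores["PC1"].to_numpy(),
                metadata.table.loc[pca.scores.index, "gestational_age_weeks"].to_numpy(),
            )
            write_table(pca.scores, f"{outdir}/pca_scores.tsv", index_label="sample_id")
            write_table(
                pca.loadings, f"{outdir}/pca_loadings.tsv", index_label="analyte_id"
            )
            summary = pd.DataFrame(
                {
                    "component": list(pca.scores.columns),
                    "variance_fraction": pca.variance_fraction,
                }
            ).set_index("component")
            write_table(summary, f"{outdir}/pca_variance.tsv", index_label="component")
            results["pca"] = {"pca": pca, "pc1_ga_r": r, "pc1_ga_abs_r": abs(r), "p": p}

        if "modules" in stages:
            if "de" not in results:
                raise StageError("stage 'modules': requires the 'de' stage output")
            de_main = results["de"]["term_vs_mid"]
            de_mid = results["de"]["late_vs_early"]
            union = sorted(
                set(de_main.index[de_main["significant"]])
                | set(de_mid.index[de_mid["significant"]])
            )
            if len(union) < max(config.min_module_size, 4):
                raise StageError(
                    f"stage 'modules': only {len(union)} modulated analytes"
                )
            expr = log2_assay.subset(analytes=union).data
            rho = bicor_matrix(expr.to_numpy())
            adj = signed_adjacency(rho, beta=config.network_power)
            tom = topological_overlap(adj)
            assignment = detect_modules(
                tom,
                expr,
                min_module_size=config.min_module_size,
                cut_height=config.cut_height,
                merge_corr=config.module_merge_corr,
            )
            write_table(
                assignment.labels.to_frame(),
                f"{outdir}/module_assignment.tsv",
                index_label="analyte_id",
            )
            mod_result = {"assignment": assignment, "n_background": int(
                (assignment.labels == 0).sum()
            )}
            if assignment.module_ids:
                eigs, kme = module_eigenprofiles(expr, assignment.labels)
                hubs = select_hubs(kme, assignment, n=4)
                write_table(
                    eigs.profiles, f"{outdir}/module_eigenprofiles.tsv",
                    index_label="sample_id",
                )
                write_table(kme, f"{outdir}/module_kme.tsv", index_label="analyte_id")
                ga = metadata.table.loc[expr.index, "gestational_age_weeks"].to_numpy()
                curves = []
                zexpr = (expr - expr.mean()) / expr.std(ddof=1)
                for m, hub_ids in hubs.items():
                    for aid in hub_ids:
                        grid, fitted = loess_profile(
                            ga, zexpr[aid].to_numpy(), span=config.loess_span,
                            n_grid=50,
                        )
                        curves.append(
                            pd.DataFrame(
                                {
                                    "module": m,
                                    "analyte_id": aid,
                                    "ga_weeks": grid,
                                    "fitted": fitted,
                                }
                            )
                        )
                curves = pd.concat(curves, ignore_index=True)
                write_table(curves, f"{outdir}/module_hub_loess.tsv")
                mod_result.update({"eigenprofiles": eigs, "kme": kme, "hubs": hubs,
                                   "loess": curves})
            results["modules"] = mod_result

        if "enrich" in stages:
            if "de" not in results:
                raise StageError("stage 'enrich': requires the 'de' stage output")
            gene_sets = _require(inputs, "gene_sets", "enrich")
            de_main = results["de"]["term_vs_mid"]
            universe, _ = map_analytes_to_genes(annotation, assay)
            enrich_results = {}
            for direction in ("up", "down"):
                called = de_main.index[
                    de_main["significant"] & (de_main["direction"] == direction)
                ]
                query, _ = map_analytes_to_genes(annotation, called)
                table = hypergeometric_enrichment(
                    query,
                    universe,
                    gene_sets,
                    min_term_hits=config.min_term_hits,
                    q_threshold=config.q_enrich,
                )
                write_table(table, f"{outdir}/enrichment_{direction}.tsv")
                enrich_results[direction] = table
            results["enrich"] = enrich_results

        if "tissues" in stages:
            atlas = _require(inputs, "atlas", "tissues")
            universe, _ = map_analytes_to_genes(annotation, assay)
            signatures = build_tissue_signatures(
                atlas,
                universe,
                specificity_ratio=config.specificity_ratio,
                top_n=config.signature_top_n,
            )
            scores = score_tissue_signatures(
                log2_assay, signatures, annotation, metadata,
                reference_group=GROUP_MIDTRIMESTER,
            )
            comparison = compare_tissue_scores(
                scores, metadata, q_threshold=config.q_tissue
            )
            sig_table = pd.DataFrame(
                [
                    {"tissue": s.tissue, "gene": g, "ratio": r}
                    for s in signatures
                    for g, r in zip(s.genes, s.ratios)
                ]
            )
            write_table(sig_table, f"{outdir}/tissue_signatures.tsv")
            write_table(scores, f"{outdir}/tissue_scores.tsv", index_label="sample_id")
            write_table(comparison, f"{outdir}/tissue_comparison.tsv",
                        index_label="tissue")
            results["tissues"] = {
                "signatures": signatures,
                "scores": scores,
                "comparison": comparison,
            }

        if "concord" in stages:
            if "de" not in results:
                raise StageError("stage 'concord': requires the 'de' stage output")
            prior = _require(inputs, "prior", "concord")
            pairs = harmonize_ids(results["de"]["term_vs_mid"], annotation, prior)
            result = concordance(pairs, require_both_significant=True)
            write_table(result.pairs, f"{outdir}/concordance_pairs.tsv")
            summary = pd.DataFrame(
                [
                    {
                        "n_common": result.n_common,
                        "spearman_rho": result.rho,
                        "p": result.p,
                        "same_direction": result.same_direction,
                        "same_direction_fraction": result.same_direction_fraction,
                    }
                ]
            )
            write_table(summary, f"{outdir}/concordance_summary.tsv")
            results["concord"] = result
    except ValidationError as exc:
        raise StageError(f"stage failed: {exc}") from exc

    manifest = {
        "afproteome_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "config": config.to_dict(),
        "stages": list(stages),
        "n_samples": matrix.n_samples,
        "n_analytes": matrix.n_analytes,
    }
    with open(f"{outdir}/manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return results
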