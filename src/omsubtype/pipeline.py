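"""End-to-end orchestration of the four pipeline steps, per omic and
integrated, with optional stratified re-runs.

Step 1 adjusts for cell composition, z-scores, and covariate-filters each
omic; Step 2 embeds the filtered matrix (autoencoder or PCA) at a shared
width; Step 3 clusters the embedding with MineClus over a systematic (w, k)
grid; Step 4 tests clinical associations, ranks subtype-discriminating
features by SVM-RFE, and runs annotation enrichment. With two or more omics
sharing subjects, both pre-clustering (concatenated embeddings) and
post-clustering (combination subtypes) integration run as well.

Every run writes a machine-readable manifest (config, seed, library
versions, per-omic summaries) so re-running the same config and seed
reproduces byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .assoc_enrich import fisher_enrichment, test_clinical_associations
from .config import PipelineConfig
from .dimred import (
    AETrainConfig,
    choose_num_dimensions,
    fit_autoencoder,
    fit_pca,
    reconstruction_mse,
    shared_dimension,
)
from .feature_select import select_features
from .integrate import (
    contrast_group_associations,
    post_cluster_combine,
    pre_cluster_integrate,
)
from .mineclus import select_params
from .preprocess import covariate_filter, regress_out_cell_counts, zscore_standardize

logger = logging.getLogger("omsubtype")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline per the config; returns the run manifest."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    schema = io.read_schema(config.schema_path)
    clinical = io.read_clinical_table(config.clinical_path, schema)
    omics = {
        name: io.read_omics_matrix(path, name)
        for name, path in config.omics_paths.items()
    }
    annotations = {
        name: io.read_annotation_sets(path)
        for name, path in config.annotations_paths.items()
    }

    manifest = _run_once(omics, clinical, annotations, config, outdir)
    if config.stratify_by:
        var = clinical[config.stratify_by]
        if var.kind not in ("binary", "categorical") or "test" not in var.roles:
            raise ValueError(
                f"stratification variable {var.name!r} must be a declared "
                "binary/categorical test variable"
            )
        manifest["strata"] = {}
        for level in sorted(var.values.dropna().unique()):
            keep = set(var.values[var.values == level].index)
            sub_omics = {
                name: m.select_subjects([s for s in m.subject_ids if s in keep])
                for name, m in omics.items()
            }
            sub_clin = clinical.subset([s for s in clinical.subject_ids
                                        if s in keep])
            stratum_dir = outdir / f"stratum_{config.stratify_by}_{level}"
            manifest["strata"][str(level)] = _run_once(
                sub_omics, sub_clin, annotations, config, stratum_dir
            )
    _write_manifest(manifest, outdir / "manifest.json")
    return manifest


def _run_once(omics, clinical, annotations, config, outdir) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    summary: dict = {
        "config": config.to_dict(),
        "seed": seed,
        "versions": _versions(),
        "omics": {},
    }

    embeddings, clusterings = {}, {}
    prepared = {}
    for name, raw in omics.items():
        adjusted = regress_out_cell_counts(raw, clinical)
        standardized = zscore_standardize(adjusted)
        filtered, report = covariate_filter(standardized, clinical,
                                            threshold=config.filter_fdr)
        io.write_table(report.tests, outdir / f"{name}_filter_report.tsv")
        (outdir / f"{name}_kept_features.txt").write_text(
            "\n".join(filtered.feature_ids) + "\n"
        )
        prepared[name] = (raw, filtered)
        summary["omics"][name] = {
            "n_subjects": raw.n_subjects,
            "n_features": raw.n_features,
            "n_kept_features": filtered.n_features,
        }

    if config.embedding_dim is not None:
        m_shared = int(config.embedding_dim)
        summary["embedding_dim"] = {"chosen": m_shared, "method": "configured"}
    else:
        elbows = {}
        for i, (name, (_, filtered)) in enumerate(sorted(prepared.items())):
            m_i, curve = choose_num_dimensions(
                filtered, config.candidate_dims, method=config.embedding_method,
                seed=seed + 101 * i,
                train_cfg=_ae_cfg(config),
            )
            io.write_table(curve, outdir / f"{name}_dimension_curve.tsv")
            elbows[name] = m_i
        m_shared = shared_dimension(elbows.values())
        summary["embedding_dim"] = {"chosen": m_shared, "per_omic": elbows,
                                    "method": "elbow"}

    for i, (name, (raw, filtered)) in enumerate(sorted(prepared.items())):
        m = min(m_shared, min(filtered.values.shape))
        if config.embedding_method == "autoencoder":
            emb = fit_autoencoder(filtered, m, train_cfg=_ae_cfg(config),
                                  seed=seed + 11 * i)
        else:
            emb = fit_pca(filtered, m)
        embeddings[name] = emb
        io.write_table(
            pd.DataFrame(emb.coordinates, index=pd.Index(emb.subject_ids,
                                                         name="subject_id")),
            outdir / f"{name}_embedding.tsv", index=True,
        )
        info = summary["omics"][name]
        info["embedding"] = {
            "method": emb.method, "m": emb.m,
            "reconstruction_mse": reconstruction_mse(emb, filtered),
            "overfit": emb.overfit,
        }

        selection = select_params(
            emb.coordinates,
            w_grid=config.w_grid,
            k_range=config.k_range,
            min_small_silhouette=config.min_small_silhouette,
            seed=seed + 13 * i,
            beta=config.beta,
            alpha=config.alpha,
        )
        io.write_table(selection.table, outdir / f"{name}_selection.tsv")
        if selection.k1_verdict:
            info["clustering"] = {"k": 1, "verdict": "no multi-cluster structure"}
            continue
        chosen = selection.chosen
        chosen.subject_ids = list(emb.subject_ids)
        clusterings[name] = chosen
        io.write_assignments(emb.subject_ids, name, chosen.labels,
                             outdir / f"{name}_assignments.tsv")
        info["clustering"] = {
            "k": chosen.n_clusters,
            "w": chosen.params.get("w"),
            "sizes": chosen.sizes(),
            "n_outliers": chosen.n_outliers,
            "silhouette": chosen.metrics.get("silhouette"),
            "connectedness": chosen.metrics.get("connectedness"),
        }

        assoc = test_clinical_associations(
            chosen.labels, clinical, subject_ids=emb.subject_ids,
            alpha=config.clinical_fdr, seed=seed + 17 * i,
        )
        io.write_table(assoc, outdir / f"{name}_clinical_associations.tsv")
        info["n_significant_clinical"] = int(assoc["significant"].sum()) \
            if not assoc.empty else 0

        if chosen.n_clusters == 2:
            try:
                ranking = select_features(filtered, chosen.labels,
                                          seed=seed + 19 * i)
            except ValueError as exc:  # e.g. a stratum too small to fold
                logger.warning("%s: feature selection skipped (%s)", name, exc)
                continue
            io.write_table(ranking.table(), outdir / f"{name}_feature_ranking.tsv")
            info["feature_selection"] = {
                "chosen_size": ranking.chosen_size,
                "relaxed_size": len(ranking.relaxed),
            }
            if name in annotations:
                enrich = fisher_enrichment(
                    ranking.relaxed,
                    raw.feature_ids,  # non-filtered background universe
                    annotations[name],
                    fdr_threshold=config.enrichment_fdr,
                )
                io.write_table(enrich, outdir / f"{name}_enrichment.tsv")
                info["n_enriched"] = int(enrich["significant"].sum()) \
                    if not enrich.empty else 0

    if len(clusterings) >= 2:
        _integrate(embeddings, clusterings, clinical, config, outdir, summary)
    return summary


def _integrate(embeddings, clusterings, clinical, config, outdir, summary):
    names = sorted(clusterings)
    shared = set(embeddings[names[0]].subject_ids)
    for n in names[1:]:
        shared &= set(embeddings[n].subject_ids)
    if not shared:
        logger.warning("no overlapping subjects across omics; integration skipped")
        summary["integration"] = {"skipped": "no overlapping subjects"}
        return
    integration: dict = {"n_shared_subjects": len(shared)}

    selection, joined = pre_cluster_integrate(
        [embeddings[n] for n in names],
        k_range=config.k_range,
        w_grid=config.w_grid,
        min_small_silhouette=config.min_small_silhouette,
        seed=config.seed + 23,
        beta=config.beta,
        alpha=config.alpha,
    )
    io.write_table(selection.table, outdir / "integrated_selection.tsv")
    if selection.k1_verdict:
        integration["pre_clustering"] = {"k": 1}
    else:
        chosen = selection.chosen
        io.write_assignments(joined.subject_ids, "+".join(names), chosen.labels,
                             outdir / "integrated_assignments.tsv")
        integration["pre_clustering"] = {
            "k": chosen.n_clusters,
            "sizes": chosen.sizes(),
            "silhouette": chosen.metrics.get("silhouette"),
            "width": joined.m,
        }

    binary = all(clusterings[n].n_clusters == 2 for n in names)
    if binary:
        result = post_cluster_combine([clusterings[n] for n in names], names)
        io.write_table(
            result.combination.rename_axis("subject_id").reset_index(),
            outdir / "combination_subtypes.tsv",
        )
        io.write_table(
            result.counts().rename_axis("combination").reset_index(name="count"),
            outdir / "combination_counts.tsv",
        )
        assoc = contrast_group_associations(result, clinical,
                                            alpha=config.clinical_fdr,
                                            seed=config.seed + 29)
        io.write_table(assoc, outdir / "contrast_associations.tsv")
        integration["post_clustering"] = {
            "n_combination_subtypes": int(result.combination.nunique()),
            "n_excluded_outliers": result.n_excluded_outliers,
            "contrast_group_sizes": {
                k: len(v) for k, v in result.contrast_groups.items()
            },
        }
    else:
        logger.warning("post-clustering combination needs binary clusterings "
                       "in every omic; skipped")
        integration["post_clustering"] = {"skipped": "non-binary clustering"}
    summary["integration"] = integration


def _ae_cfg(config: PipelineConfig) -> AETrainConfig:
    return AETrainConfig(epochs=config.ae_epochs,
                         learning_rate=config.ae_learning_rate)


def _versions() -> dict:
    import scipy
    import sklearn

    return {
        "omsubtype": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "scikit-learn": sklearn.__version__,
    }


def _write_manifest(manifest: dict, path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True,
                                     default=str) + "\n")
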