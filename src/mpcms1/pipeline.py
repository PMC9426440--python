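"""End-to-end orchestration of the screening pipeline.

Stages run in a fixed order: preprocessing (quartile missingness, group
prevalence filter, kNN imputation, median-ratio normalization, log2) ->
robust consensus ICA -> k-medoid feature modules -> eigenfeatures ->
condition correlation -> average-linkage condition tree with silhouette
cut and AU/BP bootstrap -> optional Lasso marker models.  A master seed
fans out to per-stage seeds by fixed offsets recorded in the run report.
Stratified runs partition samples by a covariate and repeat the pipeline
per stratum.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import preprocess as pp
from .condition_tree import au_bootstrap, average_linkage_tree, condition_distance, cut_by_silhouette
from .eigenfeatures import compute_eigenfeatures, condition_indicators, correlate_eigenfeatures
from .ica import robust_ica
from .io import write_outputs
from .kmedoids import correlation_distance_matrix, select_k
from .markers import fit_lasso_loocv, loocv_auc, select_marker_module
from .types import DesignTable, IntensityMatrix

logger = logging.getLogger(__name__)

# fixed per-stage seed offsets from the master seed
STAGE_SEED_OFFSETS = {
    "ica": 11,
    "feature_clustering": 23,
    "bootstrap": 37,
    "markers": 53,
}

DEFAULT_CONFIG: dict[str, Any] = {
    "censor": "none",
    "min_frac": 0.5,
    "knn_k": 10,
    "colmax": 0.95,
    "rowmax": 0.5,
    "n_runs": 100,
    "var_target": 0.99,
    "n_components": None,
    "ica_tol": 1e-6,
    "ica_max_iter": 1000,
    "support": 0.5,
    "link_threshold": 0.1,
    "k_min": 10,
    "k_max": 50,
    "restarts": 1,
    "cut_k_min": 2,
    "cut_k_max": None,
    "n_boot": 1000,
    "markers_outcome": None,
    "stratify_by": None,
}


@dataclass
class RunResult:
    """Everything one pipeline run produced, plus the JSON-ready report."""

    normalized: IntensityMatrix
    decomposition: Any
    clustering: Any
    eigenfeatures: Any
    correlation: Any
    tree: Any
    markers: Any | None
    report: dict[str, Any]
    manifest: dict[str, str] = field(default_factory=dict)


def _stage_seed(master: int, stage: str) -> int:
    return (int(master) + STAGE_SEED_OFFSETS[stage]) % (2**31)


def run_full(
    matrix: IntensityMatrix,
    design: DesignTable,
    config: dict[str, Any] | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> RunResult | dict[str, RunResult]:
    """Run the full pipeline; returns per-stratum results when stratified."""
    cfg = dict(DEFAULT_CONFIG)
    if config:
        unknown = set(config) - set(DEFAULT_CONFIG)
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(config)

    if cfg["stratify_by"]:
        col = cfg["stratify_by"]
        if design.covariates is None or col not in design.covariates.columns:
            raise KeyError(f"stratify covariate {col!r} not in design")
        results: dict[str, RunResult] = {}
        for level in design.covariates[col].unique():
            keep = design.covariates[col] == level
            ids = [s for s, k in zip(design.sample_ids, keep) if k]
            sub_cfg = dict(cfg)
            sub_cfg["stratify_by"] = None
            sub_out = None if out_dir is None else Path(out_dir) / f"stratum_{level}"
            results[str(level)] = run_full(
                matrix.subset_samples(np.array([s in ids for s in matrix.sample_ids])),
                design.subset(ids),
                sub_cfg,
                seed=seed,
                out_dir=sub_out,
            )
        return results

    import scipy
    import sklearn

    from . import __version__

    timings: dict[str, float] = {}
    report: dict[str, Any] = {
        "master_seed": int(seed),
        "config": {k: v for k, v in cfg.items() if not isinstance(v, np.ndarray)},
        "versions": {
            "mpcms1": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "scikit-learn": sklearn.__version__,
        },
        "stage_seed_offsets": dict(STAGE_SEED_OFFSETS),
    }

    def timed(stage):
        class _T:
            def __enter__(self_):
                self_.t0 = time.perf_counter()
            def __exit__(self_, *exc):
                timings[stage] = round(time.perf_counter() - self_.t0, 3)
        return _T()

    try:
        stage = "preprocess"
        with timed(stage):
            logged, info = pp.preprocess_pipeline(
                matrix,
                design,
                censor=cfg["censor"],
                min_frac=cfg["min_frac"],
                knn_k=cfg["knn_k"],
                colmax=cfg["colmax"],
                rowmax=cfg["rowmax"],
            )
        report["preprocess"] = info

        stage = "ica"
        with timed(stage):
            decomp = robust_ica(
                logged,
                n_runs=cfg["n_runs"],
                var_target=cfg["var_target"],
                n_components=cfg["n_components"],
                tol=cfg["ica_tol"],
                max_iter=cfg["ica_max_iter"],
                min_support=cfg["support"],
                link_threshold=cfg["link_threshold"],
                seed=_stage_seed(seed, "ica"),
            )
        report["ica"] = {
            "n_requested": decomp.n_requested,
            "n_robust": decomp.n_robust,
            "cluster_sizes": decomp.cluster_sizes,
        }

        stage = "feature_clustering"
        with timed(stage):
            dist = correlation_distance_matrix(decomp.S)
            k_max = min(cfg["k_max"], logged.n_features - 1)
            clustering = select_k(
                dist,
                k_range=range(cfg["k_min"], k_max + 1),
                seed=_stage_seed(seed, "feature_clustering"),
                restarts=cfg["restarts"],
            )
        report["feature_clustering"] = {
            "chosen_k": clustering.chosen_k,
            "silhouette_by_k": {str(k): v for k, v in clustering.silhouette_by_k.items()},
        }

        stage = "eigenfeatures"
        with timed(stage):
            eigen = compute_eigenfeatures(logged, clustering)
            indicators, levels = condition_indicators(design.subset(logged.sample_ids))
            profile = correlate_eigenfeatures(eigen, indicators, levels)
        report["eigenfeatures"] = {
            "explained_variance": eigen.explained_variance.tolist(),
        }

        stage = "condition_tree"
        with timed(stage):
            cdist = condition_distance(profile)
            tree = average_linkage_tree(cdist, levels)
            cut_max = cfg["cut_k_max"] or max(2, len(levels) - 1)
            tree = cut_by_silhouette(tree, cdist, k_range=range(cfg["cut_k_min"], cut_max + 1))
            tree = au_bootstrap(
                profile,
                tree,
                n_boot=cfg["n_boot"],
                seed=_stage_seed(seed, "bootstrap"),
            )
        report["condition_tree"] = {
            "chosen_k": tree.chosen_k,
            "au": [None if np.isnan(a) else round(float(a), 6) for a in tree.au],
            "bp": [round(float(b), 6) for b in tree.bp],
        }

        marker_models = None
        if cfg["markers_outcome"]:
            stage = "markers"
            with timed(stage):
                outcome = cfg["markers_outcome"]
                module_id = select_marker_module(profile, outcome)
                rows = clustering.labels == module_id
                X = logged.values[rows].T  # samples x features
                yvec = np.array(
                    [1.0 if c == outcome else 0.0 for c in design.aligned_conditions(logged.sample_ids)]
                )
                model = fit_lasso_loocv(
                    X,
                    yvec,
                    feature_ids=[f for f, r in zip(logged.feature_ids, rows) if r],
                    outcome=outcome,
                    module_id=module_id,
                    seed=_stage_seed(seed, "markers"),
                )
                if model.kept:
                    loocv_auc(model, X, yvec)
                marker_models = model
            report["markers"] = {
                "outcome": outcome,
                "module_id": module_id,
                "lambda_1se": model.lambda_1se,
                "kept": model.kept,
                "nonzero_features": model.nonzero_features,
                "loocv_auc": model.loocv_auc,
            }
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    report["timings_s"] = timings

    result = RunResult(
        normalized=logged,
        decomposition=decomp,
        clustering=clustering,
        eigenfeatures=eigen,
        correlation=profile,
        tree=tree,
        markers=marker_models,
        report=report,
    )
    if out_dir is not None:
        result.manifest = write_result(result, design, out_dir)
    return result


def write_result(result: RunResult, design: DesignTable, out_dir: str | Path) -> dict[str, str]:
    """Serialize a RunResult through the standard output writer."""
    logged = result.normalized
    modules = pd.DataFrame(
        {
            "feature_id": logged.feature_ids,
            "module": result.clustering.labels,
            "rt": logged.rt if logged.rt is not None else np.nan,
            "mz": logged.mz if logged.mz is not None else np.nan,
        }
    )
    eig = pd.DataFrame(result.eigenfeatures.E, columns=logged.sample_ids)
    eig.insert(0, "module", result.eigenfeatures.module_ids)
    corr = pd.DataFrame(result.correlation.R, columns=result.correlation.conditions)
    corr.insert(0, "module", result.correlation.module_ids)
    flat = pd.DataFrame(
        {"condition": result.tree.leaves, "cluster": result.tree.flat_labels}
    )
    # report timings are excluded from hashing via the manifest design:
    # the manifest covers data outputs only and is embedded in the report.
    return write_outputs(
        {
            "normalized": logged,
            "modules": modules,
            "eigenfeatures": eig,
            "correlation": corr,
            "flat_labels": flat,
            "tree": result.tree,
            "report": result.report,
        },
        out_dir,
    )
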