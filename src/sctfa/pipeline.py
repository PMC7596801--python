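"""Configuration object and end-to-end pipeline runner.

The pipeline chains: load -> optional cell subsampling -> gene/TF filters ->
log2 transform -> train/test split -> standardization -> task-tree
construction -> model fitting (with cross-validation) -> test-set
evaluation -> TF-level interpretation. Every source of randomness is
seeded through the config, so identical configs give identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from .containers import ExpressionMatrix, FeatureMatrix
from .interpret import build_activity_report, tf_expr_cor
from .models import (
    DEFAULT_LAMBDA_GRID,
    FitResult,
    cross_validate_omtl,
    cross_validate_tree,
    evaluate_per_cell,
    fit_omtl,
    fit_stl,
    fit_tree_guided,
    predict,
)
from .preprocess import (
    detect_gene_filter,
    drop_zero_expression_tfs,
    log2_expression,
    log2_transform,
    split_train_test,
    standardize,
    variance_filter,
)
from .trees import build_embedding_tree, build_hc_tree, build_star_tree, shuffle_expression

logger = logging.getLogger(__name__)

TREE_VARIANTS = ("hc", "embedding", "star", "shuffled")
MODEL_KINDS = ("stl", "omtl", "tree")


@dataclass
class RunConfig:
    """Validated description of one pipeline run."""

    expression: str
    features: str
    out_dir: str
    feature_flavour: str = "generic"
    labels: str | None = None
    coords: str | None = None
    tree_variant: str = "hc"
    model: str = "tree"
    lambda_grid: list[float] = field(default_factory=lambda: list(DEFAULT_LAMBDA_GRID))
    folds: int = 5
    seed: int = 0
    min_expr: float = 0.1
    min_cells: int = 10
    log2_pseudocount: float = 1.0
    split_frac: float = 0.6
    subsample_cells: float | None = None
    skip_filters: bool = False
    max_iter: int = 1000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def validate(self) -> None:
        for key in ("expression", "features"):
            p = getattr(self, key)
            if not Path(p).exists():
                raise FileNotFoundError(f"{key} file not found: {p}")
        for key in ("labels", "coords"):
            p = getattr(self, key)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{key} file not found: {p}")
        if self.tree_variant not in TREE_VARIANTS:
            raise ValueError(f"tree_variant must be one of {TREE_VARIANTS}")
        if self.model not in MODEL_KINDS:
            raise ValueError(f"model must be one of {MODEL_KINDS}")
        if not self.lambda_grid:
            raise ValueError("lambda_grid must be nonempty")
        if self.tree_variant == "embedding" and self.coords is None:
            raise ValueError("embedding tree requires a coords file")
        if self.subsample_cells is not None and not 0 < self.subsample_cells <= 1:
            raise ValueError("subsample_cells must be in (0, 1]")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _subsample_cells(expr: ExpressionMatrix, frac: float, seed: int) -> ExpressionMatrix:
    k = expr.n_cells
    keep_n = int(round(frac * k))
    rng = np.random.default_rng(seed)
    keep_idx = np.sort(rng.choice(k, size=keep_n, replace=False))
    return expr.subset_cells([expr.cell_ids[i] for i in keep_idx])


def apply_filters(
    features: FeatureMatrix,
    expr: ExpressionMatrix,
    min_expr: float = 0.1,
    min_cells: int = 10,
    tf_gene_map: dict[str, str] | None = None,
):
    """Canonical filter chain on raw TPM: detect -> variance -> TF drop.

    Returns the filtered (still raw-scale) feature and expression matrices
    plus the two filter reports.
    """
    detected, detect_report = detect_gene_filter(expr, min_expr, min_cells)
    shared = [g for g in features.gene_ids if g in set(detected)]
    features = features.subset_genes(shared)
    kept_var, var_report = variance_filter(features)
    features = features.subset_genes(kept_var)
    features = drop_zero_expression_tfs(features, expr, tf_gene_map)
    expr = expr.subset_genes(features.gene_ids)
    return features, expr, detect_report, var_report


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured workflow; returns the output directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"config": asdict(config), "stages": {}}

    def stage(name: str):
        logger.info("stage: %s", name)
        log["stages"][name] = "started"

    try:
        stage("load")
        labels = sio.read_labels(config.labels) if config.labels else None
        expr = sio.read_expression(config.expression, cell_labels=labels)
        features = sio.read_feature_matrix(config.features, config.feature_flavour)

        if config.subsample_cells is not None:
            stage("subsample")
            expr = _subsample_cells(expr, config.subsample_cells, config.seed)
            log["stages"]["subsample"] = f"kept {expr.n_cells} cells"

        if config.tree_variant == "shuffled":
            stage("shuffle")
            expr = shuffle_expression(expr, config.seed)

        if not config.skip_filters:
            stage("filter")
            features, expr, detect_report, var_report = apply_filters(
                features, expr, config.min_expr, config.min_cells
            )
            sio.write_filter_report(detect_report, out / "detect_filter.tsv")
            sio.write_filter_report(var_report, out / "variance_filter.tsv")
            log["stages"]["filter"] = f"{features.n_genes} genes, {features.n_features} features"
        else:
            shared = [g for g in features.gene_ids if g in set(expr.gene_ids)]
            features = features.subset_genes(shared)
            expr = expr.subset_genes(shared)

        stage("log2")
        X_raw = log2_transform(features.values, config.log2_pseudocount)
        if expr.scale == "tpm":
            expr = log2_expression(expr, config.log2_pseudocount)
        Y_raw = expr.values

        stage("split")
        split = split_train_test(features.n_genes, config.split_frac, config.seed)
        sio.write_split(split, features.gene_ids, out / "split.tsv")

        stage("standardize")
        tr, te = split.train_gene_indices, split.test_gene_indices
        std = standardize(X_raw[tr], Y_raw[tr], X_raw[te], Y_raw[te])

        stage("tree")
        tree = None
        if config.model == "tree":
            if config.tree_variant == "star":
                tree = build_star_tree(expr.cell_ids)
            elif config.tree_variant == "embedding":
                tree = build_embedding_tree(sio.read_coords(config.coords))
            else:  # hc, and shuffled (clustering runs on the shuffled matrix)
                tree = build_hc_tree(expr)
            sio.write_tree(tree, out / "tree.nwk", out / "tree_nodes.tsv")

        stage("fit")
        X_train, Y_train = std["X_train"], std["Y_train"]
        cv = None
        if config.model == "tree":
            cv = cross_validate_tree(
                X_train, Y_train, tree, tuple(config.lambda_grid),
                folds=config.folds, seed=config.seed, max_iter=config.max_iter,
            )
            fit = fit_tree_guided(X_train, Y_train, tree, cv.selected,
                                  max_iter=config.max_iter)
        elif config.model == "omtl":
            cv = cross_validate_omtl(
                X_train, Y_train, tuple(config.lambda_grid),
                folds=config.folds, seed=config.seed, max_iter=config.max_iter,
            )
            fit = fit_omtl(X_train, Y_train, cv.selected, max_iter=config.max_iter)
        else:
            fit = fit_stl(X_train, Y_train, seed=config.seed)
        fit.x_scaler = std["x_scaler"]
        fit.y_scaler = std["y_scaler"]
        fit.split = split
        fit.feature_ids = [features.feature_ids[i] for i in std["x_scaler"].kept_columns]
        fit.cell_ids = [expr.cell_ids[j] for j in std["y_scaler"].kept_columns]
        sio.write_fit(fit, out / "fit")
        if cv is not None:
            pd.DataFrame(
                {"lambda": cv.grid, "mean_loss": cv.mean_losses}
            ).to_csv(out / "cv.tsv", sep="\t", index=False)

        stage("evaluate")
        Y_hat = predict(fit, X_raw[te])
        Y_te = Y_raw[np.ix_(te, std["y_scaler"].kept_columns)]
        r = evaluate_per_cell(Y_hat, Y_te)
        pd.DataFrame({"cell_id": fit.cell_ids, "pearson_r": r}).to_csv(
            out / "per_cell_correlation.tsv", sep="\t", index=False
        )
        log["stages"]["evaluate"] = {
            "median_r": float(np.nanmedian(r)),
            "n_undefined": int(np.isnan(r).sum()),
        }

        stage("interpret")
        B = pd.DataFrame(fit.B, index=fit.feature_ids, columns=fit.cell_ids)
        cell_labels = None
        if labels is not None and len(set(labels.values())) == 2:
            cell_labels = {c: labels[c] for c in fit.cell_ids}
        tf_expression = None
        expr_frame = expr.to_frame()
        tf_genes = [f for f in fit.feature_ids if f in expr_frame.index]
        if tf_genes:
            tf_expression = expr_frame.loc[tf_genes, fit.cell_ids]
        report = build_activity_report(
            B, cell_labels=cell_labels, tf_expression=tf_expression
        )
        report.to_frame().to_csv(out / "activity_report.tsv", sep="\t",
                                 index_label="tf_id")

        log["stages"]["done"] = True
        return out
    except StageError:
        raise
    except Exception as exc:  # annotate with the failing stage
        failed = [s for s, v in log["stages"].items() if v == "started"]
        raise StageError(failed[-1] if failed else "unknown", exc) from exc
    finally:
        (out / "run_log.json").write_text(json.dumps(log, indent=2, default=str) + "\n")


def null_model_correlations(
    features: FeatureMatrix,
    expr: ExpressionMatrix,
    lam: float,
    seed: int,
    log2_pseudocount: float = 1.0,
    max_iter: int = 1000,
) -> pd.Series:
    """TF-expression/coefficient correlations under the shuffled-expression model.

    Shuffles each cell's expression, rebuilds the clustering tree on the
    shuffled matrix, refits, and correlates coefficients against the
    shuffled expression of each TF gene present in the matrix.
    """
    shuffled = shuffle_expression(expr, seed)
    if shuffled.scale == "tpm":
        shuffled = log2_expression(shuffled, log2_pseudocount)
    X = log2_transform(features.values, log2_pseudocount)
    std = standardize(X, shuffled.values)
    tree = build_hc_tree(shuffled)
    fit = fit_tree_guided(std["X_train"], std["Y_train"], tree, lam, max_iter=max_iter)
    feature_ids = [features.feature_ids[i] for i in std["x_scaler"].kept_columns]
    cell_ids = [shuffled.cell_ids[j] for j in std["y_scaler"].kept_columns]
    B = pd.DataFrame(fit.B, index=feature_ids, columns=cell_ids)
    expr_frame = shuffled.to_frame()
    tf_genes = [f for f in feature_ids if f in expr_frame.index]
    if not tf_genes:
        raise ValueError("no feature ids present in the expression matrix")
    return tf_expr_cor(B.loc[tf_genes], expr_frame.loc[tf_genes, cell_ids])
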