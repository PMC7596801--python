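"""Gene/TF filtering, log2 transform, standardization, and train/test split.

The canonical filter order is: detected-gene filter on raw TPM, then
feature-variance filter, then removal of unexpressed TFs, then log2
transform of both matrices.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .containers import DYNAMIC_EXTRA_COLUMNS, ExpressionMatrix, FeatureMatrix

logger = logging.getLogger(__name__)


@dataclass
class FilterReport:
    """Record of what the gene/TF filters saw and decided."""

    per_gene_variance: dict[str, float] = field(default_factory=dict)
    threshold: float | None = None
    kept_genes: list[str] = field(default_factory=list)
    kept_tfs: list[str] = field(default_factory=list)
    detected_counts: dict[str, int] = field(default_factory=dict)


def detect_gene_filter(
    expr: ExpressionMatrix, min_expr: float = 0.1, min_cells: int = 10
) -> tuple[list[str], FilterReport]:
    """Keep genes detected (expression >= ``min_expr``) in at least ``min_cells`` cells."""
    if expr.scale != "tpm":
        raise ValueError("detected-gene filter operates on raw TPM values")
    if expr.n_cells < min_cells:
        warnings.warn(
            f"only {expr.n_cells} cells < min_cells={min_cells}; every gene will be dropped",
            stacklevel=2,
        )
    detected = (expr.values >= min_expr).sum(axis=1)
    kept = [g for g, c in zip(expr.gene_ids, detected) if c >= min_cells]
    report = FilterReport(
        kept_genes=kept,
        detected_counts=dict(zip(expr.gene_ids, (int(c) for c in detected))),
    )
    return kept, report


def variance_filter(features: FeatureMatrix) -> tuple[list[str], FilterReport]:
    """Keep genes whose per-row feature variance reaches the third quartile.

    The threshold is the type-7 (linear interpolation) Q3 of the per-gene
    sample variances; genes with variance >= threshold are kept, so a
    constant matrix (all variances zero) keeps everything.
    """
    if features.n_genes < 4:
        raise ValueError("variance filter needs at least 4 genes")
    variances = features.values.var(axis=1, ddof=1)
    threshold = float(np.quantile(variances, 0.75))
    if threshold == 0.0:
        logger.warning("variance threshold is 0; all genes kept")
    keep_mask = variances >= threshold
    kept = [g for g, k in zip(features.gene_ids, keep_mask) if k]
    report = FilterReport(
        per_gene_variance=dict(zip(features.gene_ids, variances.tolist())),
        threshold=threshold,
        kept_genes=kept,
    )
    return kept, report


def drop_zero_expression_tfs(
    features: FeatureMatrix,
    expr: ExpressionMatrix,
    tf_gene_map: dict[str, str] | None = None,
) -> FeatureMatrix:
    """Remove TF columns whose encoding gene has zero total expression.

    ``tf_gene_map`` maps feature ids to gene ids in ``expr``; when omitted the
    feature id itself is used. The ``Peak_*`` summary columns are exempt, and
    a TF without a mapped gene is retained with a warning.
    """
    if expr.scale != "tpm":
        raise ValueError("TF expression check operates on raw TPM values")
    totals = dict(zip(expr.gene_ids, expr.values.sum(axis=1)))
    kept: list[str] = []
    for fid in features.feature_ids:
        if fid in DYNAMIC_EXTRA_COLUMNS:
            kept.append(fid)
            continue
        gene = (tf_gene_map or {}).get(fid, fid)
        if gene not in totals:
            warnings.warn(f"feature {fid}: no expression record for gene {gene}; retained",
                          stacklevel=2)
            kept.append(fid)
        elif totals[gene] > 0:
            kept.append(fid)
    return features.subset_features(kept)


def log2_transform(values: np.ndarray, pseudocount: float = 1.0) -> np.ndarray:
    """Entry-wise ``log2(x + pseudocount)``; with the default pseudocount 0 maps to 0."""
    values = np.asarray(values, dtype=float)
    if np.any(values < 0):
        raise ValueError("log2 transform requires nonnegative entries")
    return np.log2(values + pseudocount)


def log2_expression(expr: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    return ExpressionMatrix(
        log2_transform(expr.values, pseudocount),
        expr.gene_ids,
        expr.cell_ids,
        expr.cell_labels,
        scale="log2",
    )


@dataclass
class Standardizer:
    """Column-wise zero-mean / unit-variance transform fit on training rows only.

    Zero-variance columns are dropped (recorded in ``dropped``), never divided
    by zero. ``transform`` applies the stored training statistics to any rows.
    """

    means: np.ndarray | None = None
    scales: np.ndarray | None = None
    kept_columns: np.ndarray | None = None
    dropped: list[int] = field(default_factory=list)

    def fit(self, values: np.ndarray) -> "Standardizer":
        values = np.asarray(values, dtype=float)
        means = values.mean(axis=0)
        scales = values.std(axis=0, ddof=1)
        keep = scales > 0
        if not np.all(keep):
            self.dropped = list(np.flatnonzero(~keep))
            warnings.warn(
                f"{len(self.dropped)} zero-variance column(s) dropped during standardization",
                stacklevel=2,
            )
        self.means = means[keep]
        self.scales = scales[keep]
        self.kept_columns = np.flatnonzero(keep)
        return self

    def transform(self, values: np.ndarray) -> np.ndarray:
        if self.means is None:
            raise RuntimeError("Standardizer not fitted")
        return (np.asarray(values, dtype=float)[:, self.kept_columns] - self.means) / self.scales

    def fit_transform(self, values: np.ndarray) -> np.ndarray:
        return self.fit(values).transform(values)

    def inverse_transform(self, values: np.ndarray) -> np.ndarray:
        if self.means is None:
            raise RuntimeError("Standardizer not fitted")
        return np.asarray(values, dtype=float) * self.scales + self.means


def standardize(
    X_train: np.ndarray,
    Y_train: np.ndarray,
    X_test: np.ndarray | None = None,
    Y_test: np.ndarray | None = None,
) -> dict:
    """Standardize feature and response columns using training statistics.

    Returns a dict with transformed ``X_train``/``Y_train`` (and test splits
    when given) plus the fitted ``x_scaler``/``y_scaler``.
    """
    xs = Standardizer().fit(X_train)
    ys = Standardizer().fit(Y_train)
    out = {
        "X_train": xs.transform(X_train),
        "Y_train": ys.transform(Y_train),
        "x_scaler": xs,
        "y_scaler": ys,
    }
    if X_test is not None:
        out["X_test"] = xs.transform(X_test)
    if Y_test is not None:
        out["Y_test"] = ys.transform(Y_test)
    return out


@dataclass(frozen=True)
class SplitSpec:
    """Reproducible disjoint train/test partition over gene indices."""

    train_gene_indices: np.ndarray
    test_gene_indices: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        train = set(self.train_gene_indices.tolist())
        test = set(self.test_gene_indices.tolist())
        if train & test:
            raise ValueError("train and test indices overlap")


def split_train_test(n: int, frac: float = 0.6, seed: int = 0) -> SplitSpec:
    """Uniformly random split of ``n`` genes into round(frac * n) train and the rest test."""
    if not 0.0 < frac < 1.0:
        raise ValueError("frac must be in (0, 1)")
    if n < 5:
        raise ValueError("need at least 5 genes to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(frac * n))
    return SplitSpec(
        train_gene_indices=np.sort(perm[:n_train]),
        test_gene_indices=np.sort(perm[n_train:]),
        seed=seed,
    )
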