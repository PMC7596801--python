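"""Core labelled-matrix containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Extra per-gene open-chromatin summary columns carried by dynamic feature matrices.
DYNAMIC_EXTRA_COLUMNS = ("Peak_Counts", "Peak_Length", "Peak_Signal")

FLAVOURS = ("static", "dynamic", "chipseq", "generic")


def _check_unique(ids, what: str) -> None:
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate {what} ids")


@dataclass
class FeatureMatrix:
    """Genes x TF-features matrix.

    Rows are genes, columns are TF features (plus, for the dynamic flavour,
    the three ``Peak_*`` summary columns). Values are nonnegative on the raw
    scale; they may become real-valued only after standardization.
    """

    values: np.ndarray
    gene_ids: list[str]
    feature_ids: list[str]
    flavour: str = "generic"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = list(self.gene_ids)
        self.feature_ids = list(self.feature_ids)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        n, p = self.values.shape
        if n != len(self.gene_ids) or p != len(self.feature_ids):
            raise ValueError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.gene_ids)} gene ids / {len(self.feature_ids)} feature ids"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite entries")
        if self.flavour not in FLAVOURS:
            raise ValueError(f"unknown flavour {self.flavour!r}")
        if self.flavour == "dynamic":
            missing = [c for c in DYNAMIC_EXTRA_COLUMNS if c not in self.feature_ids]
            if missing:
                raise ValueError(f"dynamic flavour missing columns {missing}")
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.feature_ids, "feature")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.feature_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, flavour: str = "generic") -> "FeatureMatrix":
        return cls(
            values=df.to_numpy(dtype=float),
            gene_ids=[str(g) for g in df.index],
            feature_ids=[str(f) for f in df.columns],
            flavour=flavour,
        )

    def subset_genes(self, keep: list[str]) -> "FeatureMatrix":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [idx[g] for g in keep]
        return FeatureMatrix(self.values[rows], list(keep), self.feature_ids, self.flavour)

    def subset_features(self, keep: list[str]) -> "FeatureMatrix":
        idx = {f: i for i, f in enumerate(self.feature_ids)}
        cols = [idx[f] for f in keep]
        return FeatureMatrix(self.values[:, cols], self.gene_ids, list(keep), self.flavour)


@dataclass
class ExpressionMatrix:
    """Genes x cells response matrix (TPM, or log2 scale after transform)."""

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    cell_labels: dict[str, str] | None = None
    scale: str = "tpm"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = list(self.gene_ids)
        self.cell_ids = list(self.cell_ids)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        n, k = self.values.shape
        if n != len(self.gene_ids) or k != len(self.cell_ids):
            raise ValueError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.gene_ids)} gene ids / {len(self.cell_ids)} cell ids"
            )
        if self.scale not in ("tpm", "log2"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.scale == "tpm" and np.any(self.values < 0):
            raise ValueError("negative entries on tpm scale")
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.cell_ids, "cell")
        if self.cell_labels is not None:
            missing = [c for c in self.cell_ids if c not in self.cell_labels]
            if missing:
                raise ValueError(f"cell_labels missing {len(missing)} cells (e.g. {missing[0]!r})")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        cell_labels: dict[str, str] | None = None,
        scale: str = "tpm",
    ) -> "ExpressionMatrix":
        return cls(
            values=df.to_numpy(dtype=float),
            gene_ids=[str(g) for g in df.index],
            cell_ids=[str(c) for c in df.columns],
            cell_labels=cell_labels,
            scale=scale,
        )

    def subset_genes(self, keep: list[str]) -> "ExpressionMatrix":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [idx[g] for g in keep]
        return ExpressionMatrix(
            self.values[rows], list(keep), self.cell_ids, self.cell_labels, self.scale
        )

    def subset_cells(self, keep: list[str]) -> "ExpressionMatrix":
        idx = {c: i for i, c in enumerate(self.cell_ids)}
        cols = [idx[c] for c in keep]
        labels = None
        if self.cell_labels is not None:
            labels = {c: self.cell_labels[c] for c in keep}
        return ExpressionMatrix(self.values[:, cols], self.gene_ids, list(keep), labels, self.scale)
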