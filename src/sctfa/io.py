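"""Readers and writers for the standard formats the pipeline consumes.

Conventions: all matrices are TSV with genes in rows (header row = column
ids, first column = row ids); genomic intervals are 0-based half-open (BED
native); trees are Newick with a sidecar TSV carrying node weights.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import Phylo, motifs as bio_motifs
from Bio.Phylo.BaseTree import Clade, Tree as PhyloTree
from scipy.io import mmread, mmwrite
from scipy.sparse import coo_matrix

from .containers import ExpressionMatrix, FeatureMatrix
from .features import GeneAnnotation, Peak, Pwm
from .models import FitResult
from .preprocess import FilterReport, SplitSpec
from .trees import TaskTree


def _read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise ValueError(f"{path}: duplicate row ids")
    if df.columns.has_duplicates:
        raise ValueError(f"{path}: duplicate column ids")
    bad = df.columns[df.dtypes == object]
    if len(bad):
        for col in bad:
            try:
                df[col] = pd.to_numeric(df[col])
            except (ValueError, TypeError) as exc:
                raise ValueError(f"{path}: non-numeric values in column {col!r}") from exc
    return df


# --------------------------------------------------------------------------
# expression / feature matrices


def read_expression(
    path: str | Path,
    cell_labels: dict[str, str] | None = None,
    scale: str = "tpm",
) -> ExpressionMatrix:
    return ExpressionMatrix.from_frame(_read_matrix_tsv(path), cell_labels, scale)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.to_frame().to_csv(path, sep="\t", index_label="gene_id")


def read_expression_mtx(
    mtx_path: str | Path,
    genes_path: str | Path,
    cells_path: str | Path,
    scale: str = "tpm",
) -> ExpressionMatrix:
    """Matrix-market triplet plus one-id-per-line row and column files."""
    values = np.asarray(mmread(mtx_path).todense(), dtype=float)
    gene_ids = Path(genes_path).read_text().split()
    cell_ids = Path(cells_path).read_text().split()
    return ExpressionMatrix(values, gene_ids, cell_ids, scale=scale)


def write_expression_mtx(
    expr: ExpressionMatrix,
    mtx_path: str | Path,
    genes_path: str | Path,
    cells_path: str | Path,
) -> None:
    mmwrite(str(mtx_path), coo_matrix(expr.values))
    Path(genes_path).write_text("\n".join(expr.gene_ids) + "\n")
    Path(cells_path).write_text("\n".join(expr.cell_ids) + "\n")


def read_feature_matrix(path: str | Path, flavour: str = "generic") -> FeatureMatrix:
    return FeatureMatrix.from_frame(_read_matrix_tsv(path), flavour)


def write_feature_matrix(features: FeatureMatrix, path: str | Path) -> None:
    features.to_frame().to_csv(path, sep="\t", index_label="gene_id")


# --------------------------------------------------------------------------
# annotations, peaks, motifs, genome


def read_annotation(path: str | Path) -> list[GeneAnnotation]:
    """BED6 gene annotation: TSS = start on '+', end - 1 on '-'."""
    genes: list[GeneAnnotation] = []
    seen: set[str] = set()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 6:
            raise ValueError(f"{path}:{lineno}: expected >= 6 BED columns")
        chrom, start, end, name, _score, strand = parts[:6]
        start_i, end_i = int(start), int(end)
        if end_i <= start_i:
            raise ValueError(f"{path}:{lineno}: end <= start")
        if name in seen:
            raise ValueError(f"{path}:{lineno}: duplicate gene id {name!r}")
        seen.add(name)
        tss = start_i if strand == "+" else end_i - 1
        genes.append(GeneAnnotation(name, chrom, tss, strand))
    return genes


def write_annotation(genes: list[GeneAnnotation], path: str | Path, width: int = 1) -> None:
    lines = []
    for g in genes:
        if g.strand == "+":
            start, end = g.tss, g.tss + width
        else:
            start, end = g.tss - width + 1, g.tss + 1
        lines.append(f"{g.chrom}\t{start}\t{end}\t{g.gene_id}\t0\t{g.strand}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_peaks(path: str | Path) -> list[Peak]:
    """BED or narrowPeak intervals; narrowPeak column 7 is the signal, BED
    score (column 5) is used as the integer count when present."""
    peaks: list[Peak] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
        chrom, start, end = parts[0], int(parts[1]), int(parts[2])
        if end <= start:
            raise ValueError(f"{path}:{lineno}: end <= start")
        signal: float | None = 0.0
        count = 0
        if len(parts) >= 7:  # narrowPeak: signalValue in column 7
            signal = float(parts[6])
        if len(parts) >= 5 and parts[4] not in (".", ""):
            count = int(float(parts[4]))
        peaks.append(Peak(chrom, start, end, signal=signal, count=count))
    return peaks


def write_peaks(peaks: list[Peak], path: str | Path) -> None:
    """narrowPeak-style output preserving signal (col 7) and count (score col 5)."""
    lines = []
    for i, p in enumerate(peaks):
        signal = 0.0 if p.signal is None else p.signal
        lines.append(
            f"{p.chrom}\t{p.start}\t{p.end}\tpeak{i}\t{p.count}\t.\t{signal}\t-1\t-1\t-1"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_pwms(path: str | Path, pseudocount: float = 0.01) -> list[Pwm]:
    """JASPAR-format PFM text file (possibly several motifs)."""
    with open(path) as handle:
        records = bio_motifs.parse(handle, "jaspar")
    pwms = []
    for record in records:
        counts = np.array([record.counts[b] for b in "ACGT"], dtype=float)
        name = record.name or record.matrix_id
        pwms.append(Pwm.from_counts(str(name), counts, pseudocount))
    return pwms


def write_pwms(pwms: list[Pwm], path: str | Path, scale: float = 100.0) -> None:
    """JASPAR PFM text; probabilities are written as pseudo-counts * scale."""
    blocks = []
    for pwm in pwms:
        rows = [f">{pwm.name}\t{pwm.name}"]
        for b, base in enumerate("ACGT"):
            vals = " ".join(f"{v * scale:.2f}" for v in pwm.probs[b])
            rows.append(f"{base}  [ {vals} ]")
        blocks.append("\n".join(rows))
    Path(path).write_text("\n".join(blocks) + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    from pyfaidx import Fasta

    with Fasta(str(path), as_raw=True, sequence_always_upper=True) as fa:
        return {name: str(fa[name][:]) for name in fa.keys()}


def write_fasta(genome: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# --------------------------------------------------------------------------
# trees


def write_tree(tree: TaskTree, newick_path: str | Path, sidecar_path: str | Path) -> None:
    """Newick topology (leaf labels = cell ids, internal labels = node ids)
    plus a sidecar TSV with node_id, weight, and the node's leaf ids."""

    def clade_of(v: int) -> Clade:
        if not tree.children[v]:
            return Clade(name=tree.cell_ids[v], branch_length=1.0)
        c = Clade(name=f"n{v}", branch_length=1.0)
        c.clades = [clade_of(ch) for ch in tree.children[v]]
        return c

    Phylo.write(PhyloTree(root=clade_of(tree.root), rooted=True), str(newick_path), "newick")
    rows = []
    for v in range(tree.n_nodes):
        leaf_ids = ",".join(tree.cell_ids[i] for i in tree.groups[v])
        rows.append({"node_id": v, "weight": tree.weights[v], "leaf_ids": leaf_ids})
    pd.DataFrame(rows).to_csv(sidecar_path, sep="\t", index=False)


def read_tree(newick_path: str | Path, sidecar_path: str | Path) -> TaskTree:
    sidecar = pd.read_csv(sidecar_path, sep="\t")
    leaf_node: dict[str, int] = {}
    for _, row in sidecar.iterrows():
        ids = str(row["leaf_ids"]).split(",")
        if len(ids) == 1:
            leaf_node.setdefault(ids[0], int(row["node_id"]))
    phylo = Phylo.read(str(newick_path), "newick")

    n_nodes = int(sidecar["node_id"].max()) + 1
    parents: list[int | None] = [None] * n_nodes
    cell_ids: list[str] = [""] * len(leaf_node)

    def node_id(clade: Clade) -> int:
        if clade.clades:
            name = clade.name or (str(clade.confidence) if clade.confidence is not None else None)
            if name is None or not str(name).startswith("n"):
                raise ValueError("internal node without an 'n<id>' label")
            return int(str(name)[1:])
        return leaf_node[clade.name]

    def walk(clade: Clade, parent: int | None) -> None:
        v = node_id(clade)
        parents[v] = parent
        if not clade.clades:
            cell_ids[v] = clade.name
        for child in clade.clades:
            walk(child, v)

    walk(phylo.root, None)
    tree = TaskTree(parents, cell_ids)
    tree.weights = {int(r["node_id"]): float(r["weight"]) for _, r in sidecar.iterrows()}
    return tree


# --------------------------------------------------------------------------
# reports, splits, fits, labels, coordinates


def write_filter_report(report: FilterReport, path: str | Path) -> None:
    genes = sorted(
        set(report.per_gene_variance) | set(report.detected_counts) | set(report.kept_genes)
    )
    kept = set(report.kept_genes)
    df = pd.DataFrame(
        {
            "gene_id": genes,
            "variance": [report.per_gene_variance.get(g, np.nan) for g in genes],
            "detected_cells": [report.detected_counts.get(g, np.nan) for g in genes],
            "kept": [g in kept for g in genes],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_split(split: SplitSpec, gene_ids: list[str], path: str | Path) -> None:
    rows = [(gene_ids[i], "train") for i in split.train_gene_indices]
    rows += [(gene_ids[i], "test") for i in split.test_gene_indices]
    pd.DataFrame(rows, columns=["gene_id", "partition"]).to_csv(path, sep="\t", index=False)


def read_labels(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", header=None, names=["cell_id", "label"], comment="#")
    if df["cell_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate cell ids")
    return dict(zip(df["cell_id"].astype(str), df["label"].astype(str)))


def write_labels(labels: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(sorted(labels.items())).to_csv(path, sep="\t", index=False, header=False)


def read_coords(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] != 2:
        raise ValueError(f"{path}: expected exactly 2 coordinate columns")
    return df


def write_fit(fit: FitResult, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    features = fit.feature_ids or [f"f{i}" for i in range(fit.B.shape[0])]
    cells = fit.cell_ids or [f"cell{j}" for j in range(fit.B.shape[1])]
    pd.DataFrame(fit.B, index=features, columns=cells).to_csv(
        out / "coefficients.tsv", sep="\t", index_label="feature_id"
    )
    meta = {
        "model_kind": fit.model_kind,
        "lambda": fit.lam,
        "alpha": fit.alpha,
        "n_iter": fit.n_iter,
        "converged": fit.converged,
        "seed": fit.split.seed if fit.split is not None else None,
    }
    (out / "fit.json").write_text(json.dumps(meta, indent=2) + "\n")
    pd.DataFrame(
        {"iteration": range(len(fit.objective_history)), "objective": fit.objective_history}
    ).to_csv(out / "convergence.tsv", sep="\t", index=False)


def read_fit_coefficients(fit_dir: str | Path) -> pd.DataFrame:
    return _read_matrix_tsv(Path(fit_dir) / "coefficients.tsv")
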