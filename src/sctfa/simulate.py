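"""Seeded synthetic fixtures with the statistical structure the models assume.

Three generators: a regression fixture (affinity-like features, planted
cluster-structured coefficients, Gaussian noise), a TPM expression fixture
with dropout and genes planted to fail the detected-gene rule, and a
genomic fixture (genome + motifs + annotations + peaks) for the feature
builders. Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import ExpressionMatrix, FeatureMatrix
from .features import GeneAnnotation, Peak, Pwm
from .trees import TaskTree

#: One place for the default fixture sizes used by tests and the CLI.
DEFAULTS = {
    "regression": dict(n=500, p=50, k=40, n_clusters=2, tfs_per_cluster=5,
                       effect_size=1.0, noise_sd=0.1),
    "tpm": dict(n=200, k=50, dropout_rate=0.2, n_fail_genes=20, detected_floor=0.2),
    "genomic": dict(n_genes=12, n_tfs=3, n_peaks=24, chrom_length=120_000),
}

_BASES = np.array(list("ACGT"))


@dataclass
class SyntheticTruth:
    """Ground truth planted into a regression fixture."""

    true_B: np.ndarray  # p x k
    cell_clusters: dict[str, str]
    active_tfs: dict[str, list[str]]
    noise_sd: float
    dropout_rate: float
    seed: int

    @property
    def active_rows(self) -> np.ndarray:
        return np.flatnonzero(np.any(self.true_B != 0, axis=1))


def _cluster_reference_tree(k: int, n_clusters: int, cell_ids: list[str]) -> TaskTree:
    # leaves 0..k-1, cluster nodes k..k+C-1, root k+C
    per = k // n_clusters
    parents: list[int | None] = [0] * (k + n_clusters + 1)
    for leaf in range(k):
        parents[leaf] = k + leaf // per
    for c in range(n_clusters):
        parents[k + c] = k + n_clusters
    parents[k + n_clusters] = None
    return TaskTree(parents, cell_ids)


def generate_regression_fixture(
    n: int = 500,
    p: int = 50,
    k: int = 40,
    n_clusters: int = 2,
    tfs_per_cluster: int = 5,
    effect_size: float = 1.0,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> tuple[FeatureMatrix, ExpressionMatrix, SyntheticTruth, TaskTree]:
    """Affinity-like X, planted block-sparse B, and Y = X B + Gaussian noise.

    Cells come in ``n_clusters`` contiguous, equally sized clusters; each
    cluster has ``tfs_per_cluster`` private active TF rows whose coefficients
    equal ``effect_size`` on that cluster's cells and 0 elsewhere.
    """
    if k % n_clusters != 0:
        raise ValueError("k must be divisible by n_clusters")
    if n_clusters * tfs_per_cluster > p:
        raise ValueError("more active TFs than features")
    import warnings

    if effect_size == 0:
        warnings.warn("effect_size 0: nothing planted to recover", stacklevel=2)
    rng = np.random.default_rng(seed)

    gene_ids = [f"g{i:04d}" for i in range(n)]
    cell_ids = [f"cell{j:03d}" for j in range(k)]
    tf_ids = [f"TF{i:03d}" for i in range(p)]
    per = k // n_clusters

    X = np.abs(rng.standard_normal((n, p)))  # folded normal: nonnegative, right-skewed
    B = np.zeros((p, k))
    clusters: dict[str, str] = {}
    active: dict[str, list[str]] = {}
    for c in range(n_clusters):
        cname = f"cluster{c}"
        cells = range(c * per, (c + 1) * per)
        for j in cells:
            clusters[cell_ids[j]] = cname
        rows = range(c * tfs_per_cluster, (c + 1) * tfs_per_cluster)
        active[cname] = [tf_ids[r] for r in rows]
        for r in rows:
            B[r, c * per : (c + 1) * per] = effect_size
    Y = X @ B + noise_sd * rng.standard_normal((n, k))

    features = FeatureMatrix(X, gene_ids, tf_ids, flavour="generic")
    expr = ExpressionMatrix(Y, gene_ids, cell_ids, cell_labels=clusters, scale="log2")
    truth = SyntheticTruth(
        true_B=B,
        cell_clusters=clusters,
        active_tfs=active,
        noise_sd=noise_sd,
        dropout_rate=0.0,
        seed=seed,
    )
    tree = _cluster_reference_tree(k, n_clusters, cell_ids)
    return features, expr, truth, tree


def generate_tpm_fixture(
    n: int = 200,
    k: int = 50,
    dropout_rate: float = 0.2,
    n_fail_genes: int = 20,
    detected_floor: float = 0.2,
    seed: int = 0,
) -> tuple[ExpressionMatrix, list[str]]:
    """Log-normal TPM with dropout; returns the matrix and the planted-fail gene ids.

    Planted-fail genes are expressed (>= 0.1) in exactly 9 cells so the
    detected-gene rule removes them; all other genes have 12 dropout-protected
    cells floored at ``detected_floor`` so they are guaranteed to pass.
    """
    if not 0.0 <= dropout_rate < 1.0:
        raise ValueError("dropout_rate must be in [0, 1)")
    if k < 12:
        raise ValueError("need at least 12 cells to guarantee passing genes")
    if n_fail_genes >= n:
        raise ValueError("n_fail_genes must be smaller than n")
    rng = np.random.default_rng(seed)
    gene_ids = [f"g{i:04d}" for i in range(n)]
    cell_ids = [f"cell{j:03d}" for j in range(k)]

    values = rng.lognormal(mean=1.0, sigma=1.0, size=(n, k))
    drop = rng.random((n, k)) < dropout_rate
    values[drop] = 0.0

    n_pass = n - n_fail_genes
    for i in range(n_pass):  # protect 12 cells per passing gene
        protected = rng.choice(k, size=12, replace=False)
        values[i, protected] = np.maximum(
            rng.lognormal(mean=1.0, sigma=1.0, size=12), detected_floor
        )
    fail_ids = gene_ids[n_pass:]
    for i in range(n_pass, n):
        row = np.zeros(k)
        on = rng.choice(k, size=9, replace=False)
        row[on] = 5.0
        values[i] = row
    expr = ExpressionMatrix(values, gene_ids, cell_ids, scale="tpm")
    return expr, fail_ids


@dataclass
class GenomicFixture:
    genome: dict[str, str]
    genes: list[GeneAnnotation]
    pwms: list[Pwm]
    peaks: list[Peak]  # open-chromatin style peaks with signal
    tf_peaks: dict[str, list[Peak]]  # ChIP style peaks with counts
    planted_motifs: dict[str, str] = field(default_factory=dict)  # gene -> pwm name
    peak_offsets: dict[str, list[int]] = field(default_factory=dict)  # gene -> offsets


def _random_pwm(name: str, length: int, rng: np.random.Generator) -> Pwm:
    # sharp motif: a planted consensus hit dominates the background baseline
    consensus = rng.integers(0, 4, size=length)
    counts = np.full((4, length), 2.0)
    counts[consensus, np.arange(length)] = 94.0
    return Pwm.from_counts(name, counts)


def generate_genomic_fixture(
    n_genes: int = 12,
    n_tfs: int = 3,
    n_peaks: int = 24,
    chrom_length: int = 120_000,
    seed: int = 0,
    gene_spacing: int = 8000,
    motif_length: int = 12,
) -> GenomicFixture:
    """Random genome with motif instances planted near half the TSSs.

    Genes are evenly spaced on one chromosome. Gene ``2i`` gets the exact
    consensus of motif ``i mod n_tfs`` written 100 bp downstream of its TSS;
    odd genes stay motif-free. Open-chromatin peaks of width 200 bp are
    centred at fixed offsets {0, +3000, -12000} from the first
    ``n_peaks // 3`` genes' TSSs.
    """
    min_len = (n_genes + 1) * gene_spacing
    if chrom_length < min_len:
        raise ValueError(f"chrom_length must be >= {min_len}")
    rng = np.random.default_rng(seed)
    seq = rng.choice(_BASES, size=chrom_length)

    pwms = [_random_pwm(f"TF{i:03d}", motif_length, rng) for i in range(n_tfs)]
    genes = [
        GeneAnnotation(f"g{i:04d}", "chr1", (i + 1) * gene_spacing, "+")
        for i in range(n_genes)
    ]

    planted: dict[str, str] = {}
    for i in range(0, n_genes, 2):
        pwm = pwms[(i // 2) % n_tfs]
        pos = genes[i].tss + 100
        seq[pos : pos + len(pwm)] = list(pwm.consensus())
        planted[genes[i].gene_id] = pwm.name
    genome = {"chr1": "".join(seq)}

    offsets = [0, 3000, -12000]
    peaks: list[Peak] = []
    peak_offsets: dict[str, list[int]] = {}
    for gi in range(max(1, n_peaks // len(offsets))):
        gene = genes[gi % n_genes]
        for off in offsets:
            center = gene.tss + off
            start = max(0, center - 100)
            peaks.append(
                Peak("chr1", start, start + 200,
                     signal=float(np.round(rng.uniform(1, 10), 3)))
            )
            peak_offsets.setdefault(gene.gene_id, []).append(off)
            if len(peaks) >= n_peaks:
                break
        if len(peaks) >= n_peaks:
            break

    tf_peaks: dict[str, list[Peak]] = {}
    for t, pwm in enumerate(pwms):
        plist = []
        for gi in range(t, n_genes, n_tfs):
            center = genes[gi].tss + int(rng.integers(-1000, 1000))
            start = max(0, center - 150)
            plist.append(
                Peak("chr1", start, start + 300, signal=None,
                     count=int(rng.integers(1, 50)))
            )
        tf_peaks[pwm.name] = plist

    return GenomicFixture(
        genome=genome,
        genes=genes,
        pwms=pwms,
        peaks=peaks,
        tf_peaks=tf_peaks,
        planted_motifs=planted,
        peak_offsets=peak_offsets,
    )
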