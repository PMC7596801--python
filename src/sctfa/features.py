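"""Gene x TF feature matrices from sequence, motif, peak, and annotation inputs.

Three flavours are produced:

* ``static``  — biophysical motif-binding affinities in a 2-kb promoter window,
* ``dynamic`` — affinities inside open-chromatin peaks in a 50-kb window, decayed
  by distance to the TSS, plus three per-gene peak summary columns,
* ``chipseq`` — per-TF read counts of peaks overlapping a 3-kb promoter window.

All genomic intervals use 0-based half-open semantics.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .containers import DYNAMIC_EXTRA_COLUMNS, FeatureMatrix

logger = logging.getLogger(__name__)

#: Mismatch-energy scale of the biophysical binding model.
DEFAULT_LAMBDA_TRAP = 0.7
#: ln R0 = LN_R0_SLOPE * motif_length + LN_R0_INTERCEPT
LN_R0_SLOPE = 0.584
LN_R0_INTERCEPT = -5.66
#: Exponential-decay constant (bp) for distance weighting of peak affinities.
DEFAULT_DECAY_D0 = 5000.0
DEFAULT_PSEUDOCOUNT = 0.01

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene anchored at its transcription start site (0-based)."""

    gene_id: str
    chrom: str
    tss: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError(f"gene {self.gene_id}: tss must be >= 0")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")


@dataclass(frozen=True)
class Peak:
    """0-based half-open genomic interval with optional signal and read count."""

    chrom: str
    start: int
    end: int
    signal: float | None = 0.0
    count: int = 0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"peak {self.chrom}:{self.start}-{self.end}: start must be < end")
        if self.signal is not None and self.signal < 0:
            raise ValueError("peak signal must be nonnegative")
        if self.count < 0:
            raise ValueError("peak count must be nonnegative")

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    @property
    def length(self) -> int:
        return self.end - self.start


class Pwm:
    """Column-normalized position weight matrix over the DNA alphabet.

    ``probs`` has shape (4, L) with rows in A, C, G, T order; every column
    sums to 1. Constructed from raw count/frequency matrices with a
    per-cell pseudocount so no probability is exactly zero.
    """

    def __init__(self, name: str, probs: np.ndarray):
        probs = np.asarray(probs, dtype=float)
        if probs.ndim != 2 or probs.shape[0] != 4 or probs.shape[1] < 1:
            raise ValueError("probs must have shape (4, L) with L >= 1")
        if np.any(probs <= 0):
            raise ValueError("probabilities must be strictly positive (use a pseudocount)")
        colsums = probs.sum(axis=0)
        if np.any(np.abs(colsums - 1.0) > 1e-9):
            raise ValueError("every column must sum to 1 +/- 1e-9")
        self.name = name
        self.probs = probs

    def __len__(self) -> int:
        return self.probs.shape[1]

    def __repr__(self) -> str:
        return f"Pwm({self.name!r}, L={len(self)})"

    @classmethod
    def from_counts(
        cls, name: str, counts: np.ndarray, pseudocount: float = DEFAULT_PSEUDOCOUNT
    ) -> "Pwm":
        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 2 or counts.shape[0] != 4:
            raise ValueError("counts must have shape (4, L)")
        if np.any(counts < 0):
            raise ValueError("counts must be nonnegative")
        if pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        padded = counts + pseudocount
        return cls(name, padded / padded.sum(axis=0, keepdims=True))

    def consensus(self) -> str:
        bases = "ACGT"
        return "".join(bases[i] for i in np.argmax(self.probs, axis=0))

    def log_mismatch(self) -> np.ndarray:
        """Per-base mismatch energies ln(p_max / p_base), shape (4, L).

        Zero at each column's preferred base, positive elsewhere; the energy
        of a window is the sum over its positions.
        """
        logp = np.log(self.probs)
        return logp.max(axis=0, keepdims=True) - logp

    def ln_r0(self) -> float:
        return LN_R0_SLOPE * len(self) + LN_R0_INTERCEPT


def encode_sequence(sequence: str) -> np.ndarray:
    """Map a DNA string to int codes (A=0, C=1, G=2, T=3, anything else -1)."""
    table = np.full(256, -1, dtype=np.int8)
    for base, code in _BASE_INDEX.items():
        table[ord(base)] = code
        table[ord(base.lower())] = code
    return table[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)].astype(np.int64)


def _window_energies(codes: np.ndarray, lmis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Energies of all windows of width L and a validity mask (no N inside)."""
    L = lmis.shape[1]
    windows = sliding_window_view(codes, L)
    valid = (windows >= 0).all(axis=1)
    safe = np.where(windows >= 0, windows, 0)
    energies = lmis[safe, np.arange(L)].sum(axis=1)
    return energies, valid


def trap_affinity(
    sequence: str,
    pwm: Pwm,
    lambda_trap: float = DEFAULT_LAMBDA_TRAP,
    ln_r0: float | None = None,
) -> float:
    """Aggregate binding affinity of a motif over a sequence window.

    Sums, over every motif-width window on both strands, the occupancy
    probability ``1 / (1 + exp(E_w / lambda - ln R0))`` where ``E_w`` is the
    window's mismatch energy relative to the motif's best match. Windows
    containing an ambiguous base contribute 0.
    """
    if len(sequence) == 0:
        raise ValueError("empty sequence")
    L = len(pwm)
    if len(sequence) < L:
        warnings.warn(
            f"sequence shorter than motif {pwm.name} ({len(sequence)} < {L}); affinity 0",
            stacklevel=2,
        )
        return 0.0
    if lambda_trap <= 0:
        raise ValueError("lambda_trap must be positive")
    if ln_r0 is None:
        ln_r0 = pwm.ln_r0()

    codes = encode_sequence(sequence)
    lmis = pwm.log_mismatch()
    total = 0.0
    # reversing both axes of the mismatch matrix scores the reverse strand:
    # the base axis A,C,G,T reverses to its complement T,G,C,A.
    for mat in (lmis, lmis[::-1, ::-1]):
        energies, valid = _window_energies(codes, mat)
        if valid.any():
            z = energies[valid] / lambda_trap - ln_r0
            total += float(np.sum(1.0 / (1.0 + np.exp(z))))
    return total


def decay_weight(distance: float, d0: float = DEFAULT_DECAY_D0) -> float:
    """Exponential distance decay ``exp(-distance / d0)`` in (0, 1]."""
    if distance < 0:
        raise ValueError("distance must be nonnegative")
    if d0 <= 0:
        raise ValueError("d0 must be positive")
    return float(np.exp(-distance / d0))


def _chrom_sequence(genome, chrom: str) -> str | None:
    """Fetch a full chromosome as an uppercase string from a dict or FASTA handle."""
    try:
        record = genome[chrom]
    except KeyError:
        return None
    if isinstance(record, str):
        return record.upper()
    return str(record[:]).upper()  # pyfaidx FastaRecord


def _gene_window(gene: GeneAnnotation, half_window: int, chrom_len: int) -> tuple[int, int]:
    return max(0, gene.tss - half_window), min(chrom_len, gene.tss + half_window)


def build_static_features(
    genes: Sequence[GeneAnnotation],
    genome: Mapping[str, str],
    pwms: Sequence[Pwm],
    half_window: int = 1000,
    lambda_trap: float = DEFAULT_LAMBDA_TRAP,
) -> FeatureMatrix:
    """Motif affinities in the ``[tss - half_window, tss + half_window)`` promoter window."""
    if len(pwms) == 0:
        raise ValueError("at least one PWM is required")
    rows: list[np.ndarray] = []
    kept: list[str] = []
    for gene in genes:
        seq = _chrom_sequence(genome, gene.chrom)
        if seq is None:
            logger.warning("gene %s: chromosome %s missing from genome; row dropped",
                           gene.gene_id, gene.chrom)
            continue
        start, end = _gene_window(gene, half_window, len(seq))
        window = seq[start:end]
        row = np.array(
            [trap_affinity(window, pwm, lambda_trap=lambda_trap) if len(window) >= len(pwm)
             else 0.0
             for pwm in pwms]
        )
        rows.append(row)
        kept.append(gene.gene_id)
    values = np.vstack(rows) if rows else np.empty((0, len(pwms)))
    return FeatureMatrix(values, kept, [p.name for p in pwms], flavour="static")


def _overlaps(peak: Peak, wstart: int, wend: int) -> bool:
    return peak.start < wend and peak.end > wstart


def build_dynamic_features(
    genes: Sequence[GeneAnnotation],
    genome: Mapping[str, str],
    pwms: Sequence[Pwm],
    peaks: Sequence[Peak],
    half_window: int = 25000,
    d0: float = DEFAULT_DECAY_D0,
    lambda_trap: float = DEFAULT_LAMBDA_TRAP,
) -> FeatureMatrix:
    """Distance-decayed motif affinities within open-chromatin peaks near the TSS.

    Affinities are computed on the full peak sequence even when the peak only
    partially overlaps the window; ``Peak_Length`` counts only the overlapping
    base pairs. ``Peak_Signal`` sums the full peak signal.
    """
    if len(pwms) == 0:
        raise ValueError("at least one PWM is required")
    if len(peaks) == 0:
        warnings.warn("no peaks supplied; all TF columns will be zero", stacklevel=2)

    # affinity of every peak for every motif, computed once
    peak_aff = np.zeros((len(peaks), len(pwms)))
    for i, peak in enumerate(peaks):
        seq = _chrom_sequence(genome, peak.chrom)
        if seq is None:
            logger.warning("peak on missing chromosome %s ignored", peak.chrom)
            continue
        pseq = seq[peak.start:peak.end]
        for j, pwm in enumerate(pwms):
            if len(pseq) >= len(pwm):
                peak_aff[i, j] = trap_affinity(pseq, pwm, lambda_trap=lambda_trap)

    by_chrom: dict[str, list[int]] = {}
    for i, peak in enumerate(peaks):
        by_chrom.setdefault(peak.chrom, []).append(i)

    feature_ids = [p.name for p in pwms] + list(DYNAMIC_EXTRA_COLUMNS)
    rows: list[np.ndarray] = []
    kept: list[str] = []
    for gene in genes:
        seq = _chrom_sequence(genome, gene.chrom)
        if seq is None:
            logger.warning("gene %s: chromosome %s missing from genome; row dropped",
                           gene.gene_id, gene.chrom)
            continue
        wstart, wend = _gene_window(gene, half_window, len(seq))
        tf_sum = np.zeros(len(pwms))
        n_overlap = 0
        length_sum = 0
        signal_sum = 0.0
        for i in by_chrom.get(gene.chrom, []):
            peak = peaks[i]
            if not _overlaps(peak, wstart, wend):
                continue
            n_overlap += 1
            length_sum += min(peak.end, wend) - max(peak.start, wstart)
            if peak.signal is None:
                raise ValueError(
                    f"peak {peak.chrom}:{peak.start}-{peak.end} lacks a signal value "
                    "required for Peak_Signal"
                )
            signal_sum += peak.signal
            w = decay_weight(abs(gene.tss - peak.center), d0)
            tf_sum += w * peak_aff[i]
        rows.append(np.concatenate([tf_sum, [n_overlap, length_sum, signal_sum]]))
        kept.append(gene.gene_id)
    values = np.vstack(rows) if rows else np.empty((0, len(feature_ids)))
    return FeatureMatrix(values, kept, feature_ids, flavour="dynamic")


def build_chipseq_features(
    genes: Sequence[GeneAnnotation],
    tf_peaks: Mapping[str, Iterable[Peak]],
    half_window: int = 1500,
) -> FeatureMatrix:
    """Summed per-TF peak read counts in the ``[tss - half, tss + half)`` window."""
    tf_names = list(tf_peaks)
    if not tf_names:
        raise ValueError("at least one TF peak set is required")
    peak_lists = {tf: list(plist) for tf, plist in tf_peaks.items()}
    for tf, plist in peak_lists.items():
        if not plist:
            warnings.warn(f"TF {tf} has no peaks; its column will be zero", stacklevel=2)

    values = np.zeros((len(genes), len(tf_names)))
    for g, gene in enumerate(genes):
        wstart = max(0, gene.tss - half_window)
        wend = gene.tss + half_window
        for t, tf in enumerate(tf_names):
            total = 0
            for peak in peak_lists[tf]:
                if peak.chrom == gene.chrom and _overlaps(peak, wstart, wend):
                    total += peak.count
            values[g, t] = total
    return FeatureMatrix(values, [g.gene_id for g in genes], tf_names, flavour="chipseq")
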