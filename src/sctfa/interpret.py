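"""TF-level interpretation of a fitted coefficient matrix.

Turns the features x cells coefficient matrix into per-TF summaries:
heat-map selection by summed absolute coefficients, activity ranking,
differential activity between two cell types, Spearman correlation between
a TF's own expression and its inferred per-cell activity, and the
permutation-null and sign-agreement filters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

HEATMAP_THRESHOLD = 0.5
DIFF_SIGNIFICANCE = 0.1
TOP_K = 20


@dataclass
class ActivityReport:
    """Per-TF derived quantities assembled by :func:`build_activity_report`."""

    tf_ids: list[str]
    summed_abs_coef: np.ndarray
    activity: np.ndarray
    tf_expr_cor: np.ndarray | None = None
    null_interval: tuple[float, float] | None = None
    diff_p_raw: np.ndarray | None = None
    diff_p_adj: np.ndarray | None = None
    flags: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"summed_abs_coef": self.summed_abs_coef, "activity": self.activity},
            index=self.tf_ids,
        )
        if self.tf_expr_cor is not None:
            df["tf_expr_cor"] = self.tf_expr_cor
        if self.diff_p_raw is not None:
            df["diff_p_raw"] = self.diff_p_raw
            df["diff_p_adj"] = self.diff_p_adj
        if self.flags is not None:
            df = df.join(self.flags)
        return df


def select_heatmap_tfs(
    B: pd.DataFrame, threshold: float = HEATMAP_THRESHOLD
) -> list[str]:
    """TFs whose summed absolute coefficient across cells strictly exceeds the threshold."""
    sums = B.abs().sum(axis=1)
    return [tf for tf, s in sums.items() if s > threshold]


def scale_coefficients(B: pd.DataFrame, scaling: str = "maxabs") -> pd.DataFrame:
    """Per-cell column scaling applied before activity summation.

    ``maxabs`` divides each cell's column by its maximum absolute value (all-zero
    columns untouched); ``zscore`` standardizes each column; ``none`` is identity.
    """
    if scaling == "none":
        return B
    if scaling == "maxabs":
        denom = B.abs().max(axis=0).replace(0.0, 1.0)
        return B / denom
    if scaling == "zscore":
        sd = B.std(axis=0, ddof=1).replace(0.0, 1.0)
        return (B - B.mean(axis=0)) / sd
    raise ValueError(f"unknown scaling {scaling!r}")


def rank_tf_activity(B: pd.DataFrame, scaling: str = "maxabs") -> pd.Series:
    """Summed scaled coefficients per TF, sorted descending (ties break by TF id)."""
    activity = scale_coefficients(B, scaling).sum(axis=1)
    order = sorted(activity.index, key=lambda tf: (-activity[tf], tf))
    return activity.loc[order]


def top_k(ranked: pd.Series, k: int = TOP_K) -> list[str]:
    if len(ranked) > k and ranked.iloc[k - 1] == ranked.iloc[k]:
        logger.info("tie at rank %d broken deterministically by TF id", k)
    return list(ranked.index[:k])


def differential_activity(
    B: pd.DataFrame,
    cell_labels: dict[str, str],
    significance: float = DIFF_SIGNIFICANCE,
) -> pd.DataFrame:
    """Two-sided Mann-Whitney per TF between the two cell types, BH-adjusted.

    Returns a frame with U statistic, raw and adjusted p-values, and a
    significance flag at the given adjusted-p cutoff.
    """
    types = sorted(set(cell_labels.values()))
    if len(types) != 2:
        raise ValueError(f"exactly 2 cell types required, got {types}")
    group_a = [c for c in B.columns if cell_labels[c] == types[0]]
    group_b = [c for c in B.columns if cell_labels[c] == types[1]]
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each cell type needs at least 2 cells")

    stats_u = np.empty(len(B.index))
    p_raw = np.empty(len(B.index))
    for i, tf in enumerate(B.index):
        a = B.loc[tf, group_a].to_numpy(dtype=float)
        b = B.loc[tf, group_b].to_numpy(dtype=float)
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        stats_u[i] = res.statistic
        p_raw[i] = res.pvalue
    _, p_adj, _, _ = multipletests(p_raw, method="fdr_bh")
    return pd.DataFrame(
        {
            "U": stats_u,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "significant": p_adj <= significance,
        },
        index=B.index,
    )


def tf_expr_cor(B: pd.DataFrame, tf_expression: pd.DataFrame) -> pd.Series:
    """Spearman correlation, across cells, of each TF's expression with its coefficients.

    ``tf_expression`` holds log2 TPM values, TFs x cells, aligned to ``B``'s
    columns. Constant coefficient rows (or expression rows) give NaN.
    """
    if B.shape[1] < 3:
        raise ValueError("need at least 3 cells")
    expr = tf_expression.loc[:, B.columns]
    out = pd.Series(np.nan, index=B.index, dtype=float)
    for tf in B.index:
        if tf not in expr.index:
            continue
        coefs = B.loc[tf].to_numpy(dtype=float)
        e = expr.loc[tf].to_numpy(dtype=float)
        if np.all(coefs == coefs[0]) or np.all(e == e[0]):
            continue
        rho, _ = stats.spearmanr(e, coefs)
        out[tf] = rho
    return out


def permutation_null_filter(
    rho_real: pd.Series, rho_null: pd.Series
) -> tuple[list[str], tuple[float, float]]:
    """Keep TFs whose correlation falls outside the pooled null range.

    The null interval is [min, max] of the correlations obtained from the
    shuffled-expression model; values inside (inclusive) are removed.
    """
    null_values = rho_null.dropna()
    if null_values.empty:
        raise ValueError("empty null correlation set")
    lo, hi = float(null_values.min()), float(null_values.max())
    kept = [
        tf
        for tf, rho in rho_real.items()
        if np.isfinite(rho) and not (lo <= rho <= hi)
    ]
    return kept, (lo, hi)


def sign_agreement_filter(
    rho: pd.Series, coef_sums: pd.Series
) -> list[str]:
    """Keep TFs where the correlation sign agrees with the coefficient-sum sign.

    A TF survives iff sign(rho) * sign(sum of coefficients) > 0; zero in
    either quantity discards.
    """
    kept = []
    for tf in rho.index:
        r = rho.get(tf, np.nan)
        s = coef_sums.get(tf, np.nan)
        if np.isfinite(r) and np.isfinite(s) and np.sign(r) * np.sign(s) > 0:
            kept.append(tf)
    return kept


def build_activity_report(
    B: pd.DataFrame,
    cell_labels: dict[str, str] | None = None,
    tf_expression: pd.DataFrame | None = None,
    rho_null: pd.Series | None = None,
    scaling: str = "maxabs",
    heatmap_threshold: float = HEATMAP_THRESHOLD,
    significance: float = DIFF_SIGNIFICANCE,
) -> ActivityReport:
    """Assemble all per-TF summaries available from the provided inputs."""
    tf_ids = list(B.index)
    summed_abs = B.abs().sum(axis=1)
    ranked = rank_tf_activity(B, scaling)
    activity = ranked.reindex(tf_ids)
    heat = set(select_heatmap_tfs(B, heatmap_threshold))
    top = set(top_k(ranked))

    flags = pd.DataFrame(
        {
            "heatmap_selected": [tf in heat for tf in tf_ids],
            "in_top20": [tf in top for tf in tf_ids],
        },
        index=tf_ids,
    )
    report = ActivityReport(
        tf_ids=tf_ids,
        summed_abs_coef=summed_abs.to_numpy(),
        activity=activity.to_numpy(),
        flags=flags,
    )
    if cell_labels is not None:
        diff = differential_activity(B, cell_labels, significance)
        report.diff_p_raw = diff["p_raw"].to_numpy()
        report.diff_p_adj = diff["p_adj"].to_numpy()
        flags["diff_significant"] = diff["significant"].to_numpy()
    if tf_expression is not None:
        rho = tf_expr_cor(B, tf_expression)
        report.tf_expr_cor = rho.to_numpy()
        coef_sums = B.sum(axis=1)
        agree = set(sign_agreement_filter(rho, coef_sums))
        flags["sign_agrees"] = [tf in agree for tf in tf_ids]
        if rho_null is not None:
            kept, interval = permutation_null_filter(rho, rho_null)
            report.null_interval = interval
            flags["outside_null"] = [tf in set(kept) for tf in tf_ids]
    report.flags = flags
    return report
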