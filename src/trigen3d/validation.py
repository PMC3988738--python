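"""Correlation-based validation of triclusters and tidy view exports.

A tricluster with #G genes, #C conditions and #T times defines #C * #T
gene-expression series, one per (condition, time) combination, each of
length #G.  The validation summarises how coherent a solution is by the
mean pairwise Pearson (or Spearman) correlation over all unordered pairs
of these series — a perfectly additive tricluster scores 1.0, while a
solution mixing positively and negatively correlated gene groups averages
out near zero even though it is perfectly homogeneous under the 3-D
residue (the residue, unlike plain correlation, embraces sign-flipped
patterns).

Three tidy "view" tables mirror the standard graphical representations:
sample curves (per time: gene x condition), time curves (per condition:
gene x time) and gene curves (per condition: time x gene).
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import ExpressionTensor3D, Tricluster, validate_tricluster

__all__ = [
    "extract_series",
    "correlation_summary",
    "correlation_table",
    "extract_views",
]


def extract_series(tensor: ExpressionTensor3D, tc: Tricluster
                   ) -> dict[tuple[str, str], np.ndarray]:
    """One gene-expression vector per (condition, time) pair of ``tc``.

    Keys are (condition label, time label); each vector lists the #G
    expression values in the tricluster's gene order.  Requires #G >= 2
    (correlations over shorter series are undefined).
    """
    verdict = validate_tricluster(tc, tensor)
    if not verdict:
        raise ValueError(f"invalid tricluster: {verdict.reason}")
    if len(tc.genes) < 2:
        raise ValueError("at least 2 genes are required to form "
                         "correlatable series")
    sub = tensor.subtensor(tc)
    out: dict[tuple[str, str], np.ndarray] = {}
    for ci, c in enumerate(tc.conditions):
        for ti, t in enumerate(tc.times):
            key = (tensor.condition_labels[c], tensor.time_labels[t])
            out[key] = sub[:, ci, ti].copy()
    return out


def _pairwise_mean_correlation(series: np.ndarray, method: str) -> float:
    """Mean correlation over all unordered pairs of rows of ``series``.

    Zero-variance rows yield undefined coefficients; any pair involving one
    contributes 0 (with a warning), so a defined mean is always returned.
    """
    if method == "spearman":
        series = np.apply_along_axis(stats.rankdata, 1, series)
    elif method != "pearson":
        raise ValueError("method must be 'pearson' or 'spearman'")
    n = series.shape[0]
    sd = series.std(axis=1)
    constant = sd == 0.0
    if constant.any():
        warnings.warn("constant series encountered; their pairwise "
                      "correlations are undefined and counted as 0",
                      RuntimeWarning, stacklevel=3)
    centered = series - series.mean(axis=1, keepdims=True)
    denom = np.where(constant, 1.0, sd * np.sqrt(series.shape[1]))
    z = centered / denom[:, None]
    corr = z @ z.T
    corr[constant, :] = 0.0
    corr[:, constant] = 0.0
    iu = np.triu_indices(n, k=1)
    return float(np.clip(corr[iu], -1.0, 1.0).mean())


def correlation_summary(tensor: ExpressionTensor3D, tc: Tricluster,
                        method: str = "pearson") -> float:
    """Mean pairwise correlation of a tricluster's condition-time series.

    Computes the chosen coefficient for every unordered pair of the
    #C * #T series and returns the unweighted arithmetic mean, in [-1, 1].
    """
    series = extract_series(tensor, tc)
    if len(series) < 2:
        raise ValueError("at least 2 condition-time series are required")
    mat = np.vstack(list(series.values()))
    return _pairwise_mean_correlation(mat, method)


def correlation_table(tensor: ExpressionTensor3D,
                      solutions: Iterable[Tricluster],
                      methods: Sequence[str] = ("pearson", "spearman"),
                      ) -> pd.DataFrame:
    """One row per solution with its averaged correlation coefficients.

    Values are rounded to 2 decimals for display, one column per method;
    the row index is the 1-based solution number.
    """
    rows = []
    for i, tc in enumerate(solutions, start=1):
        row = {"TC_sol": i}
        for m in methods:
            row[m] = round(correlation_summary(tensor, tc, m), 2)
        rows.append(row)
    return pd.DataFrame(rows, columns=["TC_sol", *methods])


def extract_views(tensor: ExpressionTensor3D, tc: Tricluster
                  ) -> dict[str, pd.DataFrame]:
    """Tidy tables behind the three standard tricluster plots.

    - ``sample_curves``: one graph per time; rows (time, gene, condition,
      value) with genes on the x-axis and one line per condition.
    - ``time_curves``: one graph per condition; rows (condition, gene,
      time, value) with genes on the x-axis and one line per time.
    - ``gene_curves``: one graph per condition; rows (condition, time,
      gene, value) with times on the x-axis and one line per gene.
    """
    verdict = validate_tricluster(tc, tensor)
    if not verdict:
        raise ValueError(f"invalid tricluster: {verdict.reason}")
    sub = tensor.subtensor(tc)
    g_lab = [tensor.gene_labels[i] for i in tc.genes]
    c_lab = [tensor.condition_labels[i] for i in tc.conditions]
    t_lab = [tensor.time_labels[i] for i in tc.times]

    sample_rows, time_rows, gene_rows = [], [], []
    for ti, t in enumerate(t_lab):
        for gi, g in enumerate(g_lab):
            for ci, c in enumerate(c_lab):
                sample_rows.append((t, g, c, sub[gi, ci, ti]))
    for ci, c in enumerate(c_lab):
        for gi, g in enumerate(g_lab):
            for ti, t in enumerate(t_lab):
                time_rows.append((c, g, t, sub[gi, ci, ti]))
    for ci, c in enumerate(c_lab):
        for ti, t in enumerate(t_lab):
            for gi, g in enumerate(g_lab):
                gene_rows.append((c, t, g, sub[gi, ci, ti]))
    return {
        "sample_curves": pd.DataFrame(
            sample_rows, columns=["time", "gene", "condition", "value"]),
        "time_curves": pd.DataFrame(
            time_rows, columns=["condition", "gene", "time", "value"]),
        "gene_curves": pd.DataFrame(
            gene_rows, columns=["condition", "time", "gene", "value"]),
    }
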