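"""Mean-squared-residue homogeneity scores for biclusters and triclusters.

The 2-D score is the classic Cheng & Church mean squared residue: the mean,
over a bicluster's cells, of the squared deviation of each cell from the
additive (row effect + column effect) structure implied by the cluster's
marginal means,

    r_gc = v(g,c) - M_G(c) - M_C(g) + M_GC,

which is zero exactly when the bicluster is "coherent" (each row is a
constant shift of every other row).

The 3-D extension scores a tricluster (genes x conditions x times) by the
mean squared *three-way interaction* residual

    r_gct = v + M_CT(g) + M_GT(c) + M_GC(t)
              - M_G(c,t) - M_C(g,t) - M_T(g,c) - M_GCT,

where M_X(..) denotes the marginal mean over the omitted axes within the
tricluster.  The score is zero for any values of the form
f(g,c) + h(g,t) + k(c,t) — in particular for constant, fully additive and
sign-flipped (negatively correlated) gene patterns — and grows with the
genuine three-way interaction left after removing all pairwise structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import (Bicluster, ExpressionTensor3D, Tricluster,
                         validate_tricluster)

__all__ = [
    "MarginalMeans2D",
    "MarginalMeans3D",
    "marginal_means_2d",
    "marginal_means_3d",
    "residue_2d",
    "residue_3d",
    "msr2d",
    "msr3d",
    "msr3d_from_array",
]


@dataclass(frozen=True)
class MarginalMeans3D:
    """All marginal means of a tricluster's cells.

    One-index means (``m_ct_of_g`` is the mean over conditions and times for
    each gene, etc.), two-index means (``m_g_of_ct`` is the mean over genes
    for each fixed (condition, time) pair, etc.) and the grand mean
    ``m_gct``.  Arrays are ordered like the tricluster's index sequences.
    """

    m_ct_of_g: np.ndarray   # per gene
    m_gt_of_c: np.ndarray   # per condition
    m_gc_of_t: np.ndarray   # per time
    m_g_of_ct: np.ndarray   # (condition, time)
    m_c_of_gt: np.ndarray   # (gene, time)
    m_t_of_gc: np.ndarray   # (gene, condition)
    m_gct: float


@dataclass(frozen=True)
class MarginalMeans2D:
    m_g_of_c: np.ndarray    # per condition (mean over genes)
    m_c_of_g: np.ndarray    # per gene (mean over conditions)
    m_gc: float


def _require_valid(tensor: ExpressionTensor3D, tc: Tricluster) -> None:
    verdict = validate_tricluster(tc, tensor)
    if not verdict:
        raise ValueError(f"invalid tricluster: {verdict.reason}")


def marginal_means_3d(tensor: ExpressionTensor3D,
                      tc: Tricluster) -> MarginalMeans3D:
    """Compute every marginal mean of the cells selected by ``tc``."""
    _require_valid(tensor, tc)
    sub = tensor.subtensor(tc)
    return MarginalMeans3D(
        m_ct_of_g=sub.mean(axis=(1, 2)),
        m_gt_of_c=sub.mean(axis=(0, 2)),
        m_gc_of_t=sub.mean(axis=(0, 1)),
        m_g_of_ct=sub.mean(axis=0),
        m_c_of_gt=sub.mean(axis=1),
        m_t_of_gc=sub.mean(axis=2),
        m_gct=float(sub.mean()),
    )


def _interaction_residuals(sub: np.ndarray) -> np.ndarray:
    """Three-way interaction residual tensor of a dense (g, c, t) block."""
    m_ct_of_g = sub.mean(axis=(1, 2), keepdims=True)
    m_gt_of_c = sub.mean(axis=(0, 2), keepdims=True)
    m_gc_of_t = sub.mean(axis=(0, 1), keepdims=True)
    m_g_of_ct = sub.mean(axis=0, keepdims=True)
    m_c_of_gt = sub.mean(axis=1, keepdims=True)
    m_t_of_gc = sub.mean(axis=2, keepdims=True)
    grand = sub.mean()
    return (sub + m_ct_of_g + m_gt_of_c + m_gc_of_t
            - m_g_of_ct - m_c_of_gt - m_t_of_gc - grand)


def residue_3d(tensor: ExpressionTensor3D, tc: Tricluster,
               g: int, c: int, t: int) -> float:
    """Signed interaction residual of one cell of a tricluster.

    ``(g, c, t)`` are tensor-level indices and must belong to ``tc``.
    """
    _require_valid(tensor, tc)
    gi = np.searchsorted(tc.genes, g)
    ci = np.searchsorted(tc.conditions, c)
    ti = np.searchsorted(tc.times, t)
    if (gi >= len(tc.genes) or tc.genes[gi] != g
            or ci >= len(tc.conditions) or tc.conditions[ci] != c
            or ti >= len(tc.times) or tc.times[ti] != t):
        raise ValueError(f"cell ({g}, {c}, {t}) is not in the tricluster")
    sub = tensor.subtensor(tc)
    return float(_interaction_residuals(sub)[gi, ci, ti])


def msr3d(tensor: ExpressionTensor3D, tc: Tricluster) -> float:
    """Mean squared 3-D residue of a tricluster; >= 0, 0 iff coherent."""
    _require_valid(tensor, tc)
    return msr3d_from_array(tensor.subtensor(tc))


def msr3d_from_array(sub: np.ndarray) -> float:
    """MSR of a dense (genes x conditions x times) block of values.

    Low-level entry point used by the search loop, which extracts blocks
    itself; ``sub`` must be a 3-D float array.
    """
    r = _interaction_residuals(sub)
    return float(np.mean(r * r))


def marginal_means_2d(matrix: np.ndarray, bc: Bicluster) -> MarginalMeans2D:
    matrix = np.asarray(matrix, dtype=float)
    sub = matrix[np.ix_(bc.genes, bc.conditions)]
    return MarginalMeans2D(
        m_g_of_c=sub.mean(axis=0),
        m_c_of_g=sub.mean(axis=1),
        m_gc=float(sub.mean()),
    )


def residue_2d(matrix: np.ndarray, bc: Bicluster, g: int, c: int) -> float:
    """Cheng–Church residue of one cell: v - M_G(c) - M_C(g) + M_GC."""
    matrix = np.asarray(matrix, dtype=float)
    gi = np.searchsorted(bc.genes, g)
    ci = np.searchsorted(bc.conditions, c)
    if (gi >= len(bc.genes) or bc.genes[gi] != g
            or ci >= len(bc.conditions) or bc.conditions[ci] != c):
        raise ValueError(f"cell ({g}, {c}) is not in the bicluster")
    sub = matrix[np.ix_(bc.genes, bc.conditions)]
    return float(sub[gi, ci] - sub.mean(axis=0)[ci] - sub.mean(axis=1)[gi]
                 + sub.mean())


def msr2d(matrix: np.ndarray, bc: Bicluster) -> float:
    """Mean squared Cheng–Church residue of a bicluster; >= 0."""
    matrix = np.asarray(matrix, dtype=float)
    if bc.genes[-1] >= matrix.shape[0] or bc.conditions[-1] >= matrix.shape[1]:
        raise ValueError("bicluster indices out of bounds for the matrix")
    sub = matrix[np.ix_(bc.genes, bc.conditions)]
    r = (sub - sub.mean(axis=0, keepdims=True)
         - sub.mean(axis=1, keepdims=True) + sub.mean())
    return float(np.mean(r * r))
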