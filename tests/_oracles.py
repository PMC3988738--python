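"""Independent brute-force oracles used to cross-check the implementation.

Everything here recomputes quantities from first principles with plain
Python loops (or direct scipy calls), deliberately sharing no code with
the package's optimised paths.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import stats


def naive_msr3d(sub: np.ndarray) -> float:
    """Triple-loop 3-D mean squared residue, recomputing every mean from
    scratch for every cell."""
    ng, nc, nt = sub.shape
    total = 0.0
    for g, c, t in itertools.product(range(ng), range(nc), range(nt)):
        m_ct_g = sum(sub[g, j, k] for j in range(nc)
                     for k in range(nt)) / (nc * nt)
        m_gt_c = sum(sub[i, c, k] for i in range(ng)
                     for k in range(nt)) / (ng * nt)
        m_gc_t = sum(sub[i, j, t] for i in range(ng)
                     for j in range(nc)) / (ng * nc)
        m_g_ct = sum(sub[i, c, t] for i in range(ng)) / ng
        m_c_gt = sum(sub[g, j, t] for j in range(nc)) / nc
        m_t_gc = sum(sub[g, c, k] for k in range(nt)) / nt
        m_gct = sub.sum() / (ng * nc * nt)
        r = (sub[g, c, t] + m_ct_g + m_gt_c + m_gc_t
             - m_g_ct - m_c_gt - m_t_gc - m_gct)
        total += r * r
    return total / (ng * nc * nt)


def naive_msr2d(sub: np.ndarray) -> float:
    """Double-loop Cheng–Church mean squared residue."""
    ng, nc = sub.shape
    total = 0.0
    for g in range(ng):
        for c in range(nc):
            r = (sub[g, c] - sub[:, c].mean() - sub[g, :].mean()
                 + sub.mean())
            total += r * r
    return total / (ng * nc)


def naive_mean_pairwise_correlation(series: np.ndarray, method: str) -> float:
    """Mean pairwise coefficient over rows via direct scipy calls."""
    n = series.shape[0]
    vals = []
    for i in range(n):
        for j in range(i + 1, n):
            if series[i].std() == 0 or series[j].std() == 0:
                vals.append(0.0)
            elif method == "pearson":
                vals.append(stats.pearsonr(series[i], series[j]).statistic)
            else:
                vals.append(stats.spearmanr(series[i], series[j]).statistic)
    return float(np.mean(vals))
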