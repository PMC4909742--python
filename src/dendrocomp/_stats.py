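"""Small statistical helpers shared across modules."""

from __future__ import annotations

import math

import numpy as np
from scipy import stats

__all__ = ["weighted_ks"]


def weighted_ks(x1, w1, x2, w2) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test on weighted samples.

    The KS statistic is the sup-distance between the weight-normalized
    ECDFs; the p-value uses the asymptotic Kolmogorov law with Kish
    effective sample sizes n_eff = (sum w)^2 / sum w^2.
    """
    x1, w1, x2, w2 = map(np.asarray, (x1, w1, x2, w2))
    xs = np.union1d(x1, x2)

    def cdf(x, w, grid):
        idx = np.argsort(x, kind="stable")
        x, w = x[idx], w[idx]
        cw = np.cumsum(w) / np.sum(w)
        # right-continuous step ECDF evaluated on the grid
        pos = np.searchsorted(x, grid, side="right") - 1
        out = np.where(pos >= 0, cw[np.clip(pos, 0, None)], 0.0)
        return out

    d = float(np.max(np.abs(cdf(x1, w1, xs) - cdf(x2, w2, xs))))
    n1 = np.sum(w1) ** 2 / np.sum(w1**2)
    n2 = np.sum(w2) ** 2 / np.sum(w2**2)
    ne = n1 * n2 / (n1 + n2)
    p = float(stats.kstwobign.sf(d * (math.sqrt(ne) + 0.12 + 0.11 / math.sqrt(ne))))
    return d, min(1.0, p)
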