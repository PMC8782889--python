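"""Independent brute-force oracles used by several test modules.

These deliberately re-derive the quantities with plain loops and the
textbook formulas, independently of the package's vectorized code paths.
"""

from __future__ import annotations

import numpy as np


def loreau_hector(mixture_yields, pure_means, sowing):
    """Direct evaluation of the additive partition for one plot-year.

    ``NE = Y_O - Y_E``, ``CE = N * mean(dRY) * mean(M)``,
    ``SE = N * cov(dRY, M)`` with divisor-N covariance and
    ``dRY_i = Y_i / M_i - RY_E_i``.
    """
    n = len(mixture_yields)
    dry = [y / m - e for y, m, e in zip(mixture_yields, pure_means, sowing)]
    mean_dry = sum(dry) / n
    mean_m = sum(pure_means) / n
    ce = n * mean_dry * mean_m
    cov = sum((d - mean_dry) * (m - mean_m) for d, m in zip(dry, pure_means)) / n
    se = n * cov
    y_o = sum(mixture_yields)
    y_e = sum(e * m for e, m in zip(sowing, pure_means))
    return {"NE": y_o - y_e, "CE": ce, "SE": se, "Y_O": y_o, "Y_E": y_e}


def corrected_relative_yield(mixture_yield, block_pure_yield, sowing):
    """RY_O, delta RY and RY_C from their definitions."""
    ry_o = mixture_yield / block_pure_yield
    return {"RY_O": ry_o, "delta_RY": ry_o - sowing, "RY_C": ry_o / sowing}


def spearman(x, y):
    """Spearman rank correlation via ranks + Pearson (no ties expected)."""
    rx = np.argsort(np.argsort(x)).astype(float)
    ry = np.argsort(np.argsort(y)).astype(float)
    return float(np.corrcoef(rx, ry)[0, 1])
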