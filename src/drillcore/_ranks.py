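"""Vectorised Spearman rank correlation used by the Monte-Carlo tests.

Both the observed statistic and the simulated null draws go through the
same code path (average ranks for ties, Pearson correlation of ranks) so
that tie handling is identical on both sides of a comparison.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata


def spearman_rows(matrix: np.ndarray, x: np.ndarray, fill: float = 0.0) -> np.ndarray:
    """Spearman rho between each row of ``matrix`` and the vector ``x``.

    Ties receive average ranks.  Rows with zero rank variance (a constant
    row) get ``fill`` — the Monte-Carlo tests treat a flat simulated
    profile as carrying no trend.
    """
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    x = np.asarray(x, dtype=float)
    ry = rankdata(matrix, axis=1)
    rx = rankdata(x)
    ry_c = ry - ry.mean(axis=1, keepdims=True)
    rx_c = rx - rx.mean()
    denom = np.sqrt((ry_c**2).sum(axis=1) * (rx_c**2).sum())
    num = ry_c @ rx_c
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), fill)
    return rho


def spearman(y: np.ndarray, x: np.ndarray) -> float:
    """Spearman rho of two vectors; NaN when either vector is constant."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if np.all(y == y[0]) or np.all(x == x[0]):
        return float("nan")
    return float(spearman_rows(y[None, :], x)[0])
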