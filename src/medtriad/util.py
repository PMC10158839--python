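"""Small shared numerical helpers."""

from __future__ import annotations

import numpy as np

__all__ = ["multiple_correlation", "pearson"]


def pearson(u: np.ndarray, v: np.ndarray) -> float:
    u = u - u.mean()
    v = v - v.mean()
    denom = np.sqrt((u @ u) * (v @ v))
    if denom == 0:
        return np.nan
    return float((u @ v) / denom)


def multiple_correlation(block: np.ndarray, v: np.ndarray) -> float:
    """First canonical correlation between a column block and a univariate v.

    With a univariate second set the canonical correlation reduces to the
    multiple correlation, computed here as sqrt(R^2) of regressing ``v`` on
    the block (with intercept) for numerical robustness.
    """
    n = len(v)
    X = np.column_stack([np.ones(n), block])
    coef, *_ = np.linalg.lstsq(X, v, rcond=None)
    fitted = X @ coef
    vc = v - v.mean()
    tss = float(vc @ vc)
    if tss == 0:
        return np.nan
    rss = float(((v - fitted) ** 2).sum())
    r2 = max(0.0, 1.0 - rss / tss)
    return float(np.sqrt(r2))
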