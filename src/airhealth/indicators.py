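"""Indicator preprocessing and descriptive statistics.

Min–max standardization to [0, 1], Spearman rank-correlation screening
of the candidate indicators against unit-level PM2.5, and grouped
descriptive statistics (per city and pooled).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def minmax_standardize(values) -> np.ndarray:
    """(x − min) / (max − min), mapping the data span onto [0, 1].

    A constant vector carries no ordering information and maps to all
    zeros (with a logged warning) rather than raising.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0 or not np.isfinite(x).any():
        raise ValueError("minmax_standardize needs at least one finite value")
    if np.isnan(x).any():
        raise ValueError("missing values are not allowed; apply a fill policy upstream")
    lo, hi = x.min(), x.max()
    if hi == lo:
        logger.warning("constant vector in minmax_standardize; returning zeros")
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def standardize_frame(frame: pd.DataFrame) -> pd.DataFrame:
    """Column-wise min–max standardization of an attribute table."""
    return frame.apply(lambda col: pd.Series(minmax_standardize(col), index=col.index))


def spearman_screen(
    attributes: pd.DataFrame, acp, alpha: float = 0.05
) -> pd.DataFrame:
    """Spearman rank correlation of each attribute with unit PM2.5.

    Ties receive average ranks; p-values are two-sided.  A
    zero-variance attribute has undefined rank correlation and is
    reported with missing rho/p and ``significant=False``.
    """
    acp = np.asarray(acp, dtype=float)
    if len(acp) != len(attributes):
        raise ValueError("attribute table and acp length mismatch")
    if len(acp) < 4:
        raise ValueError("need at least 4 paired observations")
    rows = []
    for name in attributes.columns:
        x = attributes[name].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(acp) == 0:
            rows.append({"attribute": name, "rho": np.nan, "p": np.nan, "significant": False})
            continue
        rho, p = stats.spearmanr(x, acp)
        rows.append(
            {"attribute": name, "rho": float(rho), "p": float(p), "significant": bool(p < alpha)}
        )
    return pd.DataFrame(rows)


def _moment_stats(x: np.ndarray) -> dict:
    n = len(x)
    out = {
        "N": n,
        "mean": float(np.mean(x)),
        "min": float(np.min(x)),
        "max": float(np.max(x)),
    }
    # sample SD (n−1); undefined for a single observation
    out["sd"] = float(np.std(x, ddof=1)) if n >= 2 else np.nan
    if n >= 2 and np.ptp(x) > 0:
        # adjusted (sample-corrected) moment skewness; plain moment
        # kurtosis so the Gaussian reference value is 3, not 0
        out["skewness"] = float(stats.skew(x, bias=False)) if n >= 3 else np.nan
        out["kurtosis"] = float(stats.kurtosis(x, fisher=False, bias=True))
    else:
        out["skewness"] = np.nan
        out["kurtosis"] = np.nan
    return out


def descriptive_stats(values, groups) -> pd.DataFrame:
    """Per-group and pooled descriptive statistics of unit PM2.5.

    One row per city group plus a ``Total`` row: N, mean, sample SD,
    min, max, adjusted skewness, plain (non-excess) kurtosis.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if len(values) != len(groups):
        raise ValueError("values and groups length mismatch")
    rows = []
    for g in pd.unique(groups):
        rows.append({"group": g, **_moment_stats(values[groups == g])})
    rows.append({"group": "Total", **_moment_stats(values)})
    return pd.DataFrame(rows)


def pooled_mean(group_sizes, group_means) -> float:
    """Count-weighted mean, Σ nᵢ mᵢ / Σ nᵢ — recombines city means."""
    n = np.asarray(group_sizes, dtype=float)
    m = np.asarray(group_means, dtype=float)
    if n.shape != m.shape:
        raise ValueError("group_sizes and group_means length mismatch")
    if (n <= 0).any():
        raise ValueError("group sizes must be positive")
    return float((n * m).sum() / n.sum())
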