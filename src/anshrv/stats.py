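"""Two-group Mann–Whitney comparison of HRV feature tables.

The statistic reported is U = min(U_x, U_y) with midranks for ties.  For
small samples (n*m <= 400) without ties the two-sided p-value is exact —
computed from the full null distribution of U by dynamic programming
over all label arrangements; otherwise a normal approximation with tie
and continuity corrections is used.  Significance is assessed per
feature at alpha = 0.01 with no multiplicity correction, mirroring the
per-feature reporting convention of the clinical comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.stats import rankdata, norm

__all__ = ["mann_whitney_u", "compare_groups", "COMPARISON_FEATURES"]

#: Feature ordering of the published comparison table.
COMPARISON_FEATURES = [
    "sdnn_ms", "rmssd_ms", "lf_nu", "hf_nu", "lf_hf", "sd1_ms", "sd2_ms", "sd2_sd1",
]

EXACT_LIMIT = 400  # n*m at or below which the exact null distribution is used


@lru_cache(maxsize=64)
def _u_counts(n: int, m: int) -> np.ndarray:
    """Number of label arrangements giving each U value, for samples of
    size n and m without ties.

    ``counts[u]`` enumerates arrangements with U_x = u via the standard
    recurrence  N(u; n, m) = N(u - m; n - 1, m) + N(u; n, m - 1).
    """
    if n == 0 or m == 0:
        c = np.zeros(n * m + 1)
        c[0] = 1.0
        return c
    a = _u_counts(n - 1, m)
    b = _u_counts(n, m - 1)
    c = np.zeros(n * m + 1)
    c[m:][: a.size] += a
    c[: b.size] += b
    return c


def mann_whitney_u(x, y, method: str = "auto") -> tuple[float, float]:
    """Two-sided Mann–Whitney test; returns (U, p) with U = min(U_x, U_y).

    ``method`` is 'auto' (exact when n*m <= 400 and tie-free, else
    normal), 'exact', or 'normal'.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n, m = x.size, y.size
    ranks = rankdata(np.concatenate([x, y]))
    r_x = float(ranks[:n].sum())
    u_x = r_x - n * (n + 1) / 2.0
    u_y = n * m - u_x
    u = min(u_x, u_y)

    _, tie_counts = np.unique(np.concatenate([x, y]), return_counts=True)
    has_ties = bool(np.any(tie_counts > 1))

    if method == "auto":
        method = "exact" if (n * m <= EXACT_LIMIT and not has_ties) else "normal"
    if method == "exact":
        if has_ties:
            raise ValueError("exact p-value is undefined with ties; use method='normal'")
        counts = _u_counts(n, m)
        p = 2.0 * counts[: int(u) + 1].sum() / counts.sum()
    elif method == "normal":
        N = n + m
        mu = n * m / 2.0
        tie_term = ((tie_counts**3 - tie_counts).sum() / (N * (N - 1))) if N > 1 else 0.0
        sigma2 = n * m / 12.0 * ((N + 1) - tie_term)
        if sigma2 <= 0:  # all observations identical
            return u, 1.0
        z = (u - mu + 0.5) / np.sqrt(sigma2)  # u <= mu by construction
        p = 2.0 * norm.cdf(z)
    else:
        raise ValueError("method must be 'auto', 'exact' or 'normal'")
    return float(u), float(min(p, 1.0))


def compare_groups(
    features: pd.DataFrame,
    alpha: float = 0.01,
    group_col: str = "group",
    feature_cols: list[str] | None = None,
) -> pd.DataFrame:
    """Per-feature two-group comparison.

    ``features`` holds one subject per row with a two-level group column.
    Returns a table ordered like the published comparison (SDNN, RMSSD,
    LF(nu), HF(nu), LF/HF, SD1, SD2, SD2/SD1) with group medians, U, p
    and the significance flag at ``alpha``.
    """
    groups = list(pd.unique(features[group_col]))
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, found {groups}")
    if feature_cols is None:
        feature_cols = [c for c in COMPARISON_FEATURES if c in features.columns]
        if not feature_cols:
            feature_cols = [
                c for c in features.columns
                if c != group_col and pd.api.types.is_numeric_dtype(features[c])
            ]
    g_a = features[features[group_col] == groups[0]]
    g_b = features[features[group_col] == groups[1]]
    if len(g_a) < 2 or len(g_b) < 2:
        raise ValueError("each group needs at least 2 subjects")
    rows = []
    for feat in feature_cols:
        a = g_a[feat].to_numpy(dtype=float)
        b = g_b[feat].to_numpy(dtype=float)
        if np.any(~np.isfinite(a)) or np.any(~np.isfinite(b)):
            raise ValueError(f"feature {feat} contains non-finite values")
        u, p = mann_whitney_u(a, b)
        rows.append({
            "feature": feat,
            f"median_{groups[0]}": float(np.median(a)),
            f"median_{groups[1]}": float(np.median(b)),
            "u_value": u,
            "p_value": p,
            f"significant_at_{alpha:g}": bool(p < alpha),
        })
    return pd.DataFrame(rows)
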