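"""Shared oracles and fixture configurations for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd

# adoption windows compressed into a 20-day horizon for small fixtures
COMPACT_WINDOWS = {
    "ip": ("2020-03-03", "2020-03-10"),
    "sh": ("2020-03-07", "2020-03-14"),
    "ro": ("2020-03-12", "2020-03-20"),
}


def dummy_variable_wls(y, X: pd.DataFrame, unit, time, weights) -> pd.Series:
    """Independent oracle: explicit fixed-effect dummies via statsmodels WLS."""
    import statsmodels.api as sm

    Z = pd.concat(
        [
            X.reset_index(drop=True),
            pd.get_dummies(pd.Series(np.asarray(unit)), prefix="u", drop_first=True, dtype=float),
            pd.get_dummies(pd.Series(np.asarray(time)), prefix="t", drop_first=True, dtype=float),
        ],
        axis=1,
    )
    Z.insert(0, "const", 1.0)
    res = sm.WLS(np.asarray(y), Z, weights=np.asarray(weights)).fit()
    return res.params[X.columns]


def brute_force_cluster_vcov(X, y, beta, weights, codes, k_absorbed=0) -> np.ndarray:
    """Direct CR1 sandwich assembly from per-cluster score outer products."""
    X = np.asarray(X, dtype=float)
    w = np.asarray(weights, dtype=float)
    e = np.asarray(y, dtype=float) - X @ beta
    bread = np.linalg.inv(X.T @ (w[:, None] * X))
    meat = np.zeros((X.shape[1],) * 2)
    for g in np.unique(codes):
        s = ((w * e)[:, None] * X)[codes == g].sum(axis=0)
        meat += np.outer(s, s)
    G = len(np.unique(codes))
    N, k = X.shape
    c = (G / (G - 1.0)) * ((N - 1.0) / max(N - k - k_absorbed, 1))
    return c * bread @ meat @ bread
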