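"""Two-way fixed-effects weighted least squares.

County and day intercepts are absorbed by weighted alternating projections
(iterated group demeaning) rather than by explicit dummies, which scales to
thousands of counties and days while remaining exactly checkable against a
dummy-variable fit on small instances (the Frisch–Waugh–Lovell identity).
Coefficients are on the log scale; ``percent_effect`` converts them to the
percent changes practitioners quote.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

from .errors import ConvergenceError, RankDeficiencyError
from .exposures import DEFAULT_CONTROLS, Design, assemble_design


def weighted_two_way_demean(
    X: np.ndarray,
    codes_a: np.ndarray,
    codes_b: np.ndarray,
    weights: np.ndarray,
    tol: float = 1e-10,
    max_sweeps: int = 500,
) -> tuple[np.ndarray, list]:
    """Remove weighted group means over two crossed groupings.

    Alternates weighted demeaning over ``codes_a`` (e.g. county) and
    ``codes_b`` (e.g. day) until the largest mean subtracted in a sweep falls
    below ``tol``.  On a balanced panel with equal weights this converges to
    the classical row-mean/column-mean/grand-mean closed form.

    Returns the transformed copy of ``X`` and the per-sweep convergence trace.
    """
    X = np.array(X, dtype=float, copy=True)
    if X.ndim == 1:
        X = X[:, np.newaxis]
    weights = np.asarray(weights, dtype=float)
    if (weights <= 0).any():
        raise ValueError("weights must be strictly positive")
    codes_a = np.asarray(codes_a)
    codes_b = np.asarray(codes_b)
    na, nb = codes_a.max() + 1, codes_b.max() + 1
    wa = np.bincount(codes_a, weights, minlength=na)
    wb = np.bincount(codes_b, weights, minlength=nb)

    trace: list = []
    k = X.shape[1]
    for _ in range(max_sweeps):
        biggest = 0.0
        for codes, wsum, n in ((codes_a, wa, na), (codes_b, wb, nb)):
            for j in range(k):
                means = np.bincount(codes, weights * X[:, j], minlength=n) / wsum
                X[:, j] -= means[codes]
                amax = np.abs(means).max(initial=0.0)
                if amax > biggest:
                    biggest = amax
        trace.append(biggest)
        if biggest < tol:
            return X, trace
    raise ConvergenceError(trace)


@dataclass
class WLSFit:
    """Point estimates plus the bread matrix for sandwich covariances."""

    beta: np.ndarray
    bread: np.ndarray        # (X'WX)^-1
    residuals: np.ndarray
    X: np.ndarray
    weights: np.ndarray
    k_absorbed: int = 0      # dof soaked up by absorbed fixed effects


def wls_fit(
    X: np.ndarray, y: np.ndarray, weights: np.ndarray, names: list | None = None
) -> WLSFit:
    """Minimize sum_i w_i (y_i - x_i'b)^2.

    Raises :class:`RankDeficiencyError` naming the collinear columns when the
    (weighted) design is rank deficient.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if (weights <= 0).any():
        raise ValueError("weights must be strictly positive")
    sw = np.sqrt(weights)
    Xw = X * sw[:, np.newaxis]

    _, R, piv = scipy.linalg.qr(Xw, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    cutoff = diag.max(initial=0.0) * max(Xw.shape) * np.finfo(float).eps * 100
    rank = int((diag > cutoff).sum())
    if rank < X.shape[1]:
        bad = piv[rank:]
        labels = [names[j] if names else j for j in sorted(bad)]
        raise RankDeficiencyError(labels)

    XtWX = Xw.T @ Xw
    beta = np.linalg.solve(XtWX, Xw.T @ (y * sw))
    bread = np.linalg.inv(XtWX)
    return WLSFit(beta=beta, bread=bread, residuals=y - X @ beta, X=X, weights=weights)


def percent_effect(beta):
    """Exact percent change implied by a log-scale coefficient: 100*(exp(b)-1)."""
    return 100.0 * np.expm1(beta)


def log_point(percent):
    """Inverse of :func:`percent_effect`: log(1 + pct/100)."""
    return np.log1p(np.asarray(percent) / 100.0)


@dataclass
class FitResult:
    """A fitted panel model with cluster metadata and effect conversions."""

    names: list
    beta: np.ndarray
    vcov: np.ndarray
    nobs: int
    n_units: int
    n_times: int
    weights_desc: str
    cluster_desc: str
    df_inference: int
    demean_sweeps: int
    internals: WLSFit = field(repr=False, default=None)
    clusters: pd.DataFrame = field(repr=False, default=None)
    model: str = ""
    outcome: str = ""

    def se(self) -> np.ndarray:
        # clip rounding-level negatives (zero-residual fits) before the sqrt
        return np.sqrt(np.clip(np.diag(self.vcov), 0.0, None))

    def tstats(self) -> np.ndarray:
        return self.beta / self.se()

    def conf_int(self, level: float = 0.95) -> np.ndarray:
        from scipy.stats import t

        crit = t.ppf(0.5 + level / 2.0, self.df_inference)
        se = self.se()
        return np.column_stack([self.beta - crit * se, self.beta + crit * se])

    def coef(self, name: str) -> float:
        return float(self.beta[self.names.index(name)])

    def tidy(self, level: float = 0.95) -> pd.DataFrame:
        """Term-by-term table in log points and percent."""
        ci = self.conf_int(level)
        return pd.DataFrame(
            {
                "term": self.names,
                "estimate": self.beta,
                "se": self.se(),
                "ci_low": ci[:, 0],
                "ci_high": ci[:, 1],
                "pct": percent_effect(self.beta),
                "pct_approx": 100.0 * self.beta,
                "pct_ci_low": percent_effect(ci[:, 0]),
                "pct_ci_high": percent_effect(ci[:, 1]),
                "cluster": self.cluster_desc,
                "weights": self.weights_desc,
            }
        )


def _fit_design(
    design: Design,
    weights: np.ndarray,
    cluster_cols: list,
    weights_desc: str,
    demean_tol: float = 1e-10,
) -> FitResult:
    """Demean, fit WLS, and attach one-way or two-way cluster covariance."""
    from . import inference  # late import: inference depends on WLSFit

    stacked = np.column_stack([design.y, design.X])
    demeaned, trace = weighted_two_way_demean(
        stacked, design.unit_codes, design.time_codes, weights, tol=demean_tol
    )
    yd, Xd = demeaned[:, 0], demeaned[:, 1:]
    fit = wls_fit(Xd, yd, weights, names=design.names)
    fit.k_absorbed = design.n_units + design.n_times - 1

    labels = [design.clusters[c] for c in cluster_cols]
    if len(labels) == 1:
        codes = pd.factorize(labels[0])[0]
        vcov = inference.cluster_robust_vcov(fit, codes)
        G = codes.max() + 1
        desc = f"one-way: {cluster_cols[0]}"
    else:
        ca, cb = (pd.factorize(lab)[0] for lab in labels)
        vcov = inference.two_way_cluster_vcov(fit, ca, cb)
        G = min(ca.max() + 1, cb.max() + 1)
        desc = f"two-way: {cluster_cols[0]} x {cluster_cols[1]}"

    return FitResult(
        names=design.names,
        beta=fit.beta,
        vcov=vcov,
        nobs=len(yd),
        n_units=design.n_units,
        n_times=design.n_times,
        weights_desc=weights_desc,
        cluster_desc=desc,
        df_inference=max(int(G) - 1, 1),
        demean_sweeps=len(trace),
        internals=fit,
        clusters=design.clusters,
    )


def fit_spillover_did(
    panel: pd.DataFrame,
    model: str = "eq2",
    outcome: str = "locations_visited",
    controls: tuple = DEFAULT_CONTROLS,
) -> FitResult:
    """Estimate the county-day DiD model with county and day effects absorbed.

    ``model='eq1'`` regresses the log outcome on the three own-state policy
    indicators; ``model='eq2'`` adds the three alter-state spillover
    exposures.  The fit is population-weighted WLS; standard errors cluster
    on the ego county's state.
    """
    design = assemble_design(panel, model, outcome, controls)
    res = _fit_design(design, design.weights, ["state"], "county population")
    res.model, res.outcome = model, outcome
    return res
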