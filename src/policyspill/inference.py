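"""Cluster-robust covariance and Fisherian randomization inference.

One-way clustering uses the CR1 sandwich with the G/(G-1) * (N-1)/(N-K)
small-sample factor; two-way clustering combines the two one-way sandwiches
and the intersection clustering by inclusion-exclusion.  Randomization
inference permutes entire state policy timelines (ip, sh, ro as a block)
across states, rebuilding indicators and spillover exposures for every draw,
so the permutation preserves both the within-state ordering of policy periods
and the national adoption profile under the sharp null of no policy effect.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix
from .errors import ConfigError, ConsistencyError
from .exposures import DEFAULT_CONTROLS, EXPOSURE_COLS, INDICATOR_COLS, POLICIES
from .twfe import WLSFit, weighted_two_way_demean, wls_fit


def _cluster_meat(fit: WLSFit, codes: np.ndarray) -> tuple[np.ndarray, int]:
    """Sum of per-cluster score outer products, s_g = sum_{i in g} w_i e_i x_i."""
    G = int(codes.max()) + 1
    u = (fit.weights * fit.residuals)[:, np.newaxis] * fit.X
    k = u.shape[1]
    S = np.empty((G, k))
    for j in range(k):
        S[:, j] = np.bincount(codes, u[:, j], minlength=G)
    return S.T @ S, G


def _cr1(fit: WLSFit, G: int) -> float:
    N, k = fit.X.shape
    K = k + fit.k_absorbed
    denom = max(N - K, 1)
    return (G / (G - 1.0)) * ((N - 1.0) / denom)


def _as_codes(labels) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.dtype.kind in "iu" and labels.min(initial=0) >= 0:
        return labels.astype(np.int64)
    return pd.factorize(labels)[0]


def cluster_robust_vcov(fit: WLSFit, clusters) -> np.ndarray:
    """One-way cluster-robust sandwich covariance with CR1 correction."""
    codes = _as_codes(clusters)
    if len(codes) != len(fit.residuals):
        raise ConsistencyError("cluster labels do not match observations")
    meat, G = _cluster_meat(fit, codes)
    if G < 2:
        raise ConfigError("cluster-robust covariance needs at least 2 clusters")
    V = _cr1(fit, G) * fit.bread @ meat @ fit.bread
    return 0.5 * (V + V.T)


def two_way_cluster_vcov(fit: WLSFit, clusters_a, clusters_b) -> np.ndarray:
    """Two-way clustering by inclusion-exclusion: V_a + V_b - V_{a&b}.

    Each component carries its own CR1 correction.  If the combination is not
    positive semidefinite, negative eigenvalues are truncated at zero (a
    documented repair; flagged via the ``two_way_cluster_vcov.truncated``
    attribute of the most recent call).
    """
    ca, cb = _as_codes(clusters_a), _as_codes(clusters_b)
    if int(ca.max()) + 1 < 2 or int(cb.max()) + 1 < 2:
        raise ConfigError("two-way clustering needs >= 2 clusters in each dimension")
    inter = pd.factorize(ca.astype(np.int64) * (int(cb.max()) + 1) + cb)[0]

    V = np.zeros((fit.X.shape[1],) * 2)
    for codes, sign in ((ca, 1.0), (cb, 1.0), (inter, -1.0)):
        meat, G = _cluster_meat(fit, codes)
        V += sign * _cr1(fit, G) * fit.bread @ meat @ fit.bread
    V = 0.5 * (V + V.T)

    evals, evecs = np.linalg.eigh(V)
    truncated = bool((evals < -1e-12 * max(evals.max(initial=0.0), 1.0)).any())
    if truncated:
        V = (evecs * np.clip(evals, 0.0, None)) @ evecs.T
    two_way_cluster_vcov.truncated = truncated
    return V


@dataclass
class RandomizationResult:
    """Permutation test output for the policy coefficients."""

    names: list
    t_obs: np.ndarray
    draws: np.ndarray            # (B, k) permutation t statistics
    p_values: np.ndarray
    n_perm: int
    seed: int | None
    exhaustive: bool
    beta_obs: np.ndarray = field(default=None)

    def table(self) -> pd.DataFrame:
        """Full permutation statistic table for audit."""
        out = pd.DataFrame(self.draws, columns=self.names)
        out.insert(0, "draw", np.arange(len(out)))
        return out


def p_from_draws(t_obs: float, draws: np.ndarray, exhaustive: bool) -> float:
    """Two-sided permutation p-value.

    Monte-Carlo draws get the add-one correction p = (1 + #{|t*|>=|t|})/(1+B);
    exhaustive enumeration (identity included among the draws) uses the plain
    proportion.  Either way p >= 1/(B+1) and adding a draw with smaller |t*|
    can only lower p.
    """
    draws = np.asarray(draws, dtype=float)
    hits = int((np.abs(draws) >= abs(t_obs) - 1e-12).sum())
    if exhaustive:
        return hits / len(draws)
    return (1 + hits) / (1 + len(draws))


class _TimelineRandomizer:
    """Rebuilds policy columns and t statistics under permuted timelines."""

    def __init__(self, panel, timelines, matrix, model, outcome, controls, state_of=None):
        from .exposures import assemble_design

        self.model = model
        if model == "eq2":
            if matrix is None:
                raise ConfigError("eq2 randomization inference needs a connectivity matrix")
            panel = panel[~panel["county"].isin(matrix.flagged_egos)]
        panel = panel.reset_index(drop=True)
        design = assemble_design(panel, model, outcome, controls)
        self.names = list(INDICATOR_COLS) + (list(EXPOSURE_COLS) if model == "eq2" else [])
        kp = len(self.names)

        self.w = design.weights
        self.ci, self.di = design.unit_codes, design.time_codes
        self.cluster_codes = pd.factorize(panel["state"])[0]
        self.n_units, self.n_times = design.n_units, design.n_times
        self.k_absorbed = design.n_units + design.n_times - 1

        # controls and response never change across draws: demean them once
        passive = np.column_stack([design.y, design.X[:, kp:]])
        passive, _ = weighted_two_way_demean(passive, self.ci, self.di, self.w)
        self.yd, self.Cd = passive[:, 0], passive[:, 1:]

        self.counties = pd.Index(sorted(panel["county"].unique()))
        self.dates = pd.DatetimeIndex(sorted(panel["date"].unique()))
        county_pos = pd.Series(np.arange(len(self.counties)), index=self.counties)
        self.row_cpos = county_pos[panel["county"]].to_numpy()
        self.row_dpos = pd.Series(
            np.arange(len(self.dates)), index=self.dates
        )[panel["date"]].to_numpy()

        self.states = timelines["state"].to_numpy()
        self.enact = {
            m: pd.to_datetime(timelines[f"{m}_date"]).to_numpy() for m in POLICIES
        }
        state_pos = pd.Series(np.arange(len(self.states)), index=self.states)
        panel_states = panel.groupby("county", sort=True)["state"].first()
        self.county_state_pos = state_pos[panel_states.to_numpy()].to_numpy()

        if model == "eq2":
            # align W rows to panel counties, columns to all matrix counties
            keep = matrix.egos.get_indexer(self.counties)
            if (keep < 0).any():
                raise ConsistencyError("panel counties absent from connectivity matrix")
            self.W = matrix.weights[keep]
            lookup = panel_states if state_of is None else pd.Series(state_of)
            alter_states = lookup.reindex(matrix.alters)
            if alter_states.isna().any():
                # alters outside the panel (e.g. counties dropped by the device
                # filter) still broadcast their state's policy; a state map
                # covering them must then be supplied explicitly
                raise ConsistencyError(
                    "alter counties missing state labels; pass state_of covering all alters"
                )
            self.alter_state_pos = state_pos[alter_states.to_numpy()].to_numpy()
        else:
            self.W = None

        self.date_grid = self.dates.to_numpy()[np.newaxis, :]

    def stats(self, assignment: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(t, beta) for the policy coefficients under a timeline assignment."""
        cols = []
        for m in POLICIES:
            enact = self.enact[m][assignment][self.county_state_pos]
            D = (self.date_grid >= enact[:, np.newaxis]).astype(float)
            cols.append(D[self.row_cpos, self.row_dpos])
        if self.model == "eq2":
            for m in POLICIES:
                enact_alter = self.enact[m][assignment][self.alter_state_pos]
                Dalt = (self.date_grid >= enact_alter[:, np.newaxis]).astype(float)
                E = self.W @ Dalt
                cols.append(E[self.row_cpos, self.row_dpos])
        P = np.column_stack(cols)
        Pd, _ = weighted_two_way_demean(P, self.ci, self.di, self.w)
        X = np.column_stack([Pd, self.Cd])
        fit = wls_fit(X, self.yd, self.w)
        fit.k_absorbed = self.k_absorbed
        V = cluster_robust_vcov(fit, self.cluster_codes)
        kp = len(self.names)
        se = np.sqrt(np.diag(V)[:kp])
        return fit.beta[:kp] / se, fit.beta[:kp]


def randomization_inference(
    panel: pd.DataFrame,
    timelines: pd.DataFrame,
    matrix: ConnectivityMatrix | None = None,
    model: str = "eq2",
    outcome: str = "locations_visited",
    n_perm: int = 199,
    seed: int | None = 0,
    controls: tuple = DEFAULT_CONTROLS,
    exhaustive: bool = False,
    state_of: pd.Series | None = None,
) -> RandomizationResult:
    """Permutation test of the sharp null of no policy effect.

    Entire state timelines are shuffled across states; for each draw the
    indicators and (for eq2) the spillover exposures are rebuilt and the model
    refit, collecting cluster-robust t statistics.  ``exhaustive=True``
    enumerates all orderings (identity included) instead of sampling.
    """
    n_states = len(timelines)
    if n_states < 3:
        raise ConfigError("randomization inference needs at least 3 states")
    if not exhaustive and n_perm < 1:
        raise ConfigError("n_perm must be >= 1")

    engine = _TimelineRandomizer(panel, timelines, matrix, model, outcome, controls, state_of)
    identity = np.arange(n_states)
    t_obs, beta_obs = engine.stats(identity)

    if exhaustive:
        if math.factorial(n_states) > 50_000:
            raise ConfigError("exhaustive enumeration infeasible for this many states")
        draws = np.array(
            [engine.stats(np.array(p))[0] for p in itertools.permutations(range(n_states))]
        )
    else:
        rng = np.random.default_rng(seed)
        draws = np.array([engine.stats(rng.permutation(n_states))[0] for _ in range(n_perm)])

    p = np.array([p_from_draws(t_obs[j], draws[:, j], exhaustive) for j in range(len(t_obs))])
    return RandomizationResult(
        names=engine.names,
        t_obs=t_obs,
        draws=draws,
        p_values=p,
        n_perm=len(draws),
        seed=seed,
        exhaustive=exhaustive,
        beta_obs=beta_obs,
    )
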