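"""Cross-state travel models on directed county-pair day panels.

Flows from an origin county to a destination county in a different state are
regressed on origin and destination policy indicators, optionally with the
full 3x3 grid of origin-by-destination interactions, absorbing directed-pair
and day fixed effects.  The count outcome is fit unweighted; the
flow-proportion outcome is weighted by origin county population.  Standard
errors cluster two-way on origin and destination state.  Marginal effects of
a destination policy given the origin's current period combine the main and
interaction terms with delta-method uncertainty.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from .errors import ConfigError, SchemaError
from .exposures import POLICIES
from .twfe import FitResult, _fit_design, percent_effect
from .exposures import Design

log = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0088
ORIGIN_COLS = tuple(f"o_{m}" for m in POLICIES)
DEST_COLS = tuple(f"d_{m}" for m in POLICIES)
INTERACTION_COLS = tuple(f"o_{m}:d_{n}" for m in POLICIES for n in POLICIES)
DYAD_CONTROLS = ("o_temp", "o_log_cases", "d_temp", "d_log_cases")


def haversine_distance(lat1, lon1, lat2, lon2):
    """Great-circle distance in km (Earth radius 6371.0088 km); vectorized."""
    lat1, lon1, lat2, lon2 = (np.asarray(a, dtype=float) for a in (lat1, lon1, lat2, lon2))
    for lat in (lat1, lat2):
        if (np.abs(lat) > 90).any():
            raise ValueError("latitude outside [-90, 90]")
    for lon in (lon1, lon2):
        if (np.abs(lon) > 180).any():
            raise ValueError("longitude outside [-180, 180]")
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlam = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def classify_pairs(panel: pd.DataFrame, threshold_km: float = 100.0) -> dict:
    """Boolean masks for the all / nearby (<threshold) / distant (>threshold) subgroups.

    Pairs exactly at the threshold belong to neither subgroup (strict
    inequalities on both sides).
    """
    if "distance_km" not in panel.columns:
        raise SchemaError("panel has no 'distance_km' column")
    d = panel["distance_km"].to_numpy(dtype=float)
    return {
        "all": np.ones(len(d), dtype=bool),
        "nearby": d < threshold_km,
        "distant": d > threshold_km,
    }


def _dyad_design(panel, interactions, outcome, controls) -> tuple[Design, np.ndarray]:
    names = list(ORIGIN_COLS) + list(DEST_COLS)
    work = panel.copy()
    if interactions:
        for m in POLICIES:
            for n in POLICIES:
                work[f"o_{m}:d_{n}"] = work[f"o_{m}"] * work[f"d_{n}"]
        names += list(INTERACTION_COLS)
    cols = names + list(controls)

    outcome_col = {"count": "flow", "proportion": "proportion"}.get(outcome)
    if outcome_col is None:
        raise SchemaError(f"unknown dyadic outcome {outcome!r}")
    required = cols + [outcome_col, "pair", "date", "o_state", "d_state"]
    if outcome == "proportion":
        required.append("o_population")
    missing = [c for c in required if c not in work.columns]
    if missing:
        raise SchemaError(f"dyad panel missing columns {missing}")

    yraw = work[outcome_col].to_numpy(dtype=float)
    unit_codes, units = pd.factorize(work["pair"], sort=True)
    time_codes, times = pd.factorize(work["date"], sort=True)
    if outcome == "proportion":
        weights = work["o_population"].to_numpy(dtype=float)
    else:
        weights = np.ones(len(work))
    design = Design(
        X=work[cols].to_numpy(dtype=float),
        names=cols,
        y=np.log(yraw),
        weights=weights,
        unit_codes=unit_codes,
        time_codes=time_codes,
        n_units=len(units),
        n_times=len(times),
        clusters=work[["o_state", "d_state"]].copy(),
    )
    return design, yraw


def fit_dyadic_did(
    panel: pd.DataFrame,
    interactions: bool = False,
    outcome: str = "count",
    subgroup: str = "all",
    threshold_km: float = 100.0,
    controls: tuple = DYAD_CONTROLS,
    zero_flow: str = "drop",
) -> FitResult:
    """Estimate the dyadic travel model on a distance subgroup.

    ``subgroup`` in {'all', 'nearby', 'distant'} refits on the masked sample
    with its own pair and day fixed effects.  Zero flows are dropped before
    the log transform by default (count logged); ``zero_flow='log1p'``
    switches the response to log(1 + Y), which changes the coefficient
    interpretation.
    """
    masks = classify_pairs(panel, threshold_km)
    if subgroup not in masks:
        raise ConfigError(f"unknown subgroup {subgroup!r}")
    sub = panel[masks[subgroup]]
    if len(sub) == 0:
        raise ConfigError(f"subgroup {subgroup!r} is empty")

    outcome_col = "flow" if outcome == "count" else "proportion"
    if zero_flow == "drop":
        n_zero = int((sub[outcome_col] <= 0).sum())
        if n_zero:
            log.info("dropping %d zero-flow dyad-days before log transform", n_zero)
            sub = sub[sub[outcome_col] > 0]
    elif zero_flow == "log1p":
        sub = sub.assign(**{outcome_col: sub[outcome_col] + 1.0})
    else:
        raise ConfigError(f"unknown zero_flow policy {zero_flow!r}")
    sub = sub.reset_index(drop=True)

    design, _ = _dyad_design(sub, interactions, outcome, controls)
    desc = "origin population" if outcome == "proportion" else "unweighted"
    res = _fit_design(design, design.weights, ["o_state", "d_state"], desc)
    res.model = "eq4" if interactions else "eq3"
    res.outcome = outcome
    return res


@dataclass
class InteractionGrid:
    """Marginal destination-policy effects for each origin policy period."""

    table: pd.DataFrame

    def lookup(self, origin: str, dest: str) -> pd.Series:
        t = self.table
        return t[(t["origin_period"] == origin) & (t["dest_period"] == dest)].iloc[0]


def marginal_interaction_effects(fit: FitResult, level: float = 0.95) -> InteractionGrid:
    """Destination-policy marginal effects by origin period from an eq4 fit.

    For origin period m (including the pre-policy baseline) and destination
    period n, the marginal effect is psi_n + pi_{m,n} (pi absent at the
    baseline), with delta-method SE sqrt(Var psi + Var pi + 2 Cov).
    """
    names = fit.names
    for required in DEST_COLS + INTERACTION_COLS:
        if required not in names:
            raise ConfigError("marginal effects need an interaction (eq4) fit")
    idx = {nm: names.index(nm) for nm in names}

    rows = []
    for m in ("pre",) + POLICIES:
        for n in POLICIES:
            j = idx[f"d_{n}"]
            est = fit.beta[j]
            var = fit.vcov[j, j]
            if m != "pre":
                i = idx[f"o_{m}:d_{n}"]
                est = est + fit.beta[i]
                var = var + fit.vcov[i, i] + 2.0 * fit.vcov[i, j]
            se = float(np.sqrt(max(var, 0.0)))
            crit = t_dist.ppf(0.5 + level / 2.0, fit.df_inference)
            rows.append(
                {
                    "origin_period": m,
                    "dest_period": n,
                    "estimate": float(est),
                    "se": se,
                    "ci_low": float(est - crit * se),
                    "ci_high": float(est + crit * se),
                    "pct": float(percent_effect(est)),
                    "pct_ci_low": float(percent_effect(est - crit * se)),
                    "pct_ci_high": float(percent_effect(est + crit * se)),
                }
            )
    return InteractionGrid(pd.DataFrame(rows))
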