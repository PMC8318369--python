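"""Policy indicators, network-weighted spillover exposures, sample filters.

State policy timelines collapse the many individual interventions into three
policy periods — initial policies (ip), shelter-in-place (sh), reopening (ro).
Each period is encoded as an *absorbing* indicator: it switches to 1 on the
enactment date (inclusive) and never switches back, so regression
coefficients measure average marginal differences between consecutive policy
periods.  A county's spillover exposure to period *m* is the
connectedness-weighted average of its out-of-state alters' indicators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix
from .errors import ConsistencyError, SchemaError

POLICIES = ("ip", "sh", "ro")
INDICATOR_COLS = tuple(f"d_{m}" for m in POLICIES)
EXPOSURE_COLS = tuple(f"exp_{m}" for m in POLICIES)
OUTCOMES = ("locations_visited", "prop_gt2km", "prop_away_gt1hr", "prop_leaving_home")
DEFAULT_CONTROLS = ("temp", "log_cases")
TIMELINE_DATE_COLS = tuple(f"{m}_date" for m in POLICIES)


def validate_timelines(timelines: pd.DataFrame) -> pd.DataFrame:
    """Check the ip <= sh <= ro ordering for every state (missing dates allowed)."""
    missing = [c for c in ("state",) + TIMELINE_DATE_COLS if c not in timelines.columns]
    if missing:
        raise SchemaError(f"timeline table missing columns {missing}")
    if timelines["state"].duplicated().any():
        dup = timelines.loc[timelines["state"].duplicated(), "state"].tolist()
        raise SchemaError(f"duplicate timelines for states {dup}")
    for earlier, later in (("ip_date", "sh_date"), ("sh_date", "ro_date"), ("ip_date", "ro_date")):
        both = timelines[earlier].notna() & timelines[later].notna()
        bad = timelines.loc[both & (timelines[earlier] > timelines[later]), "state"]
        if len(bad) > 0:
            raise SchemaError(
                f"states {bad.tolist()} violate {earlier} <= {later}"
            )
    return timelines


def build_policy_indicators(
    timelines: pd.DataFrame,
    state_of: pd.Series,
    dates: pd.DatetimeIndex,
) -> pd.DataFrame:
    """Absorbing 0/1 indicators for every county-day.

    Returns a table with one row per (county, date) and columns
    ``d_ip, d_sh, d_ro``.  A state with no date for a period contributes 0
    for that period throughout.
    """
    validate_timelines(timelines)
    state_of = pd.Series(state_of)
    tl = timelines.set_index("state")
    unknown = pd.Index(state_of.unique()).difference(tl.index)
    if len(unknown) > 0:
        raise ConsistencyError(f"counties reference states with no timeline: {list(unknown)}")

    counties = state_of.index
    dates = pd.DatetimeIndex(dates).sort_values()
    out = pd.DataFrame(
        {
            "county": np.repeat(counties.to_numpy(), len(dates)),
            "date": np.tile(dates.to_numpy(), len(counties)),
        }
    )
    date_grid = dates.to_numpy()[np.newaxis, :]
    for m in POLICIES:
        enact = tl[f"{m}_date"].reindex(state_of.to_numpy()).to_numpy()
        # NaT compares False: states without the period stay at 0
        ind = (date_grid >= enact[:, np.newaxis]).astype(np.int8)
        out[f"d_{m}"] = ind.ravel()
    return out


def build_spillover_exposure(
    indicators: pd.DataFrame,
    matrix: ConnectivityMatrix,
) -> pd.DataFrame:
    """Weighted average of alter counties' indicators through a normalized matrix.

    exposure_i(m, t) = sum_j w_ij * d_j(m, t).  Rows are emitted only for
    non-flagged egos; exposures are guaranteed to lie in [0, 1] because each
    admissible row of ``matrix`` is a probability vector.
    """
    if not matrix.normalized:
        raise ConsistencyError("exposure requires a normalized connectivity matrix")
    have = pd.Index(indicators["county"].unique())
    missing = matrix.alters.difference(have)
    if len(missing) > 0:
        raise ConsistencyError(f"indicator series missing for alter counties: {list(missing)}")

    keep = ~matrix.egos.isin(matrix.flagged_egos)
    egos = matrix.egos[keep]
    W = matrix.weights[keep.to_numpy() if hasattr(keep, "to_numpy") else keep]

    frames = {}
    dates = None
    for m in POLICIES:
        wide = indicators.pivot(index="county", columns="date", values=f"d_{m}")
        if wide.isna().any().any():
            raise ConsistencyError("indicator table has missing county-days")
        wide = wide.reindex(matrix.alters)
        dates = wide.columns
        frames[m] = W @ wide.to_numpy(dtype=float)

    out = pd.DataFrame(
        {
            "county": np.repeat(egos.to_numpy(), len(dates)),
            "date": np.tile(dates.to_numpy(), len(egos)),
        }
    )
    for m in POLICIES:
        out[f"exp_{m}"] = frames[m].ravel()
    return out


def filter_low_device_counties(
    panel: pd.DataFrame, threshold: float = 500.0
) -> tuple[pd.DataFrame, list]:
    """Drop counties whose mean daily device count falls below ``threshold``.

    Mirrors the sample restriction to counties with a daily mean device count
    of at least 500, which limits measurement error from differential-privacy
    noise in device panels.  Returns the filtered panel and the list of
    dropped counties.
    """
    if "devices" not in panel.columns:
        raise SchemaError("panel has no 'devices' column")
    means = panel.groupby("county", sort=False)["devices"].mean()
    dropped = means.index[means < threshold]
    kept = panel[~panel["county"].isin(dropped)].reset_index(drop=True)
    return kept, list(dropped)


@dataclass
class Design:
    """Assembled estimation inputs for one model/outcome pair."""

    X: np.ndarray
    names: list
    y: np.ndarray
    weights: np.ndarray
    unit_codes: np.ndarray      # county (or pair) integer codes
    time_codes: np.ndarray      # date integer codes
    n_units: int
    n_times: int
    clusters: pd.DataFrame      # one column per cluster dimension


def assemble_design(
    panel: pd.DataFrame,
    model: str,
    outcome: str,
    controls: tuple = DEFAULT_CONTROLS,
) -> Design:
    """Build response, regressors, weights and group labels for eq1/eq2.

    The response is the natural log of the chosen outcome; eq1 uses the three
    own-policy indicators, eq2 adds the three spillover exposures.  Weights
    are county population, clusters are the ego county's state.
    """
    if model not in ("eq1", "eq2"):
        raise SchemaError(f"unknown model {model!r}; expected 'eq1' or 'eq2'")
    regressors = list(INDICATOR_COLS) + (list(EXPOSURE_COLS) if model == "eq2" else [])
    cols = regressors + list(controls)
    missing = [c for c in cols + [outcome, "county", "date", "state", "population"]
               if c not in panel.columns]
    if missing:
        raise SchemaError(f"panel missing columns {missing}")

    yraw = panel[outcome].to_numpy(dtype=float)
    bad = ~(yraw > 0)
    if bad.any():
        where = panel.loc[bad, ["county", "date"]].iloc[0]
        raise SchemaError(
            f"outcome {outcome!r} not strictly positive at county "
            f"{where['county']} date {where['date']}"
        )

    unit_codes, units = pd.factorize(panel["county"], sort=True)
    time_codes, times = pd.factorize(panel["date"], sort=True)
    return Design(
        X=panel[cols].to_numpy(dtype=float),
        names=cols,
        y=np.log(yraw),
        weights=panel["population"].to_numpy(dtype=float),
        unit_codes=unit_codes,
        time_codes=time_codes,
        n_units=len(units),
        n_times=len(times),
        clusters=panel[["state"]].copy(),
    )
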