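"""Synthetic geography, policy timelines, connectedness, and panels.

Every downstream stage is exercised on data generated here with known
ground-truth parameters, emulating the empirical setting: staggered state
adoption of three policy periods (initial policies, shelter-in-place,
reopening), a gravity-like county connectedness network standing in for the
Social Connectedness Index, log-linear county-day mobility outcomes with
county and day fixed effects, direct effects (delta) and network spillover
effects (gamma), AR(1) county-level controls, and directed cross-state
dyad-day travel flows with origin/destination policy effects and their
interactions.

County-day log outcomes follow

    log Y_it = base + delta . D_it + gamma . Dbar_it + theta' X_it
               + alpha_i + tau_t + eps_it,

where D are the absorbing own-state indicators and Dbar the
connectedness-weighted alter-state exposures, built with the same
connectivity and exposure code the estimators consume, so zero-noise runs
are exactly identified.  Dyad-day log flows follow the analogous model with
origin effects (lambda), destination effects (psi), their 3x3 interactions
(pi), and directed-pair fixed effects.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .connectivity import population_weight_sci, restrict_to_alter_states
from .dyadic import haversine_distance
from .errors import ConfigError, ConsistencyError
from .exposures import (
    OUTCOMES,
    POLICIES,
    build_policy_indicators,
    build_spillover_exposure,
)

# Overlapping windows: early adopters close before laggards act, so every
# origin-by-destination policy interaction has identifying variation (with
# disjoint windows the absorbing products collapse onto the main effects,
# e.g. o_ip * d_ro == d_ro once every state has enacted initial policies).
DEFAULT_WINDOWS = {
    "ip": ("2020-03-01", "2020-05-01"),
    "sh": ("2020-03-15", "2020-05-15"),
    "ro": ("2020-04-01", "2020-06-01"),
}
# log-scale baselines: visits per device, and three visit-share outcomes
DEFAULT_BASES = {
    "locations_visited": float(np.log(4.0)),
    "prop_gt2km": float(np.log(0.35)),
    "prop_away_gt1hr": float(np.log(0.25)),
    "prop_leaving_home": float(np.log(0.60)),
}
LOG_POP_MEAN = 10.5
LOG_POP_SD = 1.0


@dataclass
class SimConfig:
    """Study conditions for one synthetic run.

    Effects are in log points.  Defaults reproduce the magnitudes the
    framework is meant to detect: a small direct effect of initial policies,
    a ~3% direct shelter-in-place reduction, a ~2.5% direct reopening
    increase, and substantially larger alter-state spillovers.
    """

    n_states: int = 40
    counties_per_state: int = 5
    n_days: int = 120
    start_date: str = "2020-02-15"
    true_delta: tuple = (-0.01, -0.03, 0.025)
    true_gamma: tuple = (-0.07, -0.10, 0.16)
    true_lambda: tuple = (-0.01, -0.05, 0.04)
    true_psi: tuple = (-0.01, -0.05, 0.05)
    true_pi: tuple = (
        (0.0, 0.0, 0.0),
        (0.03, 0.02, 0.07),
        (0.0, -0.05, -0.01),
    )
    control_coeffs: tuple = (0.004, -0.02)
    noise_sd: float = 0.05
    fe_sd_county: float = 0.3
    fe_sd_day: float = 0.1
    adoption_windows: dict = field(default_factory=lambda: dict(DEFAULT_WINDOWS))
    # partial adoption: some states never close, never shelter in place, or do
    # not reopen within the study window.  Besides realism (a handful of US
    # states never issued stay-at-home orders), never/partially treated states
    # provide the cross-state contrast that identifies the origin-by-
    # destination policy interactions under absorbing indicator coding.
    frac_untreated: float = 0.08
    frac_no_sh: float = 0.10
    frac_no_ro: float = 0.10
    seed: int = 0
    eta: float = 1.5               # gravity distance-decay exponent
    device_rate: float = 0.05      # mean devices per resident
    missing_fraction: float = 0.0  # county-days dropped to unbalance the panel
    max_dyad_pairs: int | None = None
    base_flow_rate: float = 0.002  # baseline fraction of origin devices travelling
    outcome_bases: dict = field(default_factory=lambda: dict(DEFAULT_BASES))

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_states < 2 or self.counties_per_state < 1 or self.n_days < 2:
            raise ConfigError(
                "need n_states >= 2, counties_per_state >= 1, n_days >= 2"
            )
        if not 0.0 <= self.missing_fraction < 1.0:
            raise ConfigError("missing_fraction must be in [0, 1)")
        if self.noise_sd < 0 or self.fe_sd_county < 0 or self.fe_sd_day < 0:
            raise ConfigError("dispersion parameters must be nonnegative")
        wins = self.windows()
        prev_end = None
        for m in POLICIES:
            s, e = wins[m]
            if s > e:
                raise ConfigError(f"adoption window for {m!r} has start after end")
            if prev_end is not None and prev_end > e:
                raise ConfigError(
                    "adoption windows cannot guarantee ip <= sh <= ro ordering"
                )
            prev_end = e
        for name in ("frac_untreated", "frac_no_sh", "frac_no_ro"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.frac_untreated + self.frac_no_sh + self.frac_no_ro > 1.0:
            raise ConfigError("partial-adoption fractions sum to more than 1")
        if np.shape(np.asarray(self.true_pi)) != (3, 3):
            raise ConfigError("true_pi must be a 3x3 matrix")
        for name in ("true_delta", "true_gamma", "true_lambda", "true_psi"):
            if len(getattr(self, name)) != 3:
                raise ConfigError(f"{name} must have 3 entries (ip, sh, ro)")

    def windows(self) -> dict:
        missing = [m for m in POLICIES if m not in self.adoption_windows]
        if missing:
            raise ConfigError(f"adoption_windows missing periods {missing}")
        return {
            m: (pd.Timestamp(self.adoption_windows[m][0]),
                pd.Timestamp(self.adoption_windows[m][1]))
            for m in POLICIES
        }

    def dates(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start_date, periods=self.n_days, freq="D")

    def to_dict(self) -> dict:
        # JSON round-trip canonicalizes tuples to lists so serialized ground
        # truth compares equal after a YAML round trip
        import json

        return json.loads(json.dumps(dataclasses.asdict(self)))


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    # independent stream per operation so adding stages never reshuffles others
    return np.random.default_rng([int(config.seed), stream])


@dataclass
class GroundTruth:
    """Realized parameters, fixed effects and timelines of a simulation run."""

    kind: str
    config: dict
    delta: list = None
    gamma: list = None
    theta: list = None
    lam: list = None
    psi: list = None
    pi: list = None
    outcome_bases: dict = None
    county_fe: dict = None
    day_fe: dict = None
    pair_fe: dict = None
    timelines: dict = None

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "GroundTruth":
        return cls(**yaml.safe_load(text))


def _timelines_dict(timelines: pd.DataFrame) -> dict:
    return {
        r["state"]: {
            m: (r[f"{m}_date"].strftime("%Y-%m-%d") if pd.notna(r[f"{m}_date"]) else None)
            for m in POLICIES
        }
        for _, r in timelines.iterrows()
    }


def simulate_geography(config: SimConfig) -> pd.DataFrame:
    """Counties with state labels, centroids, populations, device counts.

    Counties cluster around a state center inside a continental-US-like
    bounding box; populations are log-normal(10.5, 1); mean device counts
    scale with population so a realistic minority of counties falls under
    the 500-device sample filter.
    """
    rng = _rng(config, 1)
    states = [f"S{i:02d}" for i in range(config.n_states)]
    center_lat = rng.uniform(27.0, 47.0, size=config.n_states)
    center_lon = rng.uniform(-120.0, -75.0, size=config.n_states)

    rows = []
    for s, (st, clat, clon) in enumerate(zip(states, center_lat, center_lon)):
        for j in range(config.counties_per_state):
            rows.append((f"{st}-C{j:02d}", st, clat, clon))
    geo = pd.DataFrame(rows, columns=["county", "state", "lat", "lon"])
    n = len(geo)
    geo["lat"] = np.clip(geo["lat"] + rng.normal(0.0, 0.7, n), -89.9, 89.9)
    geo["lon"] = np.clip(geo["lon"] + rng.normal(0.0, 0.7, n), -179.9, 179.9)
    geo["population"] = rng.lognormal(LOG_POP_MEAN, LOG_POP_SD, n)
    geo["mean_devices"] = (
        geo["population"] * config.device_rate * np.exp(rng.normal(0.0, 0.3, n))
    )
    return geo


def simulate_policy_timelines(config: SimConfig) -> pd.DataFrame:
    """Staggered per-state enactment dates with ip <= sh <= ro guaranteed.

    Each state's ip date is uniform on the ip window; sh and ro are uniform
    on their windows truncated below at the previous period's draw.
    """
    rng = _rng(config, 2)
    wins = config.windows()
    n = config.n_states

    def count(frac: float) -> int:
        return max(1, round(frac * n)) if frac > 0 else 0

    order = rng.permutation(n)
    k_unt, k_nosh, k_noro = count(config.frac_untreated), count(config.frac_no_sh), count(
        config.frac_no_ro
    )
    untreated = set(order[:k_unt])
    no_sh = set(order[k_unt:k_unt + k_nosh])
    no_ro = set(order[k_unt + k_nosh:k_unt + k_nosh + k_noro])

    rows = []
    for i in range(n):
        dates = {m: pd.NaT for m in POLICIES}
        if i not in untreated:
            prev = None
            for m in POLICIES:
                if (m == "sh" and i in no_sh) or (m == "ro" and i in no_ro):
                    continue
                lo, hi = wins[m]
                if prev is not None and prev > lo:
                    lo = prev
                span = (hi - lo).days
                dates[m] = lo + pd.Timedelta(days=int(rng.integers(0, span + 1)))
                prev = dates[m]
        rows.append((f"S{i:02d}", dates["ip"], dates["sh"], dates["ro"]))
    return pd.DataFrame(rows, columns=["state", "ip_date", "sh_date", "ro_date"])


def simulate_connectivity(geography: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Gravity-kernel connectedness scores in the long SCI format.

    score(i, j) = pop_i * pop_j / (1 + d_ij)^eta: symmetric, decaying in
    distance and increasing in alter population, so the top alters of any
    ego mix nearby counties with distant populous ones — the qualitative
    signature of the empirical connectedness index.
    """
    if len(geography) < 2:
        raise ConsistencyError("connectivity needs at least two counties")
    lat = geography["lat"].to_numpy()
    lon = geography["lon"].to_numpy()
    pop = geography["population"].to_numpy()
    d = haversine_distance(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
    score = pop[:, None] * pop[None, :] / (1.0 + d) ** config.eta
    np.fill_diagonal(score, 0.0)
    i, j = np.nonzero(score)
    return pd.DataFrame(
        {
            "ego": geography["county"].to_numpy()[i],
            "alter": geography["county"].to_numpy()[j],
            "sci": score[i, j],
        }
    )


def _ar1_controls(rng, n_units: int, n_days: int) -> tuple[np.ndarray, np.ndarray]:
    """Temperature-like AR(1) and cumulative-case-like drifting series."""
    mean_temp = rng.normal(15.0, 5.0, n_units)
    temp = np.empty((n_units, n_days))
    temp[:, 0] = mean_temp + rng.normal(0.0, 2.0, n_units)
    for t in range(1, n_days):
        temp[:, t] = mean_temp + 0.9 * (temp[:, t - 1] - mean_temp) + rng.normal(
            0.0, 2.0, n_units
        )
    log_cases = np.cumsum(
        np.abs(rng.normal(0.02, 0.02, (n_units, n_days))), axis=1
    )
    return temp, log_cases


def _check_same_counties(geography: pd.DataFrame, timelines: pd.DataFrame) -> None:
    geo_states = set(geography["state"])
    tl_states = set(timelines["state"])
    if not geo_states <= tl_states:
        raise ConsistencyError(
            f"states without timelines: {sorted(geo_states - tl_states)}"
        )


def simulate_county_panel(
    config: SimConfig,
    geography: pd.DataFrame,
    timelines: pd.DataFrame,
    connectivity: pd.DataFrame,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Balanced county-day panel generated from the spillover DiD model.

    Indicators and exposures are constructed with the same code the
    estimators use (population-weighted, alter-state-restricted,
    row-normalized connectedness), so with ``noise_sd=0`` the generating
    delta and gamma are recovered exactly.
    """
    _check_same_counties(geography, timelines)
    sci_counties = set(connectivity["ego"]) | set(connectivity["alter"])
    if not sci_counties == set(geography["county"]):
        raise ConsistencyError("connectivity counties differ from geography counties")

    rng = _rng(config, 3)
    state_of = geography.set_index("county")["state"]
    pops = geography.set_index("county")["population"]
    dates = config.dates()

    indicators = build_policy_indicators(timelines, state_of, dates)
    W = population_weight_sci(connectivity, pops)
    Wn = restrict_to_alter_states(W, state_of)
    exposures = build_spillover_exposure(indicators, Wn)
    if Wn.flagged_egos:
        indicators = indicators[~indicators["county"].isin(Wn.flagged_egos)]

    panel = indicators.merge(exposures, on=["county", "date"], how="inner")
    panel = panel.sort_values(["county", "date"]).reset_index(drop=True)
    counties = pd.Index(sorted(panel["county"].unique()))
    n_c, n_d = len(counties), len(dates)

    temp, log_cases = _ar1_controls(rng, n_c, n_d)
    alpha = rng.normal(0.0, config.fe_sd_county, n_c)
    tau = rng.normal(0.0, config.fe_sd_day, n_d)

    cpos = counties.get_indexer(panel["county"])
    dpos = dates.get_indexer(pd.DatetimeIndex(panel["date"]))
    panel["state"] = state_of.reindex(panel["county"]).to_numpy()
    panel["population"] = pops.reindex(panel["county"]).to_numpy()
    panel["temp"] = temp[cpos, dpos]
    panel["log_cases"] = log_cases[cpos, dpos]

    mean_dev = geography.set_index("county")["mean_devices"].reindex(counties).to_numpy()
    panel["devices"] = np.round(
        mean_dev[cpos] * np.exp(rng.normal(0.0, 0.05, len(panel)))
    ).astype(int)

    delta = np.asarray(config.true_delta, dtype=float)
    gamma = np.asarray(config.true_gamma, dtype=float)
    theta = np.asarray(config.control_coeffs, dtype=float)
    D = panel[[f"d_{m}" for m in POLICIES]].to_numpy(dtype=float)
    E = panel[[f"exp_{m}" for m in POLICIES]].to_numpy(dtype=float)
    X = panel[["temp", "log_cases"]].to_numpy(dtype=float)
    structural = D @ delta + E @ gamma + X @ theta + alpha[cpos] + tau[dpos]

    for outcome in OUTCOMES:
        eps = rng.normal(0.0, config.noise_sd, len(panel)) if config.noise_sd > 0 else 0.0
        panel[outcome] = np.exp(config.outcome_bases[outcome] + structural + eps)

    if config.missing_fraction > 0:
        keep = rng.random(len(panel)) >= config.missing_fraction
        panel = panel[keep].reset_index(drop=True)

    truth = GroundTruth(
        kind="county_panel",
        config=config.to_dict(),
        delta=delta.tolist(),
        gamma=gamma.tolist(),
        theta=theta.tolist(),
        outcome_bases={k: float(v) for k, v in config.outcome_bases.items()},
        county_fe={c: float(a) for c, a in zip(counties, alpha)},
        day_fe={d.strftime("%Y-%m-%d"): float(t) for d, t in zip(dates, tau)},
        timelines=_timelines_dict(timelines),
    )
    cols = ["county", "state", "date"] + list(OUTCOMES) + [
        "devices", "population", "temp", "log_cases",
        "d_ip", "d_sh", "d_ro", "exp_ip", "exp_sh", "exp_ro",
    ]
    return panel[cols], truth


def simulate_dyad_panel(
    config: SimConfig,
    geography: pd.DataFrame,
    timelines: pd.DataFrame,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Directed cross-state dyad-day flow panel from the interaction model.

    Only origin-destination pairs in different states are emitted.  Baseline
    flows are a small fraction of origin devices with gravity-style distance
    decay; origin device counts are held constant over days so the count and
    proportion outcomes differ only by a pair-level shift absorbed by the
    pair fixed effects.
    """
    _check_same_counties(geography, timelines)
    if geography["state"].nunique() < 2:
        raise ConsistencyError("dyad panel needs counties in at least two states")

    rng = _rng(config, 4)
    dates = config.dates()
    state_of = geography.set_index("county")["state"]

    idx = np.arange(len(geography))
    oi, di = np.meshgrid(idx, idx, indexing="ij")
    oi, di = oi.ravel(), di.ravel()
    cross = (
        geography["state"].to_numpy()[oi] != geography["state"].to_numpy()[di]
    )
    oi, di = oi[cross], di[cross]
    if config.max_dyad_pairs is not None and len(oi) > config.max_dyad_pairs:
        pick = rng.choice(len(oi), size=config.max_dyad_pairs, replace=False)
        pick.sort()
        oi, di = oi[pick], di[pick]

    geo = geography.reset_index(drop=True)
    origin = geo["county"].to_numpy()[oi]
    dest = geo["county"].to_numpy()[di]
    dist = haversine_distance(
        geo["lat"].to_numpy()[oi], geo["lon"].to_numpy()[oi],
        geo["lat"].to_numpy()[di], geo["lon"].to_numpy()[di],
    )
    o_devices = geo["mean_devices"].to_numpy()[oi]

    n_pairs, n_d = len(oi), len(dates)
    indicators = build_policy_indicators(timelines, state_of, dates)
    ind_wide = {
        m: indicators.pivot(index="county", columns="date", values=f"d_{m}")
        .reindex(index=geo["county"], columns=dates)
        .to_numpy(dtype=float)
        for m in POLICIES
    }

    counties = geo["county"]
    temp, log_cases = _ar1_controls(rng, len(geo), n_d)
    pair_fe_noise = rng.normal(0.0, config.fe_sd_county, n_pairs)
    pair_fe = (
        np.log(config.base_flow_rate * o_devices)
        - 1.0 * np.log1p(dist / 100.0)
        + pair_fe_noise
    )
    tau = rng.normal(0.0, config.fe_sd_day, n_d)

    lam = np.asarray(config.true_lambda, dtype=float)
    psi = np.asarray(config.true_psi, dtype=float)
    pi = np.asarray(config.true_pi, dtype=float)
    theta = np.asarray(config.control_coeffs, dtype=float)

    log_flow = pair_fe[:, None] + tau[None, :]
    Do = {m: ind_wide[m][oi] for m in POLICIES}   # (n_pairs, n_days)
    Dd = {n: ind_wide[n][di] for n in POLICIES}
    for k, m in enumerate(POLICIES):
        log_flow += lam[k] * Do[m]
        log_flow += psi[k] * Dd[m]
    for a, m in enumerate(POLICIES):
        for b, n in enumerate(POLICIES):
            if pi[a, b] != 0.0:
                log_flow += pi[a, b] * Do[m] * Dd[n]
    log_flow += theta[0] * temp[oi] + theta[1] * log_cases[oi]
    log_flow += theta[0] * temp[di] + theta[1] * log_cases[di]
    if config.noise_sd > 0:
        log_flow += rng.normal(0.0, config.noise_sd, (n_pairs, n_d))

    flow = np.exp(log_flow)
    panel = pd.DataFrame(
        {
            "origin": np.repeat(origin, n_d),
            "dest": np.repeat(dest, n_d),
            "o_state": np.repeat(geo["state"].to_numpy()[oi], n_d),
            "d_state": np.repeat(geo["state"].to_numpy()[di], n_d),
            "date": np.tile(dates.to_numpy(), n_pairs),
            "flow": flow.ravel(),
            "o_devices": np.repeat(o_devices, n_d),
            "o_population": np.repeat(geo["population"].to_numpy()[oi], n_d),
            "distance_km": np.repeat(dist, n_d),
            "o_temp": temp[oi].ravel(),
            "o_log_cases": log_cases[oi].ravel(),
            "d_temp": temp[di].ravel(),
            "d_log_cases": log_cases[di].ravel(),
        }
    )
    panel["pair"] = panel["origin"] + "->" + panel["dest"]
    panel["proportion"] = panel["flow"] / panel["o_devices"]
    for m in POLICIES:
        panel[f"o_{m}"] = Do[m].ravel().astype(np.int8)
        panel[f"d_{m}"] = Dd[m].ravel().astype(np.int8)

    if config.missing_fraction > 0:
        keep = rng.random(len(panel)) >= config.missing_fraction
        panel = panel[keep].reset_index(drop=True)

    truth = GroundTruth(
        kind="dyad_panel",
        config=config.to_dict(),
        lam=lam.tolist(),
        psi=psi.tolist(),
        pi=pi.tolist(),
        theta=theta.tolist(),
        pair_fe={p: float(v) for p, v in zip(origin + "->" + dest, pair_fe)},
        day_fe={d.strftime("%Y-%m-%d"): float(t) for d, t in zip(dates, tau)},
        timelines=_timelines_dict(timelines),
    )
    return panel, truth


def simulate_all(config: SimConfig, dyads: bool = True) -> dict:
    """Run every generator stage; returns a dict of tables and ground truths."""
    geo = simulate_geography(config)
    tl = simulate_policy_timelines(config)
    sci = simulate_connectivity(geo, config)
    county_panel, county_truth = simulate_county_panel(config, geo, tl, sci)
    out = {
        "geography": geo,
        "timelines": tl,
        "sci": sci,
        "county_panel": county_panel,
        "county_truth": county_truth,
    }
    if dyads:
        dyad_panel, dyad_truth = simulate_dyad_panel(config, geo, tl)
        out["dyad_panel"] = dyad_panel
        out["dyad_truth"] = dyad_truth
    return out
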