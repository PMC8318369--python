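"""End-to-end pipeline: simulate/read -> weights -> exposures -> fit -> infer.

Each stage consumes and produces delimited text tables, so stages are
independently runnable and every reported number can be reproduced from the
run manifest (configuration + seed + package versions) alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .connectivity import population_weight_sci, restrict_to_alter_states
from .dyadic import fit_dyadic_did, marginal_interaction_effects
from .errors import ConfigError, RankDeficiencyError
from .exposures import (
    INDICATOR_COLS,
    OUTCOMES,
    build_policy_indicators,
    build_spillover_exposure,
    filter_low_device_counties,
)
from .inference import randomization_inference
from .simulate import SimConfig, simulate_all
from .twfe import fit_spillover_did

log = logging.getLogger(__name__)

COUNTY_MODELS = ("eq1", "eq2")
DYAD_MODELS = ("eq3", "eq4")


@dataclass
class PipelineConfig:
    """Validated configuration for one pipeline run."""

    seed: int = 0
    outdir: str = "results/run"
    simulate: dict | None = field(default_factory=dict)
    inputs: dict | None = None
    models: list = field(default_factory=lambda: ["eq1", "eq2"])
    outcomes: list = field(default_factory=lambda: ["locations_visited"])
    dyad_outcomes: list = field(default_factory=lambda: ["count", "proportion"])
    subgroups: list = field(default_factory=lambda: ["all", "nearby", "distant"])
    device_threshold: float = 500.0
    distance_threshold_km: float = 100.0
    ri: dict | None = None

    def __post_init__(self) -> None:
        known = {m for m in self.models}
        bad = known - set(COUNTY_MODELS) - set(DYAD_MODELS)
        if bad:
            raise ConfigError(f"unknown models {sorted(bad)}")
        bad = set(self.outcomes) - set(OUTCOMES)
        if bad:
            raise ConfigError(f"unknown outcomes {sorted(bad)}")
        if self.simulate is None and self.inputs is None:
            raise ConfigError("either 'simulate' settings or 'inputs' paths required")
        if self.ri is not None:
            bad = set(self.ri) - {"model", "outcome", "n_perm", "exhaustive"}
            if bad:
                raise ConfigError(f"unknown ri keys {sorted(bad)}")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - names
        if unknown:
            raise ConfigError(f"unknown configuration keys {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


def _prepare_tables(config: PipelineConfig, outdir: Path, diagnostics: dict) -> dict:
    if config.inputs is not None:
        tables = io.read_tables(config.inputs)
        if "county_panel" in tables and not set(INDICATOR_COLS) <= set(
            tables["county_panel"].columns
        ):
            tables["county_panel"] = attach_exposures(
                tables["county_panel"], tables["timelines"], tables.get("sci")
            )
        return tables
    sim_cfg = SimConfig(**{**(config.simulate or {}), "seed": config.seed})
    need_dyads = any(m in DYAD_MODELS for m in config.models)
    tables = simulate_all(sim_cfg, dyads=need_dyads)
    datadir = outdir / "data"
    for kind in ("geography", "timelines", "sci", "county_panel", "dyad_panel"):
        if kind in tables:
            io.write_table(tables[kind], datadir / f"{kind}.csv")
    (datadir / "ground_truth.yaml").write_text(tables["county_truth"].to_yaml())
    diagnostics["simulated"] = True
    return tables


def attach_exposures(panel: pd.DataFrame, timelines: pd.DataFrame, sci: pd.DataFrame | None):
    """Merge freshly built indicators (and exposures, if SCI given) into a panel."""
    state_of = panel.groupby("county", sort=True)["state"].first()
    dates = pd.DatetimeIndex(sorted(panel["date"].unique()))
    indicators = build_policy_indicators(timelines, state_of, dates)
    panel = panel.merge(indicators, on=["county", "date"], how="left")
    if sci is not None:
        pops = panel.groupby("county", sort=True)["population"].first()
        Wn = restrict_to_alter_states(population_weight_sci(sci, pops), state_of)
        exposures = build_spillover_exposure(indicators, Wn)
        panel = panel.merge(exposures, on=["county", "date"], how="inner")
    return panel


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all configured stages and write the result bundle to disk."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    diagnostics: dict = {}
    results: dict = {"fits": {}, "tables": {}}

    tables = _prepare_tables(config, outdir, diagnostics)

    # connectivity weights + flagged-ego diagnostics
    matrix = None
    if "sci" in tables:
        state_of = tables["geography"].set_index("county")["state"] \
            if "geography" in tables else tables["county_panel"].groupby("county")["state"].first()
        pops = tables["geography"].set_index("county")["population"] \
            if "geography" in tables else tables["county_panel"].groupby("county")["population"].first()
        matrix = restrict_to_alter_states(population_weight_sci(tables["sci"], pops), state_of)
        io.write_table(matrix.to_long(), outdir / "weights.csv")
        diagnostics["flagged_egos"] = matrix.flagged_egos

    if any(m in COUNTY_MODELS for m in config.models):
        panel, dropped = filter_low_device_counties(
            tables["county_panel"], config.device_threshold
        )
        diagnostics["counties_dropped_by_device_filter"] = len(dropped)
        diagnostics["counties_retained"] = int(panel["county"].nunique())
        for model in [m for m in config.models if m in COUNTY_MODELS]:
            for outcome in config.outcomes:
                fit = fit_spillover_did(panel, model=model, outcome=outcome)
                key = f"{model}_{outcome}"
                results["fits"][key] = fit
                path = outdir / f"coefficients_{key}.csv"
                io.write_table(fit.tidy(), path)
                results["tables"][key] = path

        if config.ri is not None:
            ri_model = config.ri.get("model", "eq2")
            ri = randomization_inference(
                panel,
                tables["timelines"],
                matrix,
                model=ri_model,
                outcome=config.ri.get("outcome", config.outcomes[0]),
                n_perm=int(config.ri.get("n_perm", 199)),
                seed=config.seed,
                exhaustive=bool(config.ri.get("exhaustive", False)),
                state_of=tables["county_panel"].groupby("county")["state"].first(),
            )
            results["ri"] = ri
            io.write_table(ri.table(), outdir / "ri_draws.csv")
            io.write_table(
                pd.DataFrame(
                    {"term": ri.names, "t_obs": ri.t_obs, "p_value": ri.p_values}
                ),
                outdir / "ri_pvalues.csv",
            )

    if any(m in DYAD_MODELS for m in config.models):
        dyad = tables["dyad_panel"]
        for model in [m for m in config.models if m in DYAD_MODELS]:
            interactions = model == "eq4"
            for outcome in config.dyad_outcomes:
                for subgroup in config.subgroups:
                    try:
                        fit = fit_dyadic_did(
                            dyad,
                            interactions=interactions,
                            outcome=outcome,
                            subgroup=subgroup,
                            threshold_km=config.distance_threshold_km,
                        )
                    except (ConfigError, RankDeficiencyError) as err:
                        if subgroup == "all":
                            raise
                        log.warning("skipping %s/%s/%s: %s", model, outcome, subgroup, err)
                        diagnostics.setdefault("skipped_subgroups", []).append(
                            f"{model}_{outcome}_{subgroup}"
                        )
                        continue
                    key = f"{model}_{outcome}_{subgroup}"
                    results["fits"][key] = fit
                    path = outdir / f"coefficients_{key}.csv"
                    io.write_table(fit.tidy(), path)
                    results["tables"][key] = path
                    if interactions:
                        grid = marginal_interaction_effects(fit)
                        io.write_table(
                            grid.table, outdir / f"marginal_effects_{outcome}_{subgroup}.csv"
                        )

    manifest = {
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "versions": {
            "policyspill": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "diagnostics": diagnostics,
    }
    (outdir / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    (outdir / "diagnostics.json").write_text(json.dumps(diagnostics, indent=2, default=str))
    results["diagnostics"] = diagnostics
    results["outdir"] = outdir
    return results
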