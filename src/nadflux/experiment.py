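"""End-to-end experiment runner: config parsing, seeded pipeline, manifest.

An experiment config (YAML) names a list of scenarios, a sampling design
and a master seed; ``run_experiment`` simulates each scenario, quantifies
noisy cohorts, runs the flux, steady-state, degeneration and statistics
layers, and writes a reproducible CSV/JSON bundle plus a run manifest
(canonical config hash, seed, package version).  A fixed seed gives a
byte-identical bundle.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .degeneration import DEGENERATION_DEFAULTS, threshold_onset_model
from .flux import consumption_rate, synthesis_rate
from .kinetics import simulate
from .measurement import SamplingDesign, generate_cohort
from .params import build_scenario
from .stats import holm_bonferroni, one_way_anova
from .steady_state import relative_levels

logger = logging.getLogger(__name__)

__all__ = ["ExperimentConfig", "run_experiment", "load_config", "figure4_config"]


@dataclass
class ExperimentConfig:
    """Validated configuration of a seeded end-to-end experiment."""

    scenarios: list            # dicts: name, axotomized, t_axotomy, tracer_start, ...
    times: tuple = (0.0, 2.0, 4.0, 6.0)
    n_wells: int = 9
    noise_cv: float = 0.15
    seed: int = 0
    duration: float = 8.0
    atp_normalization: bool = False
    flux_t0: float = 0.0
    degeneration: bool = True
    di_duration: float = 72.0
    reference_group: str = "control"

    def __post_init__(self):
        if not self.scenarios:
            raise ValueError("config must list at least one scenario")
        for s in self.scenarios:
            if "name" not in s:
                raise ValueError("each scenario entry needs a 'name'")

    def canonical_json(self) -> str:
        payload = {
            "scenarios": self.scenarios,
            "times": list(self.times),
            "n_wells": self.n_wells,
            "noise_cv": self.noise_cv,
            "seed": self.seed,
            "duration": self.duration,
            "atp_normalization": self.atp_normalization,
            "flux_t0": self.flux_t0,
            "degeneration": self.degeneration,
            "di_duration": self.di_duration,
            "reference_group": self.reference_group,
        }
        return json.dumps(payload, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]


def load_config(path: str | Path) -> ExperimentConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if "times" in raw:
        raw["times"] = tuple(float(t) for t in raw["times"])
    return ExperimentConfig(**raw)


def figure4_config(seed: int = 0) -> ExperimentConfig:
    """The bundled flux-survey config: every genotype, cut and uncut."""
    scenarios = []
    for name in ("control", "FK866", "NAMPT_OE", "NRK1_NR", "cytNMNAT1",
                 "NMN_DD", "NMN_SN", "NMN_DD_SN", "SARM1_KO"):
        for axo in (False, True):
            scenarios.append(
                {"name": name, "axotomized": axo, "t_axotomy": 0.0, "tracer_start": 0.0}
            )
    return ExperimentConfig(scenarios=scenarios, seed=seed)


def _build(entry: dict, duration: float):
    overrides = dict(entry.get("overrides", {}))
    return build_scenario(
        entry["name"],
        overrides,
        axotomized=bool(entry.get("axotomized", False)),
        t_axotomy=float(entry.get("t_axotomy", 0.0)),
        tracer_start=entry.get("tracer_start", None),
        duration=duration,
    )


def run_experiment(config: ExperimentConfig, out_dir: str | Path, *, force: bool = False) -> dict:
    """Simulate -> quantify -> flux + steady-state + degeneration + stats.

    Writes the bundle under ``out_dir`` and returns the manifest dict.
    Refuses to overwrite an existing bundle unless ``force`` is set.
    """
    out = Path(out_dir)
    manifest_path = out / "manifest.json"
    if manifest_path.exists() and not force:
        raise FileExistsError(f"{manifest_path} exists; pass force=True to overwrite")
    out.mkdir(parents=True, exist_ok=True)

    pairs = [_build(e, config.duration) for e in config.scenarios]
    design = SamplingDesign(
        times=config.times, n_wells=config.n_wells,
        noise_cv=config.noise_cv, seed=config.seed,
    )
    logger.info("stage 1/4: simulating and quantifying %d scenarios", len(pairs))
    try:
        table = generate_cohort(pairs, design, config.seed)
    except Exception as exc:
        raise RuntimeError(f"[simulate/quantify] {exc}") from exc
    table.to_csv(out / "measurements.csv", index=False)

    logger.info("stage 2/4: flux estimates")
    norm = "ATP" if config.atp_normalization else "none"
    flux_rows = []
    for scen, _ in pairs:
        sub = table[table.scenario_id == scen.scenario_id]
        try:
            cons = consumption_rate(sub, config.flux_t0, normalization=norm)
            syn = synthesis_rate(sub, config.flux_t0, normalization=norm)
        except Exception as exc:
            raise RuntimeError(f"[flux:{scen.scenario_id}] {exc}") from exc
        for est in (cons, syn):
            flux_rows.append(
                (scen.scenario_id, scen.genotype_treatment, scen.axotomized, est.kind,
                 est.rate_mean, est.rate_sd, est.n, est.interval[0], est.interval[1], norm)
            )
    flux_df = pd.DataFrame(
        flux_rows,
        columns=["scenario_id", "genotype_treatment", "axotomized", "kind",
                 "rate_mean", "rate_sd", "n", "t0", "t1", "normalization"],
    )
    flux_df.to_csv(out / "flux.csv", index=False)

    logger.info("stage 3/4: steady-state relative levels + ANOVA")
    stats_payload = {}
    baseline = table[table.time_h == config.times[0]]
    for metab in ("NAD", "NMN"):
        try:
            rel = relative_levels(baseline, metab, config.reference_group,
                                  time_h=config.times[0])
            rel.table.to_csv(out / f"relative_{metab}.csv", index=False)
        except ValueError:
            continue
        groups = [
            g.conc_uM.to_numpy()
            for _, g in baseline[
                (baseline.metabolite == metab)
                & (baseline.label == "total")
                & (~baseline.censored.astype(bool))
            ].groupby("genotype_treatment")
            if len(g) >= 2
        ]
        if len(groups) >= 2:
            res = one_way_anova(groups)
            stats_payload[metab] = {
                "F": res.F, "df": [res.df_between, res.df_within], "p": res.p,
            }
    (out / "stats.json").write_text(json.dumps(stats_payload, indent=2))

    if config.degeneration:
        logger.info("stage 4/4: threshold-onset degeneration curves")
        di_rows = []
        grid = np.round(np.arange(0.0, config.di_duration + 1e-9, 0.25), 10)
        for entry in config.scenarios:
            if not entry.get("axotomized", False):
                continue
            scen, params = _build({**entry, "tracer_start": None}, config.di_duration)
            scen.duration = config.di_duration
            try:
                traj = simulate(scen, params, grid)
            except Exception as exc:
                raise RuntimeError(f"[degeneration:{scen.scenario_id}] {exc}") from exc
            di = threshold_onset_model(
                grid, traj.total("NAD"),
                t_onset_from=scen.t_axotomy,
                sarm1_present=scen.genotype_treatment != "SARM1_KO",
            )
            for t, d in zip(grid[::4], di[::4]):  # hourly output
                di_rows.append((scen.scenario_id, t, d))
        pd.DataFrame(di_rows, columns=["scenario_id", "time_h", "di"]).to_csv(
            out / "degeneration.csv", index=False
        )

    manifest = {
        "config": json.loads(config.canonical_json()),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "nadflux_version": _pkg_version,
        "outputs": sorted(p.name for p in out.iterdir() if p.name != "manifest.json"),
    }
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
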