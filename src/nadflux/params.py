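"""Pathway parameters and perturbation scenarios.

The kinetic model describes the mammalian NAD+ salvage pathway in cultured
DRG axons: medium nicotinamide (Nam) is converted to NMN by NAMPT
(feedback-inhibited by NAD+), NMN to NAD+ by NMNAT, with a deamidated
branch (NMN -> NaMN -> NaAD -> NAD+) opened up by bacterial NMN deamidase /
NMN synthetase, an alternative NR -> NMN route through NRK1, and NAD+
consumption split into a basal component and a SARM1-dependent component
that switches on after axotomy.  All concentrations are in uM and all times
in hours.

The shipped default parameter values are calibrated so that the flux
estimators applied to noiseless simulated control cohorts reproduce the
experimentally reported synthesis/consumption rates; see
``nadflux/data/default_params.json`` and docs/methods.md.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, fields, replace
from importlib import resources

__all__ = [
    "GENOTYPES",
    "PathwayParameters",
    "Scenario",
    "build_scenario",
    "load_default_params",
    "load_scenario_constants",
]

GENOTYPES = (
    "control",
    "FK866",
    "NAMPT_OE",
    "NRK1_NR",
    "cytNMNAT1",
    "NMN_DD",
    "NMN_SN",
    "NMN_DD_SN",
    "NMN_DD_SN_NR",
    "SARM1_KO",
)


@dataclass
class PathwayParameters:
    """Rate constants, pool sizes and medium composition of the kinetic model.

    Units: Vmax in uM/h, first-order constants in 1/h, Michaelis/inhibition
    constants and pools in uM, half-lives and delays in hours.
    """

    vmax_nampt: float = 0.55          # NAMPT Vmax (uM/h)
    km_nampt_nam: float = 0.1         # NAMPT Km for medium Nam (uM)
    ki_nampt_nad: float = 0.75        # NAD+ feedback inhibition constant (uM)
    hill_nampt: float = 6.0           # cooperativity of the NAD+ feedback
    k_nmnat: float = 0.75             # NMNAT: NMN -> NAD+ (1/h)
    k_nmnat_namn: float = 0.05        # NMNAT: NaMN -> NaAD (1/h)
    k_nadsyn: float = 0.0025          # NAD synthetase: NaAD -> NAD+ (1/h)
    k_nrk: float = 0.0                # NRK1: NR -> NMN (1/h per uM NR, low-NR slope)
    km_nrk: float = 300.0             # NRK1 saturation: flux = k_nrk*NR*km/(km+NR)
    k_deamidase: float = 0.0          # NMN deamidase: NMN -> NaMN (1/h)
    k_synthetase: float = 0.0         # NMN synthetase: NaMN -> NMN (1/h)
    k_nmn_leak: float = 0.25          # NMNAT-independent NMN clearance (1/h)
    k_cons_basal: float = 0.17        # basal NAD+ consumption (1/h)
    k_cons_sarm1: float = 0.36        # SARM1 consumption after injury (1/h)
    t_half_nmnat2: float = 0.35       # post-axotomy NMNAT2 decay half-life (h)
    nmnat_decay_delay_h: float = 1.6  # latency before NMNAT2 decay begins (h)
    k_adenylate_decay: float = 0.35   # post-axotomy adenylate decline (1/h)
    k_exchange: float = 0.15          # D4-NAD+ -> D3-NAD+ via NAD+/NADH cycling (1/h)
    nam_medium: float = 30.0          # unlabeled medium Nam (uM)
    d4nam_medium: float = 300.0       # D4-Nam tracer added at tracer_start (uM)
    nr_medium: float = 0.0            # medium nicotinamide riboside (uM)
    # initial pools (uM); control values are the calibrated steady state
    nad_init: float = 1.0
    nmn_init: float = 0.2267
    namn_init: float = 0.0
    naad_init: float = 0.0
    atp_init: float = 5.0
    adp_init: float = 1.0
    amp_init: float = 0.3

    def validate(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v) and not (
                f.name == "t_half_nmnat2" and v == math.inf
            ):
                raise ValueError(f"parameter {f.name} is not finite: {v}")
            if v < 0:
                raise ValueError(f"parameter {f.name} must be >= 0, got {v}")
        if self.km_nampt_nam <= 0 or self.ki_nampt_nad <= 0:
            raise ValueError("km_nampt_nam and ki_nampt_nad must be > 0")
        if self.t_half_nmnat2 <= 0:
            raise ValueError("t_half_nmnat2 must be > 0")

    def with_overrides(self, overrides: dict) -> "PathwayParameters":
        unknown = set(overrides) - {f.name for f in fields(self)}
        if unknown:
            raise KeyError(f"unknown parameter override(s): {sorted(unknown)}")
        out = replace(self, **overrides)
        out.validate()
        return out


@dataclass
class Scenario:
    """An experimental condition: genotype/treatment, injury and tracer timing."""

    genotype_treatment: str = "control"
    axotomized: bool = False
    t_axotomy: float = 0.0            # hours; only meaningful if axotomized
    tracer_start: float | None = None  # D4-Nam addition time (h); None = no tracer
    nr_dose: float = 0.0              # NR in the medium (uM)
    duration: float = 8.0             # hours simulated
    sarm1_activation: float = 1.0     # scenario-graded SARM1 engagement in [0, 1]
    nmnat_stable: bool = False        # True for cytNMNAT1 (axotomy-resistant NMNAT)
    equilibrate_h: float = 0.0        # pre-run burn-in with scenario enzymes active
    scenario_id: str = ""

    def __post_init__(self) -> None:
        if self.genotype_treatment not in GENOTYPES:
            raise ValueError(f"unknown genotype/treatment {self.genotype_treatment!r}")
        if not self.scenario_id:
            suffix = "axotomy" if self.axotomized else "uninjured"
            self.scenario_id = f"{self.genotype_treatment}_{suffix}"

    def validate(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.axotomized and not 0 <= self.t_axotomy <= self.duration:
            raise ValueError("t_axotomy must lie within [0, duration]")
        if self.tracer_start is not None and not 0 <= self.tracer_start <= self.duration:
            raise ValueError("tracer_start must lie within [0, duration]")
        if not 0 <= self.sarm1_activation <= 1:
            raise ValueError("sarm1_activation must lie in [0, 1]")


_SCENARIO_FIELDS = {f.name for f in fields(Scenario)}


def _load_json(name: str) -> dict:
    with resources.files("nadflux.data").joinpath(name).open() as fh:
        return json.load(fh)


def load_default_params() -> PathwayParameters:
    """The frozen calibrated default parameter set shipped with the package."""
    payload = _load_json("default_params.json")
    p = PathwayParameters(**payload["parameters"])
    p.validate()
    return p


def load_scenario_constants() -> dict:
    """Calibrated scenario-level constants (enzyme expression strengths etc.)."""
    return _load_json("default_params.json")["scenario_constants"]


def build_scenario(
    name: str,
    overrides: dict | None = None,
    *,
    axotomized: bool = False,
    t_axotomy: float = 0.0,
    tracer_start: float | None = None,
    duration: float = 8.0,
) -> tuple[Scenario, PathwayParameters]:
    """Build a (Scenario, PathwayParameters) pair for a named perturbation.

    ``overrides`` may name any :class:`PathwayParameters` field or any
    :class:`Scenario` field; scenario-specific modifications (e.g. FK866
    zeroing NAMPT activity, SARM1-KO zeroing injury-induced consumption)
    are applied first, then user overrides.
    """
    if name not in GENOTYPES:
        raise ValueError(f"unknown scenario name {name!r}; choose from {GENOTYPES}")
    overrides = dict(overrides or {})

    params = load_default_params()
    consts = load_scenario_constants()

    scen = Scenario(
        genotype_treatment=name,
        axotomized=axotomized,
        t_axotomy=t_axotomy,
        tracer_start=tracer_start,
        duration=duration,
    )

    pmod: dict = {}
    if name == "FK866":
        pmod["vmax_nampt"] = 0.0
        scen.sarm1_activation = consts["sarm1_activation"]["FK866"]
    elif name == "NAMPT_OE":
        pmod["vmax_nampt"] = params.vmax_nampt * consts["nampt_oe_fold"]
        scen.sarm1_activation = consts["sarm1_activation"]["NAMPT_OE"]
        scen.equilibrate_h = consts["equilibrate_h"]
    elif name == "NRK1_NR":
        pmod["k_nrk"] = consts["k_nrk"]
        scen.nr_dose = consts["nr_dose_uM"]["NRK1_NR"]
        scen.sarm1_activation = consts["sarm1_activation"]["NRK1_NR"]
        scen.equilibrate_h = consts["equilibrate_h"]
    elif name == "cytNMNAT1":
        scen.nmnat_stable = True
        scen.sarm1_activation = 0.0
        scen.equilibrate_h = consts["equilibrate_h"]
    elif name == "NMN_DD":
        pmod["k_deamidase"] = consts["k_deamidase"]
        scen.sarm1_activation = 0.0
        scen.equilibrate_h = consts["equilibrate_h"]
    elif name == "NMN_SN":
        pmod["k_synthetase"] = consts["k_synthetase"]
        scen.equilibrate_h = consts["equilibrate_h"]
    elif name == "NMN_DD_SN":
        pmod["k_deamidase"] = consts["k_deamidase"]
        pmod["k_synthetase"] = consts["k_synthetase"]
        scen.sarm1_activation = 0.0
        scen.equilibrate_h = consts["equilibrate_h"]
    elif name == "NMN_DD_SN_NR":
        pmod["k_deamidase"] = consts["k_deamidase"]
        pmod["k_synthetase"] = consts["k_synthetase"]
        pmod["k_nrk"] = consts["k_nrk"]
        scen.nr_dose = consts["nr_dose_uM"]["NMN_DD_SN_NR"]
        scen.sarm1_activation = 0.0
        scen.equilibrate_h = consts["equilibrate_h"]
    elif name == "SARM1_KO":
        pmod["k_cons_sarm1"] = 0.0

    scen_over = {k: v for k, v in overrides.items() if k in _SCENARIO_FIELDS}
    param_over = {k: v for k, v in overrides.items() if k not in _SCENARIO_FIELDS}
    pmod.update(param_over)
    params = params.with_overrides(pmod)
    for k, v in scen_over.items():
        setattr(scen, k, v)
    scen.validate()
    # regenerate the id after overrides may have changed injury status
    scen.scenario_id = overrides.get(
        "scenario_id",
        f"{name}_{'axotomy' if scen.axotomized else 'uninjured'}",
    )
    return scen, params
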