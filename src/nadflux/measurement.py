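"""Synthetic LC-MS/MS measurement layer.

Converts true simulated trajectories into noisy per-well quantified
metabolite tables (tidy "MeasurementTable" DataFrames), mimicking targeted
MRM quantitation against external standard curves.  Chromatography is
metadata only; no peaks are simulated.

A MeasurementTable has the columns::

    scenario_id, genotype_treatment, time_h, well_id, metabolite,
    label (D0 | D3 | D4 | total), conc_uM, censored

Per-well measurement error is multiplicative lognormal with a stated CV
(mean-one convention), applied independently per quantified transition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pyteomics import mass as _ptmass

from .kinetics import Trajectory, simulate
from .params import PathwayParameters, Scenario

__all__ = [
    "MrmTransition",
    "load_mrm_transitions",
    "nominal_precursor_mz",
    "Calibration",
    "make_standard_curve",
    "SamplingDesign",
    "quantify",
    "generate_cohort",
    "TABLE_COLUMNS",
]

TABLE_COLUMNS = [
    "scenario_id",
    "genotype_treatment",
    "time_h",
    "well_id",
    "metabolite",
    "label",
    "conc_uM",
    "censored",
]

_PROTON = 1.00727646688

#: labels emitted per metabolite (besides a "total" row)
_EMITTED_LABELS = {"NAD": ("D0", "D3", "D4"), "NMN": ("D0", "D4")}
_TOTAL_ONLY = ("NaMN", "NaAD", "ATP", "ADP", "AMP")


@dataclass(frozen=True)
class MrmTransition:
    """One multiple-reaction-monitoring transition (positive ESI)."""

    metabolite: str
    ms1_mz: int
    ms2_mz: int
    fragmentation_v: float
    collision_energy_v: float
    cell_ac_v: float

    def __post_init__(self):
        if not self.ms1_mz > self.ms2_mz > 0:
            raise ValueError("require ms1_mz > ms2_mz > 0")


def load_mrm_transitions() -> list[MrmTransition]:
    """The packaged MRM transition table for all quantified metabolites."""
    from importlib import resources

    with resources.files("nadflux.data").joinpath("mrm_transitions.csv").open() as fh:
        df = pd.read_csv(fh)
    return [
        MrmTransition(
            r.metabolite,
            int(r.ms1_mz),
            int(r.ms2_mz),
            float(r.fragmentation_v),
            float(r.collision_energy_v),
            float(r.cell_ac_v),
        )
        for r in df.itertuples()
    ]


def nominal_precursor_mz(formula: str, n_deuterium: int = 0) -> int:
    """Nominal integer m/z of the protonated, n-fold deuterated molecule.

    Computes the monoisotopic mass from the molecular formula, adds one
    proton, rounds to the nominal integer and adds one mass unit per H->D
    substitution.
    """
    if n_deuterium < 0:
        raise ValueError("n_deuterium must be >= 0")
    try:
        m = _ptmass.calculate_mass(formula=formula)
    except Exception as exc:  # pyteomics raises on unknown element symbols
        raise ValueError(f"cannot parse molecular formula {formula!r}: {exc}") from exc
    return int(round(m + _PROTON)) + n_deuterium


@dataclass
class Calibration:
    """A linear external standard curve for one metabolite."""

    metabolite: str
    levels: list  # [(true uM, simulated response), ...]
    slope: float  # response per uM (fitted)
    intercept: float
    top_standard: float
    lod: float  # uM; back-calculated values below this are censored
    response_factor: float = 1.0  # the generating response per uM

    def __post_init__(self):
        if self.slope <= 0:
            raise ValueError("calibration slope must be > 0")

    def response(self, conc: float) -> float:
        """Instrument response for a true concentration (generating map)."""
        return self.response_factor * conc

    def back_calculate(self, response: float) -> float:
        return (response - self.intercept) / self.slope


def make_standard_curve(
    metabolite: str,
    top: float,
    n_levels: int,
    noise_cv: float,
    seed: int,
    *,
    response_factor: float = 1.0,
    blank_sd: float | None = None,
    n_blanks: int = 5,
) -> Calibration:
    """Simulate a 2-fold serial-dilution standard curve and fit it.

    The limit of detection is the lowest standard level whose simulated
    response exceeds three times the blank standard deviation.
    """
    if top <= 0:
        raise ValueError("top standard must be > 0")
    if n_levels < 3:
        raise ValueError("need at least 3 standard levels")
    rng = np.random.default_rng(seed)
    concs = top / 2.0 ** np.arange(n_levels)
    if blank_sd is None:
        blank_sd = 1e-3 * response_factor * top
    mult = _lognormal_mult(rng, noise_cv, n_levels)
    responses = response_factor * concs * mult
    if n_blanks > 0 and blank_sd > 0:
        responses = responses + rng.normal(0.0, blank_sd, n_levels)
    if np.allclose(responses, responses[0]):
        raise ValueError("degenerate standard curve: zero response variance")
    slope, intercept = np.polyfit(concs, responses, 1)
    detectable = concs[responses > 3.0 * blank_sd]
    lod = float(detectable.min()) if len(detectable) else float(concs.max())
    return Calibration(
        metabolite=metabolite,
        levels=list(zip(concs.tolist(), responses.tolist())),
        slope=float(slope),
        intercept=float(intercept),
        top_standard=top,
        lod=lod,
        response_factor=response_factor,
    )


def _ideal_calibration(metabolite: str) -> Calibration:
    return Calibration(
        metabolite=metabolite,
        levels=[],
        slope=1.0,
        intercept=0.0,
        top_standard=np.inf,
        lod=0.0,
        response_factor=1.0,
    )


def _lognormal_mult(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-one multiplicative lognormal noise with coefficient of variation cv."""
    if cv <= 0:
        return np.ones(size) if size is not None else 1.0
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


@dataclass
class SamplingDesign:
    """Which times are sampled, how many wells, and the measurement noise."""

    times: tuple = (0.0, 2.0, 4.0, 6.0)
    n_wells: int = 3
    noise_cv: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if self.n_wells < 1:
            raise ValueError("n_wells must be >= 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


def quantify(
    trajectory: Trajectory,
    design: SamplingDesign,
    calibrations: dict[str, Calibration] | None = None,
) -> pd.DataFrame:
    """Sample a trajectory into a noisy per-well MeasurementTable.

    Each well draws independent lognormal measurement noise per quantified
    transition; label-resolved rows (D0/D3/D4 for NAD+, D0/D4 for NMN) are
    drawn individually and the per-well "total" row is their sum, so label
    sub-pools add up to the reported total by construction.  Values whose
    back-calculated concentration falls below the calibration LOD are
    censored (conc_uM = NaN, censored = True).
    """
    for t in design.times:
        trajectory.at(t)  # raises KeyError if not on the grid
    rng = np.random.default_rng(design.seed)
    scen = trajectory.scenario
    rows = []

    def measure(metab: str, true: float) -> tuple[float, bool]:
        cal = (calibrations or {}).get(metab) or _ideal_calibration(metab)
        noisy = true * _lognormal_mult(rng, design.noise_cv, None)
        conc = cal.back_calculate(cal.response(noisy))
        if conc < cal.lod:
            return float("nan"), True
        return float(conc), False

    for t in design.times:
        for w in range(design.n_wells):
            well = f"w{w + 1:02d}"
            for sp in ("NAD", "NMN"):
                total = 0.0
                any_censored = False
                for lab in _EMITTED_LABELS[sp]:
                    conc, cens = measure(sp, trajectory.value(sp, lab, t))
                    rows.append(
                        (scen.scenario_id, scen.genotype_treatment, t, well, sp, lab, conc, cens)
                    )
                    if cens:
                        any_censored = True
                    else:
                        total += conc
                rows.append(
                    (scen.scenario_id, scen.genotype_treatment, t, well, sp,
                     "total", total, False)
                )
            idx = int(np.searchsorted(trajectory.t, t))
            for sp in _TOTAL_ONLY:
                if sp in ("NaMN", "NaAD"):
                    true = float(trajectory.total(sp)[idx])
                else:
                    true = float(trajectory.adenylate(sp)[idx])
                conc, cens = measure(sp, true)
                rows.append(
                    (scen.scenario_id, scen.genotype_treatment, t, well, sp, "total", conc, cens)
                )
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def generate_cohort(
    scenarios: list[tuple[Scenario, PathwayParameters]],
    design: SamplingDesign,
    seed: int,
    *,
    calibrations: dict[str, Calibration] | None = None,
    t_grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Simulate and quantify a list of scenarios with per-scenario child seeds.

    Deterministic for a fixed master seed: scenario sub-seeds are spawned
    from a :class:`numpy.random.SeedSequence` in list order.
    """
    if not scenarios:
        raise ValueError("generate_cohort requires at least one scenario")
    children = np.random.SeedSequence(seed).spawn(len(scenarios))
    tables = []
    for (scen, params), child in zip(scenarios, children):
        grid = t_grid
        if grid is None:
            grid = np.unique(np.asarray(sorted(set(design.times) | {0.0}), dtype=float))
        traj = simulate(scen, params, grid)
        sub = SamplingDesign(
            times=design.times,
            n_wells=design.n_wells,
            noise_cv=design.noise_cv,
            seed=int(child.generate_state(1)[0] % (2**31 - 1)),
        )
        tables.append(quantify(traj, sub, calibrations))
    return pd.concat(tables, ignore_index=True)
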