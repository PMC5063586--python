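"""Isotopologue-resolved kinetic simulation of the NAD+ salvage pathway.

State vector (all uM): five Nam-moiety species x three isotopologues
(D0 / D3 / D4), three adenylates and nicotinamide riboside:

    Nam, NMN, NaMN, NAD, NaAD  (x D0, D3, D4)   indices 0..14
    ATP, ADP, AMP, NR                            indices 15..18

Reactions
---------
* NAMPT: medium Nam -> NMN.  Michaelis-Menten in Nam with cooperative NAD+
  feedback inhibition ki^h / (ki^h + NAD^h) and proportional to the
  adenylate charge ATP/ATP0 (PRPP regeneration collapses with the
  adenylate pool after axotomy).  Label split follows the Nam pool.
* NRK1: NR -> NMN (D0; the riboside is unlabeled).
* NMNAT: NMN -> NAD+ and NaMN -> NaAD, label preserving, scaled by the
  time-dependent NMNAT activity a(t) (decays after axotomy unless the
  scenario expresses axotomy-resistant cytNMNAT1).
* NMN deamidase / NMN synthetase: NMN <-> NaMN, label preserving.
* NAD synthetase: NaAD -> NAD+.
* NMN clearance: first-order, NMNAT-independent leak (to NR in the closed
  variant).
* NAD+ consumption: k_cons_basal plus a SARM1 component switched on at
  axotomy (scaled by the scenario's sarm1_activation); glycosidic cleavage
  returns Nam carrying the ring label to the medium.
* C4 exchange: D4-NAD+ -> D3-NAD+ first order (NAD+/NADH cycling).

By default the medium is an infinite reservoir (Nam and NR pools are held
constant and released Nam is discarded); ``closed_medium=True`` makes them
finite so the nicotinamide moiety is strictly conserved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .params import PathwayParameters, Scenario

__all__ = [
    "SPECIES",
    "LABELS",
    "Trajectory",
    "AxotomySchedule",
    "axotomize",
    "simulate",
    "IntegrationError",
]

SPECIES = ("Nam", "NMN", "NaMN", "NAD", "NaAD")
LABELS = ("D0", "D3", "D4")
_IDX = {(s, l): 3 * i + j for i, s in enumerate(SPECIES) for j, l in enumerate(LABELS)}
_ATP, _ADP, _AMP, _NR = 15, 16, 17, 18
_NSTATE = 19

_NEG_TOL = -1e-9  # states below this abort the run (uM)


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails or produces unphysical states."""


def _nmnat_activity(t: float, scen: Scenario, p: PathwayParameters) -> float:
    """Fractional NMNAT activity: 1 before injury, delayed exponential after."""
    if not scen.axotomized or scen.nmnat_stable or t < scen.t_axotomy:
        return 1.0
    te = t - scen.t_axotomy - p.nmnat_decay_delay_h
    if te <= 0:
        return 1.0
    return float(2.0 ** (-te / p.t_half_nmnat2))


def _consumption_k(t: float, scen: Scenario, p: PathwayParameters) -> float:
    k = p.k_cons_basal
    if scen.axotomized and t >= scen.t_axotomy:
        k += p.k_cons_sarm1 * scen.sarm1_activation
    return k


def _adenylate_decay(t: float, scen: Scenario, p: PathwayParameters) -> float:
    """Post-injury adenylate-pool decline.

    The energy failure is downstream of SARM1-driven NAD+ consumption, so
    axons in which SARM1 is absent or not engaged keep their adenylate pool
    (protected genotypes show no metabolite changes after axotomy).
    """
    sarm1_engaged = scen.sarm1_activation > 0 and p.k_cons_sarm1 > 0
    if scen.axotomized and t >= scen.t_axotomy and sarm1_engaged:
        return p.k_adenylate_decay
    return 0.0


@dataclass
class AxotomySchedule:
    """Piecewise time-dependent parameter schedule induced by axotomy."""

    scenario: Scenario
    params: PathwayParameters

    def nmnat_activity(self, t: float) -> float:
        return _nmnat_activity(t, self.scenario, self.params)

    def consumption_rate_constant(self, t: float) -> float:
        return _consumption_k(t, self.scenario, self.params)

    def adenylate_decay_rate(self, t: float) -> float:
        return _adenylate_decay(t, self.scenario, self.params)


def axotomize(params: PathwayParameters, scenario: Scenario) -> AxotomySchedule:
    """Return the post-injury parameter schedule for an axotomized scenario."""
    if not scenario.axotomized:
        raise ValueError("axotomize() requires an axotomized scenario")
    return AxotomySchedule(scenario, params)


def _rhs(t, y, scen: Scenario, p: PathwayParameters, closed: bool, atp0: float):
    nam = y[0:3]
    nmn = y[3:6]
    namn = y[6:9]
    nad = y[9:12]
    naad = y[12:15]
    atp = y[_ATP]
    nr = y[_NR]

    a = _nmnat_activity(t, scen, p)
    kc = _consumption_k(t, scen, p)
    k_aden = _adenylate_decay(t, scen, p)

    nam_tot = max(nam.sum(), 0.0)
    nad_tot = max(nad.sum(), 0.0)
    atp_f = min(max(atp / atp0, 0.0), 1.0) if atp0 > 0 else 1.0

    kih = p.ki_nampt_nad ** p.hill_nampt
    inhib = kih / (kih + nad_tot ** p.hill_nampt)
    v_nampt = p.vmax_nampt * nam_tot / (p.km_nampt_nam + nam_tot) * inhib * atp_f
    frac = nam / nam_tot if nam_tot > 0 else np.zeros(3)

    # NR -> NMN: linear at low NR, saturating at millimolar doses
    nr_pos = max(nr, 0.0)
    v_nrk = p.k_nrk * nr_pos * p.km_nrk / (p.km_nrk + nr_pos)

    dy = np.zeros(_NSTATE)
    # NMN
    dy[3:6] = (
        v_nampt * frac
        + p.k_synthetase * namn
        - (a * p.k_nmnat + p.k_deamidase + p.k_nmn_leak) * nmn
    )
    dy[3] += v_nrk
    # NaMN
    dy[6:9] = p.k_deamidase * nmn - (p.k_synthetase + a * p.k_nmnat_namn) * namn
    # NAD
    dy[9:12] = a * p.k_nmnat * nmn + p.k_nadsyn * naad - kc * nad
    dy[10] += p.k_exchange * nad[2]  # D4 -> D3
    dy[11] -= p.k_exchange * nad[2]
    # NaAD
    dy[12:15] = a * p.k_nmnat_namn * namn - p.k_nadsyn * naad
    # medium pools
    if closed:
        dy[0:3] = -v_nampt * frac + kc * nad  # cleavage returns ring-labeled Nam
        dy[_NR] = p.k_nmn_leak * nmn.sum() - v_nrk
    # adenylates
    if k_aden > 0:
        dy[_ATP] = -k_aden * atp
        dy[_ADP] = -k_aden * y[_ADP]
        dy[_AMP] = -k_aden * y[_AMP]
    return dy


@dataclass
class Trajectory:
    """Time-resolved concentrations of every species x isotopologue."""

    t: np.ndarray            # hours, strictly increasing
    y: np.ndarray            # shape (len(t), 19), uM
    scenario: Scenario
    params: PathwayParameters

    def get(self, species: str, label: str) -> np.ndarray:
        return self.y[:, _IDX[(species, label)]]

    def total(self, species: str) -> np.ndarray:
        i = 3 * SPECIES.index(species)
        return self.y[:, i : i + 3].sum(axis=1)

    def adenylate(self, which: str) -> np.ndarray:
        return self.y[:, {"ATP": _ATP, "ADP": _ADP, "AMP": _AMP, "NR": _NR}[which]]

    def heavy_nad(self) -> np.ndarray:
        """Combined D3 + D4 NAD+, the newly synthesized pool."""
        return self.get("NAD", "D3") + self.get("NAD", "D4")

    def at(self, time: float) -> np.ndarray:
        i = int(np.searchsorted(self.t, time))
        if i >= len(self.t) or abs(self.t[i] - time) > 1e-9:
            raise KeyError(f"time {time} h not on the trajectory grid")
        return self.y[i]

    def value(self, species: str, label: str, time: float) -> float:
        return float(self.at(time)[_IDX[(species, label)]])

    def moiety_sum(self) -> np.ndarray:
        """Total nicotinamide moiety (all five species, all labels, plus NR)."""
        return self.y[:, 0:15].sum(axis=1) + self.y[:, _NR]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (sp, lab), idx in _IDX.items():
            for ti, t in enumerate(self.t):
                rows.append((t, sp, lab, self.y[ti, idx], self.scenario.scenario_id))
        for name, idx in (("ATP", _ATP), ("ADP", _ADP), ("AMP", _AMP), ("NR", _NR)):
            for ti, t in enumerate(self.t):
                rows.append((t, name, "total", self.y[ti, idx], self.scenario.scenario_id))
        return pd.DataFrame(
            rows, columns=["time_h", "species", "label", "conc_uM", "scenario_id"]
        )


def _initial_state(scen: Scenario, p: PathwayParameters) -> np.ndarray:
    y0 = np.zeros(_NSTATE)
    y0[_IDX[("Nam", "D0")]] = p.nam_medium
    y0[_IDX[("NMN", "D0")]] = p.nmn_init
    y0[_IDX[("NaMN", "D0")]] = p.namn_init
    y0[_IDX[("NAD", "D0")]] = p.nad_init
    y0[_IDX[("NaAD", "D0")]] = p.naad_init
    y0[_ATP] = p.atp_init
    y0[_ADP] = p.adp_init
    y0[_AMP] = p.amp_init
    y0[_NR] = scen.nr_dose if scen.nr_dose > 0 else p.nr_medium
    return y0


def _integrate(scen, p, y0, t0, t1, t_eval, closed, atp0):
    """Integrate one smooth segment, returning states at t_eval plus endpoint."""
    if t1 - t0 <= 0:
        return np.empty((0, _NSTATE)), y0
    sol = solve_ivp(
        _rhs,
        (t0, t1),
        y0,
        method="LSODA",
        t_eval=None,
        dense_output=True,
        rtol=1e-8,
        atol=1e-10,
        args=(scen, p, closed, atp0),
    )
    if not sol.success:
        raise IntegrationError(f"ODE solver failed on [{t0}, {t1}]: {sol.message}")
    out = sol.sol(t_eval).T if len(t_eval) else np.empty((0, _NSTATE))
    return out, sol.y[:, -1].copy()


def _equilibrated_start(scen: Scenario, p: PathwayParameters, closed: bool) -> np.ndarray:
    """Burn in scenario enzymes (no tracer, no injury) to the scenario baseline."""
    base = Scenario(
        genotype_treatment=scen.genotype_treatment,
        axotomized=False,
        tracer_start=None,
        nr_dose=scen.nr_dose,
        duration=scen.equilibrate_h,
        nmnat_stable=scen.nmnat_stable,
        scenario_id=scen.scenario_id + "_burnin",
    )
    y0 = _initial_state(base, p)
    atp0 = y0[_ATP]
    _, yend = _integrate(base, p, y0, 0.0, scen.equilibrate_h, np.array([]), False, atp0)
    if closed:
        # reset medium pools: burn-in is always run against the open reservoir
        yend[0:3] = [p.nam_medium, 0.0, 0.0]
    return yend


def simulate(
    scenario: Scenario,
    params: PathwayParameters,
    t_grid: np.ndarray,
    *,
    closed_medium: bool = False,
) -> Trajectory:
    """Integrate the pathway ODEs for one scenario and sample them on t_grid."""
    params.validate()
    scenario.validate()
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 1 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be a strictly increasing 1-D time vector")
    if t_grid[0] < 0:
        raise ValueError("t_grid must start at or after 0 h")

    if scenario.equilibrate_h > 0:
        y0 = _equilibrated_start(scenario, params, closed_medium)
    else:
        y0 = _initial_state(scenario, params)
    atp0 = y0[_ATP] if y0[_ATP] > 0 else params.atp_init

    t_end = max(t_grid[-1], scenario.duration)
    breaks = {0.0, t_end}
    if scenario.tracer_start is not None:
        breaks.add(scenario.tracer_start)
    if scenario.axotomized:
        breaks.add(scenario.t_axotomy)
        if not scenario.nmnat_stable:
            breaks.add(scenario.t_axotomy + params.nmnat_decay_delay_h)
    breaks = sorted(b for b in breaks if 0.0 <= b <= t_end)

    out = np.empty((len(t_grid), _NSTATE))
    filled = np.zeros(len(t_grid), dtype=bool)
    y = y0.copy()
    for t0, t1 in zip(breaks[:-1], breaks[1:]):
        if scenario.tracer_start is not None and abs(t0 - scenario.tracer_start) < 1e-12:
            y[_IDX[("Nam", "D4")]] += params.d4nam_medium
        # grid points inside (t0, t1]; t=0 handled below
        mask = (~filled) & (t_grid > t0 + 1e-12) & (t_grid <= t1 + 1e-12)
        seg_eval = np.clip(t_grid[mask], t0, t1)
        y_seg, y = _integrate(scenario, params, y, t0, t1, seg_eval, closed_medium, atp0)
        out[mask] = y_seg
        filled[mask] = True
    if scenario.tracer_start is not None and abs(breaks[-1] - scenario.tracer_start) < 1e-12:
        y[_IDX[("Nam", "D4")]] += params.d4nam_medium
    mask0 = (~filled) & (np.abs(t_grid - breaks[0]) <= 1e-12)
    if mask0.any():
        start = y0.copy()
        if scenario.tracer_start is not None and scenario.tracer_start <= 1e-12:
            start[_IDX[("Nam", "D4")]] += params.d4nam_medium
        out[mask0] = start
        filled[mask0] = True
    if not filled.all():
        raise IntegrationError("internal error: grid points not covered by segments")

    if out.min() < _NEG_TOL:
        raise IntegrationError(
            f"negative concentration beyond tolerance: min={out.min():.3e} uM"
        )
    out[out < 0] = 0.0
    return Trajectory(t=t_grid, y=out, scenario=scenario, params=params)
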