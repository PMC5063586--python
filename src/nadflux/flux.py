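"""NAD+ flux estimators on labeled measurement tables.

The assay: D4-nicotinamide is added to the medium at t0; newly synthesized
NAD+ appears as heavy (D3 + D4) NAD+ while pre-existing NAD+ stays light
(D0).  Rates are interval averages expressed as percent of the reference
pool per hour -- exactly what the bench protocol computes -- not
instantaneous rate constants:

    consumption = 100 * (L(t0) - L(t1)) / (L(t0) * (t1 - t0)),  t1 = t0 + 4 h
    synthesis   = 100 * (H(t1) - H(t0)) / (T(t0) * (t1 - t0)),  t1 = t0 + 2 h

where L is light NAD+, H the combined heavy pool, and T total NAD+ at t0.
Wells are the replication unit; group mean and s.d. are taken over wells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FluxEstimate",
    "FoldIncrease",
    "combine_heavy",
    "normalize_to_atp",
    "consumption_rate",
    "synthesis_rate",
    "synthesis_fold_increase",
]


@dataclass
class FluxEstimate:
    """A per-cohort interval-average rate in percent per hour."""

    scenario_id: str
    kind: str                      # "synthesis" | "consumption"
    rate_mean: float               # % per hour, mean over wells
    rate_sd: float                 # s.d. over wells
    interval: tuple                # (t0, t1) in hours
    normalization: str = "none"    # "none" | "ATP"
    per_well: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.per_well)


@dataclass
class FoldIncrease:
    fold: float
    sd: float
    defined: bool = True


def combine_heavy(d3, d4):
    """Combined heavy NAD+ (the newly synthesized pool): D3 + D4."""
    d3 = np.asarray(d3, dtype=float)
    d4 = np.asarray(d4, dtype=float)
    if np.any(d3 < 0) or np.any(d4 < 0):
        raise ValueError("isotopologue abundances must be non-negative")
    out = d3 + d4
    return float(out) if out.ndim == 0 else out


def _valid(table: pd.DataFrame) -> pd.DataFrame:
    return table[~table["censored"].astype(bool)]


def normalize_to_atp(table: pd.DataFrame) -> pd.DataFrame:
    """Divide every NAD+ row by the same-well, same-time ATP value.

    Wells whose ATP measurement is censored or non-positive are dropped with
    a logged warning.  Returned NAD+ values are dimensionless ratios.
    """
    atp = _valid(table[(table.metabolite == "ATP")])
    if atp.empty:
        raise ValueError("no uncensored ATP rows present")
    atp_map = atp.set_index(["scenario_id", "well_id", "time_h"])["conc_uM"]

    out = table.copy()
    nad = out.metabolite == "NAD"
    keys = list(zip(out.scenario_id, out.well_id, out.time_h))
    denom = np.array([atp_map.get(k, np.nan) for k in keys])
    bad = nad & (~np.isfinite(denom) | (denom <= 0))
    if bad.any():
        dropped = out.loc[bad, ["scenario_id", "well_id", "time_h"]].drop_duplicates()
        for r in dropped.itertuples(index=False):
            logger.warning(
                "dropping well %s (scenario %s, t=%g h): ATP missing or <= LOD",
                r.well_id, r.scenario_id, r.time_h,
            )
    out.loc[nad, "conc_uM"] = out.loc[nad, "conc_uM"] / denom[nad.to_numpy()]
    return out[~bad.to_numpy()].reset_index(drop=True)


def _nad_pivot(table: pd.DataFrame, label, times) -> pd.DataFrame:
    """Per-well NAD+ values of the given label(s), wells x times."""
    labels = (label,) if isinstance(label, str) else tuple(label)
    sub = _valid(table[(table.metabolite == "NAD") & (table.label.isin(labels))])
    sub = sub[sub.time_h.isin(times)]
    return sub.pivot_table(
        index="well_id", columns="time_h", values="conc_uM", aggfunc="sum"
    )


def consumption_rate(
    table: pd.DataFrame,
    t0: float,
    t1: float | None = None,
    *,
    normalization: str = "none",
    scenario_id: str | None = None,
) -> FluxEstimate:
    """Interval-average NAD+ consumption from the loss of light NAD+.

    Per well: 100 * (L(t0) - L(t1)) / (L(t0) * (t1 - t0)).  Wells whose
    light NAD+ is censored at either end, or zero at t0, are excluded.
    """
    if t1 is None:
        t1 = t0 + 4.0
    if normalization == "ATP":
        table = normalize_to_atp(table)
    elif normalization != "none":
        raise ValueError("normalization must be 'none' or 'ATP'")
    if scenario_id is not None:
        table = table[table.scenario_id == scenario_id]
    piv = _nad_pivot(table, "D0", (t0, t1)).dropna()
    piv = piv[piv[t0] > 0]
    if piv.empty:
        raise ValueError("no wells with uncensored, positive light NAD+ at t0")
    rates = 100.0 * (piv[t0] - piv[t1]) / (piv[t0] * (t1 - t0))
    sid = scenario_id or (table.scenario_id.iloc[0] if len(table) else "")
    return FluxEstimate(
        scenario_id=sid,
        kind="consumption",
        rate_mean=float(rates.mean()),
        rate_sd=float(rates.std(ddof=1)) if len(rates) > 1 else 0.0,
        interval=(t0, t1),
        normalization=normalization,
        per_well=rates.to_dict(),
    )


def synthesis_rate(
    table: pd.DataFrame,
    t0: float,
    t1: float | None = None,
    *,
    normalization: str = "none",
    scenario_id: str | None = None,
) -> FluxEstimate:
    """Interval-average NAD+ synthesis from the gain of heavy (D3+D4) NAD+.

    Per well: 100 * (H(t1) - H(t0)) / (T(t0) * (t1 - t0)) where T is total
    NAD+ at t0 (H(t0) is 0 when the tracer is added at t0).
    """
    if t1 is None:
        t1 = t0 + 2.0
    if normalization == "ATP":
        table = normalize_to_atp(table)
    elif normalization != "none":
        raise ValueError("normalization must be 'none' or 'ATP'")
    if scenario_id is not None:
        table = table[table.scenario_id == scenario_id]
    heavy = _nad_pivot(table, ("D3", "D4"), (t0, t1)).dropna()
    total = _nad_pivot(table, "total", (t0,)).dropna()
    wells = heavy.index.intersection(total.index)
    total = total.loc[wells]
    wells = total[total[t0] > 0].index
    if len(wells) == 0:
        raise ValueError("no wells with uncensored, positive total NAD+ at t0")
    rates = (
        100.0
        * (heavy.loc[wells, t1] - heavy.loc[wells, t0])
        / (total.loc[wells, t0] * (t1 - t0))
    )
    sid = scenario_id or (table.scenario_id.iloc[0] if len(table) else "")
    return FluxEstimate(
        scenario_id=sid,
        kind="synthesis",
        rate_mean=float(rates.mean()),
        rate_sd=float(rates.std(ddof=1)) if len(rates) > 1 else 0.0,
        interval=(t0, t1),
        normalization=normalization,
        per_well=rates.to_dict(),
    )


def synthesis_fold_increase(cut: FluxEstimate, uncut: FluxEstimate) -> FoldIncrease:
    """Fold change of synthesis in cut vs uncut axons, with propagated spread."""
    if uncut.rate_mean <= 0:
        return FoldIncrease(fold=float("nan"), sd=float("nan"), defined=False)
    fold = cut.rate_mean / uncut.rate_mean
    rel = 0.0
    if cut.rate_mean != 0:
        rel += (cut.rate_sd / cut.rate_mean) ** 2
    rel += (uncut.rate_sd / uncut.rate_mean) ** 2
    return FoldIncrease(fold=float(fold), sd=float(abs(fold) * np.sqrt(rel)))
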