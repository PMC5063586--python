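"""Relative steady-state metabolite analyses.

Fold-changes of metabolite group means against a reference group (control
for NMN/NAD+, the deamidase-expressing group for NaMN/NaAD, whose levels
are undetectable in control neurons), plus the adenylate-pool bookkeeping
used to show that the post-injury rise of NMN/adenylate ratios reflects
adenylate decline rather than NMN accumulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RelativeLevels",
    "relative_levels",
    "adenylate_pool",
    "nmn_over_adenylate",
]

_ADENYLATES = ("ATP", "ADP", "AMP")


@dataclass
class RelativeLevels:
    """Per-group fold-changes of one metabolite against a reference group."""

    metabolite: str
    reference: str
    table: pd.DataFrame = field(repr=False)  # group, fold_mean, fold_sd, n

    def fold(self, group: str) -> float:
        row = self.table[self.table.group == group]
        if row.empty:
            raise KeyError(f"group {group!r} not present")
        return float(row.fold_mean.iloc[0])


def _group_values(table: pd.DataFrame, metabolite: str, label: str) -> pd.DataFrame:
    sub = table[
        (table.metabolite == metabolite)
        & (table.label == label)
        & (~table.censored.astype(bool))
    ]
    return sub


def relative_levels(
    table: pd.DataFrame,
    metabolite: str,
    reference_group: str,
    *,
    label: str = "total",
    group_col: str = "genotype_treatment",
    time_h: float | None = None,
) -> RelativeLevels:
    """Group means of one metabolite divided by the reference-group mean.

    Dispersion is propagated from per-well values (s.d. of well/reference-mean
    ratios), matching the figure convention of normalizing to a group mean.
    """
    sub = _group_values(table, metabolite, label)
    if time_h is not None:
        sub = sub[sub.time_h == time_h]
    if sub.empty:
        raise ValueError(f"no uncensored rows for {metabolite} ({label})")
    ref = sub[sub[group_col] == reference_group]
    if ref.empty:
        raise ValueError(f"reference group {reference_group!r} absent")
    ref_mean = ref.conc_uM.mean()
    if not ref_mean > 0:
        raise ValueError("reference group mean must be positive")
    rows = []
    for group, g in sub.groupby(group_col):
        ratios = g.conc_uM / ref_mean
        rows.append(
            (
                group,
                float(g.conc_uM.mean() / ref_mean),
                float(ratios.std(ddof=1)) if len(ratios) > 1 else 0.0,
                int(len(ratios)),
            )
        )
    out = pd.DataFrame(rows, columns=["group", "fold_mean", "fold_sd", "n"])
    return RelativeLevels(metabolite=metabolite, reference=reference_group, table=out)


def adenylate_pool(table: pd.DataFrame) -> pd.DataFrame:
    """Per-well adenylate pool AxP = ATP + ADP + AMP (uM).

    Wells missing any of the three adenylates (absent or censored) are
    dropped.  Returns columns scenario_id, well_id, time_h, axp_uM.
    """
    sub = table[
        table.metabolite.isin(_ADENYLATES) & (~table.censored.astype(bool))
    ]
    piv = sub.pivot_table(
        index=["scenario_id", "well_id", "time_h"],
        columns="metabolite",
        values="conc_uM",
    ).reindex(columns=list(_ADENYLATES))
    piv = piv.dropna(subset=list(_ADENYLATES))
    piv["axp_uM"] = piv[list(_ADENYLATES)].sum(axis=1)
    return piv.reset_index()[["scenario_id", "well_id", "time_h", "axp_uM"]]


def nmn_over_adenylate(table: pd.DataFrame) -> pd.DataFrame:
    """Per-well, per-time NMN / (ATP+ADP+AMP) ratio series.

    Wells whose adenylate pool is censored are excluded.  Returns columns
    scenario_id, well_id, time_h, nmn_uM, axp_uM, ratio.
    """
    axp = adenylate_pool(table)
    nmn = table[
        (table.metabolite == "NMN")
        & (table.label == "total")
        & (~table.censored.astype(bool))
    ][["scenario_id", "well_id", "time_h", "conc_uM"]].rename(
        columns={"conc_uM": "nmn_uM"}
    )
    merged = nmn.merge(axp, on=["scenario_id", "well_id", "time_h"], how="inner")
    merged = merged[merged.axp_uM > 0]
    merged["ratio"] = merged.nmn_uM / merged.axp_uM
    return merged.reset_index(drop=True)
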