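"""Flux estimators: closed-form oracles, worked examples, recovery, epistasis."""

import numpy as np
import pandas as pd
import pytest

from nadflux import (
    FluxEstimate,
    combine_heavy,
    consumption_rate,
    normalize_to_atp,
    synthesis_fold_increase,
    synthesis_rate,
)
from tests.conftest import make_flux_table


def _table(rows):
    """rows: (well, time, metabolite, label, conc)"""
    return pd.DataFrame(
        [("s", "control", t, w, m, l, c, False) for w, t, m, l, c in rows],
        columns=["scenario_id", "genotype_treatment", "time_h", "well_id",
                 "metabolite", "label", "conc_uM", "censored"],
    )


class TestCombineHeavy:
    def test_empty_and_sum(self):
        assert combine_heavy(0.0, 0.0) == 0.0
        assert combine_heavy(0.2, 0.5) == pytest.approx(0.7)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            combine_heavy(-0.1, 0.5)

    def test_combined_heavy_equals_trajectory_label_accounting(self, control_uninjured):
        """With C4 exchange on, D3+D4 at 2 h equals total synthesized label."""
        traj, tab = control_uninjured
        measured = synthesis_rate(tab, 0.0)
        i2 = int(np.searchsorted(traj.t, 2.0))
        h2 = traj.heavy_nad()[i2]
        t0 = traj.total("NAD")[0]
        assert measured.rate_mean == pytest.approx(100 * h2 / (t0 * 2.0), rel=1e-9)


class TestConsumptionRate:
    def test_constant_pool_zero_rate(self):
        rows = [(f"w{i}", t, "NAD", "D0", 0.8) for i in range(3) for t in (0.0, 4.0)]
        est = consumption_rate(_table(rows), 0.0)
        assert est.rate_mean == pytest.approx(0.0, abs=1e-12)

    def test_exponential_closed_form(self):
        """L(t) = L0 e^(-kt), 4 h window -> 100 (1 - e^(-4k)) / 4 exactly."""
        k = 0.25
        rows = [("w1", t, "NAD", "D0", 2.0 * np.exp(-k * t)) for t in (0.0, 4.0)]
        est = consumption_rate(_table(rows), 0.0)
        expected = 100 * (1 - np.exp(-4 * k)) / 4
        assert est.rate_mean == pytest.approx(expected, abs=1e-8)
        assert expected == pytest.approx(15.8, abs=0.05)

    @pytest.mark.parametrize("k", [1e-6, 1e-4, 1e-3])
    def test_small_rate_linearization(self, k):
        rows = [("w1", t, "NAD", "D0", np.exp(-k * t)) for t in (0.0, 4.0)]
        est = consumption_rate(_table(rows), 0.0)
        assert est.rate_mean == pytest.approx(100 * k, rel=4 * k)

    def test_censored_baseline_excluded(self):
        rows = [("w1", 0.0, "NAD", "D0", 1.0), ("w1", 4.0, "NAD", "D0", 0.5),
                ("w2", 4.0, "NAD", "D0", 0.4)]
        tab = _table(rows)
        tab = pd.concat([tab, _table([("w2", 0.0, "NAD", "D0", 1.0)])])
        tab.loc[(tab.well_id == "w2") & (tab.time_h == 0.0), "censored"] = True
        est = consumption_rate(tab, 0.0)
        assert est.n == 1


class TestSynthesisRate:
    def test_no_tracer_zero_rate(self):
        rows = []
        for w in ("w1", "w2"):
            for t in (0.0, 2.0):
                rows += [(w, t, "NAD", "D3", 0.0), (w, t, "NAD", "D4", 0.0),
                         (w, t, "NAD", "total", 1.0)]
        est = synthesis_rate(_table(rows), 0.0)
        assert est.rate_mean == 0.0

    def test_formula_arithmetic(self):
        """H(2) = 0.14 T(0) -> 7.0 % per hour."""
        rows = [("w1", 0.0, "NAD", "D3", 0.0), ("w1", 0.0, "NAD", "D4", 0.0),
                ("w1", 0.0, "NAD", "total", 2.0),
                ("w1", 2.0, "NAD", "D3", 0.08), ("w1", 2.0, "NAD", "D4", 0.2)]
        est = synthesis_rate(_table(rows), 0.0)
        assert est.rate_mean == pytest.approx(7.0)


class TestAtpNormalization:
    def test_unit_atp_is_identity(self):
        rows = [("w1", 0.0, "NAD", "D0", 0.5), ("w1", 0.0, "ATP", "total", 1.0)]
        out = normalize_to_atp(_table(rows))
        assert out[out.metabolite == "NAD"].conc_uM.iloc[0] == pytest.approx(0.5)

    def test_division(self):
        rows = [("w1", 0.0, "NAD", "D0", 0.5), ("w1", 0.0, "ATP", "total", 2.0)]
        out = normalize_to_atp(_table(rows))
        assert out[out.metabolite == "NAD"].conc_uM.iloc[0] == pytest.approx(0.25)

    def test_missing_atp_well_dropped(self):
        rows = [("w1", 0.0, "NAD", "D0", 0.5), ("w1", 0.0, "ATP", "total", 2.0),
                ("w2", 0.0, "NAD", "D0", 0.4)]
        out = normalize_to_atp(_table(rows))
        assert "w2" not in out[out.metabolite == "NAD"].well_id.values

    def test_uninjured_normalized_and_raw_rates_agree(self):
        """ATP is constant in uninjured axons, so normalization is neutral."""
        _, tab = make_flux_table("control", False, n_wells=9, noise_cv=0.15, seed=11)
        raw = consumption_rate(tab, 0.0)
        norm = consumption_rate(tab, 0.0, normalization="ATP")
        pooled = np.sqrt(raw.rate_sd**2 + norm.rate_sd**2)
        assert abs(raw.rate_mean - norm.rate_mean) < pooled


class TestFoldIncrease:
    def _est(self, mean, sd=0.0):
        return FluxEstimate("s", "synthesis", mean, sd, (0.0, 2.0))

    def test_identity(self):
        f = synthesis_fold_increase(self._est(5.0), self._est(5.0))
        assert f.fold == pytest.approx(1.0)

    def test_reported_control_ratio(self):
        """Printed post-axotomy 14.0 vs uncut 6.6 %/h -> ~2.12-fold."""
        f = synthesis_fold_increase(self._est(14.0, 6.9), self._est(6.6, 3.7))
        assert f.fold == pytest.approx(14.0 / 6.6, rel=1e-12)
        assert f.fold == pytest.approx(2.12, abs=0.01)
        assert f.sd > 0

    def test_zero_uncut_flagged_undefined(self):
        f = synthesis_fold_increase(self._est(5.0), self._est(0.0))
        assert not f.defined

    def test_sarm1_ko_fold_near_unity(self):
        _, cut = make_flux_table("SARM1_KO", True, n_wells=9, noise_cv=0.15, seed=21)
        _, uncut = make_flux_table("SARM1_KO", False, n_wells=9, noise_cv=0.15, seed=22)
        f = synthesis_fold_increase(synthesis_rate(cut, 0.0), synthesis_rate(uncut, 0.0))
        assert f.fold == pytest.approx(1.0, abs=2 * f.sd + 0.15)


class TestPipelineProperties:
    @pytest.mark.parametrize("name,axo", [
        ("control", False), ("control", True),
        ("SARM1_KO", True), ("cytNMNAT1", True),
    ])
    def test_parameter_recovery_noisy_vs_noiseless(self, name, axo):
        """n = 9, CV 0.15 cohort means land within 15% of the noiseless value."""
        _, clean = make_flux_table(name, axo)
        _, noisy = make_flux_table(name, axo, n_wells=9, noise_cv=0.15, seed=31)
        ref = consumption_rate(clean, 0.0).rate_mean
        got = consumption_rate(noisy, 0.0).rate_mean
        assert got == pytest.approx(ref, rel=0.15)

    def test_uninjured_steady_state_closure(self):
        _, tab = make_flux_table("control", False, n_wells=9, noise_cv=0.15, seed=41)
        syn = synthesis_rate(tab, 0.0)
        cons = consumption_rate(tab, 0.0)
        pooled = np.sqrt(syn.rate_sd**2 + cons.rate_sd**2)
        assert abs(syn.rate_mean - cons.rate_mean) < pooled

    def test_sarm1_epistasis_ordering(self):
        """Post-axotomy consumption: control >> protected genotypes and KO."""
        rates = {}
        for name in ("control", "cytNMNAT1", "NMN_DD", "SARM1_KO"):
            _, tab = make_flux_table(name, True, n_wells=9, noise_cv=0.15, seed=51)
            rates[name] = consumption_rate(tab, 0.0).rate_mean
        assert rates["control"] > rates["cytNMNAT1"]
        assert rates["control"] > rates["NMN_DD"]
        assert rates["control"] > rates["SARM1_KO"]
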