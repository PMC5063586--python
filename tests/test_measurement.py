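"""Measurement layer: m/z arithmetic, standard curves, noisy quantitation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nadflux import (
    SamplingDesign,
    build_scenario,
    generate_cohort,
    load_mrm_transitions,
    make_standard_curve,
    nominal_precursor_mz,
    quantify,
    simulate,
)

NAD_FORMULA = "C21H27N7O14P2"


class TestPrecursorMz:
    @pytest.mark.parametrize(
        "formula,n_d,expected",
        [
            (NAD_FORMULA, 0, 664),   # NAD+ [M+H]+
            (NAD_FORMULA, 4, 668),   # D4-NAD+
            (NAD_FORMULA, 3, 667),   # D3-NAD+
            ("C11H15N2O8P", 0, 335),  # NMN
            ("C11H14NO9P", 0, 336),   # NaMN
        ],
    )
    def test_known_metabolites(self, formula, n_d, expected):
        assert nominal_precursor_mz(formula, n_d) == expected

    @given(n=st.integers(min_value=0, max_value=10))
    def test_each_deuterium_adds_one(self, n):
        base = nominal_precursor_mz(NAD_FORMULA, 0)
        assert nominal_precursor_mz(NAD_FORMULA, n) == base + n

    def test_unknown_element_rejected(self):
        with pytest.raises(ValueError):
            nominal_precursor_mz("Xx2H4")

    def test_table_consistency(self):
        table = {t.metabolite: t for t in load_mrm_transitions()}
        assert table["NAD"].ms1_mz == 664
        assert table["D4-NAD"].ms1_mz == 668
        assert all(t.ms1_mz > t.ms2_mz > 0 for t in table.values())


class TestStandardCurve:
    def test_noiseless_slope_recovers_response_factor(self):
        cal = make_standard_curve("NAD", top=25.0, n_levels=8, noise_cv=0.0,
                                  seed=0, response_factor=3.7, blank_sd=0.0,
                                  n_blanks=0)
        assert cal.slope == pytest.approx(3.7, abs=1e-12)
        assert cal.intercept == pytest.approx(0.0, abs=1e-9)

    def test_serial_dilution_levels(self):
        cal = make_standard_curve("NAD", top=25.0, n_levels=8, noise_cv=0.0, seed=0)
        lowest = min(c for c, _ in cal.levels)
        assert lowest == pytest.approx(25.0 / 2**7)

    def test_mean_slope_unbiased_over_seeds(self):
        slopes = [
            make_standard_curve("NMN", top=25.0, n_levels=8, noise_cv=0.1,
                                seed=s, response_factor=2.0).slope
            for s in range(500)
        ]
        assert np.mean(slopes) == pytest.approx(2.0, rel=0.01)

    def test_degenerate_curve_rejected(self):
        with pytest.raises(ValueError):
            make_standard_curve("NAD", top=25.0, n_levels=3, noise_cv=0.0,
                                seed=0, response_factor=0.0, blank_sd=0.0,
                                n_blanks=0)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            make_standard_curve("NAD", top=-1.0, n_levels=8, noise_cv=0.0, seed=0)
        with pytest.raises(ValueError):
            make_standard_curve("NAD", top=25.0, n_levels=2, noise_cv=0.0, seed=0)


@pytest.fixture(scope="module")
def short_traj():
    scen, params = build_scenario("control", {}, tracer_start=0.0, duration=4.0)
    return simulate(scen, params, np.array([0.0, 1.0, 2.0, 3.0, 4.0]))


class TestQuantify:
    def test_noiseless_identity(self, short_traj):
        design = SamplingDesign(times=(0.0, 2.0), n_wells=1, noise_cv=0.0, seed=0)
        tab = quantify(short_traj, design)
        row = tab[(tab.metabolite == "NAD") & (tab.label == "D0") & (tab.time_h == 2.0)]
        assert row.conc_uM.iloc[0] == pytest.approx(
            short_traj.value("NAD", "D0", 2.0), rel=1e-12
        )
        atp = tab[(tab.metabolite == "ATP") & (tab.time_h == 0.0)]
        assert atp.conc_uM.iloc[0] == pytest.approx(5.0)

    def test_row_counts(self, short_traj):
        design = SamplingDesign(times=(0.0, 1.0, 2.0, 3.0, 4.0), n_wells=3,
                                noise_cv=0.0, seed=0)
        tab = quantify(short_traj, design)
        per_label = tab.groupby(["metabolite", "label"]).size()
        assert (per_label == 15).all()  # 3 wells x 5 times

    def test_cv_recovery(self, short_traj):
        design = SamplingDesign(times=(2.0,), n_wells=500, noise_cv=0.15, seed=42)
        tab = quantify(short_traj, design)
        vals = tab[(tab.metabolite == "ATP")].conc_uM
        cv = vals.std(ddof=1) / vals.mean()
        assert 0.13 <= cv <= 0.17

    def test_label_rows_sum_to_total(self, short_traj):
        design = SamplingDesign(times=(2.0,), n_wells=5, noise_cv=0.2, seed=3)
        tab = quantify(short_traj, design)
        nad = tab[tab.metabolite == "NAD"]
        for well, g in nad.groupby("well_id"):
            parts = g[g.label.isin(["D0", "D3", "D4"])].conc_uM.sum()
            total = g[g.label == "total"].conc_uM.iloc[0]
            assert total == pytest.approx(parts, rel=1e-12)

    def test_censoring_monotone_in_lod(self, short_traj):
        from nadflux.measurement import Calibration

        def table_with_lod(lod):
            cal = {"NMN": Calibration("NMN", [], 1.0, 0.0, 25.0, lod)}
            design = SamplingDesign(times=(0.0, 2.0), n_wells=10, noise_cv=0.1, seed=9)
            t = quantify(short_traj, design, cal)
            return (~t[t.metabolite == "NMN"].censored).sum()

        uncensored = [table_with_lod(l) for l in (1.0, 0.3, 0.05, 0.0)]
        assert all(a <= b for a, b in zip(uncensored, uncensored[1:]))

    def test_time_off_grid_rejected(self, short_traj):
        with pytest.raises(KeyError):
            quantify(short_traj, SamplingDesign(times=(1.5,), n_wells=1,
                                                noise_cv=0.0, seed=0))


class TestGenerateCohort:
    def _pairs(self):
        return [
            build_scenario("control", {}, tracer_start=0.0, duration=6.0),
            build_scenario("SARM1_KO", {}, axotomized=True, t_axotomy=0.0,
                           tracer_start=0.0, duration=6.0),
        ]

    def test_same_seed_identical(self):
        design = SamplingDesign(times=(0.0, 2.0, 4.0), n_wells=3, noise_cv=0.15, seed=0)
        a = generate_cohort(self._pairs(), design, seed=123)
        b = generate_cohort(self._pairs(), design, seed=123)
        pd.testing.assert_frame_equal(a, b)

    def test_different_seed_differs(self):
        design = SamplingDesign(times=(0.0, 2.0), n_wells=3, noise_cv=0.15, seed=0)
        a = generate_cohort(self._pairs(), design, seed=1)
        b = generate_cohort(self._pairs(), design, seed=2)
        assert not a.conc_uM.equals(b.conc_uM)

    def test_control_steady_state_within_noise(self):
        design = SamplingDesign(times=(0.0, 6.0), n_wells=9, noise_cv=0.15, seed=5)
        tab = generate_cohort(self._pairs()[:1], design, seed=5)
        nad = tab[(tab.metabolite == "NAD") & (tab.label == "total")]
        m0 = nad[nad.time_h == 0.0].conc_uM
        m6 = nad[nad.time_h == 6.0].conc_uM
        pooled_se = np.sqrt(m0.var(ddof=1) / len(m0) + m6.var(ddof=1) / len(m6))
        assert abs(m0.mean() - m6.mean()) < 3 * pooled_se

    def test_sarm1_ko_light_nad_spared_after_injury(self):
        """KO axons lose light NAD+ at the basal rate only; injured controls
        lose most of it within 4 h."""
        design = SamplingDesign(times=(0.0, 4.0), n_wells=9, noise_cv=0.15, seed=7)
        ctrl_cut = build_scenario("control", {}, axotomized=True, t_axotomy=0.0,
                                  tracer_start=0.0, duration=6.0)
        tab = generate_cohort([self._pairs()[1], ctrl_cut], design, seed=7)
        light = tab[(tab.metabolite == "NAD") & (tab.label == "D0")]

        def mean(sid, t):
            sub = light[(light.scenario_id == sid) & (light.time_h == t)]
            return sub.conc_uM.mean()

        ko_frac = mean("SARM1_KO_axotomy", 4.0) / mean("SARM1_KO_axotomy", 0.0)
        ctrl_frac = mean("control_axotomy", 4.0) / mean("control_axotomy", 0.0)
        assert ko_frac > 2 * ctrl_frac       # injury-induced loss requires SARM1
        assert 0.4 < ko_frac < 0.85          # basal turnover still proceeds

    def test_empty_scenarios_rejected(self):
        design = SamplingDesign(times=(0.0,), n_wells=1, noise_cv=0.0, seed=0)
        with pytest.raises(ValueError):
            generate_cohort([], design, seed=0)
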