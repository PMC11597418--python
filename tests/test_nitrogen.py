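"""Surface-water N pools: fertilization, decay, partitioning, runoff loss."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import paddyn as pn
from paddyn.management import FertEvent, green_manure, split_fertilizer, straw_return
from paddyn.nitrogen import (
    NRateParams,
    NitrogenError,
    SurfaceNState,
    apply_fertilization,
    partition_forms,
    runoff_n_loss,
    simulate_season,
    step_nitrogen,
)
from paddyn.water import IrrigationPolicy, SoilHydroParams


class TestFertilization:
    def test_unit_oracle_concentration_jump(self):
        """1 kg N/ha dissolved in 1 mm of water is 100 mg/L, so 30% of
        60 kg/ha into 50 mm raises NH4 by 36 mg/L."""
        state = apply_fertilization(SurfaceNState(), FertEvent(1, 60.0, f_surf=0.3), 50.0)
        assert state.concentrations(50.0)["nh4"] == pytest.approx(36.0)

    def test_zero_amount_is_identity(self):
        s0 = SurfaceNState(m_nh4=1.0)
        s1 = apply_fertilization(s0, FertEvent(1, 0.0), 50.0)
        assert s1 == s0

    def test_two_applications_add_linearly(self):
        ev = FertEvent(1, 40.0, f_surf=0.5)
        once = apply_fertilization(SurfaceNState(), ev, 50.0)
        twice = apply_fertilization(once, ev, 50.0)
        assert twice.m_nh4 == pytest.approx(2 * once.m_nh4)

    def test_dry_field_application_rejected(self):
        with pytest.raises(NitrogenError):
            apply_fertilization(SurfaceNState(), FertEvent(1, 60.0), 0.0)


class TestStep:
    def test_exponential_decay_oracle(self):
        rates = NRateParams(k_nh4=0.3, nitrif_frac=0.0)
        state, _ = step_nitrogen(SurfaceNState(m_nh4=10.0), rates)
        assert state.m_nh4 == pytest.approx(10.0 * np.exp(-0.3))

    def test_zero_rates_conserve_mass(self):
        rates = NRateParams(k_nh4=0, k_no3=0, k_don=0, k_pn=0, nitrif_frac=0)
        s0 = SurfaceNState(1.0, 2.0, 3.0, 4.0)
        s1, sinks = step_nitrogen(s0, rates)
        assert s1 == s0
        assert sinks["decay_loss"] == 0

    def test_dilution_halves_concentration(self):
        """Doubling the depth with no N fluxes halves every concentration:
        concentration is derived from mass, never integrated."""
        state = SurfaceNState(2.0, 1.0, 0.5, 0.25)
        c1 = state.concentrations(50.0)
        c2 = state.concentrations(100.0)
        for k in c1:
            assert c2[k] == pytest.approx(c1[k] / 2)

    def test_nitrification_routes_mass_to_no3(self):
        rates = NRateParams(k_nh4=0.5, k_no3=0.0, nitrif_frac=0.2)
        state, sinks = step_nitrogen(SurfaceNState(m_nh4=10.0), rates)
        removed = 10.0 * (1 - np.exp(-0.5))
        assert state.m_no3 == pytest.approx(0.2 * removed)
        assert sinks["nitrified"] == pytest.approx(0.2 * removed)


class TestPartition:
    def test_difference_method_sums(self):
        din, dtn, tn = partition_forms(5, 0.5, 2, 1.5)
        assert (din, dtn, tn) == (5.5, 7.5, 9.0)
        assert partition_forms(0, 0, 0, 0) == (0, 0, 0)

    @given(
        st.tuples(*[st.floats(0, 1e3) for _ in range(4)])
    )
    @settings(max_examples=200, deadline=None)
    def test_difference_method_round_trips(self, c):
        """Assembling TN/DTN/DIN from the parts and inverting by differences
        recovers the parts exactly (the algebraic inverse oracle)."""
        nh4, no3, don, pn = c
        din, dtn, tn = partition_forms(nh4, no3, don, pn)
        assert tn - dtn == pytest.approx(pn, abs=1e-9 * max(1, tn))
        assert dtn - din == pytest.approx(don, abs=1e-9 * max(1, tn))
        assert din - nh4 == pytest.approx(no3, abs=1e-9 * max(1, tn))
        assert tn >= dtn >= din >= nh4


class TestRunoffLoss:
    def test_ten_to_minus_two_factor(self):
        event = runoff_n_loss({"tn": 10.0}, 50.0)
        assert event.loss["tn"] == pytest.approx(5.0)

    def test_zero_runoff_zero_loss(self):
        event = runoff_n_loss({"tn": 99.0, "din": 5.0}, 0.0)
        assert all(v == 0 for v in event.loss.values())

    def test_seasonal_total_matches_brute_force(self):
        """Accumulated seasonal loss equals an independent Σ Ci·Rf·10⁻²."""
        rng = np.random.default_rng(5)
        loss = pn.SeasonNLoss()
        concs, rfs = rng.uniform(0, 30, 20), rng.uniform(0, 60, 20)
        for i, (c, rf) in enumerate(zip(concs, rfs)):
            loss.add(runoff_n_loss({"tn": c}, rf, day=i))
        brute = sum(c * rf * 1e-2 for c, rf in zip(concs, rfs))
        assert loss.totals["tn"] == pytest.approx(brute, abs=1e-12)


def _mini_schedule(fert_n=120.0, organics=(), f_surf=0.3,
                   windows=((40, 44),), transplant="2001-06-10", harvest="2001-09-20"):
    policy = IrrigationPolicy(pd_lower=40, pd_target=60, pd_upper=80,
                              drainage_windows=windows)
    return pn.ManagementSchedule(
        transplant=transplant, harvest=harvest,
        fert_events=split_fertilizer(fert_n, (6, 4), (1, 20), f_surf=f_surf),
        organic_inputs=organics, policy=policy,
    )


class TestSeason:
    def test_no_inputs_no_loss(self, default_obs):
        sched = dataclasses.replace(
            _mini_schedule(), fert_events=(), organic_inputs=()
        )
        sim = simulate_season(default_obs["weather"], SoilHydroParams(), sched, NRateParams())
        assert sim.losses.totals["tn"] == 0.0

    def test_nitrogen_mass_balance_closes(self, default_simulation):
        assert abs(default_simulation.balance["residual"]) < 1e-9

    def test_concentration_identity_chain_every_day(self, default_simulation):
        n = default_simulation.nitrogen
        assert (n["c_tn"] >= n["c_dtn"] - 1e-12).all()
        assert (n["c_dtn"] >= n["c_din"] - 1e-12).all()
        assert (n["c_din"] >= n["c_nh4"] - 1e-12).all()

    def test_loss_monotone_in_fertilizer_rate(self, default_obs):
        """Scaling the fertilizer schedule (all else fixed) never decreases
        seasonal TN loss — the linear-pool monotonicity theorem."""
        weather = default_obs["weather"]
        totals = []
        for frac in (0.2, 0.6, 1.0, 1.4):
            sched = _mini_schedule(fert_n=180.0 * frac)
            sim = simulate_season(weather, SoilHydroParams(), sched, NRateParams())
            totals.append(sim.losses.totals["tn"])
        assert all(b >= a - 1e-12 for a, b in zip(totals, totals[1:]))

    def test_loss_monotone_in_f_surf(self, default_obs):
        weather = default_obs["weather"]
        totals = []
        for f in (0.1, 0.3, 0.5):
            sim = simulate_season(
                weather, SoilHydroParams(), _mini_schedule(f_surf=f), NRateParams()
            )
            totals.append(sim.losses.totals["tn"])
        assert all(b >= a - 1e-12 for a, b in zip(totals, totals[1:]))

    def test_reduced_fertilizer_with_gm_loses_less_din(self, default_obs):
        """The 40%-reduced schedule with a green-manure input loses less DIN
        than the conventional schedule on the same weather."""
        weather = default_obs["weather"]
        fr = simulate_season(
            weather, SoilHydroParams(), _mini_schedule(180.0), NRateParams()
        )
        mr_sched = _mini_schedule(180.0 * 0.6, organics=(green_manure(day=-10),))
        mr = simulate_season(weather, SoilHydroParams(), mr_sched, NRateParams())
        assert mr.losses.totals["din"] < fr.losses.totals["din"]

    def test_peak_on_first_day_after_fertilization(self, flat_weather):
        """On a rain-free field the monitored concentration peaks at the
        day-1 sample after each application and the pool mass declines
        monotonically afterwards (depth cycling can wiggle the daily
        concentration, but not the sampled peak)."""
        w = flat_weather.copy()
        sched = _mini_schedule(windows=(), transplant="2001-06-10", harvest="2001-08-31")
        sim = simulate_season(w, SoilHydroParams(perc_rate=5), sched, NRateParams())
        n = sim.nitrogen.set_index("day")["c_tn"]
        for ev_day in (1, 20):
            samples = [ev_day + off for off in (1, 3, 5, 7, 10)]
            values = n.loc[samples]
            assert values.idxmax() == ev_day + 1
            masses = sim.nitrogen.set_index("day").loc[ev_day:ev_day + 10, "m_nh4"]
            assert (masses.diff().dropna() <= 1e-12).all()

    def test_straw_immobilization_reduces_dissolved_loss(self, default_obs):
        weather = default_obs["weather"]
        fr = simulate_season(weather, SoilHydroParams(), _mini_schedule(), NRateParams())
        frs_sched = _mini_schedule(organics=(straw_return(day=-10),))
        frs = simulate_season(weather, SoilHydroParams(), frs_sched, NRateParams())
        assert frs.losses.totals["din"] < fr.losses.totals["din"]

    def test_deterministic_rerun(self, default_truth, default_obs):
        a = simulate_season(
            default_obs["weather"], default_truth.soil, default_truth.schedule,
            default_truth.rates, latitude=default_truth.latitude,
        )
        b = simulate_season(
            default_obs["weather"], default_truth.soil, default_truth.schedule,
            default_truth.rates, latitude=default_truth.latitude,
        )
        pd.testing.assert_frame_equal(a.nitrogen, b.nitrogen)
        assert a.losses.totals == b.losses.totals
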