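"""Integration engine: determinism, convergence, box behaviour."""

import numpy as np
import pytest

from planktos import engine
from planktos.dynamics import Community, element_totals
from planktos.environment import ColumnConfig
from planktos.forcing import make_scenario
from planktos.params import default_parameters

from conftest import euler_steps


class TestDeterminism:
    def test_identical_config_bit_identical_output(self):
        scen = make_scenario("Oosterschelde", years=1, seed=4)
        a = engine.run(scen, years=0.2, spinup_years=0.0, dt_minutes=60.0)
        b = engine.run(scen, years=0.2, spinup_years=0.0, dt_minutes=60.0)
        assert a.df.equals(b.df)

    def test_restart_reproduces_trajectory(self, pset, box_config):
        com = Community(pset)
        nut = {"NH4": 0.05, "NO3": 0.25, "PO4": 0.04, "Si": 0.30}
        dt = 30.0 / (24 * 60)
        full = com.init_state(box_config, nut)
        euler_steps(com, full, box_config, nsteps=200, dt=dt)
        half = com.init_state(box_config, nut)
        euler_steps(com, half, box_config, nsteps=100, dt=dt)
        resumed = half.copy()
        euler_steps(com, resumed, box_config, nsteps=100, dt=dt)
        assert np.array_equal(full.C, resumed.C)
        assert np.array_equal(full.N, resumed.N)


class TestAbioticTracking:
    def test_zero_biology_tracer_follows_relaxation_ode(self):
        """With no biology, phosphate is a conservative tracer: the
        column follows dX/dt = (b(t) - X)/tau with tau the 30-day
        residence time (lagged boundary tracking)."""
        scen = make_scenario("Noordwijk", years=1, seed=0)
        scen.config.seed_biomass = 0.0  # no boundary inoculum either
        res = engine.run(scen, years=0.5, spinup_years=0.0,
                         dt_minutes=60.0, initial_biomass=0.0,
                         pfts=["diatom"])
        po4 = res.df["PO4_0"].to_numpy()
        t = res.df["time"].to_numpy()
        # independent fine-step solution of the relaxation ODE with the
        # same daily-sampled boundary series
        tau = scen.config.residence_time
        dt = 1.0 / 240.0
        x = po4[0]
        xs = []
        steps = int(t[-1] / dt) + 1
        for s in range(steps):
            day = s * dt
            b = scen.boundary.at_day("PO4", min(int(day), int(t[-1])))
            x += dt * (b - x) / tau
            xs.append(x)
        xs = np.asarray(xs)
        idx = np.minimum((t / dt).astype(int), len(xs) - 1)
        ode = xs[idx]
        assert np.allclose(po4, ode, rtol=0.02)


class TestStepConvergence:
    def test_halving_dt_changes_trajectory_below_one_percent(self):
        scen = make_scenario("Oosterschelde", years=1, seed=2)
        coarse = engine.run(scen, years=0.5, spinup_years=0.0,
                            dt_minutes=60.0, output_hours=24.0)
        fine = engine.run(scen, years=0.5, spinup_years=0.0,
                          dt_minutes=30.0, output_hours=24.0)
        for pft in ("diatom", "green"):
            a = coarse.df[f"{pft}_C_0"].to_numpy()
            b = fine.df[f"{pft}_C_0"].to_numpy()
            rms = np.sqrt(np.mean((a - b) ** 2))
            scale = np.sqrt(np.mean(b ** 2))
            assert rms / scale < 0.01


class TestBox:
    def test_dark_box_phototrophs_collapse(self):
        res = engine.run_box_equilibrium(I0=0.0, max_years=1.0,
                                         dt_minutes=60.0)
        assert res.biomass["diatom"] < 1e-4
        assert res.biomass["green"] < 1e-4

    def test_box_closed_conserves_elements(self, pset, box_config):
        com = Community(pset)
        state = com.init_state(box_config, {"NH4": 0.05, "NO3": 0.25,
                                            "PO4": 0.04, "Si": 0.30})
        t0 = element_totals(state, box_config)
        euler_steps(com, state, box_config, nsteps=400, dt=1.0 / 24.0)
        t1 = element_totals(state, box_config)
        for e in ("C", "N", "P", "Si"):
            assert abs(t1[e] - t0[e]) / abs(t0[e]) < 1e-9

    def test_lit_box_all_five_types_stay_nonnegative(self):
        res = engine.run_box_equilibrium(max_years=0.5, dt_minutes=60.0)
        for name, b in res.biomass.items():
            assert b >= 0.0
        # phototrophs grew from the small inoculum
        assert res.biomass["diatom"] > 1e-3 or res.biomass["green"] > 1e-3

    def test_nutrient_starved_box_favours_mixotroph_fraction(self):
        """Under scarce dissolved nutrients with prey available, the
        constitutive mixoplankton's biomass fraction exceeds its
        fraction in a nutrient-replete box."""
        rich = engine.run_box_equilibrium(
            nutrients={"NH4": 0.1, "NO3": 0.5, "PO4": 0.08, "Si": 0.6},
            max_years=2.0, dt_minutes=60.0)
        poor = engine.run_box_equilibrium(
            nutrients={"NH4": 0.01, "NO3": 0.05, "PO4": 0.004, "Si": 0.06},
            max_years=2.0, dt_minutes=60.0)

        def frac(res):
            tot = sum(res.biomass.values())
            return res.biomass["CM"] / tot

        assert frac(poor) > frac(rich)


class TestSensitivityDriver:
    def test_zero_perturbation_is_identity(self):
        r = engine.run_sensitivity("Doggerbank", "PO4", 0.0, years=0.5,
                                   spinup_years=0.0, dt_minutes=120.0)
        assert r["pct_change"] == pytest.approx(0.0, abs=1e-9)

    def test_normalized_sd(self):
        assert engine.normalized_sd([1.0, 1.0, 1.0]) == 0.0
        x = np.array([1.0, 3.0])
        assert engine.normalized_sd(x) == pytest.approx(np.std(x) / 2.0)
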