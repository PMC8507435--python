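"""Conservation-equation assembly, mortality routing, mass balance."""

import copy

import numpy as np
import pytest

from planktos.dynamics import Community, element_totals, mortality_flux
from planktos.environment import ColumnConfig
from planktos.params import ParameterSet, PFTParams, default_parameters

from conftest import euler_steps

DT = 30.0 / (24 * 60)


class TestMortalityFlux:
    def test_linear_reference_value(self):
        assert mortality_flux(1.0, 0.07, "linear", T=20.0) == \
            pytest.approx(0.07)

    def test_quadratic_reference_value(self):
        assert mortality_flux(1.0, 0.007, "quadratic", T=20.0) == \
            pytest.approx(0.007)

    def test_quadratic_square_law(self):
        f1 = mortality_flux(1.0, 0.007, "quadratic", T=20.0)
        f2 = mortality_flux(2.0, 0.007, "quadratic", T=20.0)
        assert f2 == pytest.approx(4 * f1)

    def test_temperature_scaling(self):
        assert mortality_flux(1.0, 0.07, "linear", T=30.0, Q10=2.0) == \
            pytest.approx(0.14)


class TestDerivativeAssembly:
    def test_protozoo_alone_is_loss_only(self, box_config):
        """With no prey, a heterotroph loses biomass at mrt + totR."""
        ps = default_parameters().subset(["protozoo"])
        com = Community(ps)
        state = com.init_state(box_config, {}, biomass=0.5)
        ds, _, diag = com.tendencies(state, box_config, T=20.0, I0=100.0,
                                     SPM=0.0, dt=DT, want_diag=True)
        C = state.C[0, 0]
        expected = -(diag["mort_flux"][0, 0] + diag["totR"][0, 0] * C)
        assert ds["C"][0, 0] == pytest.approx(expected, rel=1e-12)

    def test_dark_diatom_term_sum(self, box_config):
        """Darkness, no predators: dC/dt = -(mrt + totR) C and chlorophyll
        decays by degradation plus the mortality share."""
        ps = default_parameters().subset(["diatom"])
        com = Community(ps)
        state = com.init_state(box_config, {}, biomass=0.3)
        ds, _, diag = com.tendencies(state, box_config, T=20.0, I0=0.0,
                                     SPM=0.0, dt=DT, want_diag=True)
        C = state.C[0, 0]
        ChlC = state.Chl[0, 0] / C
        # quota-stable pools: nutrients at optimum, nothing external
        assert diag["Cfix"][0, 0] == 0.0
        expected_dC = -(diag["mort_flux"][0, 0] + diag["totR"][0, 0] * C)
        assert ds["C"][0, 0] == pytest.approx(expected_dC, rel=1e-12)
        expected_dChl = (diag["synChl"][0, 0] - diag["degChl"][0, 0]) * C \
            - diag["mort_flux"][0, 0] * ChlC
        assert ds["Chl"][0, 0] == pytest.approx(expected_dChl, rel=1e-10)

    def test_all_zero_biomass_leaves_only_abiotic_cycling(self, box_config,
                                                          pset):
        com = Community(pset)
        state = com.init_state(box_config, {"NH4": 0.1, "NO3": 0.2},
                               biomass=0.0)
        state.ab.PON[:] = 0.5
        ds, _, _ = com.tendencies(state, box_config, T=20.0, I0=200.0,
                                  SPM=1.0, dt=DT)
        assert np.all(ds["C"] == 0.0)
        assert np.all(ds["N"] == 0.0)
        # PON decays into NH4; nitrification moves NH4 to NO3
        assert ds["ab"]["PON"][0] < 0
        assert ds["ab"]["NO3"][0] > 0


def _green_like_cm():
    """A CM parameterized identically to the default green alga with all
    phagotrophy switched off."""
    g = default_parameters()["green"]
    kw = {f: getattr(g, f) for f in (
        "UmRT", "Q10", "Tref", "mrtRT", "mortality_order", "BRfrac",
        "redco", "AR", "SDA", "NCmin", "NCopt", "NCmax", "NO3Copt",
        "NO3Cmax", "PCminNCmin", "PCminNCmax", "PCmin", "PCopt", "PCmax",
        "KtN", "KtP", "ChlCmax", "alphaChl", "relPS", "PSDOC", "ESD",
        "Ccell")}
    return PFTParams(name="cm_clone", trophic_class="CM", optCR=0.0,
                     PR={}, relPhag=0.05, AEo=0.25, AEm=0.75, **kw)


class TestStructuralRegression:
    def test_cm_without_phagotrophy_equals_green(self, box_config):
        """A CM with zero capture follows the green-algae trajectory to
        machine precision given identical physiology."""
        green = default_parameters()["green"]
        ps = ParameterSet([copy.deepcopy(green), _green_like_cm()])
        com = Community(ps)
        state = com.init_state(box_config,
                               {"NH4": 0.05, "NO3": 0.25, "PO4": 0.04},
                               biomass=1e-3)
        euler_steps(com, state, box_config, nsteps=500, dt=DT,
                    T=12.0, I0=150.0, SPM=1.0)
        assert state.C[0, 0] > 1e-3  # it actually grew
        for arr in (state.C, state.N, state.P, state.Chl):
            assert arr[0, 0] == arr[0, 1]


class TestConservation:
    def test_closed_box_conserves_elements(self, box_config, pset):
        com = Community(pset)
        state = com.init_state(box_config,
                               {"NH4": 0.05, "NO3": 0.25, "PO4": 0.04,
                                "Si": 0.30}, biomass=1e-3)
        t0 = element_totals(state, box_config)
        euler_steps(com, state, box_config, nsteps=1000, dt=DT,
                    T=12.0, I0=150.0, SPM=2.0)
        t1 = element_totals(state, box_config)
        for e in ("C", "N", "P", "Si"):
            assert abs(t1[e] - t0[e]) / abs(t0[e]) < 1e-9

    def test_open_column_conserves_with_budgets(self, pset):
        cfg = ColumnConfig(depth=20.0, n_cells=2, stratified=False)
        com = Community(pset.subset(["diatom", "green", "protozoo", "CM"]))
        state = com.init_state(cfg, {"NH4": 0.05, "NO3": 0.25, "PO4": 0.04,
                                     "Si": 0.30}, biomass=1e-3)
        t0 = element_totals(state, cfg)
        bnd = {"NH4": 0.02, "NO3": 0.1, "PO4": 0.02, "Si": 0.1}
        for _ in range(500):
            ds, db, _ = com.tendencies(state, cfg, T=10.0, I0=200.0,
                                       SPM=5.0, boundary=bnd, month=3,
                                       dt=DT)
            state.C += DT * ds["C"]
            state.N += DT * ds["N"]
            state.P += DT * ds["P"]
            state.Si += DT * ds["Si"]
            state.Chl += DT * ds["Chl"]
            for k, v in ds["ab"].items():
                getattr(state.ab, k).__iadd__(DT * v)
            for k, v in db.items():
                state.budgets[k] += DT * v
            com.apply_voiding(state)
        t1 = element_totals(state, cfg)
        for e in ("C", "N", "P", "Si"):
            assert abs(t1[e] - t0[e]) / max(abs(t0[e]), 1.0) < 1e-9

    def test_positivity_guard(self, box_config, pset):
        """Aggressive step never drives pools negative."""
        com = Community(pset)
        state = com.init_state(box_config,
                               {"NH4": 1e-6, "NO3": 1e-6, "PO4": 1e-7,
                                "Si": 1e-6}, biomass=0.5)
        big_dt = 0.5  # half a day: far beyond the stable step
        euler_steps(com, state, box_config, nsteps=40, dt=big_dt,
                    T=25.0, I0=400.0, SPM=0.0)
        for arr in (state.C, state.N, state.P, state.Si, state.Chl):
            assert np.all(arr >= -1e-12)
        for k in ("NH4", "NO3", "PO4", "Si", "POC", "PON", "POP", "opal",
                  "DOClab"):
            assert np.all(getattr(state.ab, k) >= -1e-12)
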