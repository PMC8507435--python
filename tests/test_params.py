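"""Parameter definitions, validation and the prey-handling matrix."""

import numpy as np
import pytest

from planktos.params import (ConfigurationError, ParameterSet, PFTParams,
                             ValidationError, carbon_per_cell,
                             default_parameters, load_parameter_set,
                             prey_handling_matrix, stokes_velocity)


class TestDefaults:
    def test_every_pft_shares_reference_growth_rate(self, pset):
        for p in pset:
            assert p.UmRT == 0.81

    def test_mortality_wiring(self, pset):
        for name in ("diatom", "green", "CM"):
            assert pset[name].mortality_order == "linear"
            assert pset[name].mrtRT == 0.07
        assert pset["protozoo"].mortality_order == "quadratic"
        assert pset["protozoo"].mrtRT == 0.007

    def test_default_set_validates_cleanly(self):
        default_parameters().validate()

    def test_photosynthetic_overcapacity(self, pset):
        for name in ("diatom", "green", "CM"):
            assert pset[name].relPS == 2.0

    def test_capability_flags_follow_trophic_class(self, pset):
        assert pset["diatom"].uses_silica
        assert not pset["green"].uses_silica
        assert pset["CM"].is_phototroph and pset["CM"].is_phagotroph
        assert pset["NCM"].is_kleptoplastic
        assert not pset["protozoo"].has_uptake

    def test_nitrate_quotas_below_ammonium_quotas(self, pset):
        for name in ("diatom", "green", "CM"):
            p = pset[name]
            assert p.NO3Copt <= p.NCopt
            assert p.NO3Cmax <= p.NCmax


class TestValidation:
    def test_inverted_nitrogen_quotas_rejected(self, pset):
        bad = PFTParams(name="d", trophic_class="green",
                        NCmin=0.16, NCopt=0.15, NCmax=0.2,
                        NO3Copt=0.14, NO3Cmax=0.19,
                        KtN=0.01, KtP=0.003, ChlCmax=0.03, alphaChl=0.5)
        with pytest.raises(ValidationError, match="NCmin < NCopt"):
            bad.validate()

    def test_missing_mandatory_field_names_pft_and_field(self):
        doc = {"g": {"trophic_class": "green", "NCmin": 0.07, "NCopt": 0.15,
                     "NCmax": 0.2, "NO3Copt": 0.14, "NO3Cmax": 0.19,
                     "KtN": 0.01, "KtP": 0.003, "ChlCmax": 0.03}}
        with pytest.raises(ConfigurationError) as err:
            load_parameter_set(doc)
        assert "g" in str(err.value) and "alphaChl" in str(err.value)

    def test_cm_cannot_handle_oversized_prey(self):
        pset = default_parameters()
        pset["CM"].PR["diatom"] = 0.5  # diatom ESD 24 > CM ESD 12
        with pytest.raises(ValidationError, match="larger than"):
            pset.validate()

    def test_phototroph_with_prey_handling_rejected(self):
        pset = default_parameters()
        pset["green"].PR = {"diatom": 0.3}
        with pytest.raises(ValidationError):
            pset.validate()

    def test_self_predation_rejected(self):
        pset = default_parameters()
        pset["protozoo"].PR["protozoo"] = 0.2
        with pytest.raises(ValidationError, match="self-predation"):
            pset.validate()


class TestSerialization:
    def test_yaml_roundtrip_is_identical(self, pset, tmp_path):
        path = tmp_path / "params.yaml"
        pset.to_yaml(path)
        re = load_parameter_set(path)
        assert re.names == pset.names
        for p in pset:
            q = re[p.name]
            for f in ("UmRT", "NCopt", "PCmax", "alphaChl", "Ccell", "sed",
                      "ESD", "optCR", "mrtRT"):
                assert getattr(p, f) == getattr(q, f)
            assert p.PR == q.PR


class TestPreyHandlingMatrix:
    def test_phototroph_rows_are_zero(self, pset):
        M = prey_handling_matrix(pset)
        for name in ("diatom", "green"):
            assert np.all(M[pset.names.index(name)] == 0.0)

    def test_cm_row_zero_for_larger_prey(self, pset):
        M = prey_handling_matrix(pset)
        i = pset.names.index("CM")
        for j, p in enumerate(pset):
            if p.ESD > pset["CM"].ESD:
                assert M[i, j] == 0.0

    def test_identity_configuration_gives_row_of_ones(self):
        zoo = PFTParams(name="z", trophic_class="protozoo", ESD=50.0,
                        mortality_order="quadratic", mrtRT=0.007,
                        optCR=0.3, PR={"a": 1.0, "b": 1.0})
        a = PFTParams(name="a", trophic_class="green", ESD=5.0,
                      NO3Copt=0.14, NO3Cmax=0.19, KtN=0.01, KtP=0.003,
                      ChlCmax=0.03, alphaChl=0.5)
        b = PFTParams(name="b", trophic_class="green", ESD=8.0,
                      NO3Copt=0.14, NO3Cmax=0.19, KtN=0.01, KtP=0.003,
                      ChlCmax=0.03, alphaChl=0.5)
        M = prey_handling_matrix(ParameterSet([zoo, a, b]))
        assert list(M[0]) == [0.0, 1.0, 1.0]

    def test_diagonal_forced_zero(self, pset):
        assert np.all(np.diag(prey_handling_matrix(pset)) == 0.0)


class TestHelpers:
    def test_carbon_per_cell_increases_with_size(self):
        assert carbon_per_cell(30.0) > carbon_per_cell(10.0)
        assert carbon_per_cell(20.0, diatom=True) < carbon_per_cell(20.0)

    def test_stokes_velocity_quadratic_in_diameter(self):
        assert stokes_velocity(40.0) == pytest.approx(4 * stokes_velocity(20.0))

    def test_ccell_autofilled_from_size(self):
        p = PFTParams(name="z", trophic_class="protozoo", ESD=30.0,
                      mortality_order="quadratic", optCR=0.3)
        assert p.Ccell == pytest.approx(carbon_per_cell(30.0))

    def test_subset_drops_removed_prey_entries(self, pset):
        sub = pset.subset(["diatom", "green", "protozoo", "CM"])
        assert "NCM" not in sub.names
        for p in sub:
            assert "NCM" not in p.PR
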