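import numpy as np
import pytest
from scipy.linalg import null_space

from acidflux.network import (
    BIOMASS_CLASS_PROPS,
    BiomassAdjustment,
    C_MOLAR_MASS,
    MetabolicNetwork,
    Metabolite,
    Reaction,
    Tag,
    apply_biomass_adjustment,
    apply_knockout,
    biomass_coefficients,
    carbon_imbalances,
    make_toy_network,
)
from acidflux.fba import solve_fba


class TestReactionValidation:
    def test_bounds_ordering_enforced(self):
        with pytest.raises(ValueError, match="lower_bound"):
            Reaction("r", {}, lower_bound=1.0, upper_bound=0.0)

    def test_irreversible_negative_lower_rejected(self):
        with pytest.raises(ValueError, match="irreversible"):
            Reaction("r", {}, lower_bound=-1.0, upper_bound=1.0, reversible=False)

    def test_acid_tag_needs_acid_name(self):
        with pytest.raises(ValueError, match="acid"):
            Reaction("r", {}, tag=Tag.ACID_SECRETION)


class TestNetworkValidation:
    def test_duplicate_metabolite_ids_rejected(self):
        mets = [Metabolite("a"), Metabolite("a")]
        with pytest.raises(ValueError, match="duplicate metabolite"):
            MetabolicNetwork(metabolites=mets, reactions=[])

    def test_unknown_metabolite_in_reaction_rejected(self):
        with pytest.raises(ValueError, match="unknown metabolite"):
            MetabolicNetwork(
                metabolites=[Metabolite("a")],
                reactions=[Reaction("r", {"b": 1.0})],
            )

    def test_duplicate_unique_tag_rejected(self):
        mets = [Metabolite("a")]
        rxns = [
            Reaction("r1", {"a": 1.0}, tag=Tag.BIOMASS),
            Reaction("r2", {"a": -1.0}, tag=Tag.BIOMASS),
        ]
        with pytest.raises(ValueError, match="duplicate tagged"):
            MetabolicNetwork(metabolites=mets, reactions=rxns)

    def test_composition_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            MetabolicNetwork(
                metabolites=[Metabolite("a")],
                reactions=[],
                biomass_composition={"protein": 0.5},
            )


class TestToyNetwork:
    def test_deterministic(self):
        a, b = make_toy_network(), make_toy_network()
        assert [r.id for r in a.reactions] == [r.id for r in b.reactions]
        assert np.array_equal(
            a.stoichiometric_matrix(include_boundary=True),
            b.stoichiometric_matrix(include_boundary=True),
        )

    def test_size_in_range(self, toy_net):
        assert 15 <= len(toy_net.reactions) <= 25

    def test_seven_dissociation_and_secretion_pairs(self, toy_net):
        diss = toy_net.reactions_by_tag(Tag.ACID_DISSOCIATION)
        sec = toy_net.reactions_by_tag(Tag.ACID_SECRETION)
        expected = {"citric", "oxalic", "gluconic", "acetic", "malic", "succinic", "lactic"}
        assert {r.acid for r in diss} == expected
        assert {r.acid for r in sec} == expected

    def test_acid_carbon_counts(self, toy_net):
        counts = {"citric": 6, "oxalic": 2, "gluconic": 6, "acetic": 2,
                  "malic": 4, "succinic": 4, "lactic": 3}
        for rxn in toy_net.reactions_by_tag(Tag.ACID_DISSOCIATION):
            pool_met = next(
                m for m, c in rxn.stoichiometry.items() if c > 0 and m != "h_e"
            )
            assert toy_net.metabolite(pool_met).carbon_count == counts[rxn.acid]

    def test_required_tags_present(self, toy_net):
        for tag in (Tag.BIOMASS, Tag.PROTON_OUT, Tag.STORED_P_IN, Tag.EXTERNAL_P_IN,
                    Tag.GLUCOSE_EX, Tag.XYLOSE_EX, Tag.GOX, Tag.OAH):
            assert toy_net.tagged(tag) is not None

    def test_internal_reactions_carbon_balanced(self, toy_net):
        imbalances = carbon_imbalances(toy_net)
        assert imbalances  # non-trivial check
        assert all(abs(v) < 1e-9 for v in imbalances.values())

    def test_biomass_carbon_accounted_by_composition(self, toy_net):
        cc, _, co2 = biomass_coefficients(
            toy_net.biomass_composition, toy_net.respiration_cc
        )
        biomass = toy_net.tagged(Tag.BIOMASS)
        assert biomass.stoichiometry["cc"] == pytest.approx(-cc)
        assert biomass.stoichiometry["co2_e"] == pytest.approx(co2)
        structural_g = sum(
            m * BIOMASS_CLASS_PROPS[cls][0]
            for cls, m in toy_net.biomass_composition.items()
        )
        assert cc - co2 == pytest.approx(structural_g * 1000.0 / C_MOLAR_MASS)

    def test_growth_positive_with_open_exchanges(self, toy_net):
        sol = solve_fba(toy_net, {"PI": (0.0, 0.0)}, "BIOMASS")
        assert sol.optimal
        assert sol.objective_value > 0.1

    def test_null_space_carbon_conservation(self, toy_net):
        # every steady-state flux mode moves carbon between boundary pools
        # and biomass without creating or destroying it
        S = toy_net.stoichiometric_matrix()
        N = null_space(S)
        carbon = np.array([m.carbon_count for m in toy_net.metabolites], dtype=float)
        S_full = toy_net.stoichiometric_matrix(include_boundary=True)
        cc_total, _, co2 = biomass_coefficients(
            toy_net.biomass_composition, toy_net.respiration_cc
        )
        structural = cc_total - co2
        biomass_col = [r.id for r in toy_net.reactions].index("BIOMASS")
        for k in range(N.shape[1]):
            v = N[:, k]
            boundary_carbon = carbon @ (S_full @ v)
            assert boundary_carbon + structural * v[biomass_col] == pytest.approx(
                0.0, abs=1e-8
            )

    def test_summary_counts(self, toy_net):
        summary = toy_net.summary()
        assert summary["n_reactions"] == len(toy_net.reactions)
        assert len(summary["acids_with_dissociation"]) == 7


class TestBiomassAdjustment:
    def test_identity_leaves_network_unchanged(self, toy_net):
        adjusted = apply_biomass_adjustment(toy_net, BiomassAdjustment(1.0, 1.0))
        assert adjusted.biomass_composition == toy_net.biomass_composition
        assert (
            adjusted.tagged(Tag.BIOMASS).stoichiometry
            == toy_net.tagged(Tag.BIOMASS).stoichiometry
        )

    def test_halving_nucleic_acid(self, toy_net):
        adjusted = apply_biomass_adjustment(toy_net, BiomassAdjustment(0.5, 1.0))
        comp = adjusted.biomass_composition
        assert comp["nucleic_acid"] == pytest.approx(
            0.5 * toy_net.biomass_composition["nucleic_acid"]
        )
        assert sum(comp.values()) == pytest.approx(1.0, abs=1e-12)
        # phosphate demand recomputed from the adjusted composition
        _, pi, _ = biomass_coefficients(comp, toy_net.respiration_cc)
        assert adjusted.tagged(Tag.BIOMASS).stoichiometry["pi_c"] == pytest.approx(-pi)

    @pytest.mark.parametrize("scales", [(0.5, 0.5), (1.3, 0.8), (2.0, 1.5), (0.1, 3.0)])
    def test_mass_fractions_always_sum_to_one(self, toy_net, scales):
        adjusted = apply_biomass_adjustment(toy_net, BiomassAdjustment(*scales))
        assert sum(adjusted.biomass_composition.values()) == pytest.approx(
            1.0, abs=1e-9
        )

    def test_overdrawn_glycerol_rejected(self, toy_net):
        # glycerol 0.10 cannot absorb a nucleic-acid increase of 0.04 * 5
        with pytest.raises(ValueError, match="glycerol"):
            apply_biomass_adjustment(toy_net, BiomassAdjustment(6.0, 1.0))

    def test_invalid_scales_rejected(self):
        with pytest.raises(ValueError):
            BiomassAdjustment(0.0, 1.0)

    def test_original_network_not_mutated(self, toy_net):
        before = dict(toy_net.tagged(Tag.BIOMASS).stoichiometry)
        apply_biomass_adjustment(toy_net, BiomassAdjustment(0.5, 2.0))
        assert toy_net.tagged(Tag.BIOMASS).stoichiometry == before


class TestKnockouts:
    def test_empty_set_unchanged(self, toy_net):
        out = apply_knockout(toy_net, set())
        assert out.bounds_arrays()[1].tolist() == toy_net.bounds_arrays()[1].tolist()

    def test_unknown_gene_lists_supported(self, toy_net):
        with pytest.raises(ValueError, match="gox.*oah|oah.*gox"):
            apply_knockout(toy_net, {"pfk"})

    def test_oah_pins_reaction(self, toy_net):
        out = apply_knockout(toy_net, {"oah"})
        rxn = out.tagged(Tag.OAH)
        assert (rxn.lower_bound, rxn.upper_bound) == (0.0, 0.0)

    def test_gox_disables_forcing(self, toy_net):
        out = apply_knockout(toy_net, {"gox"})
        assert out.gox_forcing_disabled
        rxn = out.tagged(Tag.GOX)
        assert (rxn.lower_bound, rxn.upper_bound) == (0.0, 0.0)

    def test_idempotent_and_commutative(self, toy_net):
        def signature(net):
            lb, ub = net.bounds_arrays()
            return (lb.tolist(), ub.tolist(), net.gox_forcing_disabled)

        once = apply_knockout(toy_net, {"oah", "gox"})
        twice = apply_knockout(once, {"oah", "gox"})
        sequential = apply_knockout(apply_knockout(toy_net, {"gox"}), {"oah"})
        reverse = apply_knockout(apply_knockout(toy_net, {"oah"}), {"gox"})
        assert signature(once) == signature(twice)
        assert signature(sequential) == signature(reverse) == signature(once)
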