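"""Speciation solver: Davies activities, mass/charge balance, oracle checks."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from comdiss.errors import ValidationError
from comdiss.kinetics import relative_undersaturation
from comdiss.speciation import (
    CA,
    CL,
    DEFAULT_CHARGES,
    NA,
    OX,
    EquilibriumReaction,
    SolutionRecipe,
    davies_log_gamma,
    default_constants,
    dissolution_recipe,
    ion_product_sqrt,
    ionic_strength,
    load_constants,
    solve_speciation,
)
from oracles import fixed_point_speciation


class TestIonicStrength:
    @pytest.mark.parametrize(
        "free, expected",
        [
            ({NA: 0.15, CL: 0.15}, 0.15),           # 1:1 salt: I equals molarity
            ({}, 0.0),                               # empty solution
            ({CA: 0.001, CL: 0.002}, 0.003),         # 1/2(0.001*4 + 0.002*1)
        ],
    )
    def test_reference_values(self, free, expected):
        assert ionic_strength(free) == pytest.approx(expected, rel=1e-12)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValidationError):
            ionic_strength({NA: -0.1})


class TestDavies:
    def test_neutral_and_infinite_dilution(self):
        assert davies_log_gamma(0, 0.3, 0.52) == 0.0
        assert davies_log_gamma(2, 0.0, 0.52) == 0.0

    def test_divalent_at_physiological_ionic_strength(self):
        lg = davies_log_gamma(2, 0.15, 0.52)
        assert lg == pytest.approx(-0.4872, abs=2e-4)
        assert 10.0 ** lg == pytest.approx(0.326, abs=1e-3)

    @given(
        z=st.integers(min_value=-3, max_value=3),
        i=st.floats(min_value=0.0, max_value=0.5),
    )
    def test_charge_sign_symmetry(self, z, i):
        """γ depends on charge only through z²."""
        assert davies_log_gamma(z, i) == davies_log_gamma(-z, i)

    def test_gamma_at_most_one_for_charged_species(self):
        for z in (1, 2, 3):
            for i in (1e-4, 0.05, 0.15, 0.5):
                assert 0.0 < 10.0 ** davies_log_gamma(z, i) <= 1.0

    def test_negative_ionic_strength_rejected(self):
        with pytest.raises(ValidationError):
            davies_log_gamma(2, -0.1)


class TestSolveSpeciation:
    def test_no_reactions_gives_free_equals_totals(self):
        recipe = dissolution_recipe(1.0e-4)
        state = solve_speciation(recipe, reactions=[], charge_balance_on=None)
        for comp, total in recipe.totals.items():
            assert state.free[comp] == pytest.approx(total, rel=1e-12)

    def test_mass_and_charge_balance_at_convergence(self):
        state = solve_speciation(dissolution_recipe(1.791e-4))
        assert state.converged
        assert state.residuals["mass_balance_rel"] <= 1e-12
        assert state.residuals["charge_imbalance_rel"] <= 1e-10

    def test_reference_recipe_free_calcium_and_sigma(self):
        """Dilute Ca/oxalate at I = 0.15: weak complexation only.

        Free calcium stays within 15% of the analytical total, and σ from
        the speciated ion product lands near the value computed from
        totals (the two differ by the complexed fraction).
        """
        recipe = dissolution_recipe(1.791e-4, pH=6.0, ionic_strength_target=0.15)
        state = solve_speciation(recipe)
        t_ca = 1.791e-4
        assert abs(state.free[CA] - t_ca) / t_ca <= 0.15
        sigma = relative_undersaturation(ion_product_sqrt(state))
        assert sigma == pytest.approx(0.10, abs=0.03)

    def test_ionic_strength_self_consistent(self):
        recipe = dissolution_recipe(1.5e-4)
        state = solve_speciation(recipe)
        recomputed = ionic_strength(state.free)
        assert abs(recomputed - state.ionic_strength) <= 1e-9

    def test_limit_agreement_vanishing_association(self):
        """As every logK → −∞ the system decouples and free → totals."""
        consts = default_constants()
        weak = [
            EquilibriumReaction(r.product, r.reactants, -20.0)
            for r in consts.reactions
        ]
        recipe = dissolution_recipe(1.791e-4)
        state = solve_speciation(recipe, reactions=weak, charge_balance_on=None)
        for comp in (CA, OX, NA, CL):
            assert state.free[comp] == pytest.approx(
                recipe.totals[comp], rel=1e-8
            )

    def test_degenerate_all_zero_totals(self):
        """Water + pH-driven species only: valid, not an error."""
        recipe = SolutionRecipe(totals={CA: 0.0, OX: 0.0, NA: 0.0, CL: 0.0}, pH=6.0)
        state = solve_speciation(recipe)
        assert state.converged
        assert state.free[CA] == 0.0
        # chloride absorbs the proton charge
        assert state.free[CL] == pytest.approx(state.free["H+"] - state.free["OH-"], rel=1e-6)

    def test_newton_matches_fixed_point_oracle_small_sample(self):
        consts = default_constants()
        rng = np.random.default_rng(7)
        for _ in range(10):
            t_ca = 10.0 ** rng.uniform(-5, -2)
            t_na = 10.0 ** rng.uniform(-5, -2)
            t_ox = rng.uniform(0.1, 0.8) * (2 * t_ca + t_na) / 2
            pH = rng.uniform(4.5, 7.5)
            totals = {CA: t_ca, OX: t_ox, NA: t_na, CL: 0.0}
            state = solve_speciation(SolutionRecipe(totals=totals, pH=pH))
            oracle, _ = fixed_point_speciation(
                totals, pH, consts.reactions, dict(DEFAULT_CHARGES)
            )
            for name, conc in oracle.items():
                if conc > 1e-300:
                    assert state.free[name] == pytest.approx(conc, rel=1e-6)


class TestIonProductSqrt:
    def test_equal_concentrations(self):
        from comdiss.speciation import SpeciationState

        st_ = SpeciationState(
            free={CA: 1.791e-4, OX: 1.791e-4}, gamma={}, ionic_strength=0.15,
            converged=True, residuals={},
        )
        assert ion_product_sqrt(st_) == pytest.approx(1.791e-4, rel=1e-12)

    def test_geometric_mean(self):
        from comdiss.speciation import SpeciationState

        st_ = SpeciationState(
            free={CA: 4e-8, OX: 1e-8}, gamma={}, ionic_strength=0.15,
            converged=True, residuals={},
        )
        assert ion_product_sqrt(st_) == pytest.approx(2e-8, rel=1e-12)

    def test_zero_oxalate(self):
        from comdiss.speciation import SpeciationState

        st_ = SpeciationState(
            free={CA: 1e-4, OX: 0.0}, gamma={}, ionic_strength=0.15,
            converged=True, residuals={},
        )
        assert ion_product_sqrt(st_) == 0.0

    def test_non_converged_state_rejected(self):
        from comdiss.errors import StateError
        from comdiss.speciation import SpeciationState

        st_ = SpeciationState(
            free={CA: 1e-4, OX: 1e-4}, gamma={}, ionic_strength=0.15,
            converged=False, residuals={},
        )
        with pytest.raises(StateError):
            ion_product_sqrt(st_)


class TestConstantsConfig:
    def test_bundled_file_loads_and_reactions_conserve_charge(self):
        consts = load_constants()
        charges = consts.charges
        for rxn in consts.reactions + consts.disabled_reactions:
            assert rxn.charge_balance_defect(charges) == 0
        assert consts.physical["h0_sqrt"] == pytest.approx(1.994e-4)

    def test_sodium_oxalate_pairing_shipped_but_disabled(self):
        consts = load_constants()
        assert "NaOx-" in {r.product for r in consts.disabled_reactions}
        assert "NaOx-" not in {r.product for r in consts.reactions}

    def test_bad_charge_in_species_rejected(self):
        from comdiss.speciation import IonSpecies

        with pytest.raises(ValidationError):
            IonSpecies("X4+", 4)

    def test_recipe_validation(self):
        with pytest.raises(ValidationError):
            SolutionRecipe(totals={CA: -1e-4}, pH=6.0)
        with pytest.raises(ValidationError):
            SolutionRecipe(totals={CA: 1e-4}, pH=15.0)
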