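"""Unit and property tests for the exact carrier-balance solver."""

from fractions import Fraction

import pytest
from hypothesis import given, settings, strategies as st

from wlpenergy import (
    InfeasibleError,
    ModelValidationError,
    PathwayModel,
    Reaction,
    RedoxCouple,
    UnderdeterminedError,
    build_balance_system,
    gen_network,
    model_from_dict,
    model_to_dict,
    parse_rational,
    solve_flux,
    validate_model,
)
from wlpenergy.synth import NetworkGenSpec

from conftest import brute_force_flux


class TestParseRational:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ("1/2", Fraction(1, 2)),
            ("3.66", Fraction(183, 50)),
            (0.5, Fraction(1, 2)),
            (3, Fraction(3)),
            (Fraction(-7, 3), Fraction(-7, 3)),
        ],
    )
    def test_exact_parsing(self, raw, expected):
        assert parse_rational(raw) == expected

    def test_rejects_non_numeric(self):
        with pytest.raises(TypeError):
            parse_rational(True)


class TestBuildBalanceSystem:
    def test_single_reaction_identity(self, single_reaction_model):
        A, b, labels = build_balance_system(single_reaction_model)
        assert A.shape == (1, 1)
        assert A[0, 0] == 1
        assert list(b) == [1]
        assert labels == ["product:P"]

    def test_co_acetate_rows(self, co_acetate_model):
        """The CO-to-acetate model: one row per internal THF-chain species,
        one per couple, one product row — 9 rows for 9 reactions."""
        A, b, labels = build_balance_system(co_acetate_model)
        species_rows = [l for l in labels if l.startswith("species:")]
        couple_rows = [l for l in labels if l.startswith("couple:")]
        assert len(species_rows) == 5
        assert couple_rows == ["couple:Fd", "couple:NADH", "couple:NADPH"]
        assert labels[-1] == "product:acetate"
        assert A.shape == (9, 9)

    def test_undeclared_couple_is_validation_error(self):
        with pytest.raises(ModelValidationError, match="FADH2"):
            PathwayModel(
                reactions=[Reaction("R", chem={"A": -1, "P": 1}, carriers={"FADH2": 1})],
                couples=[],
                external_species={"A"},
                product="P",
            )


class TestSolveFlux:
    def test_single_reaction_flux_one(self, single_reaction_model):
        sol = solve_flux(single_reaction_model)
        assert sol.fluxes == {"R": Fraction(1)}
        assert sol.net_ions == 0 and sol.slp_sum == 0

    def test_co_acetate_exact_fluxes(self, co_acetate_model):
        """Hand-solved carrier balances: NADPH demand 3/2 met by Nfn 3/4,
        NADH demand 3/4 met by Rnf, Fd demand 3 met by CO oxidation."""
        sol = solve_flux(co_acetate_model)
        assert sol.fluxes["MTHFR"] == 1
        assert sol.fluxes["CODH"] == 3
        assert sol.fluxes["FDH"] == 1
        assert sol.fluxes["MTHFD"] == 1
        assert sol.fluxes["Nfn"] == Fraction(3, 4)
        assert sol.fluxes["Rnf"] == Fraction(3, 4)
        assert all(r == 0 for r in sol.residuals.values())

    def test_h2_acetate_reverse_rnf(self):
        """On H2+CO2 the hydrogenase over-supplies NADPH, so Nfn and the
        ion-translocating Rnf both run backwards, consuming the gradient."""
        from wlpenergy import get_scenario

        sol = solve_flux(get_scenario("figs7_h2_acetate").model)
        assert sol.fluxes["Hyt"] == Fraction(3, 2)
        assert sol.fluxes["Nfn"] == Fraction(-1, 4)
        assert sol.fluxes["Rnf"] == Fraction(-1, 4)
        assert sol.net_ions == Fraction(-1, 2)

    def test_underdetermined_reports_nullity_and_free_reactions(self, single_reaction_model):
        model = single_reaction_model.copy()
        model.reactions.append(Reaction("R2", chem={"A": -2, "P": 2}))
        with pytest.raises(UnderdeterminedError) as exc:
            solve_flux(model)
        assert exc.value.nullity == 1
        assert set(exc.value.free_reactions) == {"R", "R2"}

    def test_inconsistent_system_is_infeasible(self):
        # couple C is produced but never consumed: no balance possible
        model = PathwayModel(
            reactions=[Reaction("R", chem={"A": -1, "P": 1}, carriers={"C": 1})],
            couples=[RedoxCouple("C")],
            external_species={"A"},
            product="P",
        )
        with pytest.raises(InfeasibleError):
            solve_flux(model)

    def test_irreversible_negative_flux_is_infeasible(self):
        # the couple balance forces R2 to run backwards, but it is irreversible
        model = PathwayModel(
            reactions=[
                Reaction("R1", chem={"A": -1, "P": 1}, carriers={"C": 1}),
                Reaction("R2", chem={"A": -1, "B": 1}, carriers={"C": 1}),
            ],
            couples=[RedoxCouple("C")],
            external_species={"A", "B"},
            product="P",
        )
        with pytest.raises(InfeasibleError, match="R2"):
            solve_flux(model)

    @pytest.mark.parametrize("k", [2, Fraction(1, 2), 5])
    def test_scale_invariance(self, co_acetate_model, k):
        base = solve_flux(co_acetate_model)
        scaled = solve_flux(co_acetate_model, product_target=k)
        for rid in base.fluxes:
            assert scaled.fluxes[rid] == k * base.fluxes[rid]
        assert scaled.net_ions == k * base.net_ions
        assert scaled.slp_sum == k * base.slp_sum


class TestOracleEquivalence:
    @settings(max_examples=60, deadline=None)
    @given(
        n_reactions=st.integers(1, 6),
        n_couples=st.integers(0, 3),
        seed=st.integers(0, 2**31 - 1),
    )
    def test_solver_matches_dense_fraction_elimination(self, n_reactions, n_couples, seed):
        model, planted = gen_network(NetworkGenSpec(n_reactions, n_couples, seed))
        sol = solve_flux(model)
        oracle = brute_force_flux(model)
        assert sol.fluxes == oracle
        assert sol.fluxes == planted.fluxes

    @settings(max_examples=40, deadline=None)
    @given(n_reactions=st.integers(2, 6), seed=st.integers(0, 2**31 - 1))
    def test_carrier_and_electron_conservation(self, n_reactions, seed):
        model, _ = gen_network(NetworkGenSpec(n_reactions, 3, seed))
        sol = solve_flux(model)
        for couple in model.couples:
            total = sum(
                sol.fluxes[r.id] * r.carriers.get(couple.id, Fraction(0))
                for r in model.reactions
            )
            assert total == 0
        electrons = sum(
            sol.fluxes[r.id] * model.couple(cid).n_electrons * coeff
            for r in model.reactions
            for cid, coeff in r.carriers.items()
        )
        assert electrons == 0


class TestValidateModel:
    def test_well_formed_model_is_clean(self, co_acetate_model):
        assert validate_model(co_acetate_model) == []

    def test_duplicate_reaction_id(self, single_reaction_model):
        model = single_reaction_model
        model.reactions.append(Reaction("R", chem={"A": -1, "P": 1}))
        errors = [d for d in validate_model(model) if d[0] == "error"]
        assert len(errors) == 1 and "duplicate" in errors[0][1]

    def test_unused_couple_is_warning(self, single_reaction_model):
        model = single_reaction_model
        model.couples.append(RedoxCouple("Fd"))
        diags = validate_model(model)
        assert diags == [("warning", "couple 'Fd' is declared but never used")]


class TestSerialisation:
    def test_round_trip_preserves_solution(self, co_acetate_model):
        data = model_to_dict(co_acetate_model)
        rebuilt = model_from_dict(data)
        assert solve_flux(rebuilt).fluxes == solve_flux(co_acetate_model).fluxes

    def test_rational_strings_accepted(self):
        data = {
            "couples": [{"id": "Fd", "n_electrons": 2}],
            "reactions": [
                {"id": "R", "chem": {"A": -1, "P": "1/2"}, "carriers": {}, "slp_atp": "0"},
            ],
            "external_species": ["A"],
            "product": "P",
        }
        model = model_from_dict(data)
        assert solve_flux(model).fluxes["R"] == 2

    def test_couple_invariants(self):
        with pytest.raises(ModelValidationError):
            RedoxCouple("X", n_electrons=3)
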