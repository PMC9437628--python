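"""Forward sensitivities: closed forms, finite-difference oracles, ranking."""

import numpy as np
import pytest

from sphingosim.model import PathwayModel, ReactionDef, SpeciesDef
from sphingosim.sensitivity import (
    SensitivityMatrix,
    finite_difference_check,
    rank_influences,
    sensitivity_to_initials,
    sensitivity_to_parameters,
)
from sphingosim.simulate import SimulationSettings
from sphingosim.synthetic import GeneratorConfig, random_mass_action_model

FAST = SimulationSettings(output_points=201)


@pytest.fixture()
def linear_decay():
    """X ->(k) Y with X0 = 5, k = 0.2."""
    return PathwayModel(
        [SpeciesDef("X", initial_amount=5.0), SpeciesDef("Y")],
        [ReactionDef(1, "decay", {"X": 1}, {"Y": 1}, 0.2)],
    )


class TestClosedForm:
    def test_linear_sensitivity_of_product_to_rate(self, linear_decay):
        """For X -> Y, dY/dk = t·X0·e^(-kt) pointwise; check the aggregate.

        The time integral of |t·X0·e^(-kt)| over [0, T] has the closed form
        X0/k^2 · (1 - e^(-kT)(1 + kT)).
        """
        k, x0, T = 0.2, 5.0, 100.0
        settings = SimulationSettings(t_end=T, output_points=2001)
        matrix = sensitivity_to_parameters(linear_decay, settings)
        expected = x0 / k**2 * (1 - np.exp(-k * T) * (1 + k * T))
        assert matrix.entry("Y", "1") == pytest.approx(expected, rel=1e-3)

    def test_sensitivity_of_reactant_to_own_initial(self, linear_decay):
        """dX(t)/dX0 = e^(-kt); aggregate = (1 - e^(-kT))/k."""
        k, T = 0.2, 100.0
        settings = SimulationSettings(t_end=T, output_points=2001)
        matrix = sensitivity_to_initials(linear_decay, settings)
        assert matrix.entry("X", "X") == pytest.approx((1 - np.exp(-k * T)) / k,
                                                       rel=1e-3)

    def test_initial_sensitivity_identity_at_t0(self, linear_decay):
        from sphingosim.sensitivity import _integrate_augmented

        _, S, _ = _integrate_augmented(linear_decay, FAST, "initials")
        assert np.allclose(S[:, :, 0], np.eye(2))


class TestFiniteDifferenceAgreement:
    @pytest.mark.parametrize("mode", ["parameters", "initials"])
    def test_random_model_agreement(self, mode):
        model = random_mass_action_model(GeneratorConfig(seed=11, n_species=6,
                                                         n_reactions=7))
        fwd = (sensitivity_to_parameters if mode == "parameters"
               else sensitivity_to_initials)(model, FAST)
        fd = finite_difference_check(model, mode, FAST)
        ref = fwd.values.max()
        mask = fwd.values > 0.01 * ref
        assert np.allclose(fwd.values[mask], fd.values[mask], rtol=0.02)

    def test_disconnected_parameter_has_zero_sensitivity(self):
        model = PathwayModel(
            [SpeciesDef("A", initial_amount=2.0), SpeciesDef("B"),
             SpeciesDef("P", initial_amount=1.0), SpeciesDef("Q")],
            [ReactionDef(1, "ab", {"A": 1}, {"B": 1}, 0.1),
             ReactionDef(2, "pq", {"P": 1}, {"Q": 1}, 0.1)],
        )
        matrix = sensitivity_to_parameters(model, FAST)
        assert matrix.entry("A", "2") == 0.0
        assert matrix.entry("Q", "1") == 0.0


class TestAggregations:
    def test_nonnegative_and_shaped(self, linear_decay):
        matrix = sensitivity_to_parameters(linear_decay, FAST)
        assert matrix.values.shape == (2, 1)
        assert np.all(matrix.values >= 0)

    def test_alternative_aggregations(self, linear_decay):
        for how in ("max-abs", "terminal-abs"):
            matrix = sensitivity_to_parameters(linear_decay, FAST, aggregation=how)
            assert matrix.values.shape == (2, 1)
        with pytest.raises(ValueError):
            sensitivity_to_parameters(linear_decay, FAST, aggregation="median")


@pytest.fixture(scope="module")
def flagship_matrix():
    from sphingosim import build_flagship_model

    return sensitivity_to_parameters(build_flagship_model(), FAST)


class TestFlagshipRankings:
    """Qualitative sensitivity structure of the signaling model.

    The outcome accumulators' most influential rate constants concentrate in
    the terminal death/survival reactions and the ceramide/ERK/AKT axes:
    ERK-mediated death (51) dominates the death ranking, with the caspase
    cascade parameters (27, 49, 28) in the leading third; survival is driven
    by the ERK branch (43, 51), CAPK (18), Ras/GAP cycling (34) and the
    CAPP brake on AKT (40).
    """

    def test_death_influences(self, flagship_matrix):
        ranked = [k for k, _ in rank_influences(flagship_matrix, "CellDeath")]
        assert ranked[0] == "51"
        top_third = ranked[:17]
        assert {"27", "49", "28"} <= set(top_third)

    def test_survival_influences(self, flagship_matrix):
        ranked = [k for k, _ in rank_influences(flagship_matrix, "CellSurvival")]
        top_quarter = ranked[:13]
        assert {"51", "40", "18", "43", "34"} <= set(top_quarter)


class TestRanking:
    def test_single_nonzero_column_ranked_first(self):
        matrix = SensitivityMatrix(["out"], ["a", "b", "c"],
                                   np.array([[0.0, 3.0, 0.0]]))
        assert rank_influences(matrix, "out")[0] == ("b", 3.0)

    def test_top_n_zero_gives_empty(self):
        matrix = SensitivityMatrix(["out"], ["a"], np.array([[1.0]]))
        assert rank_influences(matrix, "out", 0) == []

    def test_unknown_output(self):
        matrix = SensitivityMatrix(["out"], ["a"], np.array([[1.0]]))
        with pytest.raises(KeyError):
            rank_influences(matrix, "nope")

    def test_csv_round_trip(self, linear_decay, tmp_path):
        import pandas as pd

        matrix = sensitivity_to_parameters(linear_decay, FAST)
        matrix.to_csv(tmp_path / "sens.csv")
        back = pd.read_csv(tmp_path / "sens.csv", index_col=0)
        assert list(back.index) == matrix.outputs
        assert np.allclose(back.to_numpy(), matrix.values)
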