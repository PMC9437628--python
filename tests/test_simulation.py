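"""Time-course integration against closed forms and trajectory summaries."""

import numpy as np
import pytest

from sphingosim.model import PathwayModel, ReactionDef, SpeciesDef
from sphingosim.simulate import (
    SimulationSettings,
    Trajectory,
    balance_gap,
    peak,
    read_trajectory_csv,
    simulate,
    terminal_state,
    write_trajectory_csv,
)


def bimolecular_closed_form(t, a0=20.0, b0=10.0, k=1.0):
    """Extent of A + B -> C by quadrature of the logistic extent equation."""
    # x(t) = a0*b0*(1 - exp(-(a0-b0)kt)) / (a0 - b0*exp(-(a0-b0)kt))
    e = np.exp(-(a0 - b0) * k * t)
    return a0 * b0 * (1 - e) / (a0 - b0 * e)


class TestSimulate:
    def test_toy_closed_form(self, toy):
        traj = simulate(toy, SimulationSettings(t_end=5.0))
        x = bimolecular_closed_form(traj.time_grid)
        assert np.allclose(traj.series("A"), 20.0 - x, atol=1e-6)
        assert np.allclose(traj.series("B"), 10.0 - x, atol=1e-6)
        assert np.allclose(traj.series("C"), x, atol=1e-6)

    def test_toy_terminal_values(self, toy):
        ts = terminal_state(simulate(toy, SimulationSettings(t_end=5.0)))
        assert ts["A"] == pytest.approx(10.0, abs=1e-4)
        assert ts["B"] == pytest.approx(0.0, abs=1e-4)
        assert ts["C"] == pytest.approx(10.0, abs=1e-4)

    def test_toy_conservation(self, toy):
        """A+C and B+C are conserved moieties of the closed reaction."""
        traj = simulate(toy, SimulationSettings(t_end=5.0))
        assert np.allclose(traj.series("A") + traj.series("C"), 20.0, atol=1e-7)
        assert np.allclose(traj.series("B") + traj.series("C"), 10.0, atol=1e-7)

    def test_zero_initials_stay_zero(self, flagship):
        model = PathwayModel(
            [SpeciesDef(s.id, initial_amount=0.0) for s in flagship.species],
            flagship.reactions,
        )
        traj = simulate(model)
        assert np.all(traj.values == 0.0)

    def test_first_column_is_initial_state(self, flagship):
        traj = simulate(flagship)
        assert np.allclose(traj.values[:, 0], flagship.initial_state())

    def test_nonnegativity(self, flagship):
        traj = simulate(flagship)
        assert traj.values.min() >= -1e-8

    def test_solver_tolerance_robustness(self, flagship):
        """Halving tolerances moves terminal values by far less than 0.1%."""
        base = simulate(flagship).values[:, -1]
        tight = simulate(
            flagship, SimulationSettings(rel_tol=5e-7, abs_tol=5e-10)
        ).values[:, -1]
        scale = np.maximum(np.abs(base), 1e-6)
        assert np.max(np.abs(base - tight) / scale) < 1e-3

    def test_deterministic(self, flagship):
        t1 = simulate(flagship)
        t2 = simulate(flagship)
        assert np.array_equal(t1.values, t2.values)


class TestSummaries:
    def test_peak_of_transient_intermediate(self, flagship):
        traj = simulate(flagship)
        value, when = peak(traj, "TNFR_TRADD")
        assert 0.0 < when < 15.0  # early transient peak
        assert value > traj.series("TNFR_TRADD")[-1]  # it decays afterwards

    def test_peak_of_decreasing_curve_is_initial(self, toy):
        traj = simulate(toy, SimulationSettings(t_end=5.0))
        value, when = peak(traj, "A")
        assert value == pytest.approx(20.0)
        assert when == 0.0

    def test_peak_ties_resolve_to_earliest_time(self):
        traj = Trajectory(
            time_grid=np.array([0.0, 1.0, 2.0]),
            values=np.array([[3.0, 3.0, 3.0]]),
            species_ids=["flat"],
        )
        assert peak(traj, "flat") == (3.0, 0.0)

    def test_peak_unknown_species(self, toy):
        traj = simulate(toy, SimulationSettings(t_end=1.0))
        with pytest.raises(KeyError):
            peak(traj, "nope")

    def test_balance_gap_zero_for_identical_curves(self):
        values = np.vstack([np.linspace(0, 4, 5)] * 2)
        traj = Trajectory(np.linspace(0, 1, 5), values,
                          ["CellSurvival", "CellDeath"])
        assert balance_gap(traj) == 0.0

    def test_balance_gap_requires_outcomes(self, toy):
        traj = simulate(toy, SimulationSettings(t_end=1.0))
        with pytest.raises(KeyError):
            balance_gap(traj)

    def test_flagship_homeostasis(self, flagship):
        """Calibrated kinetics keep survival and death within 5% at t=100."""
        traj = simulate(flagship)
        gap = balance_gap(traj)
        survival = traj.series("CellSurvival")[-1]
        assert abs(gap) < 0.05 * survival

    def test_grid_refinement_stability(self, flagship):
        p1, _ = peak(simulate(flagship), "TNFR_TRADD")
        p2, _ = peak(
            simulate(flagship, SimulationSettings(output_points=2001)), "TNFR_TRADD"
        )
        assert abs(p1 - p2) / p1 < 0.005


class TestTrajectoryCsv:
    def test_round_trip(self, toy, tmp_path):
        traj = simulate(toy, SimulationSettings(t_end=5.0, output_points=11))
        path = tmp_path / "traj.csv"
        write_trajectory_csv(traj, path)
        back = read_trajectory_csv(path)
        assert back.species_ids == traj.species_ids
        assert np.allclose(back.values, traj.values)
        assert np.allclose(back.time_grid, traj.time_grid)

    def test_reader_requires_time_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("A,B\n1,2\n")
        with pytest.raises(ValueError, match="time"):
            read_trajectory_csv(path)


class TestSettingsValidation:
    @pytest.mark.parametrize(
        "kwargs", [dict(t_end=0.0), dict(output_points=1), dict(rel_tol=0.0)]
    )
    def test_invalid_settings(self, kwargs):
        with pytest.raises(ValueError):
            SimulationSettings(**kwargs)
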