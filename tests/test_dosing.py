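"""Drug attachment, schedule expansion, dosed simulation, mass accounting."""

import numpy as np
import pytest

from sphingosim.dosing import (
    DoseRow,
    DoseSchedule,
    DrugSpec,
    apoptosis_reduction,
    attach_drug,
    builtin_dose_schedule,
    builtin_drug,
    expand_schedule,
    load_dose_schedules,
    simulate_with_dosing,
)
from sphingosim.simulate import SimulationSettings, simulate, terminal_state

FAST = SimulationSettings(output_points=201)


class TestDrugSpec:
    def test_empty_targets_rejected(self):
        with pytest.raises(ValueError):
            DrugSpec("Nothing", ())

    def test_per_target_binding_constants(self):
        drug = DrugSpec("D", ("A", "B"), {"A": 0.02})
        assert drug.kf("A") == 0.02
        assert drug.kf("B") == 0.1  # default fills the gap

    def test_builtin_targets(self):
        assert builtin_drug("Etanercept").targets == ("TNFa",)
        assert set(builtin_drug("Nivocasan").targets) == {"CASP8", "CASP9"}
        assert builtin_drug("Scyphostatin").targets == ("neutral_SMase",)
        with pytest.raises(KeyError):
            builtin_drug("Aspirin")


class TestAttachDrug:
    def test_adds_species_and_reactions(self, flagship):
        drug = builtin_drug("Nivocasan")
        dosed = attach_drug(flagship, drug)
        assert len(dosed.species) == 73 + 3  # drug + two complexes
        assert len(dosed.reactions) == 51 + 2
        assert dosed.species_by_id("Nivocasan").initial_amount == 0.0
        # original untouched
        assert len(flagship.species) == 73

    def test_etanercept_consumes_tnf(self, flagship):
        dosed = attach_drug(flagship, builtin_drug("Etanercept"))
        new = [r for r in dosed.reactions if r.index > 51]
        assert len(new) == 1
        assert "TNFa" in new[0].reactants and "Etanercept" in new[0].reactants

    def test_unknown_target_named(self, toy):
        with pytest.raises(KeyError, match="TNFa"):
            attach_drug(toy, builtin_drug("Etanercept"))


class TestExpandSchedule:
    def test_repeat_events(self):
        schedule = DoseSchedule("X", [DoseRow(0.0, 0.1, 1.0, 5.0, 3)])
        assert expand_schedule(schedule) == [(0.0, 0.1), (5.0, 0.1), (10.0, 0.1)]
        assert schedule.total_amount == pytest.approx(0.3)

    def test_coincident_events_merge(self):
        schedule = DoseSchedule(
            "X", [DoseRow(0.0, 0.1, 1.0, 5.0, 2), DoseRow(5.0, 0.2, 1.0, 5.0, 1)]
        )
        events = expand_schedule(schedule)
        assert [t for t, _ in events] == [0.0, 5.0]
        assert [a for _, a in events] == pytest.approx([0.1, 0.3])

    def test_invalid_rows(self):
        with pytest.raises(ValueError):
            DoseRow(0.0, 0.1, 1.0, 5.0, 0)
        with pytest.raises(ValueError):
            DoseRow(0.0, -0.1)

    def test_bundled_table(self):
        schedules = load_dose_schedules()
        assert set(schedules) == {"Etanercept", "Nivocasan", "Scyphostatin"}
        assert all(len(rows) == 5 for rows in schedules.values())
        row = builtin_dose_schedule("Nivocasan", 5).doses[0]
        assert (row.start_time, row.amount) == (0.4, 0.8)


class TestDosedSimulation:
    def test_zero_amount_identical_to_baseline(self, flagship):
        drug = builtin_drug("Nivocasan")
        model = attach_drug(flagship, drug)
        schedule = DoseSchedule("Nivocasan", [DoseRow(0.0, 0.0, 1.0, 5.0, 3)])
        dosed = simulate_with_dosing(model, drug, schedule, FAST)
        base = simulate(model, FAST)
        # piecewise restarts only differ at solver-tolerance level
        assert np.allclose(dosed.values, base.values, atol=1e-5, rtol=1e-5)

    def test_drug_mass_accounting(self, flagship):
        """Free drug + drug bound in complexes equals total delivered."""
        drug = builtin_drug("Nivocasan")
        model = attach_drug(flagship, drug)
        schedule = builtin_dose_schedule("Nivocasan", 3)
        dosed = simulate_with_dosing(model, drug, schedule, FAST)
        delivered = np.zeros_like(dosed.time_grid)
        for t, amount in expand_schedule(schedule):
            delivered[dosed.time_grid >= t - 1e-9] += amount
        total = (
            dosed.series("Nivocasan")
            + dosed.series(drug.complex_id("CASP8"))
            + dosed.series(drug.complex_id("CASP9"))
        )
        assert np.allclose(total, delivered, atol=1e-6)

    def test_non_drug_species_continuous_at_events(self, flagship):
        drug = builtin_drug("Nivocasan")
        model = attach_drug(flagship, drug)
        schedule = DoseSchedule("Nivocasan", [DoseRow(0.0, 0.5, 1.0, 5.0, 3)])
        settings = SimulationSettings(t_end=20.0, output_points=2001)
        dosed = simulate_with_dosing(model, drug, schedule, settings)
        for sid in ("TNFa", "ceramide", "CellDeath"):
            jumps = np.abs(np.diff(dosed.series(sid)))
            assert jumps.max() < 0.1  # no bolus-sized discontinuities

    def test_late_events_warn_and_are_ignored(self, flagship):
        drug = builtin_drug("Nivocasan")
        model = attach_drug(flagship, drug)
        schedule = DoseSchedule("Nivocasan", [DoseRow(90.0, 0.1, 1.0, 50.0, 3)])
        with pytest.warns(UserWarning, match="ignored"):
            dosed = simulate_with_dosing(model, drug, schedule, FAST)
        assert dosed.time_grid[-1] == FAST.t_end

    def test_monotone_dose_response(self, flagship):
        """More Nivocasan never increases terminal death."""
        drug = builtin_drug("Nivocasan")
        model = attach_drug(flagship, drug)
        deaths = []
        for amount in (0.0, 0.4, 1.6, 6.4):
            schedule = DoseSchedule("Nivocasan", [DoseRow(0.0, amount, 1.0, 5.0, 3)])
            dosed = simulate_with_dosing(model, drug, schedule, FAST)
            deaths.append(terminal_state(dosed)["CellDeath"])
        assert all(d2 <= d1 + 1e-9 for d1, d2 in zip(deaths, deaths[1:]))


class TestApoptosisReduction:
    def test_identity_gives_zero_reduction(self, flagship):
        base = simulate(flagship, FAST)
        summary = apoptosis_reduction(base, base)
        assert summary["reduction"] == pytest.approx(0.0)
        ts = terminal_state(base)
        assert summary["fold"] == pytest.approx(ts["CellSurvival"] / ts["CellDeath"])

    def test_halved_death_gives_half_reduction(self, flagship):
        base = simulate(flagship, FAST)
        halved = simulate(flagship, FAST)
        i = halved.species_ids.index("CellDeath")
        halved.values = halved.values.copy()
        halved.values[i] *= 0.5
        assert apoptosis_reduction(halved, base)["reduction"] == pytest.approx(0.5)

    def test_missing_outcomes_rejected(self, toy):
        base = simulate(toy, SimulationSettings(t_end=1.0))
        with pytest.raises(KeyError):
            apoptosis_reduction(base, base)
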