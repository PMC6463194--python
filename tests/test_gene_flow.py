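"""Vertical and horizontal plasmid propagation rules."""

import numpy as np
import pytest

from plasmidswitch.colony import Cell, World
from plasmidswitch.gene_flow import (
    ConjugationPolicy,
    PlasmidSpecies,
    ScheduleEntry,
    SignalSchedule,
    apply_schedule,
    attempt_conjugation,
    partition_arrays,
    partition_plasmids,
    replicate_counts,
    replicate_to_setpoint,
)
from plasmidswitch.intracell_ssa import SpeciesCounts

SPECIES = {
    "A": PlasmidSpecies("A", setpoint=10),
    "B": PlasmidSpecies("B", setpoint=10),
    "R": PlasmidSpecies("R", setpoint=10, replication_active=False),
}


def make_cell(cid, strain="host", free=None, blocked=None):
    return Cell(
        id=cid, strain=strain, center=(0.0, 0.0), angle=0.0, length=2.0,
        width=1.0, counts=SpeciesCounts(dict(free or {}), dict(blocked or {})),
    )


class TestPartition:
    def test_outputs_sum_exactly_to_input(self, rng):
        counts = SpeciesCounts({"A": 7, "B": 3}, {"B": 5})
        d1, d2 = partition_plasmids(counts, rng)
        for sp in ("A", "B"):
            assert d1.free.get(sp, 0) + d2.free.get(sp, 0) == counts.free.get(sp, 0)
            assert d1.blocked.get(sp, 0) + d2.blocked.get(sp, 0) == counts.blocked.get(sp, 0)

    def test_empty_counts_split_into_empties(self, rng):
        d1, d2 = partition_plasmids(SpeciesCounts({}, {}), rng)
        assert d1.species() == set() and d2.species() == set()

    def test_each_copy_is_a_fair_coin(self):
        # 10,000 partitions of 10 copies: first-daughter mean = 5.00 +/- 0.05
        rng = np.random.default_rng(123)
        free = np.full((10_000, 1), 10, dtype=np.int64)
        f1, b1, f2, b2 = partition_arrays(free, np.zeros_like(free), rng)
        assert np.array_equal(f1 + f2, free)
        assert abs(f1.mean() - 5.0) < 0.05


class TestReplication:
    def test_active_species_tops_up_to_setpoint(self):
        out = replicate_counts(SpeciesCounts({"A": 4}, {}), SPECIES)
        assert out.free["A"] == 10

    def test_blocked_copies_never_amplified(self):
        out = replicate_counts(SpeciesCounts({"A": 0}, {"A": 4}), SPECIES)
        assert out.free["A"] == 0 and out.blocked["A"] == 4

    def test_absent_species_stays_absent(self):
        out = replicate_counts(SpeciesCounts({"B": 0}, {}), SPECIES)
        assert out.free["B"] == 0

    def test_externally_repressed_species_not_amplified(self):
        out = replicate_counts(SpeciesCounts({"R": 4}, {}), SPECIES)
        assert out.free["R"] == 4
        out = replicate_counts(
            SpeciesCounts({"A": 4}, {}), SPECIES, replication_active={"A": False}
        )
        assert out.free["A"] == 4

    def test_overshoot_from_conjugation_is_kept(self):
        out = replicate_counts(SpeciesCounts({"A": 13}, {}), SPECIES)
        assert out.free["A"] == 13

    def test_cell_level_wrapper(self):
        cell = make_cell(1, free={"A": 2})
        assert replicate_to_setpoint(cell, SPECIES).counts.free["A"] == 10


class TestConjugation:
    def test_event_copies_without_debiting_donor(self):
        policy = ConjugationPolicy(probability=1.0)
        donor = make_cell(1, free={"B": 6}, blocked={"B": 4})
        recipient = make_cell(2)
        event = attempt_conjugation(donor, [recipient], policy, np.random.default_rng(0))
        assert event is not None and event.species == "B"
        assert event.copies in (2, 3)
        assert donor.counts.free["B"] == 6 and donor.counts.blocked["B"] == 4
        # transferred copies arrive unblocked, whatever their state in the donor
        assert recipient.counts.free["B"] == event.copies
        assert recipient.counts.blocked.get("B", 0) == 0

    def test_zero_probability_never_fires(self, rng):
        policy = ConjugationPolicy(probability=0.0)
        donor = make_cell(1, free={"B": 6})
        for _ in range(50):
            assert attempt_conjugation(donor, [make_cell(2)], policy, rng) is None

    def test_strain_compatibility_is_directional(self, rng):
        policy = ConjugationPolicy(
            probability=1.0, compatibility={"input": ["computing"], "computing": []}
        )
        sender = make_cell(1, strain="input", free={"A": 5})
        receiver = make_cell(2, strain="computing", free={"A": 5})
        assert attempt_conjugation(sender, [receiver], policy, rng) is not None
        assert attempt_conjugation(receiver, [sender], policy, rng) is None

    def test_plasmid_free_donor_cannot_transfer(self, rng):
        policy = ConjugationPolicy(probability=1.0)
        assert attempt_conjugation(make_cell(1), [make_cell(2)], policy, rng) is None

    def test_species_chosen_proportionally_to_copy_number(self):
        policy = ConjugationPolicy(probability=1.0)
        picks = []
        for seed in range(300):
            donor = make_cell(1, free={"A": 9, "B": 1})
            recipient = make_cell(2)
            ev = attempt_conjugation(donor, [recipient], policy, np.random.default_rng(seed))
            picks.append(ev.species)
        frac_a = picks.count("A") / len(picks)
        assert 0.8 < frac_a < 0.98  # ~0.9 expected


class TestSchedule:
    def test_repression_window_is_half_open(self, small_two_species_config):
        world = World(small_two_species_config, seed=0)
        schedule = SignalSchedule([ScheduleEntry(2.0, 4.0, "A")])
        for gen, expect_repressed in [(1.9, False), (2.0, True), (3.9, True), (4.0, False)]:
            world.iteration = int(gen * 450)
            apply_schedule(world, schedule)
            assert world.replication_active[world.species_index["A"]] != expect_repressed

    def test_signal_step_function_is_echoed(self, small_two_species_config):
        world = World(small_two_species_config, seed=0)
        schedule = SignalSchedule([ScheduleEntry(0.0, 40.0, "s1", 1.0)])
        apply_schedule(world, schedule)
        assert world.signals["s1"] == 1.0
        world.iteration = 41 * 450
        apply_schedule(world, schedule)
        assert world.signals["s1"] == 0.0

    def test_empty_schedule_leaves_world_unchanged(self, small_two_species_config):
        world = World(small_two_species_config, seed=0)
        before = world.replication_active.copy()
        apply_schedule(world, SignalSchedule([]))
        assert np.array_equal(world.replication_active, before)

    def test_unknown_target_rejected(self, small_two_species_config):
        world = World(small_two_species_config, seed=0)
        with pytest.raises(KeyError):
            apply_schedule(world, SignalSchedule([ScheduleEntry(0.0, 1.0, "nope")]))
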