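"""Agent-based colony engine: growth, division, mechanics, contact graph."""

import numpy as np
import pytest

from plasmidswitch.colony import (
    Cell,
    PopulationCapExceeded,
    World,
    contact_graph,
    divide,
    grow,
    relax_overlaps,
)
from plasmidswitch.config import (
    ConjugationConfig,
    InitConfig,
    MechanicsConfig,
    SimulationConfig,
    SpeciesConfig,
)
from plasmidswitch.gene_flow import PlasmidSpecies
from plasmidswitch.intracell_ssa import SpeciesCounts

from conftest import make_line_world

L0 = 2.0
SPECIES = {"P": PlasmidSpecies("P", setpoint=10)}


def make_cell(length=L0, counts=None, angle=0.0):
    return Cell(
        id=0, strain="host", center=(0.0, 0.0), angle=angle, length=length,
        width=1.0, counts=counts or SpeciesCounts({}, {}),
    )


def single_species_config(n_cells=1, **overrides):
    base = dict(
        species=[SpeciesConfig(id="P", replication_active=False)],
        strains=["host"],
        init=InitConfig(
            cells_per_strain={"host": n_cells},
            initial_counts={"host": {"P": 10}},
        ),
        conjugation=ConjugationConfig(probability=0.0),
    )
    base.update(overrides)
    return SimulationConfig(**base)


class TestGrowth:
    def test_one_step_adds_one_450th_of_birth_length(self):
        cell = make_cell()
        assert grow(cell).length == pytest.approx(L0 + L0 / 450)

    def test_newborn_doubles_after_one_generation_of_steps(self):
        cell = make_cell()
        for _ in range(450):
            cell = grow(cell)
        assert cell.length == pytest.approx(2 * L0)

    def test_jittered_population_keeps_mean_doubling_time(self):
        # with +/-10% growth-rate jitter, a colony still roughly quadruples
        # over two generations (law of large numbers on division times)
        config = single_species_config(
            n_cells=200, mechanics=MechanicsConfig(growth_jitter=0.1),
            population_cap=2000, cull=False,
        )
        world = World(config, seed=5)
        world.run(2)
        assert 0.92 * 800 <= world.n <= 1.08 * 800


class TestDivision:
    def test_underlength_mother_rejected(self):
        with pytest.raises(ValueError):
            divide(make_cell(length=1.5 * L0), np.random.default_rng(0), SPECIES)

    def test_daughters_end_to_end_along_mothers_axis(self, rng):
        mother = make_cell(length=2 * L0, angle=0.3)
        d1, d2 = divide(mother, rng, SPECIES, angle_noise=0.0)
        assert d1.length == d2.length == pytest.approx(L0)
        sep = np.subtract(d1.center, d2.center)
        assert np.linalg.norm(sep) == pytest.approx(L0)
        assert abs(np.arctan2(sep[1], sep[0]) - 0.3) < 1e-12

    def test_active_species_topped_up_in_both_daughters(self, rng):
        mother = make_cell(length=2 * L0, counts=SpeciesCounts({"P": 10}, {}))
        d1, d2 = divide(mother, rng, SPECIES)
        assert d1.counts.free["P"] == 10 and d2.counts.free["P"] == 10

    def test_blocked_copies_partition_without_amplification(self):
        totals = []
        for seed in range(200):
            mother = make_cell(length=2 * L0, counts=SpeciesCounts({}, {"P": 10}))
            d1, d2 = divide(mother, np.random.default_rng(seed), SPECIES)
            assert d1.counts.blocked["P"] + d2.counts.blocked["P"] == 10
            assert d1.counts.free.get("P", 0) == 0
            totals.append(d1.counts.blocked["P"])
        assert abs(np.mean(totals) - 5.0) < 0.5  # Binomial(10, 1/2) mean

    def test_plasmid_free_mother_gives_plasmid_free_daughters(self, rng):
        d1, d2 = divide(make_cell(length=2 * L0), rng, SPECIES)
        assert d1.counts.total("P") == 0 and d2.counts.total("P") == 0


class TestMechanics:
    def test_overlapping_parallel_rods_are_separated(self):
        from plasmidswitch._geometry import capsule_pair_distances

        world = make_line_world(2, spacing=0.5)  # heavily overlapping
        relax_overlaps(world, max_sweeps=200)
        dist, _ = capsule_pair_distances(
            world.center, world.angle, world.length, 1.0,
            np.array([0]), np.array([1]),
        )
        # capsule surfaces no longer overlap (beyond the 5% width tolerance)
        assert dist[0] >= 0.95

    def test_non_overlapping_configuration_is_a_fixed_point(self):
        world = make_line_world(3, spacing=3.0)
        before = world.center.copy()
        relax_overlaps(world)
        assert np.allclose(world.center, before)

    def test_residual_overlap_small_after_sustained_growth(self):
        config = single_species_config(n_cells=20, population_cap=250, cull=True)
        world = World(config, seed=2)
        world.run(3)
        from scipy.spatial import cKDTree
        from plasmidswitch._geometry import capsule_pair_distances

        tree = cKDTree(world.center)
        pairs = tree.query_pairs(float(world.length.max()) + 1.0, output_type="ndarray")
        dist, _ = capsule_pair_distances(
            world.center, world.angle, world.length, 1.0, pairs[:, 0], pairs[:, 1]
        )
        overlaps = np.maximum(1.0 - dist, 0.0)
        assert np.percentile(overlaps[overlaps > 0], 95) < 0.10


class TestContactGraph:
    def test_adjacent_cells_touch_distant_cells_do_not(self):
        world = make_line_world(3, spacing=2.05)
        g = contact_graph(world)
        assert g.has_edge(0, 1) and g.has_edge(1, 2)
        assert not g.has_edge(0, 2)
        far = make_line_world(2, spacing=12.0)
        assert far.n == 2 and contact_graph(far).number_of_edges() == 0

    def test_freshly_divided_pair_is_connected(self):
        config = single_species_config(n_cells=1)
        world = World(config, seed=0)
        world.length[0] = 2 * L0  # force division on the next step
        world.step()
        assert world.n == 2
        g = contact_graph(world)
        assert g.has_edge(int(world.ids[0]), int(world.ids[1]))

    def test_matches_brute_force_shapely_oracle(self):
        import shapely

        config = single_species_config(n_cells=50)
        world = World(config, seed=3)
        world.run(0.5)
        gap = world.config.mechanics.contact_gap
        segs = []
        for i in range(world.n):
            h = max(world.length[i] - 1.0, 0.0) / 2.0
            u = np.array([np.cos(world.angle[i]), np.sin(world.angle[i])])
            segs.append(shapely.LineString([world.center[i] - h * u, world.center[i] + h * u]))
        expected = {
            (int(world.ids[i]), int(world.ids[j]))
            for i in range(world.n)
            for j in range(i + 1, world.n)
            if segs[i].distance(segs[j]) <= 1.0 + gap
        }
        g = contact_graph(world)
        got = {tuple(sorted(e)) for e in g.edges}
        assert got == {tuple(sorted(e)) for e in expected}


class TestStep:
    def test_empty_world_is_inert(self):
        config = single_species_config(n_cells=0)
        world = World(config, seed=0)
        world.step()
        assert world.n == 0 and world.iteration == 1

    def test_one_generation_turns_one_cell_into_two(self):
        config = single_species_config(n_cells=1)
        world = World(config, seed=0)
        world.length[0] = L0  # newborn
        for _ in range(450):
            world.step()
        assert world.n == 2

    def test_exponential_growth_without_jitter(self):
        config = single_species_config(n_cells=1, population_cap=100)
        world = World(config, seed=1)
        world.length[0] = L0
        world.run(3)
        assert world.n == 8

    def test_identical_seeds_give_identical_trajectories(self):
        def trajectory(seed):
            config = single_species_config(n_cells=10)
            world = World(config, seed=seed)
            counts = []
            world.run(1.5, on_generation=lambda w: counts.append(w.n))
            return counts, world.center.copy(), world.free.copy()

        (c1, pos1, f1), (c2, pos2, f2) = trajectory(9), trajectory(9)
        assert c1 == c2
        assert np.array_equal(pos1, pos2) and np.array_equal(f1, f2)

    def test_cell_count_never_decreases_without_culling(self):
        config = single_species_config(n_cells=5, population_cap=100)
        world = World(config, seed=4)
        counts = []
        world.run(2, on_generation=lambda w: counts.append(w.n))
        assert all(b >= a for a, b in zip(counts, counts[1:]))

    def test_population_cap_stops_run_cleanly(self):
        config = single_species_config(n_cells=10, population_cap=15, cull=False)
        world = World(config, seed=0)
        world.run(2)
        assert world.stopped_early
        assert world.n <= 2 * 15  # partial results retained

    def test_culling_keeps_population_at_cap(self):
        config = single_species_config(n_cells=10, population_cap=15, cull=True)
        world = World(config, seed=0)
        world.run(2)
        assert not world.stopped_early
        assert world.n == 15

    def test_snapshot_roundtrips_through_json(self):
        import json

        config = single_species_config(n_cells=4)
        world = World(config, seed=0)
        world.run(0.2)
        snap = json.loads(json.dumps(world.snapshot()))
        assert snap["iteration"] == world.iteration
        assert len(snap["cells"]) == world.n
        assert snap["cells"][0]["counts"]["P"] + snap["cells"][0]["blocked_counts"]["P"] >= 0
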