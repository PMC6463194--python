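import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from plasmidswitch.colony import World, relax_overlaps
from plasmidswitch.config import (
    ConjugationConfig,
    InitConfig,
    RuleConfig,
    SimulationConfig,
    SpeciesConfig,
)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_line_world(
    n_cells: int,
    spacing: float = 2.2,
    counts: dict[str, list[int]] | None = None,
    species=("P",),
    conjugation_probability: float = 0.0,
) -> World:
    """A deterministic world of horizontal cells on a line, for geometry and
    cluster tests: cell i sits at (i * spacing, 0) with angle 0, length L0."""
    config = SimulationConfig(
        species=[SpeciesConfig(id=sp, replication_active=False) for sp in species],
        strains=["host"],
        init=InitConfig(cells_per_strain={"host": n_cells}),
        conjugation=ConjugationConfig(probability=conjugation_probability),
    )
    world = World(config, seed=0)
    world.center[:, 0] = np.arange(n_cells) * spacing
    world.center[:, 1] = 0.0
    world.angle[:] = 0.0
    world.length[:] = config.mechanics.L0
    if counts:
        for sp, values in counts.items():
            world.free[:, world.species_index[sp]] = values
    relax_overlaps(world)
    return world


@pytest.fixture
def line_world_factory():
    return make_line_world


def two_species_config(**overrides) -> SimulationConfig:
    base = dict(
        species=[SpeciesConfig(id="A"), SpeciesConfig(id="B")],
        strains=["host"],
        init=InitConfig(
            cells_per_strain={"host": 10},
            initial_counts={"host": {"A": 10, "B": 10}},
        ),
        rules=[RuleConfig(repressor="A", target="B")],
        conjugation=ConjugationConfig(probability=0.0),
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture
def small_two_species_config():
    return two_species_config()
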