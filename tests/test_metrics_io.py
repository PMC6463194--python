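"""Measurements, cluster detection and config/output plumbing."""

import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plasmidswitch.metrics_io import (
    ConfigError,
    SimulationConfig,
    copy_number_histogram,
    detect_clusters,
    normalized_totals,
    read_config,
    write_config,
    write_outputs,
)
from plasmidswitch.colony import World

from conftest import make_line_world, two_species_config


class TestNormalizedTotals:
    def test_caption_rule(self):
        assert np.allclose(normalized_totals(np.array([800.0, 200.0])), [1.0, 0.25])

    def test_all_zero_time_point_maps_to_zero(self):
        assert np.allclose(normalized_totals(np.array([[0.0, 0.0]])), 0.0)

    def test_tie_maps_both_to_one(self):
        assert np.allclose(normalized_totals(np.array([300.0, 300.0])), [1.0, 1.0])

    @given(
        totals=st.lists(
            st.tuples(st.floats(0, 1e6, allow_subnormal=False), st.floats(0, 1e6, allow_subnormal=False)), min_size=1, max_size=10
        ),
        c=st.floats(1e-3, 1e3),
    )
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance(self, totals, c):
        arr = np.array(totals)
        assert np.allclose(normalized_totals(arr * c), normalized_totals(arr), atol=1e-9)

    def test_dataframe_in_dataframe_out(self):
        df = pd.DataFrame({"A": [4.0, 0.0], "B": [1.0, 2.0]})
        out = normalized_totals(df)
        assert isinstance(out, pd.DataFrame)
        assert out.loc[0, "A"] == 1.0 and out.loc[0, "B"] == 0.25
        assert out.loc[1, "B"] == 1.0

    def test_negative_totals_rejected(self):
        with pytest.raises(ValueError):
            normalized_totals(np.array([-1.0, 2.0]))


class TestHistogram:
    def test_uniform_population_fills_one_bin(self):
        world = make_line_world(8, counts={"P": [10] * 8})
        counts, edges = copy_number_histogram(world, "P")
        assert counts.sum() == 8
        assert counts[10] == 8 and counts[:10].sum() == 0

    def test_counts_always_sum_to_cell_count(self):
        world = make_line_world(20, counts={"P": list(range(20))})
        counts, _ = copy_number_histogram(world, "P")
        assert counts.sum() == 20

    def test_empty_population_is_an_error(self):
        world = make_line_world(3)
        world._compact(np.array([], dtype=np.intp))
        with pytest.raises(ValueError, match="no cells"):
            copy_number_histogram(world, "P")


class TestClusters:
    def test_nothing_above_threshold_gives_empty_report(self):
        world = make_line_world(5, counts={"P": [1] * 5})
        report = detect_clusters(world, "P", cn_threshold=10)
        assert report.clusters == ()

    def test_contiguous_run_of_high_cn_cells_is_one_cluster(self):
        world = make_line_world(9, spacing=2.05, counts={"P": [0, 0, 9, 9, 9, 9, 9, 0, 0]})
        report = detect_clusters(world, "P", cn_threshold=5)
        assert len(report.clusters) == 1
        assert report.clusters[0].size == 5
        assert report.clusters[0].members == (2, 3, 4, 5, 6)
        assert report.clusters[0].mean_copy_number == pytest.approx(9.0)

    def test_clusters_are_disjoint_and_match_flood_fill(self):
        from plasmidswitch.experiments import retention_config

        world = World(retention_config(True, n_start=30, population_cap=400), seed=7)
        world.run(2)
        report = detect_clusters(world, "P")
        seen = set()
        for cluster in report.clusters:
            assert not (seen & set(cluster.members))
            seen.update(cluster.members)
            totals = world.per_cell_totals("P")
            by_id = {int(world.ids[i]): totals[i] for i in range(world.n)}
            assert all(by_id[m] >= report.threshold for m in cluster.members)
        # oracle: BFS flood fill over the same adjacency and threshold
        from plasmidswitch.colony import contact_graph

        g = contact_graph(world)
        totals = world.per_cell_totals("P")
        high = {int(world.ids[i]) for i in range(world.n) if totals[i] >= report.threshold}
        unvisited = set(high)
        expected = set()
        while unvisited:
            comp, stack = set(), [unvisited.pop()]
            while stack:
                node = stack.pop()
                comp.add(node)
                for nb in g.neighbors(node):
                    if nb in unvisited:
                        unvisited.remove(nb)
                        stack.append(nb)
            expected.add(frozenset(comp))
        assert {frozenset(c.members) for c in report.clusters} == expected


class TestConfigIO:
    def test_json_round_trip(self, tmp_path):
        config = two_species_config()
        path = write_config(config, tmp_path / "config.json")
        assert read_config(path) == config

    def test_toml_read(self, tmp_path):
        text = """
iterations_per_generation = 450
strains = ["host"]

[[species]]
id = "A"
setpoint = 12

[init]
cells_per_strain = {host = 5}

[init.initial_counts]
host = {A = 12}
"""
        path = tmp_path / "config.toml"
        path.write_text(text)
        config = read_config(path)
        assert config.species[0].setpoint == 12
        assert config.strains == ["wt"] or config.init.cells_per_strain == {"host": 5}

    def test_unknown_keys_rejected_with_field_path(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text(json.dumps({"species": [{"id": "A"}], "bogus_knob": 1}))
        with pytest.raises(ConfigError, match="bogus_knob"):
            read_config(path)

    def test_rule_referencing_missing_species_rejected(self):
        with pytest.raises(Exception, match="unknown species"):
            SimulationConfig.model_validate(
                {
                    "species": [{"id": "A"}],
                    "rules": [{"repressor": "A", "target": "Z"}],
                }
            )

    def test_probability_outside_range_needs_override(self):
        base = {"species": [{"id": "A"}]}
        with pytest.raises(Exception, match="allow_out_of_range"):
            SimulationConfig.model_validate({**base, "conjugation": {"probability": 0.2}})
        with pytest.warns(UserWarning, match="outside the"):
            cfg = SimulationConfig.model_validate(
                {**base, "conjugation": {"probability": 0.2, "allow_out_of_range": True}}
            )
        assert cfg.conjugation.probability == 0.2

    def test_outputs_written_with_provenance(self, tmp_path):
        world = World(two_species_config(), seed=3)
        world.run(0.1)
        out = write_outputs(world, tmp_path / "run", timeseries=pd.DataFrame({"t": [0]}))
        resolved = json.loads((out / "config.resolved.json").read_text())
        assert resolved["seed"] == 3
        assert "software_version" in resolved
        assert (out / "timeseries.csv").exists()
        assert (out / "events.csv").exists()
        snaps = list((out / "snapshots").glob("iter_*.json"))
        assert len(snaps) == 1
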