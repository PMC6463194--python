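"""Measurements and file/config plumbing.

Measurements follow the conventions used to present the simulations: species
totals are normalised per time point so the most abundant plasmid maps to 1;
per-cell copy-number histograms summarise retention; spatial clusters are
connected components of the contact graph restricted to high-copy cells
(local plasmid reservoirs, the structures that re-seed a repressed task).

Configs are TOML or JSON validated against :class:`SimulationConfig`; every
output directory receives the resolved config, the seed and the software
version for provenance.  Time in all outputs is measured in generations, with
the raw iteration count kept as an integer column.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from pydantic import ValidationError

from .colony import Cell, World, contact_graph
from .config import (  # noqa: F401  (re-exported: the config surface lives here)
    CircuitConfig,
    ConjugationConfig,
    InitConfig,
    MechanicsConfig,
    RuleConfig,
    ScheduleEntryConfig,
    SimulationConfig,
    SpeciesConfig,
)

__all__ = [
    "SimulationConfig",
    "ClusterReport",
    "Cluster",
    "normalized_totals",
    "copy_number_histogram",
    "detect_clusters",
    "read_config",
    "write_config",
    "write_outputs",
    "ConfigError",
]


class ConfigError(ValueError):
    """Configuration failed validation; message lists the offending fields."""


# ---------------------------------------------------------------------------
# measurements
# ---------------------------------------------------------------------------


def normalized_totals(
    totals: Union[pd.DataFrame, np.ndarray]
) -> Union[pd.DataFrame, np.ndarray]:
    """Scale per-species population totals so the per-time-point maximum is 1.

    Rows are time points, columns species.  All-zero rows stay all-zero.  The
    operation is invariant under rescaling all totals by a common factor.
    """
    values = np.asarray(totals, dtype=float)
    if values.ndim == 1:
        values = values[None, :]
        squeeze = True
    else:
        squeeze = False
    if (values < 0).any():
        raise ValueError("totals must be non-negative")
    peak = values.max(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = np.where(peak > 0, values / np.where(peak > 0, peak, 1.0), 0.0)
    if isinstance(totals, pd.DataFrame):
        return pd.DataFrame(scaled, index=totals.index, columns=totals.columns)
    return scaled[0] if squeeze else scaled


def copy_number_histogram(
    cells: Union[World, Sequence[Cell]],
    species: str,
    bins: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of per-cell total copy number of ``species``.

    Returns ``(counts, bin_edges)``; counts always sum to the number of
    cells.  Default bins are unit-width integer bins covering [0, max].
    """
    if isinstance(cells, World):
        values = cells.per_cell_totals(species)
    else:
        values = np.array([c.counts.total(species) for c in cells])
    if values.size == 0:
        raise ValueError("no cells")
    if bins is None:
        bins = np.arange(values.max() + 2) - 0.5
    counts, edges = np.histogram(values, bins=bins)
    return counts, edges


@dataclass(frozen=True)
class Cluster:
    members: tuple[int, ...]
    centroid: tuple[float, float]
    size: int
    mean_copy_number: float


@dataclass(frozen=True)
class ClusterReport:
    """Disjoint spatial clusters of high-copy cells for one species."""

    species: str
    threshold: float
    clusters: tuple[Cluster, ...] = field(default_factory=tuple)


def detect_clusters(
    world: World,
    species: str,
    cn_threshold: Optional[float] = None,
    gap: Optional[float] = None,
) -> ClusterReport:
    """Find touching groups of cells rich in ``species``.

    Cells whose total copy number is at least ``cn_threshold`` (default:
    population median + 1 MAD, a robust reading of "higher concentration")
    are kept, and clusters are the connected components of the contact graph
    restricted to them; singletons are reported too.  Cluster mean copy
    number is attached for dot-size style rendering.
    """
    totals = world.per_cell_totals(species)
    if cn_threshold is None:
        med = float(np.median(totals))
        mad = float(np.median(np.abs(totals - med)))
        cn_threshold = med + mad
        if cn_threshold <= 0:
            cn_threshold = 1.0
    if cn_threshold <= 0:
        raise ValueError("cn_threshold must be positive")
    import networkx as nx

    high = {int(world.ids[i]) for i in np.flatnonzero(totals >= cn_threshold)}
    if not high:
        return ClusterReport(species, float(cn_threshold))
    graph = contact_graph(world, gap=gap).subgraph(high)
    by_id = {int(world.ids[i]): i for i in range(world.n)}
    clusters = []
    for comp in nx.connected_components(graph):
        members = tuple(sorted(comp))
        rows = [by_id[m] for m in members]
        centroid = world.center[rows].mean(axis=0)
        clusters.append(
            Cluster(
                members=members,
                centroid=(float(centroid[0]), float(centroid[1])),
                size=len(members),
                mean_copy_number=float(totals[rows].mean()),
            )
        )
    clusters.sort(key=lambda c: (-c.size, c.members))
    return ClusterReport(species, float(cn_threshold), tuple(clusters))


# ---------------------------------------------------------------------------
# config and output plumbing
# ---------------------------------------------------------------------------


def _format_validation_error(exc: ValidationError) -> str:
    lines = []
    for err in exc.errors():
        path = ".".join(str(p) for p in err["loc"]) or "<root>"
        lines.append(f"{path}: {err['msg']}")
    return "; ".join(lines)


def read_config(path: Union[str, Path]) -> SimulationConfig:
    """Load and validate a simulation config from TOML or JSON."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".toml":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
    else:
        with open(path) as fh:
            raw = json.load(fh)
    try:
        return SimulationConfig.model_validate(raw)
    except ValidationError as exc:
        raise ConfigError(_format_validation_error(exc)) from exc


def write_config(config: SimulationConfig, path: Union[str, Path]) -> Path:
    """Write a config as pretty-printed JSON (round-trips via read_config)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(config.model_dump(), indent=2, sort_keys=True) + "\n")
    return path


def write_outputs(
    world: World,
    out_dir: Union[str, Path],
    timeseries: Optional[pd.DataFrame] = None,
) -> Path:
    """Write a run's artefacts to ``out_dir``.

    Emits ``config.resolved.json`` (resolved config + seed + version),
    ``snapshots/iter_*.json``, ``events.csv`` (conjugation log) and, when
    given, ``timeseries.csv``.
    """
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    resolved = world.config.model_dump()
    resolved["seed"] = world.seed
    resolved["software_version"] = __version__
    (out_dir / "config.resolved.json").write_text(
        json.dumps(resolved, indent=2, sort_keys=True) + "\n"
    )
    snap_dir = out_dir / "snapshots"
    snap_dir.mkdir(exist_ok=True)
    snap = world.snapshot()
    (snap_dir / f"iter_{world.iteration:07d}.json").write_text(
        json.dumps(snap, indent=2, sort_keys=True) + "\n"
    )
    events = pd.DataFrame(
        [
            {
                "iteration": e.iteration,
                "generation": e.iteration / world.config.iterations_per_generation,
                "donor": e.donor,
                "recipient": e.recipient,
                "species": e.species,
                "copies": e.copies,
            }
            for e in world.transfer_events
        ],
        columns=["iteration", "generation", "donor", "recipient", "species", "copies"],
    )
    events.to_csv(out_dir / "events.csv", index=False)
    if timeseries is not None:
        timeseries.to_csv(out_dir / "timeseries.csv", index=False)
    return out_dir


def render_snapshot(world: World, path: Union[str, Path], dpi: int = 150) -> Path:
    """Render the colony as coloured capsules (colour = dominant species)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import FancyBboxPatch, BoxStyle
    from matplotlib.transforms import Affine2D

    palette = ["tab:red", "tab:green", "tab:blue", "tab:orange", "tab:purple"]
    colours = {}
    for i, sp in enumerate(world.species_order):
        cfg_colour = world.config.species[i].colour
        colours[sp] = cfg_colour or palette[i % len(palette)]

    fig, ax = plt.subplots(figsize=(6, 6))
    w = world.config.mechanics.width
    totals = world.free + world.blocked
    for i in range(world.n):
        if totals[i].sum() > 0:
            sp = world.species_order[int(np.argmax(totals[i]))]
            colour = colours[sp]
        else:
            colour = "0.7"
        L = world.length[i]
        patch = FancyBboxPatch(
            (-L / 2 + w / 2, -w / 2),
            L - w,
            w,
            boxstyle=BoxStyle.Round(pad=0, rounding_size=w / 2),
            linewidth=0.3,
            edgecolor="black",
            facecolor=colour,
        )
        tr = (
            Affine2D().rotate(world.angle[i]).translate(*world.center[i])
            + ax.transData
        )
        patch.set_transform(tr)
        ax.add_patch(patch)
    span = np.abs(world.center).max() + 4 if world.n else 10
    ax.set_xlim(-span, span)
    ax.set_ylim(-span, span)
    ax.set_aspect("equal")
    ax.set_title(f"generation {world.generation:.1f}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=dpi)
    plt.close(fig)
    return path
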