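"""Agent-based 2D colony engine: rod-shaped cells on a surface.

Cells are capsules that elongate at a constant rate, divide once they double
their birth length (one generation = ``iterations_per_generation`` clock
ticks, 450 by default), and push each other apart through an iterative
overlap-relaxation step that stands in for a rigid-body physics engine — the
population-level results depend on who touches whom, not on force fidelity.
Touching cells define the contact graph over which conjugation operates.

Each cell carries per-species free/blocked plasmid counts advanced by an
exact intracellular SSA, and optionally a deterministic reporter-circuit
state whose promoter totals are resynchronised to the current copy numbers
every iteration.

One iteration of :meth:`World.step` applies, in order: the external signal
schedule, growth, divisions (vertical transfer), overlap relaxation,
conjugation attempts, the intracellular SSA, and the circuit update.
Everything is driven by a single master RNG, so a run is reproducible
bit-for-bit from (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Optional

import numpy as np
from scipy.spatial import cKDTree

from . import gene_flow
from ._geometry import axis_vectors, capsule_pair_distances
from .config import SimulationConfig
from .intracell_ssa import SpeciesCounts, advance_population, compile_rules, RepressionRule
from .ode_models import CircuitState

__all__ = [
    "Cell",
    "World",
    "PopulationCapExceeded",
    "grow",
    "divide",
    "relax_overlaps",
    "contact_graph",
]


class PopulationCapExceeded(RuntimeError):
    """Raised when the population outgrows the cap and culling is disabled."""


@dataclass
class Cell:
    """Snapshot view of one rod-shaped agent."""

    id: int
    strain: str
    center: tuple[float, float]
    angle: float
    length: float
    width: float
    counts: SpeciesCounts
    birth_iteration: int = 0
    circuit: Optional[CircuitState] = None


def grow(
    cell: Cell,
    L0: float = 2.0,
    iterations_per_generation: int = 450,
    rate_factor: float = 1.0,
) -> Cell:
    """One iteration of elongation: length grows by ``L0/iterations`` so a
    newborn doubles (and divides) in exactly one generation."""
    return replace(cell, length=cell.length + rate_factor * L0 / iterations_per_generation)


def divide(
    cell: Cell,
    rng: np.random.Generator,
    species_table: dict[str, gene_flow.PlasmidSpecies],
    L0: float = 2.0,
    angle_noise: float = 0.1,
) -> tuple[Cell, Cell]:
    """Split a full-length mother into two daughters placed end-to-end.

    Plasmids are binomially partitioned and then topped up to setpoint
    (:mod:`plasmidswitch.gene_flow`); the mother's id is retired and fresh
    negative placeholder ids are assigned (the engine renumbers its own).
    """
    if cell.length < 2.0 * L0 - 1e-9:
        raise ValueError("cell has not reached division length")
    c1, c2 = gene_flow.partition_plasmids(cell.counts, rng)
    ux, uy = math.cos(cell.angle), math.sin(cell.angle)
    off = L0 / 2.0
    daughters = []
    for counts, sign in ((c1, +1.0), (c2, -1.0)):
        counts = gene_flow.replicate_counts(counts, species_table)
        daughters.append(
            Cell(
                id=-1,
                strain=cell.strain,
                center=(cell.center[0] + sign * off * ux, cell.center[1] + sign * off * uy),
                angle=cell.angle + float(rng.uniform(-angle_noise, angle_noise)),
                length=L0,
                width=cell.width,
                counts=counts,
                birth_iteration=cell.birth_iteration,
                circuit=None,
            )
        )
    return daughters[0], daughters[1]


def _check_division_length(length: float, L0: float) -> bool:
    return length >= 2.0 * L0 - 1e-9


class World:
    """The simulated colony: cell state arrays plus the iteration clock.

    Construction seeds ``init.cells_per_strain`` cells uniformly in a disc
    with uniformly random orientations and birth phases (lengths uniform in
    ``[L0, 2*L0)``), loads each strain's plasmids, and relaxes away the
    initial overlaps.
    """

    def __init__(self, config: SimulationConfig, seed: Optional[int] = None):
        self.config = config
        if seed is None:
            seed = config.seed if config.seed is not None else 0
        self.seed = int(seed)
        self.rng = np.random.default_rng(self.seed)
        self.iteration = 0
        self.stopped_early = False

        self.species_order = config.species_order
        self.species_index = {sp: i for i, sp in enumerate(self.species_order)}
        self.setpoints = np.array([sp.setpoint for sp in config.species], dtype=np.int64)
        self.base_replication_active = np.array(
            [sp.replication_active for sp in config.species], dtype=bool
        )
        self.replication_active = self.base_replication_active.copy()
        self.signals = {"s1": 0.0, "s2": 0.0}

        self.rules = [
            RepressionRule(r.repressor, r.target, r.kb, r.ku) for r in config.rules
        ]
        self._compiled = compile_rules(
            self.rules, self.species_order, config.catalyzed_unblocking
        )
        self.schedule = gene_flow.SignalSchedule(
            [
                gene_flow.ScheduleEntry(e.t_start, e.t_end, e.target, e.level)
                for e in config.schedule
            ]
        )
        self.policy = gene_flow.ConjugationPolicy(
            probability=config.conjugation.probability,
            copies_choices=tuple(config.conjugation.copies),
            compatibility=config.conjugation.compatibility,
        )
        ns = len(config.strains)
        self.strain_names = list(config.strains)
        if config.conjugation.compatibility is None:
            self.compatibility = np.ones((ns, ns), dtype=bool)
        else:
            self.compatibility = np.zeros((ns, ns), dtype=bool)
            for d, recipients in config.conjugation.compatibility.items():
                di = self.strain_names.index(d)
                for r in recipients:
                    self.compatibility[di, self.strain_names.index(r)] = True

        self.transfer_events: list[gene_flow.TransferEvent] = []
        self.audit = bool(config.audit_divisions)
        self.division_audit: list[tuple] = []
        self.conjugation_audit: list[tuple] = []

        self._init_population()
        self._contact_pairs: tuple[np.ndarray, np.ndarray] = (
            np.empty(0, dtype=np.intp),
            np.empty(0, dtype=np.intp),
        )
        relax_overlaps(self, max_sweeps=50 * config.mechanics.relax_max_sweeps)
        self._prev_total_length = float(self.length.sum()) if self.n else 0.0

    # -- construction -------------------------------------------------------

    def _init_population(self) -> None:
        cfg = self.config
        mech = cfg.mechanics
        total = sum(cfg.init.cells_per_strain.values())
        if total == 0:
            self._allocate(0)
            return
        radius = cfg.init.radius
        if radius is None:
            # ~2.5x the summed capsule footprint keeps the seeding sparse
            radius = math.sqrt(total * 2.5 * mech.L0 * mech.width / math.pi)
        self._allocate(total)
        S = len(self.species_order)
        row = 0
        for strain, n in cfg.init.cells_per_strain.items():
            si = self.strain_names.index(strain)
            counts = cfg.init.initial_counts.get(strain, {})
            for _ in range(n):
                r = radius * math.sqrt(self.rng.random())
                th = self.rng.uniform(0.0, 2.0 * math.pi)
                self.center[row] = (r * math.cos(th), r * math.sin(th))
                self.angle[row] = self.rng.uniform(0.0, 2.0 * math.pi)
                self.length[row] = self.rng.uniform(mech.L0, 2.0 * mech.L0)
                self.strain[row] = si
                for sp, c in counts.items():
                    self.free[row, self.species_index[sp]] = c
                row += 1
        self.ids = np.arange(total, dtype=np.int64)
        self._next_id = total
        if mech.growth_jitter > 0:
            self.growth_factor = self.rng.uniform(
                1.0 - mech.growth_jitter, 1.0 + mech.growth_jitter, total
            )

    def _allocate(self, n: int) -> None:
        S = len(self.species_order)
        self.ids = np.zeros(n, dtype=np.int64)
        self.strain = np.zeros(n, dtype=np.intp)
        self.center = np.zeros((n, 2))
        self.angle = np.zeros(n)
        self.length = np.zeros(n)
        self.birth_iteration = np.zeros(n, dtype=np.int64)
        self.growth_factor = np.ones(n)
        self.free = np.zeros((n, S), dtype=np.int64)
        self.blocked = np.zeros((n, S), dtype=np.int64)
        self._next_id = 0
        if self.config.circuit is not None:
            self.pAa = np.zeros(n)
            self.pBa = np.zeros(n)
            self.RFP = np.zeros(n)
            self.GFP = np.zeros(n)

    # -- basic queries -------------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def generation(self) -> float:
        return self.iteration / self.config.iterations_per_generation

    def totals(self) -> dict[str, int]:
        """Population totals (free + blocked) per species."""
        t = self.free.sum(axis=0) + self.blocked.sum(axis=0)
        return {sp: int(t[i]) for i, sp in enumerate(self.species_order)}

    def per_cell_totals(self, species: str) -> np.ndarray:
        i = self.species_index[species]
        return self.free[:, i] + self.blocked[:, i]

    @property
    def cells(self) -> list[Cell]:
        out = []
        for i in range(self.n):
            counts = SpeciesCounts(
                {sp: int(self.free[i, j]) for j, sp in enumerate(self.species_order)},
                {sp: int(self.blocked[i, j]) for j, sp in enumerate(self.species_order)},
            )
            circuit = None
            if self.config.circuit is not None:
                ia = self.species_index[self.config.circuit.species_a]
                ib = self.species_index[self.config.circuit.species_b]
                nA = float(self.free[i, ia] + self.blocked[i, ia])
                nB = float(self.free[i, ib] + self.blocked[i, ib])
                circuit = CircuitState(
                    pA=nA - self.pAa[i], pAa=self.pAa[i],
                    pB=nB - self.pBa[i], pBa=self.pBa[i],
                    s1=self.signals["s1"], s2=self.signals["s2"],
                    RFP=self.RFP[i], GFP=self.GFP[i],
                )
            out.append(
                Cell(
                    id=int(self.ids[i]),
                    strain=self.strain_names[self.strain[i]],
                    center=(float(self.center[i, 0]), float(self.center[i, 1])),
                    angle=float(self.angle[i]),
                    length=float(self.length[i]),
                    width=self.config.mechanics.width,
                    counts=counts,
                    birth_iteration=int(self.birth_iteration[i]),
                    circuit=circuit,
                )
            )
        return out

    def snapshot(self) -> dict:
        """JSON-serialisable state of the whole world."""
        cells = []
        for i in range(self.n):
            cells.append(
                {
                    "id": int(self.ids[i]),
                    "strain": self.strain_names[self.strain[i]],
                    "center": [float(self.center[i, 0]), float(self.center[i, 1])],
                    "angle": float(self.angle[i]),
                    "length": float(self.length[i]),
                    "counts": {
                        sp: int(self.free[i, j]) for j, sp in enumerate(self.species_order)
                    },
                    "blocked_counts": {
                        sp: int(self.blocked[i, j])
                        for j, sp in enumerate(self.species_order)
                    },
                }
            )
        return {
            "iteration": int(self.iteration),
            "generation": self.generation,
            "seed": self.seed,
            "cells": cells,
        }

    # -- dynamics ------------------------------------------------------------

    def step(self) -> "World":
        """Advance the world by one iteration (1/450 of a generation)."""
        cfg = self.config
        mech = cfg.mechanics
        G = cfg.iterations_per_generation
        gene_flow.apply_schedule(self, self.schedule)
        if self.n:
            # growth
            self.length += self.growth_factor * (mech.L0 / G)
            # divisions (vertical transfer)
            due = self.length >= 2.0 * mech.L0 - 1e-9
            if due.any():
                self._divide(np.flatnonzero(due))
            # mechanics: affine pre-expansion matching the colony's area
            # growth, then local pairwise relaxation (the expansion would
            # otherwise have to propagate outward one contact shell per sweep)
            total_length = float(self.length.sum())
            if self._prev_total_length > 0:
                scale = math.sqrt(total_length / self._prev_total_length)
                self.center *= min(max(scale, 0.99), 1.01)
            self._prev_total_length = total_length
            relax_overlaps(self)
            # horizontal transfer
            pi, pj = self._contact_pairs
            gene_flow.conjugation_sweep(self, pi, pj)
            # intracellular stochastic kinetics (rates are per generation)
            advance_population(self.free, self.blocked, self._compiled, 1.0 / G, self.rng)
            if cfg.circuit is not None:
                self._advance_circuits(cfg.hours_per_generation / G)
        self.iteration += 1
        return self

    def _divide(self, mothers: np.ndarray) -> None:
        cfg = self.config
        mech = cfg.mechanics
        m = mothers.size
        f1, b1, f2, b2 = gene_flow.partition_arrays(
            self.free[mothers], self.blocked[mothers], self.rng
        )
        if self.audit:
            for k in range(m):
                self.division_audit.append(
                    (
                        self.iteration,
                        int(self.ids[mothers[k]]),
                        self.free[mothers[k]].copy(),
                        self.blocked[mothers[k]].copy(),
                        f1[k].copy(), b1[k].copy(), f2[k].copy(), b2[k].copy(),
                    )
                )
        f1 = gene_flow.replicate_arrays(f1, self.setpoints, self.replication_active)
        f2 = gene_flow.replicate_arrays(f2, self.setpoints, self.replication_active)

        u = axis_vectors(self.angle[mothers])
        off = (mech.L0 / 2.0) * u
        centers = np.concatenate([self.center[mothers] + off, self.center[mothers] - off])
        noise = self.rng.uniform(-mech.angle_noise, mech.angle_noise, 2 * m)
        angles = np.concatenate([self.angle[mothers], self.angle[mothers]]) + noise
        lengths = np.full(2 * m, mech.L0)
        strains = np.concatenate([self.strain[mothers]] * 2)
        birth = np.full(2 * m, self.iteration, dtype=np.int64)
        ids = np.arange(self._next_id, self._next_id + 2 * m, dtype=np.int64)
        self._next_id += 2 * m
        if mech.growth_jitter > 0:
            gf = self.rng.uniform(1.0 - mech.growth_jitter, 1.0 + mech.growth_jitter, 2 * m)
        else:
            gf = np.ones(2 * m)
        frees = np.concatenate([f1, f2])
        blockeds = np.concatenate([b1, b2])

        keep = np.ones(self.n, dtype=bool)
        keep[mothers] = False
        self.ids = np.concatenate([self.ids[keep], ids])
        self.strain = np.concatenate([self.strain[keep], strains])
        self.center = np.concatenate([self.center[keep], centers])
        self.angle = np.concatenate([self.angle[keep], angles])
        self.length = np.concatenate([self.length[keep], lengths])
        self.birth_iteration = np.concatenate([self.birth_iteration[keep], birth])
        self.growth_factor = np.concatenate([self.growth_factor[keep], gf])
        self.free = np.concatenate([self.free[keep], frees])
        self.blocked = np.concatenate([self.blocked[keep], blockeds])
        if cfg.circuit is not None:
            half = lambda a: np.concatenate([a[keep], a[mothers] / 2.0, a[mothers] / 2.0])
            self.pAa = half(self.pAa)
            self.pBa = half(self.pBa)
            self.RFP = half(self.RFP)
            self.GFP = half(self.GFP)

        if self.n > cfg.population_cap:
            if not cfg.cull:
                raise PopulationCapExceeded(
                    f"population {self.n} exceeds cap {cfg.population_cap}"
                )
            survivors = np.sort(
                self.rng.choice(self.n, cfg.population_cap, replace=False)
            )
            self._compact(survivors)

    def _compact(self, idx: np.ndarray) -> None:
        for name in ("ids", "strain", "center", "angle", "length",
                     "birth_iteration", "growth_factor", "free", "blocked"):
            setattr(self, name, getattr(self, name)[idx])
        if self.config.circuit is not None:
            for name in ("pAa", "pBa", "RFP", "GFP"):
                setattr(self, name, getattr(self, name)[idx])

    def _advance_circuits(self, dt_hours: float) -> None:
        """Per-cell reporter circuit update over one iteration.

        Promoter binding is linear at fixed signal level and copy number, so
        the bound-promoter pools are advanced with their exact exponential
        solution; reporters use an exponential update driven by the mean
        bound (or free) promoter over the sub-interval.  Promoter totals are
        resynchronised to the current copy numbers first.
        """
        cc = self.config.circuit
        ia = self.species_index[cc.species_a]
        ib = self.species_index[cc.species_b]
        nA = (self.free[:, ia] + self.blocked[:, ia]).astype(float)
        nB = (self.free[:, ib] + self.blocked[:, ib]).astype(float)
        self.pAa = np.minimum(self.pAa, nA)
        self.pBa = np.minimum(self.pBa, nB)
        s1, s2 = self.signals["s1"], self.signals["s2"]

        def bound_update(p, n_tot, kon_s):
            lam = cc.k2 + kon_s
            if lam <= 0:
                return p, p
            q = kon_s * n_tot / lam
            p_new = q + (p - q) * math.exp(-lam * dt_hours)
            return p_new, 0.5 * (p + p_new)

        self.pAa, pAa_mean = bound_update(self.pAa, nA, cc.k1 * s1)
        if cc.mode == "inducible":
            self.pBa, pBa_mean = bound_update(self.pBa, nB, cc.k1 * s2)
            gfp_driver = pBa_mean
        else:
            kon = (cc.k1r * cc.k2 if cc.s1_repression_includes_k2 else cc.k1r) * s1
            self.pBa, pBa_mean = bound_update(self.pBa, nB, kon)
            gfp_driver = nB - pBa_mean  # free promoter drives GFP when repurposed

        if cc.k4 > 0:
            decay = math.exp(-cc.k4 * dt_hours)
            gain = (1.0 - decay) / cc.k4
        else:
            decay, gain = 1.0, dt_hours
        self.RFP = self.RFP * decay + cc.k3 * pAa_mean * gain
        self.GFP = self.GFP * decay + cc.k3 * gfp_driver * gain

    def run(
        self,
        generations: float,
        on_generation: Optional[Callable[["World"], None]] = None,
    ) -> "World":
        """Step for ``generations`` doubling times; ``on_generation`` is
        called at construction time and after every completed generation.
        Exceeding the population cap with culling disabled stops the run
        cleanly (``stopped_early`` is set) with partial results intact."""
        G = self.config.iterations_per_generation
        if on_generation is not None and self.iteration == 0:
            on_generation(self)
        target = self.iteration + int(round(generations * G))
        try:
            while self.iteration < target:
                self.step()
                if on_generation is not None and self.iteration % G == 0:
                    on_generation(self)
        except PopulationCapExceeded:
            self.stopped_early = True
        return self


# ---------------------------------------------------------------------------
# mechanics
# ---------------------------------------------------------------------------


def _candidate_pairs(world: World, slack: float) -> tuple[np.ndarray, np.ndarray]:
    mech = world.config.mechanics
    radius = float(world.length.max()) + mech.width + slack
    tree = cKDTree(world.center)
    pairs = tree.query_pairs(radius, output_type="ndarray")
    if pairs.size == 0:
        return np.empty(0, dtype=np.intp), np.empty(0, dtype=np.intp)
    return pairs[:, 0].astype(np.intp), pairs[:, 1].astype(np.intp)


def relax_overlaps(world: World, max_sweeps: Optional[int] = None) -> World:
    """Iteratively push overlapping capsules apart.

    Each sweep moves every overlapping pair half the residual overlap apart
    along the line of closest approach (displacements accumulated over all
    pairs, each capped at half a cell width), until the worst overlap is
    below ``relax_tol * width`` or the sweep cap is reached.  After the
    first sweep only near-contact pairs are revisited (per-sweep moves are
    bounded, so distant pairs cannot start overlapping).  Also refreshes the
    world's cached contact pairs (surface distance <= contact gap)."""
    from ._geometry import half_lengths, pair_distances

    mech = world.config.mechanics
    if world.n < 2:
        world._contact_pairs = (np.empty(0, dtype=np.intp), np.empty(0, dtype=np.intp))
        return world
    if max_sweeps is None:
        max_sweeps = mech.relax_max_sweeps
    width = mech.width
    tol = mech.relax_tol * width
    margin = 0.5 * width
    cap = 0.5 * width
    pi, pj = _candidate_pairs(world, slack=margin)
    u = axis_vectors(world.angle)
    h = half_lengths(world.length, width)
    for sweep in range(max_sweeps):
        if pi.size == 0:
            break
        dist, direction = pair_distances(world.center, u, h, pi, pj)
        if sweep == 0:
            # keep near-contact pairs for later sweeps and the contact graph
            near = dist < width + mech.contact_gap + margin
            pi, pj = pi[near], pj[near]
            dist, direction = dist[near], direction[near]
        overlap = width - dist
        bad = overlap > tol
        if not bad.any():
            break
        push = np.minimum(0.5 * overlap[bad], cap)[:, None] * direction[bad]
        np.add.at(world.center, pi[bad], push)
        np.add.at(world.center, pj[bad], -push)
    # contact pairs from the final configuration
    dist, _ = pair_distances(world.center, u, h, pi, pj, want_direction=False)
    touching = dist <= width + mech.contact_gap
    world._contact_pairs = (pi[touching], pj[touching])
    return world


def contact_graph(world: World, gap: Optional[float] = None):
    """Contact graph over cell ids: an edge joins two cells whose capsule
    surfaces are within ``gap`` (default ``0.1 * width``).  Returns a
    :class:`networkx.Graph`."""
    import networkx as nx

    mech = world.config.mechanics
    if gap is None:
        gap = mech.contact_gap
    g = nx.Graph()
    g.add_nodes_from(int(i) for i in world.ids)
    if world.n < 2:
        return g
    pi, pj = _candidate_pairs(world, slack=gap + mech.width)
    if pi.size:
        dist, _ = capsule_pair_distances(
            world.center, world.angle, world.length, mech.width, pi, pj
        )
        touching = dist <= mech.width + gap
        for a, b in zip(world.ids[pi[touching]], world.ids[pj[touching]]):
            g.add_edge(int(a), int(b))
    return g
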