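"""The two plasmid propagation channels: vertical and horizontal transfer.

Vertical transfer happens at cell division: every plasmid copy (free or
blocked) independently ends up in either daughter with probability 1/2, and
afterwards each replication-active species with at least one free copy is
topped back up to its engineered setpoint.  Blocked copies and externally
repressed species are never amplified, so repression turns vertical
inheritance into binomial thinning — the mean per-cell copy number of a fully
repressed species halves every generation.

Horizontal transfer (conjugation) copies 2 or 3 plasmids of one species from
a donor into a touching, strain-compatible recipient.  The donor's counts are
unchanged; transferred copies arrive in the free (unblocked) state and are
re-blocked, if at all, by the recipient's own intracellular kinetics.
Conjugation is what keeps a repressed species alive long enough for task
switching to be reversible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Optional, Sequence

import numpy as np

from .intracell_ssa import SpeciesCounts

if TYPE_CHECKING:  # pragma: no cover
    from .colony import Cell, World

__all__ = [
    "PlasmidSpecies",
    "ConjugationPolicy",
    "SignalSchedule",
    "ScheduleEntry",
    "TransferEvent",
    "partition_plasmids",
    "replicate_to_setpoint",
    "attempt_conjugation",
    "apply_schedule",
]


@dataclass(frozen=True)
class PlasmidSpecies:
    """A plasmid type: identity, copy-number setpoint and replication flag.

    ``replication_active`` is False while the species is externally
    repressed; such a species is partitioned at division but never topped up.
    """

    id: str
    setpoint: int = 10
    replication_active: bool = True
    colour: Optional[str] = None

    def __post_init__(self) -> None:
        if self.setpoint < 1:
            raise ValueError("setpoint must be >= 1")


@dataclass(frozen=True)
class ConjugationPolicy:
    """Per-iteration conjugation behaviour.

    ``compatibility`` maps donor strain to allowed recipient strains
    (``None`` = unrestricted).
    """

    probability: float = 0.01
    copies_choices: tuple[int, ...] = (2, 3)
    compatibility: Optional[dict[str, Sequence[str]]] = None

    def compatible(self, donor_strain: str, recipient_strain: str) -> bool:
        if self.compatibility is None:
            return True
        return recipient_strain in self.compatibility.get(donor_strain, ())


@dataclass(frozen=True)
class TransferEvent:
    iteration: int
    donor: int
    recipient: int
    species: str
    copies: int


# ---------------------------------------------------------------------------
# vertical channel
# ---------------------------------------------------------------------------


def partition_plasmids(
    counts: SpeciesCounts, rng: np.random.Generator
) -> tuple[SpeciesCounts, SpeciesCounts]:
    """Split every plasmid copy of a dividing mother between two daughters.

    Each copy (free and blocked pools independently) goes to the first
    daughter with probability 1/2; the two outputs sum to the input exactly,
    per species and per pool.
    """
    first = SpeciesCounts()
    second = SpeciesCounts()
    for pool in ("free", "blocked"):
        src = getattr(counts, pool)
        d1 = getattr(first, pool)
        d2 = getattr(second, pool)
        for sp, n in src.items():
            k = int(rng.binomial(n, 0.5)) if n else 0
            d1[sp] = k
            d2[sp] = n - k
    return first, second


def partition_arrays(
    free: np.ndarray, blocked: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised :func:`partition_plasmids` for ``(m, S)`` count arrays."""
    f1 = rng.binomial(free, 0.5)
    b1 = rng.binomial(blocked, 0.5)
    return f1, b1, free - f1, blocked - b1


def replicate_counts(
    counts: SpeciesCounts,
    species_table: dict[str, PlasmidSpecies],
    replication_active: Optional[dict[str, bool]] = None,
) -> SpeciesCounts:
    """Top up a daughter's free copies to each species' setpoint.

    Only species that are replication-active (their own flag, optionally
    overridden by an external-repression map) and that retain at least one
    free copy replicate; blocked copies are never amplified and a species
    absent from the daughter stays absent.
    """
    out = counts.copy()
    for sp_id, n_free in list(out.free.items()):
        spec = species_table[sp_id]
        active = spec.replication_active
        if replication_active is not None and sp_id in replication_active:
            active = replication_active[sp_id]
        if active and n_free > 0:
            out.free[sp_id] = max(n_free, spec.setpoint)
    return out


def replicate_arrays(
    free: np.ndarray, setpoints: np.ndarray, active: np.ndarray
) -> np.ndarray:
    """Vectorised top-up: ``free`` is ``(m, S)``, ``setpoints``/``active`` are
    per-species.  Returns the replicated free counts."""
    eligible = (free > 0) & active[None, :]
    return np.where(eligible, np.maximum(free, setpoints[None, :]), free)


def replicate_to_setpoint(cell: "Cell", species_table: dict[str, PlasmidSpecies]) -> "Cell":
    """Cell-level top-up wrapper used right after partitioning."""
    from dataclasses import replace

    return replace(cell, counts=replicate_counts(cell.counts, species_table))


# ---------------------------------------------------------------------------
# horizontal channel
# ---------------------------------------------------------------------------


def _choose_species(totals: np.ndarray, rng: np.random.Generator) -> int | None:
    """Pick a species index with probability proportional to total copies."""
    grand = totals.sum()
    if grand <= 0:
        return None
    u = rng.random() * grand
    return int(np.searchsorted(np.cumsum(totals), u, side="right"))


def attempt_conjugation(
    donor: "Cell",
    neighbours: Sequence["Cell"],
    policy: ConjugationPolicy,
    rng: np.random.Generator,
    iteration: int = 0,
) -> Optional[TransferEvent]:
    """One conjugation attempt by ``donor`` toward its touching neighbours.

    With probability ``policy.probability`` the event fires: a recipient is
    drawn uniformly among strain-compatible neighbours, a species with
    probability proportional to its total (free + blocked) copies in the
    donor, and 2 or 3 copies are *added to the recipient's free pool* — the
    donor is untouched.  Returns the event, or ``None`` (the probability is
    consumed even when no compatible neighbour exists).
    """
    if rng.random() >= policy.probability:
        return None
    candidates = [nb for nb in neighbours if policy.compatible(donor.strain, nb.strain)]
    if not candidates:
        return None
    recipient = candidates[int(rng.integers(len(candidates)))]
    order = sorted(donor.counts.species())
    totals = np.array([donor.counts.total(sp) for sp in order], dtype=float)
    idx = _choose_species(totals, rng)
    if idx is None:
        return None
    species = order[idx]
    copies = int(policy.copies_choices[int(rng.integers(len(policy.copies_choices)))])
    recipient.counts.free[species] = recipient.counts.free.get(species, 0) + copies
    return TransferEvent(iteration, donor.id, recipient.id, species, copies)


def conjugation_sweep(world: "World", pair_i: np.ndarray, pair_j: np.ndarray) -> None:
    """Run every cell's per-iteration conjugation attempt on the current
    contact pairs, mutating the world's count arrays and appending to its
    transfer event log.  Decision order per firing donor matches
    :func:`attempt_conjugation`."""
    policy = world.policy
    n = world.n
    if n == 0 or policy.probability <= 0:
        return
    rng = world.rng
    fire = rng.random(n) < policy.probability
    donors = np.flatnonzero(fire)
    if donors.size == 0:
        return
    # adjacency (CSR) over both directions of the pair list
    src = np.concatenate([pair_i, pair_j])
    dst = np.concatenate([pair_j, pair_i])
    order = np.argsort(src, kind="stable")
    src, dst = src[order], dst[order]
    starts = np.searchsorted(src, np.arange(n + 1))
    compat = world.compatibility
    copies_choices = policy.copies_choices
    audit = world.audit
    for d in donors:
        nbrs = dst[starts[d] : starts[d + 1]]
        if nbrs.size == 0:
            continue
        ok = nbrs[compat[world.strain[d], world.strain[nbrs]]]
        if ok.size == 0:
            continue
        r = int(ok[int(rng.integers(ok.size))])
        totals = (world.free[d] + world.blocked[d]).astype(float)
        idx = _choose_species(totals, rng)
        if idx is None:
            continue
        copies = int(copies_choices[int(rng.integers(len(copies_choices)))])
        if audit:
            donor_before = int(totals.sum())
            recipient_before = int(world.free[r].sum() + world.blocked[r].sum())
        world.free[r, idx] += copies
        event = TransferEvent(
            world.iteration, int(world.ids[d]), int(world.ids[r]),
            world.species_order[idx], copies,
        )
        if audit:
            donor_after = int(world.free[d].sum() + world.blocked[d].sum())
            recipient_after = int(world.free[r].sum() + world.blocked[r].sum())
            world.conjugation_audit.append(
                (event, donor_before, donor_after, recipient_before, recipient_after)
            )
        world.transfer_events.append(event)


# ---------------------------------------------------------------------------
# external signal schedule
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScheduleEntry:
    """One piecewise-constant input window ``[t_start, t_end)`` in
    generations; ``target`` is a species id (external replication repression
    when level > 0) or a signal id (``s1``/``s2``)."""

    t_start: float
    t_end: float
    target: str
    level: float = 1.0

    def covers(self, t: float) -> bool:
        return self.t_start <= t < self.t_end


@dataclass
class SignalSchedule:
    """A list of :class:`ScheduleEntry` windows, queried by generation time."""

    entries: list[ScheduleEntry] = field(default_factory=list)

    def signal_level(self, signal: str, t: float) -> float:
        level = 0.0
        for e in self.entries:
            if e.target == signal and e.covers(t):
                level = e.level
        return level

    def repressed(self, species: str, t: float) -> bool:
        return any(e.target == species and e.level > 0 and e.covers(t) for e in self.entries)

    def validate_targets(self, species_ids: Sequence[str], signals: Sequence[str] = ("s1", "s2")) -> None:
        for e in self.entries:
            if e.target not in species_ids and e.target not in signals:
                raise KeyError(f"schedule targets unknown id {e.target!r}")


def apply_schedule(world: "World", schedule: SignalSchedule) -> "World":
    """Set the world's replication-active flags and circuit signal levels for
    the current generation time.

    External repression only suspends vertical replication (setpoint top-up);
    conjugation and the repressor activity of existing free copies continue.
    """
    schedule.validate_targets(world.species_order)
    t = world.generation
    active = world.base_replication_active.copy()
    for i, sp in enumerate(world.species_order):
        if schedule.repressed(sp, t):
            active[i] = False
    world.replication_active = active
    world.signals = {
        "s1": schedule.signal_level("s1", t),
        "s2": schedule.signal_level("s2", t),
    }
    return world
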