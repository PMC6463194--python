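"""Exact stochastic simulation of plasmid replication blocking inside a cell.

A repression rule "A blocks the replication of B" is the reversible pair

    A + B  --kb-->  A + Bb        (a free B copy becomes blocked)
    Bb     --ku-->  B             (a blocked copy is released)

where blocking is bimolecular in the *free* copies of repressor and target
(blocked plasmids are taken to be silenced, so a blocked repressor does not
block others) and unblocking is first order in the blocked copies.  An
optional literal mass-action form makes unblocking repressor-catalysed
(propensity ku * blocked * free repressor), matching the reverse reaction as
written with the repressor on both sides; it is off by default because a
repressor-catalysed release would freeze repression forever once the
repressor is lost.

Copies are never created or destroyed here — blocking only moves copies
between the free and blocked pools — so per-species totals are conserved
along every trajectory.  Rates are expressed per generation.

:func:`gillespie_run` is the single-cell direct-method simulator with an
event log; :func:`advance_population` advances every cell of a colony by one
time slice with the same statistics, vectorised across cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "RepressionRule",
    "SpeciesCounts",
    "Reaction",
    "build_reactions",
    "gillespie_run",
    "GillespieResult",
    "stationary_blocked_fraction",
    "CompiledRules",
    "compile_rules",
    "advance_population",
]


@dataclass(frozen=True)
class RepressionRule:
    """One 'repressor blocks target replication' edge.

    ``kb``: blocking rate per (repressor copy x target copy x generation);
    ``ku``: unblocking rate per blocked copy per generation.  Defaults are
    the published values.
    """

    repressor: str
    target: str
    kb: float = 1.0
    ku: float = 0.5

    def __post_init__(self) -> None:
        if self.kb < 0 or self.ku < 0:
            raise ValueError("rates kb, ku must be non-negative")
        if self.repressor == self.target:
            raise ValueError("a plasmid species cannot repress itself")


@dataclass
class SpeciesCounts:
    """Per-species free and blocked copy counts of one cell."""

    free: dict[str, int] = field(default_factory=dict)
    blocked: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for pool in (self.free, self.blocked):
            for sp, n in pool.items():
                if n < 0 or n != int(n):
                    raise ValueError(f"count of {sp!r} must be a non-negative integer")

    def species(self) -> set[str]:
        return set(self.free) | set(self.blocked)

    def total(self, species: str) -> int:
        return self.free.get(species, 0) + self.blocked.get(species, 0)

    def copy(self) -> "SpeciesCounts":
        return SpeciesCounts(dict(self.free), dict(self.blocked))


@dataclass(frozen=True)
class Reaction:
    """One SSA channel: ``kind`` is 'block' or 'unblock' of ``rule.target``."""

    kind: str
    rule: RepressionRule

    def propensity(self, counts: SpeciesCounts, catalyzed_unblocking: bool = False) -> float:
        r = self.rule
        if self.kind == "block":
            return r.kb * counts.free.get(r.repressor, 0) * counts.free.get(r.target, 0)
        a = r.ku * counts.blocked.get(r.target, 0)
        if catalyzed_unblocking:
            a *= counts.free.get(r.repressor, 0)
        return a

    def apply(self, counts: SpeciesCounts) -> None:
        t = self.rule.target
        if self.kind == "block":
            counts.free[t] = counts.free.get(t, 0) - 1
            counts.blocked[t] = counts.blocked.get(t, 0) + 1
        else:
            counts.blocked[t] = counts.blocked.get(t, 0) - 1
            counts.free[t] = counts.free.get(t, 0) + 1


def build_reactions(
    rules: Iterable[RepressionRule], species: Sequence[str] | None = None
) -> list[Reaction]:
    """Expand repression rules into the reaction set (two channels per rule).

    When ``species`` is given, rules referencing unknown species ids raise
    :class:`KeyError`.
    """
    reactions: list[Reaction] = []
    for rule in rules:
        if species is not None:
            for sp in (rule.repressor, rule.target):
                if sp not in species:
                    raise KeyError(f"rule references unknown species id {sp!r}")
        reactions.append(Reaction("block", rule))
        reactions.append(Reaction("unblock", rule))
    return reactions


@dataclass
class GillespieResult:
    """Outcome of a single-cell SSA run.

    ``events`` holds ``(t, reaction_index)`` pairs; ``blocked_time`` maps each
    species to its time-integrated blocked copy count, so the time-averaged
    blocked fraction of species s is ``blocked_time[s] / (t_end * total(s))``.
    """

    counts: SpeciesCounts
    events: list[tuple[float, int]]
    t_end: float
    blocked_time: dict[str, float]

    def blocked_fraction(self, species: str) -> float:
        total = self.counts.total(species)
        if self.t_end == 0 or total == 0:
            return 0.0
        return self.blocked_time[species] / (self.t_end * total)


def gillespie_run(
    counts: SpeciesCounts,
    reactions: Sequence[Reaction],
    t_max: float,
    rng_seed: int | np.random.Generator | None = None,
    max_events: int | None = None,
    record_events: bool = True,
    catalyzed_unblocking: bool = False,
) -> GillespieResult:
    """Direct-method SSA from ``counts`` until ``t_max`` (or ``max_events``).

    Identical seeds give bit-identical event logs.  When every propensity is
    zero the run returns early with the clock advanced to ``t_max``.
    """
    if t_max < 0:
        raise ValueError("t_max must be non-negative")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)

    counts = counts.copy()
    species = sorted(counts.species())
    events: list[tuple[float, int]] = []
    blocked_time = {sp: 0.0 for sp in species}
    t = 0.0
    n_events = 0
    while True:
        props = [rx.propensity(counts, catalyzed_unblocking) for rx in reactions]
        a0 = sum(props)
        if a0 <= 0.0:
            break
        tau = rng.exponential(1.0 / a0)
        if t + tau > t_max:
            break
        u = rng.random() * a0
        acc = 0.0
        for i, a in enumerate(props):
            acc += a
            if u < acc:
                break
        for sp in species:
            blocked_time[sp] += counts.blocked.get(sp, 0) * tau
        t += tau
        reactions[i].apply(counts)
        if record_events:
            events.append((t, i))
        n_events += 1
        if max_events is not None and n_events >= max_events:
            t_max = t  # stop the clock with the last event
            break
    # dwell time in the final state up to the end of the observation window
    for sp in species:
        blocked_time[sp] += counts.blocked.get(sp, 0) * (t_max - t)
    counts.validate()
    return GillespieResult(counts, events, t_max, blocked_time)


def stationary_blocked_fraction(repressor_copies: int, rule: RepressionRule) -> float:
    """Stationary probability that one target copy is blocked under ``R``
    constant free repressor copies: ``kb*R / (kb*R + ku)``.

    This is the two-state Markov chain stationary law (block at rate kb*R,
    release at rate ku) and serves as the analytic oracle for the SSA.
    """
    if repressor_copies < 0:
        raise ValueError("repressor_copies must be non-negative")
    if rule.kb == 0 and rule.ku == 0:
        raise ValueError("kb = ku = 0: stationary fraction undefined")
    num = rule.kb * repressor_copies
    if num == 0 and rule.ku == 0:
        raise ValueError("zero total rate: stationary fraction undefined")
    return num / (num + rule.ku)


# ---------------------------------------------------------------------------
# vectorised multi-cell advance (used by the colony engine)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CompiledRules:
    """Repression rules compiled to index arrays over a fixed species order."""

    species_order: tuple[str, ...]
    repressor_idx: np.ndarray  # (R,)
    target_idx: np.ndarray  # (R,)
    kb: np.ndarray  # (R,)
    ku: np.ndarray  # (R,)
    catalyzed_unblocking: bool = False

    @property
    def n_rules(self) -> int:
        return len(self.kb)


def compile_rules(
    rules: Sequence[RepressionRule],
    species_order: Sequence[str],
    catalyzed_unblocking: bool = False,
) -> CompiledRules:
    index = {sp: i for i, sp in enumerate(species_order)}
    try:
        rep = np.array([index[r.repressor] for r in rules], dtype=np.intp)
        tgt = np.array([index[r.target] for r in rules], dtype=np.intp)
    except KeyError as exc:
        raise KeyError(f"rule references unknown species id {exc.args[0]!r}") from exc
    return CompiledRules(
        tuple(species_order),
        rep,
        tgt,
        np.array([r.kb for r in rules], dtype=float),
        np.array([r.ku for r in rules], dtype=float),
        catalyzed_unblocking,
    )


def advance_population(
    free: np.ndarray,
    blocked: np.ndarray,
    rules: CompiledRules,
    dt: float,
    rng: np.random.Generator,
) -> None:
    """Advance every cell's blocking SSA by ``dt``, in place.

    ``free`` and ``blocked`` are ``(n_cells, n_species)`` integer arrays.
    Each cell runs an exact direct-method trajectory; the implementation
    interleaves the per-cell event loops so each round of vectorised draws
    fires at most one reaction per cell.  With one master generator the whole
    sweep is deterministic under a fixed seed.
    """
    if rules.n_rules == 0 or free.shape[0] == 0 or dt <= 0:
        return
    R = rules.n_rules
    clock = np.zeros(free.shape[0])
    active = np.arange(free.shape[0])
    while active.size:
        f = free[active]
        b = blocked[active]
        props = np.empty((active.size, 2 * R))
        props[:, :R] = rules.kb * f[:, rules.repressor_idx] * f[:, rules.target_idx]
        props[:, R:] = rules.ku * b[:, rules.target_idx]
        if rules.catalyzed_unblocking:
            props[:, R:] *= f[:, rules.repressor_idx]
        a0 = props.sum(axis=1)
        with np.errstate(divide="ignore"):
            tau = rng.exponential(size=active.size) / a0
        clock[active] += tau
        firing = clock[active] <= dt
        if not firing.any():
            break
        cells = active[firing]
        p = props[firing]
        u = rng.random(cells.size) * a0[firing]
        channel = (np.cumsum(p, axis=1) < u[:, None]).sum(axis=1)
        channel = np.minimum(channel, 2 * R - 1)
        is_block = channel < R
        rule_i = np.where(is_block, channel, channel - R)
        sp = rules.target_idx[rule_i]
        delta = np.where(is_block, -1, 1)
        # one event per cell per round: (cell, species) pairs are unique
        np.add.at(free, (cells, sp), delta)
        np.add.at(blocked, (cells, sp), -delta)
        active = cells
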