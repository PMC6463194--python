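"""Scenario runners for the in-silico experiments.

Every experiment is a pure function of (configuration, seed): it assembles a
:class:`SimulationConfig`, runs the colony engine with per-generation
checkpoints, and returns tidy results.  The scenarios cover

* ``fig1b_scan`` — deterministic dichotomy of the two-plasmid ODE model;
* ``retention`` — loss of a fully repressed plasmid with conjugation on/off;
* ``switch`` — externally triggered reversal of which plasmid dominates;
* ``clustering`` — spatial clusters of high-copy cells;
* ``nor`` — the 4-strain consortium computing a Boolean NOR;
* ``usecase_a`` / ``usecase_b`` — signal-sensing reporter circuits;
* ``robustness`` — task switching under tenfold-stronger repression.

Population sizes are desk-scale (tens to a few thousand cells) but large
enough to preserve the spatial contact structure the mechanism relies on.
Long experiments enable uniform random culling at the population cap, which
acts like washout and leaves per-cell statistics unbiased.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .colony import World
from .config import (
    CircuitConfig,
    ConjugationConfig,
    InitConfig,
    MechanicsConfig,
    RuleConfig,
    ScheduleEntryConfig,
    SimulationConfig,
    SpeciesConfig,
)
from .metrics_io import ClusterReport, detect_clusters, normalized_totals
from .ode_models import TwoPlasmidParams, integrate_two_plasmid

__all__ = [
    "ExperimentSpec",
    "EXPERIMENTS",
    "run_fig1b_scan",
    "run_retention",
    "run_switch",
    "run_clustering",
    "run_nor",
    "run_usecase",
    "run_robustness",
    "run_conservation_audit",
    "RetentionResult",
    "SwitchResult",
    "NorResult",
    "UsecaseResult",
    "AuditResult",
]

#: conjugation probability used to showcase horizontal rescue of a repressed
#: plasmid (top of the calibrated per-iteration range)
CONJUGATION_P = 0.05
#: conjugation probability for the switching-family experiments (low end of the
#: calibrated range): vertical dilution outpaces horizontal gain, so a repressed
#: plasmid is gradually flushed yet persists long enough to be recovered
CONJUGATION_P_SWITCH = 0.002


# ---------------------------------------------------------------------------
# deterministic scan
# ---------------------------------------------------------------------------


def run_fig1b_scan(
    A0_values: Sequence[float] = (50.0, 99.0, 100.0, 101.0, 200.0),
    k1: float = 1.5,
    ratio: float = 100.0,
    B0: float = 10.0,
    t_end: float = 200.0,
) -> pd.DataFrame:
    """Integrate the two-plasmid ODE for several constant A copy numbers.

    With ``k1/k2`` fixed at ``ratio``, plasmid B grows without bound when
    ``A0 < ratio``, is lost when ``A0 > ratio`` and stays put exactly at the
    knife edge — the instability that motivates conjugation as a stabiliser.
    Returns one row per ``A0`` with the final B, the fold change and a
    monotonicity classification.
    """
    rows = []
    for A0 in A0_values:
        params = TwoPlasmidParams(k1=k1, k2=k1 / ratio, A0=float(A0), B0=B0)
        traj = integrate_two_plasmid(params, t_end)
        B = traj[:, 2]
        diffs = np.diff(B)
        tol = 1e-9 * max(B0, B.max())
        if np.all(diffs >= -tol) and B[-1] > B0 * (1 + 1e-6):
            direction = "increasing"
        elif np.all(diffs <= tol) and B[-1] < B0 * (1 - 1e-6):
            direction = "decreasing"
        else:
            direction = "flat"
        rows.append(
            {
                "A0": float(A0),
                "B_final": float(B[-1]),
                "fold_change": float(B[-1] / B0),
                "direction": direction,
                "monotone": bool(np.all(diffs >= -tol) or np.all(diffs <= tol)),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# retention of a repressed plasmid (conjugation on/off)
# ---------------------------------------------------------------------------


def retention_config(
    conjugation_enabled: bool,
    n_start: int = 50,
    setpoint: int = 10,
    probability: float = CONJUGATION_P,
    growth_jitter: float = 0.0,
    population_cap: int = 2000,
) -> SimulationConfig:
    """Single plasmid species at setpoint 10 whose replication is externally
    repressed from the start; only the two transfer channels act on it."""
    return SimulationConfig(
        species=[SpeciesConfig(id="P", setpoint=setpoint, replication_active=False)],
        strains=["host"],
        init=InitConfig(
            cells_per_strain={"host": n_start},
            initial_counts={"host": {"P": setpoint}},
        ),
        conjugation=ConjugationConfig(
            probability=probability if conjugation_enabled else 0.0
        ),
        mechanics=MechanicsConfig(growth_jitter=growth_jitter),
        population_cap=population_cap,
        cull=True,
    )


@dataclass
class RetentionResult:
    """Per-generation per-cell copy-number distributions of the repressed
    plasmid, one trajectory per seed."""

    conjugation_enabled: bool
    per_cell: dict[int, dict[int, np.ndarray]]  # seed -> generation -> totals
    tables: dict[int, pd.DataFrame] = field(default_factory=dict)

    def mean_copies(self, seed: int, generation: int) -> float:
        return float(self.per_cell[seed][generation].mean())

    def fraction_carrying(self, seed: int, generation: int) -> float:
        return float((self.per_cell[seed][generation] >= 1).mean())


def run_retention(
    conjugation_enabled: bool,
    seeds: Sequence[int],
    generations: int = 6,
    n_start: int = 50,
    **config_kwargs,
) -> RetentionResult:
    """Track how a fully repressed plasmid (initial copy number 10) is
    diluted out of a growing colony, with or without conjugation."""
    result = RetentionResult(conjugation_enabled, {})
    for seed in seeds:
        config = retention_config(conjugation_enabled, n_start=n_start, **config_kwargs)
        world = World(config, seed=seed)
        snapshots: dict[int, np.ndarray] = {}
        rows = []

        def checkpoint(w: World) -> None:
            g = int(round(w.generation))
            totals = w.per_cell_totals("P").copy()
            snapshots[g] = totals
            rows.append(
                {
                    "generation": g,
                    "n_cells": w.n,
                    "mean_copies": float(totals.mean()),
                    "frac_carrying": float((totals >= 1).mean()),
                }
            )

        world.run(generations, on_generation=checkpoint)
        result.per_cell[seed] = snapshots
        result.tables[seed] = pd.DataFrame(rows)
    return result


# ---------------------------------------------------------------------------
# task switching (two species, external repression of the dominant one)
# ---------------------------------------------------------------------------


def switch_config(
    repress_at: Optional[float] = 6.0,
    release_at: Optional[float] = 12.0,
    kb_mult: float = 1.0,
    n_start: int = 50,
    population_cap: int = 300,
    probability: float = CONJUGATION_P_SWITCH,
    setpoint: int = 10,
    horizon: float = 1e9,
    circuit: Optional[CircuitConfig] = None,
    signal_entries: Sequence[ScheduleEntryConfig] = (),
    initial_counts: Optional[dict[str, int]] = None,
) -> SimulationConfig:
    """Two plasmids, A repressing B's replication, both starting at their
    setpoint; plasmid A can be externally repressed on a schedule."""
    schedule = list(signal_entries)
    if repress_at is not None:
        t_end = release_at if release_at is not None else horizon
        schedule.append(ScheduleEntryConfig(t_start=repress_at, t_end=t_end, target="A"))
    return SimulationConfig(
        species=[
            SpeciesConfig(id="A", setpoint=setpoint, colour="tab:red"),
            SpeciesConfig(id="B", setpoint=setpoint, colour="tab:green"),
        ],
        strains=["host"],
        init=InitConfig(
            cells_per_strain={"host": n_start},
            initial_counts={"host": initial_counts or {"A": setpoint, "B": setpoint}},
        ),
        rules=[RuleConfig(repressor="A", target="B", kb=1.0 * kb_mult, ku=0.5)],
        conjugation=ConjugationConfig(probability=probability),
        schedule=schedule,
        population_cap=population_cap,
        cull=True,
        circuit=circuit,
    )


@dataclass
class SwitchResult:
    """Per-generation species totals for each seed, plus the schedule."""

    repress_at: Optional[float]
    release_at: Optional[float]
    tables: dict[int, pd.DataFrame]

    def totals_at(self, seed: int, generation: float) -> tuple[float, float]:
        df = self.tables[seed]
        row = df.iloc[(df["generation"] - generation).abs().argmin()]
        return float(row["total_A"]), float(row["total_B"])

    def recovery_lag(self, seed: int) -> float:
        """Generations from repression onset until B's total first exceeds
        A's (inf if it never does)."""
        if self.repress_at is None:
            raise ValueError("no repression was scheduled")
        df = self.tables[seed]
        after = df[(df["generation"] >= self.repress_at) & (df["total_B"] > df["total_A"])]
        if after.empty:
            return float("inf")
        return float(after["generation"].iloc[0] - self.repress_at)


def run_switch(
    seeds: Sequence[int],
    repress_at: Optional[float] = 6.0,
    release_at: Optional[float] = 12.0,
    generations: float = 20.0,
    kb_mult: float = 1.0,
    **config_kwargs,
) -> SwitchResult:
    """Simulate dominance switching: A dominates, is externally repressed at
    ``repress_at`` (B takes over), and optionally released at ``release_at``
    (A returns).  Records population totals every generation."""
    tables: dict[int, pd.DataFrame] = {}
    for seed in seeds:
        config = switch_config(
            repress_at=repress_at, release_at=release_at, kb_mult=kb_mult, **config_kwargs
        )
        world = World(config, seed=seed)
        rows = []

        def checkpoint(w: World) -> None:
            t = w.totals()
            rows.append(
                {
                    "generation": round(w.generation, 6),
                    "iteration": w.iteration,
                    "n_cells": w.n,
                    "total_A": t["A"],
                    "total_B": t["B"],
                }
            )

        world.run(generations, on_generation=checkpoint)
        df = pd.DataFrame(rows)
        norm = normalized_totals(df[["total_A", "total_B"]].to_numpy())
        df["norm_A"] = norm[:, 0]
        df["norm_B"] = norm[:, 1]
        tables[seed] = df
    return SwitchResult(repress_at, release_at, tables)


def run_clustering(
    seed: int = 0,
    generations: int = 4,
    n_start: int = 50,
    population_cap: int = 600,
) -> tuple[World, ClusterReport]:
    """Produce a colony snapshot in which the repressed plasmid survives in
    localized patches, and report the detected clusters.  Growth-rate jitter
    is enabled to break the artificial division synchrony."""
    config = retention_config(
        True, n_start=n_start, growth_jitter=0.1, population_cap=population_cap
    )
    world = World(config, seed=seed)
    world.run(generations)
    return world, detect_clusters(world, "P")


# ---------------------------------------------------------------------------
# NOR consortium
# ---------------------------------------------------------------------------


def nor_config(
    input_a: int,
    input_b: int,
    n_computing: int = 30,
    n_per_sender: int = 15,
    setpoint: int = 10,
    population_cap: int = 400,
    probability: float = 0.005,
) -> SimulationConfig:
    """Four-strain consortium evaluating NOR(input_a, input_b).

    Input bits are encoded as presence/absence of the corresponding sender
    strain; the C sender (the output plasmid's carrier) is always present.
    Senders transfer plasmids to the computing strain only and never receive;
    both input plasmids repress the replication of output plasmid C.
    """
    strains = ["sender_a", "sender_b", "sender_c", "computing"]
    cells = {"sender_c": n_per_sender, "computing": n_computing}
    if input_a:
        cells["sender_a"] = n_per_sender
    if input_b:
        cells["sender_b"] = n_per_sender
    return SimulationConfig(
        species=[
            SpeciesConfig(id="A", setpoint=setpoint, colour="tab:red"),
            SpeciesConfig(id="B", setpoint=setpoint, colour="tab:green"),
            SpeciesConfig(id="C", setpoint=setpoint, colour="tab:blue"),
        ],
        strains=strains,
        init=InitConfig(
            cells_per_strain=cells,
            initial_counts={
                "sender_a": {"A": setpoint},
                "sender_b": {"B": setpoint},
                "sender_c": {"C": setpoint},
            },
        ),
        rules=[
            RuleConfig(repressor="A", target="C"),
            RuleConfig(repressor="B", target="C"),
        ],
        conjugation=ConjugationConfig(
            probability=probability,
            compatibility={
                "sender_a": ["computing"],
                "sender_b": ["computing"],
                "sender_c": ["computing"],
                "computing": [],
            },
        ),
        population_cap=population_cap,
        cull=True,
    )


@dataclass
class NorResult:
    """Readout of the computing strain for one NOR input case."""

    input_a: int
    input_b: int
    mean_copies: dict[int, dict[str, float]]  # seed -> species -> mean copies

    def dominant(self, seed: int, c_margin: float = 2.0) -> str:
        """Species with the highest mean copy number among computing cells;
        C is only called dominant if it leads the runner-up by ``c_margin``."""
        means = self.mean_copies[seed]
        ranking = sorted(means, key=means.get, reverse=True)
        top = ranking[0]
        if top == "C":
            runner = means[ranking[1]] if len(ranking) > 1 else 0.0
            if means["C"] < c_margin * max(runner, 1e-12):
                return ranking[1] if runner > 0 else "C"
        return top

    def output_bit(self, seed: int, c_margin: float = 2.0) -> int:
        return 1 if self.dominant(seed, c_margin) == "C" else 0


def run_nor(
    input_a: int,
    input_b: int,
    seeds: Sequence[int],
    generations: float = 8.0,
    **config_kwargs,
) -> NorResult:
    """Evaluate one input case of the distributed NOR gate and read out the
    dominant species among computing-strain cells at the final generation."""
    mean_copies: dict[int, dict[str, float]] = {}
    for seed in seeds:
        config = nor_config(input_a, input_b, **config_kwargs)
        world = World(config, seed=seed)
        world.run(generations)
        computing = world.strain == world.strain_names.index("computing")
        totals = world.free[computing] + world.blocked[computing]
        mean_copies[seed] = {
            sp: float(totals[:, j].mean()) for j, sp in enumerate(world.species_order)
        }
    return NorResult(input_a, input_b, mean_copies)


# ---------------------------------------------------------------------------
# signal-sensing use cases
# ---------------------------------------------------------------------------


def default_usecase_schedule(
    mode: str, switch_at: float = 8.0, horizon: float = 26.0
) -> list[ScheduleEntryConfig]:
    """Signal pulse trains for the two use cases, in generations.

    Plasmid A is externally repressed from ``switch_at`` to the horizon;
    signal pulses are interleaved on both sides of the switch (mode A drives
    s1 and s2; mode B uses the single signal s1 throughout).  The switch is
    scheduled at the point where the dormant plasmid is very low but still
    comfortably above the stochastic extinction floor at desk-scale
    population sizes — a compressed version of the published two-phase
    timeline; pass an explicit schedule to reproduce other timelines.
    """
    f = switch_at / 8.0
    entries = [ScheduleEntryConfig(t_start=switch_at, t_end=horizon, target="A")]
    for t0, t1 in [(1.0, 3.0), (5.0, 7.0), (21.0, 23.0)]:
        entries.append(
            ScheduleEntryConfig(t_start=t0 * f, t_end=t1 * f, target="s1", level=1.0)
        )
    if mode == "A":
        for t0, t1 in [(5.0, 7.0), (22.0, 25.0)]:
            entries.append(
                ScheduleEntryConfig(t_start=t0 * f, t_end=t1 * f, target="s2", level=1.0)
            )
    return entries


@dataclass
class UsecaseResult:
    mode: str
    tables: dict[int, pd.DataFrame]

    switch_at: float = 8.0

    def crosstalk_ratio(self, seed: int) -> float:
        """Mean GFP during s2 pulses before the switch relative to after:
        small values mean the dormant task ignored its signal (mode A)."""
        df = self.tables[seed]
        on = df[df["s2"] > 0]
        pre = on[on["generation"] < self.switch_at]["mean_GFP"].mean()
        post = on[on["generation"] >= self.switch_at]["mean_GFP"].mean()
        if not np.isfinite(pre) or not np.isfinite(post) or post == 0:
            return float("nan")
        return float(pre / post)


def run_usecase(
    mode: str,
    seeds: Sequence[int],
    schedule: Optional[Sequence[ScheduleEntryConfig]] = None,
    generations: float = 26.0,
    n_start: int = 50,
    population_cap: int = 300,
    probability: float = 0.01,
) -> UsecaseResult:
    """Simulate the reporter-circuit use cases over 50 generations.

    Mode ``A``: two inducible circuits (s1 drives RFP from plasmid A's
    promoter, s2 drives GFP from plasmid B's).  Mode ``B``: one signal that
    induces A's circuit and represses B's, whose free promoter expresses
    GFP.  The run starts with task A active (plasmid B held low, "in
    memory"); partway through, plasmid A is externally repressed, handing
    the population — and hence which signal is sensed — over to plasmid B.
    """
    if mode not in ("A", "B"):
        raise ValueError("mode must be 'A' or 'B'")
    entries = list(schedule) if schedule is not None else default_usecase_schedule(mode)
    signal_entries = [e for e in entries if e.target in ("s1", "s2")]
    repress = [e for e in entries if e.target == "A"]
    repress_at = repress[0].t_start if repress else None
    release_at = repress[0].t_end if repress else None
    circuit = CircuitConfig(mode="inducible" if mode == "A" else "repurposed")
    tables: dict[int, pd.DataFrame] = {}
    for seed in seeds:
        config = switch_config(
            repress_at=repress_at,
            release_at=release_at,
            n_start=n_start,
            population_cap=population_cap,
            probability=probability,
            circuit=circuit,
            signal_entries=signal_entries,
            initial_counts={"A": 10, "B": 4},
        )
        world = World(config, seed=seed)
        rows = []

        def checkpoint(w: World) -> None:
            t = w.totals()
            rows.append(
                {
                    "generation": round(w.generation, 6),
                    "s1": w.signals["s1"],
                    "s2": w.signals["s2"],
                    "mean_RFP": float(w.RFP.mean()),
                    "mean_GFP": float(w.GFP.mean()),
                    "total_A": t["A"],
                    "total_B": t["B"],
                }
            )

        world.run(generations, on_generation=checkpoint)
        tables[seed] = pd.DataFrame(rows)
    return UsecaseResult(mode, tables, switch_at=repress_at if repress_at is not None else 0.0)


# ---------------------------------------------------------------------------
# robustness to a stronger repression rate
# ---------------------------------------------------------------------------


def run_robustness(
    seeds: Sequence[int],
    kb_multiplier: float = 10.0,
    repress_at: float = 6.0,
    generations: float = 45.0,
    **config_kwargs,
) -> tuple[SwitchResult, SwitchResult]:
    """Paired switching runs at the baseline blocking rate and at
    ``kb_multiplier`` times it (same seeds, no release).  Stronger repression
    flushes B faster initially and delays its recovery, but the switch still
    completes."""
    base = run_switch(
        seeds, repress_at=repress_at, release_at=None, generations=generations,
        kb_mult=1.0, **config_kwargs,
    )
    strong = run_switch(
        seeds, repress_at=repress_at, release_at=None, generations=generations,
        kb_mult=kb_multiplier, **config_kwargs,
    )
    return base, strong


# ---------------------------------------------------------------------------
# conservation audit
# ---------------------------------------------------------------------------


@dataclass
class AuditResult:
    n_divisions: int
    n_conjugations: int
    division_violations: int
    conjugation_violations: int

    @property
    def ok(self) -> bool:
        return self.division_violations == 0 and self.conjugation_violations == 0


def run_conservation_audit(
    seed: int = 0, generations: float = 10.0, n_start: int = 20,
    population_cap: int = 250,
) -> AuditResult:
    """Run a two-species colony with full event logging and replay the logs.

    Checks that every division conserves copies before the replication
    top-up (mother = daughter1 + daughter2, per species and per free/blocked
    pool) and that every conjugation leaves the donor untouched while the
    recipient gains exactly the transferred copies.
    """
    config = switch_config(
        repress_at=5.0, release_at=None, n_start=n_start,
        population_cap=population_cap,
    )
    config = config.model_copy(update={"audit_divisions": True})
    world = World(config, seed=seed)
    world.run(generations)

    div_bad = 0
    for (_it, _mid, mf, mb, f1, b1, f2, b2) in world.division_audit:
        if not (np.array_equal(mf, f1 + f2) and np.array_equal(mb, b1 + b2)):
            div_bad += 1
    conj_bad = 0
    for event, donor_before, donor_after, rec_before, rec_after in world.conjugation_audit:
        if donor_before != donor_after or rec_after - rec_before != event.copies:
            conj_bad += 1
    return AuditResult(
        len(world.division_audit), len(world.conjugation_audit), div_bad, conj_bad
    )


# ---------------------------------------------------------------------------
# experiment registry (CLI entry points)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExperimentSpec:
    """A named experiment: default duration plus a runner used by the CLI.

    ``runner(seed, generations, **overrides)`` returns ``(world_or_None,
    timeseries DataFrame)``.
    """

    name: str
    generations: float
    runner: Callable[..., tuple[Optional[World], pd.DataFrame]]


def _cli_fig1b(seed: int, generations: float, **kw) -> tuple[None, pd.DataFrame]:
    return None, run_fig1b_scan()


def _cli_retention(seed: int, generations: float, conjugation: bool = True, **kw):
    res = run_retention(conjugation, [seed], generations=int(generations))
    return None, res.tables[seed]


def _cli_switch(seed: int, generations: float, kb_mult: float = 1.0, **kw):
    res = run_switch([seed], generations=generations, kb_mult=kb_mult)
    return None, res.tables[seed]

def _cli_competition(seed: int, generations: float, **kw):
    res = run_switch([seed], repress_at=None, release_at=None, generations=generations)
    return None, res.tables[seed]


def _cli_clustering(seed: int, generations: float, **kw):
    world, report = run_clustering(seed, generations=int(generations))
    rows = [
        {
            "cluster": i,
            "size": c.size,
            "centroid_x": c.centroid[0],
            "centroid_y": c.centroid[1],
            "mean_copy_number": c.mean_copy_number,
        }
        for i, c in enumerate(report.clusters)
    ]
    return world, pd.DataFrame(
        rows, columns=["cluster", "size", "centroid_x", "centroid_y", "mean_copy_number"]
    )


def _cli_nor(seed: int, generations: float, input_a: int = 0, input_b: int = 0, **kw):
    res = run_nor(input_a, input_b, [seed], generations=generations)
    means = res.mean_copies[seed]
    df = pd.DataFrame(
        [
            {
                "input_a": input_a,
                "input_b": input_b,
                "species": sp,
                "mean_copies_computing": means[sp],
                "dominant": res.dominant(seed),
                "output_bit": res.output_bit(seed),
            }
            for sp in sorted(means)
        ]
    )
    return None, df


def _cli_usecase(mode: str):
    def runner(seed: int, generations: float, **kw):
        res = run_usecase(mode, [seed], generations=generations)
        return None, res.tables[seed]

    return runner


def _cli_robustness(seed: int, generations: float, kb_mult: float = 10.0, **kw):
    base, strong = run_robustness([seed], kb_multiplier=kb_mult, generations=generations)
    df = pd.DataFrame(
        [
            {"kb_mult": 1.0, "recovery_lag": base.recovery_lag(seed)},
            {"kb_mult": kb_mult, "recovery_lag": strong.recovery_lag(seed)},
        ]
    )
    return None, df


EXPERIMENTS: dict[str, ExperimentSpec] = {
    "fig1b_scan": ExperimentSpec("fig1b_scan", 0.0, _cli_fig1b),
    "retention": ExperimentSpec("retention", 6.0, _cli_retention),
    "competition": ExperimentSpec("competition", 12.0, _cli_competition),
    "switch": ExperimentSpec("switch", 20.0, _cli_switch),
    "clustering": ExperimentSpec("clustering", 4.0, _cli_clustering),
    "nor": ExperimentSpec("nor", 8.0, _cli_nor),
    "usecase_a": ExperimentSpec("usecase_a", 26.0, _cli_usecase("A")),
    "usecase_b": ExperimentSpec("usecase_b", 26.0, _cli_usecase("B")),
    "robustness": ExperimentSpec("robustness", 45.0, _cli_robustness),
}
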