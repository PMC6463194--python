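"""Structured simulation configuration (validated with pydantic).

A :class:`SimulationConfig` fully determines a run together with a seed:
species table, repression rules, strains and their conjugation compatibility,
the conjugation policy, the external signal schedule, mechanics constants and
the generation clock.  Unknown keys are rejected so that config typos fail
loudly.  The resolved config is echoed to every output directory for
provenance.
"""

from __future__ import annotations

import warnings
from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

#: per-iteration conjugation probability range used in the source setting
CONJUGATION_PROBABILITY_RANGE = (0.001, 0.05)


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class SpeciesConfig(_Model):
    """One plasmid species: identity, copy-number setpoint and whether its
    replication is active (externally repressed species start inactive)."""

    id: str
    setpoint: int = Field(default=10, ge=1)
    replication_active: bool = True
    colour: Optional[str] = None


class RuleConfig(_Model):
    """Replication-blocking edge: ``repressor`` blocks ``target``."""

    repressor: str
    target: str
    kb: float = Field(default=1.0, ge=0)
    ku: float = Field(default=0.5, ge=0)


class ConjugationConfig(_Model):
    """Per-iteration conjugation policy.

    ``probability`` is the chance that a given cell attempts one conjugation
    event in one iteration; ``copies`` the candidate number of plasmid copies
    transferred per event (drawn uniformly); ``compatibility`` maps each donor
    strain to the strains it may send to (``None`` means everyone may send to
    everyone).
    """

    probability: float = Field(default=0.01, ge=0.0, le=1.0)
    copies: tuple[int, ...] = (2, 3)
    compatibility: Optional[dict[str, list[str]]] = None
    allow_out_of_range: bool = False

    @model_validator(mode="after")
    def _check_probability(self) -> "ConjugationConfig":
        lo, hi = CONJUGATION_PROBABILITY_RANGE
        if self.probability > 0 and not lo <= self.probability <= hi:
            if self.allow_out_of_range:
                warnings.warn(
                    f"conjugation probability {self.probability} outside the"
                    f" calibrated range [{lo}, {hi}]",
                    stacklevel=2,
                )
            else:
                raise ValueError(
                    f"conjugation.probability {self.probability} outside"
                    f" [{lo}, {hi}]; set allow_out_of_range=true to override"
                )
        if any(c < 1 for c in self.copies):
            raise ValueError("copies per conjugation event must be >= 1")
        return self


class ScheduleEntryConfig(_Model):
    """Piecewise-constant external input on ``[t_start, t_end)`` generations.

    ``target`` is a species id (level > 0 means its replication is externally
    repressed in the window) or a signal id (``s1``/``s2``, level is the
    signal concentration in [0, 1]).
    """

    t_start: float = Field(ge=0)
    t_end: float
    target: str
    level: float = Field(default=1.0, ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _check_window(self) -> "ScheduleEntryConfig":
        if self.t_end <= self.t_start:
            raise ValueError("schedule entry must have t_end > t_start")
        return self


class MechanicsConfig(_Model):
    """Rod-cell geometry and overlap-relaxation constants (arbitrary length
    units; cells are born at length ``L0`` and divide at ``2*L0``)."""

    L0: float = Field(default=2.0, gt=0)
    width: float = Field(default=1.0, gt=0)
    contact_gap_factor: float = Field(default=0.1, ge=0)
    relax_tol: float = Field(default=0.05, gt=0)
    relax_max_sweeps: int = Field(default=20, ge=1)
    angle_noise: float = Field(default=0.1, ge=0)
    growth_jitter: float = Field(default=0.0, ge=0, lt=1)

    @property
    def contact_gap(self) -> float:
        return self.contact_gap_factor * self.width


class CircuitConfig(_Model):
    """Optional per-cell reporter circuit carried by two plasmid species."""

    mode: Literal["inducible", "repurposed"] = "inducible"
    species_a: str = "A"
    species_b: str = "B"
    k1: float = Field(default=1.0, ge=0)
    k2: float = Field(default=50.0, ge=0)
    k3: float = Field(default=200.0, ge=0)
    k4: float = Field(default=1.0, ge=0)
    k1r: float = Field(default=30.0, ge=0)
    s1_repression_includes_k2: bool = True


class InitConfig(_Model):
    """Initial population: cells per strain, their plasmid loadout (free
    copies per species), and an optional seeding-disc radius."""

    cells_per_strain: dict[str, int]
    initial_counts: dict[str, dict[str, int]] = Field(default_factory=dict)
    radius: Optional[float] = Field(default=None, gt=0)

    @model_validator(mode="after")
    def _check_counts(self) -> "InitConfig":
        if not self.cells_per_strain:
            raise ValueError("cells_per_strain must name at least one strain")
        for strain, n in self.cells_per_strain.items():
            if n < 0:
                raise ValueError(f"negative cell count for strain {strain!r}")
        for counts in self.initial_counts.values():
            for sp, c in counts.items():
                if c < 0:
                    raise ValueError(f"negative initial count for species {sp!r}")
        return self


class SimulationConfig(_Model):
    """Complete, validated description of one colony simulation."""

    species: list[SpeciesConfig]
    strains: list[str] = Field(default_factory=lambda: ["wt"])
    init: InitConfig = Field(
        default_factory=lambda: InitConfig(cells_per_strain={"wt": 50})
    )
    rules: list[RuleConfig] = Field(default_factory=list)
    conjugation: ConjugationConfig = Field(default_factory=ConjugationConfig)
    schedule: list[ScheduleEntryConfig] = Field(default_factory=list)
    mechanics: MechanicsConfig = Field(default_factory=MechanicsConfig)
    iterations_per_generation: int = Field(default=450, ge=1)
    hours_per_generation: float = Field(default=1.0, gt=0)
    population_cap: int = Field(default=2000, ge=1)
    cull: bool = False
    catalyzed_unblocking: bool = False
    circuit: Optional[CircuitConfig] = None
    audit_divisions: bool = False
    seed: Optional[int] = None

    @model_validator(mode="after")
    def _cross_check(self) -> "SimulationConfig":
        ids = [sp.id for sp in self.species]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate species ids")
        known = set(ids)
        for rule in self.rules:
            for sp in (rule.repressor, rule.target):
                if sp not in known:
                    raise ValueError(f"rule references unknown species {sp!r}")
            if rule.repressor == rule.target:
                raise ValueError("a species cannot repress itself")
        strains = set(self.strains)
        if len(strains) != len(self.strains):
            raise ValueError("duplicate strain names")
        if self.conjugation.compatibility is not None:
            for donor, recipients in self.conjugation.compatibility.items():
                if donor not in strains:
                    raise ValueError(f"compatibility references unknown strain {donor!r}")
                for r in recipients:
                    if r not in strains:
                        raise ValueError(f"compatibility references unknown strain {r!r}")
        for strain in self.init.cells_per_strain:
            if strain not in strains:
                raise ValueError(f"init references unknown strain {strain!r}")
        for strain, counts in self.init.initial_counts.items():
            if strain not in strains:
                raise ValueError(f"init counts reference unknown strain {strain!r}")
            for sp in counts:
                if sp not in known:
                    raise ValueError(f"init counts reference unknown species {sp!r}")
        signal_ids = {"s1", "s2"}
        for entry in self.schedule:
            if entry.target not in known and entry.target not in signal_ids:
                raise ValueError(
                    f"schedule targets unknown species/signal {entry.target!r}"
                )
        if self.circuit is not None:
            for sp in (self.circuit.species_a, self.circuit.species_b):
                if sp not in known:
                    raise ValueError(f"circuit references unknown species {sp!r}")
        return self

    @property
    def species_order(self) -> tuple[str, ...]:
        return tuple(sp.id for sp in self.species)
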