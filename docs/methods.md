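# Methods

## Model overview

`plasmidswitch` simulates a growing 2D colony of rod-shaped bacteria in
which plasmid copy numbers are the controlled quantity. Three coupled layers
run at different levels of description:

1. **Deterministic models** (`ode_models`) — the two-plasmid
   replication-repression system (dA/dt = 0, dB/dt = k1·B − k2·A·B) and the
   plasmid-borne reporter circuits of the use cases, integrated with LSODA.
2. **Intracellular stochastic kinetics** (`intracell_ssa`) — per cell, an
   exact Gillespie simulation of replication blocking:
   A + B →(kb) A + Bb and Bb →(ku) B. Blocking is bimolecular in the *free*
   copies of repressor and target; unblocking is first-order in the blocked
   copies. Copies are conserved: blocking only moves them between pools.
3. **Agent-based colony** (`colony`, `gene_flow`) — capsule-shaped cells
   grow linearly, divide on a 450-iteration generation clock, relax
   mechanical overlap, and exchange plasmids vertically (division) and
   horizontally (conjugation over the contact graph).

One `World.step()` applies, in order: external signal schedule → growth →
divisions → mechanical relaxation → conjugation attempts → SSA advance by
1/450 generation → reporter-circuit advance. A single master
`numpy.random.Generator` drives every stochastic choice, so a run is
bit-reproducible from (config, seed).

## Parameters

| parameter | default | units | notes |
|---|---|---|---|
| `k1`, `k2` (two-plasmid ODE) | 0.05, 0.005 | 1/time, 1/(copy·time) | reference values; the equilibrium condition is A = k1/k2, so experiments that probe the equilibrium at A = 100 set the ratio to 100 explicitly |
| `kb`, `ku` | 1, 0.5 | 1/(copy·generation), 1/generation | blocking/unblocking rates of replication repression |
| circuit `k1, k2, k3, k4, k1r` | 1, 50, 200, 1, 30 | molecules & hours | signal binding, unbinding, expression, degradation, repression of pB by s1 |
| setpoint | 10 | copies/cell | engineered copy number restored after division |
| iterations per generation | 450 | — | the generation clock |
| conjugation probability | 0.001–0.05 | per cell per iteration | see below; experiments pin specific values |
| copies per conjugation event | 2 or 3 (uniform) | copies | recipient gains, donor unchanged |
| `L0`, width | 2, 1 | arbitrary length | birth length and capsule width; division at 2·L0 |
| contact gap | 0.1·width | length | surface distance defining "touching" |
| population cap | 2000 | cells | uniform random culling (washout) when enabled |
| hours per generation | 1 | h | converts the circuit rates' hour clock to the colony clock |

### Conjugation probability per experiment

The per-iteration conjugation probability spans a calibrated range
(0.001–0.05) and its value selects a regime. With ~450 iterations per
generation, a cell attempts p·450 conjugations per generation, each adding
2–3 copies to a neighbour, while vertical dilution of a repressed species
removes half its copies per generation. The balance point sits near
p ≈ 0.004 at setpoint 10:

- **retention** uses p = 0.05 (and p = 0) — the extreme contrast between a
  conjugation-stabilised plasmid and pure binomial flushing;
- **switch / robustness** use p = 0.002 — below the balance point, so an
  externally repressed species is genuinely flushed (vertical loss dominates
  horizontal gain) yet survives long enough to be re-amplified, which is the
  regime the switching mechanism needs;
- **NOR** uses p = 0.005 — no external repression is involved; this simply
  sets how fast sender strains deliver plasmids into the computing strain;
- **use cases** use p = 0.01 — at desk scale the dormant plasmid's *carrier
  fraction* can only grow through conjugation (setpoint top-up plus uniform
  culling keep it constant otherwise), so the post-switch hand-over needs
  the stronger horizontal channel.

### Use-case timeline

The signal-sensing use cases follow a two-phase schedule: task A active
first, then plasmid A externally repressed so task B takes over. The default
schedule represses A at generation 8 of 26 with interleaved signal pulses on
both sides, and the population starts with plasmid B at 4 copies/cell
(task B dormant "in memory"). This is a compressed version of the published
two-phase timeline (switch at generation 40 of 50): in colonies of a few
hundred cells a plasmid repressed for 40 generations crosses the stochastic
extinction floor at every conjugation rate that still allows the dominant
plasmid to flush after the switch. The compression preserves the phenomena —
which signal is sensed, residual cross-talk, reversibility — while keeping
the dormant species viable; any other timeline can be supplied as an
explicit schedule. Because the dynamic range of per-cell copy numbers is
compressed along with the timeline, the "dormant task ignores its signal"
claim holds as a *relative* statement (pre-switch response well below
post-switch response), not as an absolute zero.

## Vertical and horizontal transfer rules

- Partitioning is an independent fair coin per plasmid copy, free and
  blocked pools alike; the daughters' counts sum exactly to the mother's.
- After partitioning, each replication-active species with ≥ 1 free copy in
  a daughter is topped up to its setpoint (`max(free, setpoint)` — an
  overshoot from conjugation is kept, since replication control can only add
  copies). Blocked copies are never amplified, and an externally repressed
  species is not amplified at all: repression converts vertical inheritance
  into binomial thinning, giving the 10·2^(−g) dilution law that the tests
  verify against 20 replicate colonies.
- Conjugation: each cell fires with probability p per iteration; a recipient
  is drawn uniformly among strain-compatible touching neighbours, a species
  proportionally to its total copies in the donor (the neutral choice; the
  mechanism is not specified further), and 2–3 copies arrive in the
  recipient's *free* pool. Repressor–operator complexes are not
  co-transferred, so blocked copies arrive unblocked and are re-blocked by
  the recipient's own kinetics. The donor's counts are never debited.
- External repression (schedules) suspends only setpoint top-up. Existing
  free copies keep acting as repressors until diluted, and the repressed
  species continues to conjugate.

## Intracellular kinetics: design choices

The reversible blocking reaction is written in the source system with the
repressor on both sides. Implemented literally (mass-action in both
directions) the release step would stall whenever the repressor is absent,
freezing repression forever in any cell that lost its repressor — which
contradicts the observed recovery of the repressed species after the
repressor is externally flushed. Unblocking is therefore first-order in the
blocked copies by default; the literal repressor-catalysed form is available
as `catalyzed_unblocking=true`. Blocked plasmids are treated as fully
silenced: they neither replicate nor act as repressors.

The colony advances every cell's SSA by one iteration (1/450 generation) per
step using a vectorised exact direct method: each round of array draws fires
at most one reaction per cell and re-draws waiting times only for cells that
fired, which is statistically identical to per-cell Gillespie loops. The
stationary blocked fraction kb·R/(kb·R + ku) of a single target copy under R
repressor copies serves as the analytic oracle; the single-cell and
vectorised implementations are both tested against it.

## Reporter circuits

Signals are exogenous, piecewise-constant inputs in [0, 1]; their ODEs are
taken as zero by default (an optional signal-conservation mode integrates
the signal balances verbatim). Promoter binding at fixed signal and copy
number is linear, so inside the colony the bound-promoter pools advance by
their exact exponential solution each iteration and the reporters by an
exponential update driven by the interval-mean bound (or free) promoter —
exact in the limit of slowly varying drivers and O(dt²) otherwise, with
dt = 1/450 h. Promoter totals are resynchronised to the cell's current copy
number once per iteration (copy number changes on the generation timescale,
binding on the ~1/k2 ≈ 72-second timescale). Standalone integration uses
LSODA with rtol 1e−8 / atol 1e−10, surfacing failures as errors and clipping
tolerance-level negative undershoot to zero with a warning.

The repurposed circuit's repression flux is implemented with the doubled
rate factor k1r·k2 exactly as published; `s1_repression_includes_k2=False`
drops the inner k2. The flux acts on the free promoter pB (acting on the
bound form, as the signal-balance equation literally reads, could never
initiate repression from pBa = 0); closed-form fixed points and long-time
integration agree to < 1e−6 relative in the tests for both modes.

## Mechanics

Cells are 2D capsules. The DiSCUS-style rigid-body physics is replaced by
overlap relaxation: pairs whose centreline distance is below the width are
pushed apart along the line of closest approach, half the overlap each
(capped at half a width per sweep), until the worst overlap is below 5% of
the width. Because a dense colony's growth pressure would otherwise have to
propagate outward one contact shell per sweep, each step first applies a
global affine expansion of positions by the square root of the total-length
growth factor, leaving only local rearrangements to the pairwise solver.
Candidate pairs come from a cKDTree query; after the first sweep only
near-contact pairs are revisited. The simplification is justified because
the population-level results depend on the contact structure (who touches
whom), not on force fidelity. Daughters are placed end-to-end along the
mother's axis with ±0.1 rad orientation noise, which reproduces the
lineage alignment visible in colony snapshots.

Division occurs at twice the birth length, reached after exactly 450 growth
increments; initial cell lengths are drawn uniformly on [L0, 2·L0), which
desynchronises divisions across lineages while keeping each lineage's
division count exactly g after g generations — the property the dilution law
test relies on. Optional ±10% growth-rate jitter (used by the clustering
experiment) breaks the residual synchrony; with it, a colony still
quadruples over two generations to within a few percent.

There is no cell death; long experiments bound the population with uniform
random culling at a cap (default 2000), which acts like washout and leaves
per-cell statistics unbiased. With culling disabled, exceeding the cap stops
the run cleanly with partial results.

## Measurements

Species totals are normalised per time point so the most abundant plasmid
maps to 1. Clusters are connected components of the contact graph restricted
to cells whose copy number is at least the population median + 1 MAD (the
"high concentration" criterion is qualitative in the source; the MAD rule is
this package's declared convention). Copy-number histograms, snapshots
(JSON), event logs (CSV) and resolved configs are written per run for
provenance; an audit mode logs every division and conjugation so the tests
can replay them and verify exact copy conservation.

## What the simulations do and do not show

The experiments are generative: all inputs are configurations, and the
colony itself is the synthetic data source. Populations are desk-scale
(50–2000 cells, 6–30 generations), large enough to preserve spatial contact
structure but far smaller than real microcolonies; consequences are noted
where they matter (compressed use-case timeline, conjugation-sustained
floors of a few copies per cell). The model omits cell death, nutrient
fields, metabolic burden of plasmid carriage, plasmid incompatibility
groups, 3D geometry, and motility. Mechanical forces are schematic. Passing
tests therefore demonstrate the internal consistency of the control
mechanism — dilution, rescue, switching, distributed logic — under these
idealisations, not quantitative agreement with any particular wet-lab
system.

## Known limitations

- The contact-shell relaxation leaves residual overlaps up to ~5% of a cell
  width; the contact graph treats surfaces within 0.1 width as touching.
- The per-iteration circuit update assumes signals and copy numbers constant
  within an iteration (1/450 generation).
- Culling is uniform and memoryless; spatially structured washout (e.g.
  edge-biased) is not modelled.
- The NOR gate's readout margin ("C dominant" requires a twofold lead)
  mirrors a colour-dominance readout and is a convention, not a fitted
  threshold.
- Under tenfold-stronger repression (the robustness experiment) the
  repressed-then-recovering plasmid hovers near ~100 copies for tens of
  generations, an absorbing random walk: in a minority of seeds (~2/10 at
  population cap 300) it goes extinct instead of completing the switch. The
  experiment's 45-generation horizon is set so the delayed reversal (median
  recovery lag ~26 generations, versus ~4 at the baseline rate) is
  observable in the seeds where B survives; the tests assert completion for
  the median run and dominance in the majority, not in every seed.
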