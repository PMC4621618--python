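# Methods

germsim couples two long-standing formalisms into one model of germ-cell
development in the *C. elegans* gonad: a **qualitative network** (QN) for
each cell's signaling state and **Brownian dynamics** (BD) for its physical
motion, joined by an interface layer that turns position into signaling
inputs and signaling state into physical events.

## Qualitative networks

A QN is a finite synchronous dynamical system. Variable `v` holds an
integer level in `[0, N_v]` (`N_v = 1` for Boolean variables) and has a
target function `T_v`; each tick, every variable moves one level toward its
clamped target, all variables updating concurrently from the same
predecessor state. Executions are deterministic, so every run ends in a
cycle; a network is *stabilizing* when all states reach one length-1 cycle.

Two target forms exist. The default is the rounded average difference
`round(mean(activators) − mean(inhibitors))`, clamped to the variable's
range, with an empty regulator set contributing 0. Fractional halves round
away from zero — the printed sources do not fix the convention, so we chose
the deterministic one used by common executable-biology tools. The second
form is an explicit integer expression tree over `min/max/+/−/×/constants`,
which is what latches ("become, and remain, active") need.

Attractor search is exhaustive and vectorised: the full successor table is
built once (the same batched evaluator drives per-cell simulation), then
pointer doubling lands every state on its terminal cycle in `O(S log S)`
gathers. A guard (default 2^20 states) refuses larger spaces rather than
silently sampling.

## The germline network

The shipped network (`data/germline_*.qn`, 19 Boolean variables) is a
minimal reconstruction of germ-cell signaling from the textual description
of the pathway, not a transcription of any published wiring diagram:

* inputs `DELTA`, `RASinput`, `MSP`, `RASdown` — the external conditions a
  compartment imposes;
* `DELTA → NOTCH → MITOSIS`, with NOTCH also suppressing `PACHYTENE`
  (`1 − NOTCH`) and resetting all downstream commitment latches — the
  distal niche both maintains mitosis and erases meiotic progression, which
  is what makes the niche environment globally stabilizing;
* `RASinput/VAB1 → RAS → MAPK`, the pachytene-exit signal; `MAPK` drives
  the `CEP1 → EGL1 → CED3` pro-apoptotic chain (length configurable; the
  chain only delays the output, it cannot change the MAPK–death
  relationship);
* commitment latches: `DIPLOTENE = min(1−NOTCH, max(DIPLOTENE, MAPK))`,
  `DIAKINESIS = min(1−NOTCH, max(DIAKINESIS, min(DIPLOTENE, 1−MAPK)))`,
  `MATURATION = min(1−NOTCH, max(MATURATION, min(DIAKINESIS, MAPK, VAB1)))`.
  Diplotene latching encodes that gene-expression changes downstream of
  MAPK persist after the ligand is left behind; gating maturation on the
  MSP-specific branch (`VAB1`) is essential — with maturation driven by
  bare MAPK, cells jittering across the growth-factor boundary transiently
  lose MAPK, latch diakinesis, regain MAPK and mature *before the bend*.
  Transient boundary diakinesis itself remains a real (and documented)
  property of the spatial-ligand variant; the timed variant excludes it;
* a meiotic cell-cycle block: `CCLICENSE` (cleared by NOTCH, otherwise
  held) gating a `CYCB`/`APC` negative-feedback loop. From initial states
  carrying the license the loop oscillates indefinitely in the ligand-free
  environment; the license is off on every state reachable from the niche's
  stable state, so the oscillation exists in the state space without ever
  being visited by a wild-type cell. This reproduces, in miniature, the
  coexistence of a stabilizing niche with a multistable, oscillatory
  ligand-free environment;
* exactly five Boolean fate variables (mitosis, pachytene, diplotene,
  diakinesis, maturation ⇒ 32 joint assignments); decoding picks the most
  advanced active stage, and pro-apoptotic status is read from `CED3`
  separately rather than counted as a fate.

In the `timed_ras` variant, `RAS = min(1−RASdown, max(RAS, RASinput,
VAB1))`: a one-tick `RASinput` pulse (fired when a cell's pachytene timer
crosses `ras_delay`) latches RAS until `RASdown` (bend entry) clears it.

## Stability propagation and the compartment chain

`prove_crossing(spec, env_stable, env_other)` certifies that a cell
shuttling by diffusion between two environments can only reach one fix
point in the second. It is a worklist closure over deterministic
trajectories: find the stable state A of the first environment (exhaustive
enumeration, or a sampled certificate above the guard); simulate A under
the other environment to its fix point B, collecting intermediates;
relax every collected state back to A under the stable environment,
forward-simulate every newly seen state, and repeat until closed
(`single_fixpoint`) or a different attractor appears (`counterexample`,
with the trace). Every intermediate state is seeded back — the safe
superset reading of "the set of states between A and B are collected".
The visited set is closed under both environments' updates (tested
directly), and on small networks the verdict is checked against full
product-graph enumeration.

`compartment_chain` iterates this along the gonad: terminal states of
compartment *k* seed compartment *k+1* (DELTA-active → ligand-free →
RAS-active → bend/RAS-down → MSP). Although four of the five environments
are multistable when all states are admitted, chain seeding admits exactly
one fate per compartment, in the canonical order — fate invariance is a
property of the *flow through* compartments, not of any single environment.

## Brownian dynamics

Positions update as `x' = x + dt·F·β + sqrt(2·kB·T·dt·β)·r` per axis, with
no velocity state (overdamped, momentum-free). Units are µm, s, pg, pN;
`kB·T` at 298 K is 4.114×10⁻³ pN·µm. The only force is harmonic repulsion
`F = k·δ` on boundary overlap `δ`, with `k = 36 pN/µm`, applied between
cells and against the static wall particles tiling the gonad surfaces.
Coincident centres (a measure-zero event after division) repel along the
cell's orientation axis, deterministically.

The damping scale `β` is exposed as `gamma/m` (per-mass damping; a
friction-coefficient reading `β = 1/gamma` is selectable via
`damping_mode`), because the literature value for the friction coefficient
in this setting is not dimensionally usable in the printed update equation.
The default `gamma = 0.2 pg·µm/(pN·s)` gives a 2 µm cell a 3D RMS thermal
displacement of ~0.006 µm per 0.3 s (~0.3% of its radius). The calibration
trades thermal mobility against integration cost: the explicit-Euler
contact relaxation time is `1/(2kβ)` ≈ 3 s at this setting, which the
adaptive timestep resolves in a few substeps, while a several-fold larger
mobility forces ~20 substeps per interval for no change in the emergent
flow (which is quasi-static: set by growth and removal rates, not by β).
Larger `gamma` remains a config knob for runs where thermal mixing per unit
time matters more than wall-clock cost.

The timestep is variable: each substep uses
`dt = min(dt_max, drift_fraction · r_min / max_i |F_i| β_i)` with
`dt_max = 3 s` and `drift_fraction = 0.1` — the largest drift displacement
never exceeds 10% of the smallest cell radius. Hybrid (physics ↔ QN)
updates run every 0.3 s by default; the desk-scale presets decimate the
hybrid interval to the 3 s timestep cap, which is the configuration that
makes two-simulated-day runs tractable on one CPU.

Division axes are unit vectors under rotational diffusion (isotropic
Gaussian kick of per-axis variance `2·D_rot·dt`, then renormalisation;
`D_rot = 10⁻⁴ s⁻¹`, decorrelating over a few hours — the randomisation of
cleavage planes that mixes the stem-cell pool).

Neighbour search is a KD-tree-built Verlet list (skin 0.8 µm, rebuilt when
any cell moves half the skin or grows past its allowance). Its contract is
exactness, not approximation: candidate pairs are a superset of possible
contacts, and tests compare against the all-pairs sum bitwise.

## Geometry

The gonad is a rigid U-tube in the x–z plane: distal cylinder (tip at
axial 0), half-torus bend, proximal cylinder capped at the far end, plus a
rachis — an inner coaxial cylinder spanning the distal arm only, which
forces the distal cells into a monolayer shell. All surfaces are tiled
deterministically with static wall particles (spacing ≤ the wall-particle
radius, so cells cannot tunnel). The *axial coordinate* of a point is the
arc length of its nearest centreline point; in the full-scale geometry the
RAS-activating region spans axial 100–120 µm with the bend starting at
120 µm. Exact organ dimensions are not published; the defaults (distal arm
120 µm, tube radius 10 µm, rachis 4.4 µm, bend radius 15 µm, proximal arm
100 µm) were chosen to satisfy those printed axial landmarks while leaving
the distal shell wide enough that a division-threshold cell fits between
the rachis and outer wall *including* the wall-particle radius each
surface adds — a narrower shell wall-squeezes full-grown mitotic cells
past the pressure threshold into permanent growth arrest.

## The interface layer

Every hybrid interval, in order: (1) BD substeps; (2) one synchronous QN
step per cell; (3) development on a frozen snapshot — growth, then
apoptosis, then division, then fertilization, so same-frame events cannot
cascade; (4) the executable update writes zone membership (or timers) into
the QN inputs. Ligand zones are half-open axis-aligned cuboids (DELTA at
the tip, RAS before the bend, MSP at the proximal end). In zone mode the
`RASdown` input is held at 0 — downregulation is simply the loss of the
zone ligand; in timed mode `RASdown` switches on at bend entry.

Growth is linear in radius. Mitotic-fate cells grow at a rate that takes a
newborn to the mean division threshold over `growth_period` (20 h), then
divide into two equal-volume daughters (`r_d = r_p·2^(−1/3)`) displaced
`±r_d` along the parent's orientation, copying the parent's QN state and
drawing fresh division thresholds from a normal distribution (sd = 10% of
the mean, clipped at ±2 sd — the clip prevents pathological thresholds
below the birth radius). Post-RAS cells (diakinesis/maturation fates) grow
at their own rate until they reach `oocyte_max_radius` — a full-grown
oocyte fills the tube lumen and stops. The explicit cap is needed because
the pressure feedback cannot arrest oocyte growth by itself: pressure is
the sum of contact-force magnitudes divided by surface area, which falls
as r⁻², so neighbour forces never catch up with a growing sphere. All
growth is additionally arrested while the cell's contact pressure exceeds
`pressure_threshold`; this negative feedback is what keeps a
death-defective gonad from rupturing. The default threshold (4 pN/µm²)
sits above the pressures of a normally packed monolayer (median ~0.5,
transient maxima ~2.4 in relaxed desk-scale runs) so that only genuine
crowding arrests growth.

Random events use the memoryless conversion
`p_step = 1 − (1−P)^(dt/period)`, so compounding over a period reproduces
the configured probability exactly. Apoptosis eligibility is MAPK activity
by default (gating on decoded fate or the CED3 output is a config switch;
the behaviour does not differ, since fate changes are themselves
MAPK-driven). Two mechanisms:

* **single-step** — an eligible cell dies and is removed with constant
  per-step probability;
* **multistep** — with constant per-step probability the cell shrinks by
  `shrink_quantum`; it dies on reaching `min_radius`. A cell must
  accumulate ~6–8 quanta, so death propensity integrates residence time
  (and smaller cells need fewer steps — the mechanism selects small cells
  for death). An additional explicit scaling of the hazard with time spent
  in the RAS region is available (`death_time_scaling`) but off by
  default, as the quantum-counting already provides the time integration.

Matured oocytes inside the MSP region are removed as fertilised until the
cap (150) is reached; afterwards the tube blocks and oocytes stack.

## Scenarios and scale

Presets: `wildtype`, `multistep_death`, `ced_off` / `ced_single_step`
(apoptosis disabled — the cell-death-defective mutant), `timed_ras`, and
desk-scale `mini_*` / `tiny*` variants. The full-scale wild-type scenario
(single founder, 21 simulated days, ~10³ cells, 150 fertilisations) is the
nightly configuration driven by `examples/full_run.py`; it is far outside
an interactive test budget.

The **mini** scenario is the quantitative desk-scale stand-in: a 70 µm
distal arm (RAS zone axial 50–70 µm), tube radius 9.6 µm, ~140 cells seeded
at steady flow (mitotic sizes in the distal shell, a single file of
oocytes grown backward from the proximal cap, QN states taken from the
compartment chain's terminal states), run for 2 simulated days with the
hybrid interval at the 3 s cap. Cell dimensions are larger than full scale
(division threshold 2.6 µm) so that ~10² cells fill the organ. The
**tiny** scenario shortens everything further and accelerates growth
(2 h division period); it is the fixture for fast behavioural tests, not
for quantitative claims.

Death calibration: the wild-type death hazard is, by construction,
calibrated to the biological anchor that at least half of the cells
passing the RAS region die. Steady-flow transit of the mini RAS zone takes
roughly a day (measured from run trajectories), and `death_period` is set
so a full transit carries ~60% mortality; the full-scale preset uses the
same hazard scaled to its ~4-day transit. The multistep shrink period is
chosen so the expected quantum count over one transit is near the count
needed to die, which both matches the ~50% mortality and concentrates
deaths at the bend end of the zone.

What the desk-scale runs do and do not show: they exercise every coupling
of the hybrid loop (zones → QN → fates → growth/division/death/
fertilisation → flow) under steady flow, with honest force resolution and
the real network; they do not reproduce full-organ cell counts, absolute
flow speeds, or multi-week clonal-dominance times, all of which depend on
organ size and the 21-day horizon. The synthetic seeding emulates a gonad
already in homeostasis; it does not model larval organogenesis, the
syncytial cytoplasm, sperm depletion with age, or deformable cell shapes.

## The scripted death-location experiment

Comparing death mechanisms needs hundreds of deaths, far more than a
desk-scale organ produces. `zone_transit_experiment` therefore scripts the
relevant physics: a packed single-file column in which cells are injected
at the distal edge of the RAS zone, advance at constant packing (a death
opens a gap that absorbs the push of the cells behind — the
incompressible-column abstraction of the gonad's packed tube, which is
also why apoptosis reduces flow), and receive the configured death
machinery each step. Under constant packing, occupancy along the zone is
nearly uniform, so single-step (constant-hazard) deaths fall uniformly
along the zone, while the multistep mechanism, whose cells must accumulate
quanta over their transit, kills predominantly at the bend end — the two
signatures the death-location analyses compare.

## Numerical and degenerate-input conventions

Round-half-away-from-zero for average-difference targets; half-open zone
membership (min corner in, max corner out); division processed in
descending cell-index order within a frame (removals cannot shift
later indices); deterministic RNG streams (one `numpy` Generator per run,
fixed draw order — two runs with one seed produce bit-identical event
logs); orientation fallback `+x` when no axis is defined; newborn cells
cannot re-divide in their birth frame (thresholds exceed birth radius by
construction except in the clipped tail). Newick export uses a fixed
dialect (labels on all nodes, branch lengths in hours, 6 significant
digits, censored leaves at run end) so exports are bit-reproducible;
round-tripping is tested against an independent parser.

## Known limitations

Exhaustive attractor search is bounded at ~10⁶ states (the germline
network's 2^19 fits; larger user networks need sampling). The
spatial-ligand variant admits transient diakinesis at the growth-factor
boundary (a genuine property of that mechanism, not a bug; the timed
variant excludes it). Pressure is an isotropic scalar — no stress tensor.
Wall particles are frozen — the gonad neither grows nor deforms. The
desk-scale apoptosis fraction is measured on resolved fates only, and
early in a run deaths resolve faster than maturations, so the measured
fraction sits above the long-run steady-state value; it is reported as a
lower-bounded quantity (≥50%) for exactly that reason.
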