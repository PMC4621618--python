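# germsim

A hybrid executable/physical model of germline stem-cell homeostasis in
*Caenorhabditis elegans*.

Each germ cell is simultaneously two things: a **particle** — an overdamped
sphere moving under Brownian dynamics inside a rigid U-shaped gonad tube —
and an **executable signaling state** — one state of a qualitative network
(QN) describing DELTA/NOTCH, RAS/MAPK and MSP signaling together with five
Boolean cell-fate variables. An interface layer couples the two every
0.3 s of simulated time: a cell's position decides which ligand zones write
its network inputs (DELTA at the distal tip, a RAS-activating growth
factor before the bend, sperm protein at the proximal end), and its network
state decides its physical life cycle — growth, division, shrinkage,
apoptosis, oocyte maturation and fertilization. On top of the simulator
sit lineage tracking (Newick phylogenies, clonal-dominance metrics), death-
location statistics, and a formal-analysis component that *proves* fate
progression is invariant across gonad compartments.

The package is for computational biologists studying stem-cell niches,
tissue-level homeostasis, and hybrid discrete/continuous modelling — both
as a concrete germline model and as a reusable QN engine + BD substrate.

## The model in brief

**Qualitative network.** Variables hold integers in `[0, N_v]`; each has a
target function `T_v` (by default `round(mean(activators) −
mean(inhibitors))`, clamped). All variables update synchronously, one step
toward the target:

    d' = d − 1  if T_v(s) < d, d > 0
    d' = d + 1  if T_v(s) > d, d < N_v
    d' = d      otherwise

Executions are deterministic and finite, so each ends in a cycle; if every
state reaches one fixed point, the network is *stabilizing*.

**Brownian dynamics.** Momentum-free positions with harmonic contact
repulsion (k = 36 pN/µm, including static wall particles tiling the tube):

    x' = x + dt·F·(γ/m) + sqrt(2·kB·T·dt·(γ/m))·r,   r ~ N(0, 1)

at T = 298 K, cell density 1.3 pg/µm³, variable timestep capped at 3 s.

**The invariance argument.** The DELTA niche environment is globally
stabilizing (every one of the network's 2¹⁹ states runs to a single
mitotic fixed point). `prove_crossing` shows this stability *propagates*:
a cell diffusing back and forth across the niche boundary can reach only
one fix point outside (pachytene), although the ligand-free environment in
isolation is multistable and oscillatory. Chaining compartments
(DELTA → no ligand → RAS → bend → MSP) yields exactly one decoded fate per
compartment: mitosis → pachytene → diplotene → diakinesis → maturation.

## A worked example

`examples/stability_proof.py` runs the formal analyses:

```text
crossing distal_tip -> no_ligand: single_fixpoint
  stable state A decodes mitosis
  fix point B decodes    pachytene
  accessible states checked: 8

compartment chain (each seeded by the previous):
  distal_tip     -> ['mitosis']
  meiotic_entry  -> ['pachytene']
  ras_zone       -> ['diplotene']
  bend           -> ['diakinesis']
  proximal       -> ['maturation']
```

Eight accessible states suffice to certify the crossing, and although the
five fate bits could combine into 32 states, the compartment chain admits
exactly one per compartment, in developmental order.

`examples/death_mechanisms.py` contrasts the two apoptosis mechanisms on a
steady-flow column through the 20 µm RAS zone (axial 0 = distal edge,
20 = the bend):

```text
single_step : 550 deaths (69% of transits), mean axial 9.7 um
  per-fifth counts [118, 114, 118, 94, 106]  uniformity chi2=3.8 p=4.36e-01
multistep   : 369 deaths (46% of transits), mean axial 16.1 um
  per-fifth counts [0, 5, 40, 98, 226]  uniformity chi2=475.2 p=1.51e-101
```

Single-step (constant-hazard) death is uniform along the zone; the
multistep shrink-then-die mechanism concentrates deaths at the bend end —
where apoptotic corpses are observed in the animal, the argument that
germ-cell death is a multistep process.

Other examples: `qn_attractors.py` (per-compartment attractor
enumeration), `mini_run.py` (a desk-scale organ run and its fate layout),
`lineage_metrics.py` (phylogenies, founder colouring, dominance),
`full_run.py` (the full-size 21-day organ; nightly-scale).

There is also a thin CLI: `germsim run|qn|prove|analyze|fixtures --help`.

## Layout

| module | contents |
| --- | --- |
| `germsim.qn` | generic QN engine: expressions, synchronous updates, exhaustive attractor search, `.qn` file I/O |
| `germsim.germline` | the germ-cell network (both variants), fate decoding, compartment environments |
| `germsim.physics` | BD integrator, contact forces, neighbour lists, orientation diffusion |
| `germsim.geometry` | the U-tube with rachis and wall-particle tiling, axial coordinates |
| `germsim.hybrid` | zones, scenario configs/presets, the interface layer and main loop |
| `germsim.lineage` | event-log → forest, Newick export, generation/dominance metrics |
| `germsim.stability` | `prove_crossing`, `compartment_chain` |
| `germsim.analysis` | death histograms/heatmaps, motion vector fields, event-rate series |

`docs/methods.md` documents the model assumptions, parameter defaults and
their calibrations, and what the desk-scale scenarios do and do not show.
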