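# Methods

`myopace` simulates the emergence of multicellular automaticity — the
collective spontaneous beating of a biological-pacemaker monolayer — from
three microscopic ingredients: the intrinsic oscillation of bias-current-
driven myocytes, the stochastic spatial arrangement of those pacemaker (PM)
cells among quiescent but excitable neighbors, and the discrete
intercellular coupling of a semi-discrete monolayer microstructure.  This
note records the models, the parameter choices and their rationale, the
numerical methods, and what the package's synthetic conditions do and do
not say about real monolayers.

## The cell model and its automaticity window

Each node of the tissue carries a Luo–Rudy phase-1 (LR1) ventricular
membrane: six ionic currents (fast Na⁺ `INa`, slow inward `Isi`,
time-dependent K⁺ `IK`, inward rectifier `IK1`, plateau K⁺ `IKp`, linear
background `Ib`), six Hodgkin–Huxley gates (`m, h, j, d, f, X`) and the
intracellular calcium concentration `Cai`.  Automaticity is induced by a
constant inward bias current `Ibias` (µA/cm²) subtracted from the total
outward ionic current, so

    dV/dt = −(I_ion − Ibias)/Cm .

Quiescent cells have `Ibias = 0`; PM cells carry a single value in
[2.6, 4.7] µA/cm² ("weak" 2.6 or "strong" 3.5 in the group protocols).

**Parameter set.**  The published 1991 LR1 parameters turn out not to
oscillate under a constant bias: their depolarized equilibrium is stable,
so a biased cell fires one action potential and halts.  We verified our
transcription independently (resting potential −84.5 mV, APD90 ≈ 362 ms,
a second blind transcription agreeing to 1e−10) before concluding the
behaviour is a property of the parameter set, not a coding slip.  The
package therefore ships an automaticity-enabled variant with three
conductances recalibrated once against the reference single-cell
bifurcation anchors and then frozen:

| parameter | 1991 value | default here |
|-----------|-----------:|-------------:|
| `g_si`    | 0.09       | 0.0703       |
| `g_K`     | 0.282      | 0.821        |
| `g_K1`    | 0.6047     | 0.695        |

Everything else (INa, all gate kinetics, Ca²⁺ handling, reversal
potentials) is the published set; `myopace.lr1.canonical_lr1()` returns the
unmodified parameters.  With the defaults the biased cell reproduces the
reference structure: sustained oscillation on `Ibias ∈ [2.555, 4.70]`
bounded by two cycle folds; subcritical Hopf bifurcations of the resting
and depolarized fixed-point branches at 2.556 and 4.461 (reference values
2.554 / 4.470); the lower Hopf point and lower fold within 0.01 of each
other (the subcritical signature); steady cycle lengths 1431 ms at
`Ibias = 2.6` and 590 ms at 3.5 (reference 1428 / 599).  One residual
discrepancy is documented rather than tuned away: our cycle-length curve is
steeper immediately above the lower fold (2060 ms at fold + 0.005 µA/cm²
versus a reference maximum of 1989 ms, and a sweep minimum of ~527 ms
versus 516), i.e. the lower fold of this variant has a partial
saddle-node-on-invariant-circle character.  Exploring additional knobs
(g_Na 10–23, Ca-removal rate 0.045–0.10/ms, X-gate speed) could not remove
this residual without breaking the anchors that match exactly.

**Bifurcation tooling.**  Equilibria are found by eliminating all gates and
`Cai` at their steady state given `V` (the Ca balance is solved by
bracketed bisection; `Isi` grows with `Cai` through its reversal potential,
so the root is unique), reducing the 8-D fixed-point problem to 1-D
bracketing of the steady-state current balance on a 0.25 mV grid.
Stability comes from the eigenvalues of the full 8-D Jacobian (central
finite differences, relative step 1e−6).  Hopf points are located by
bisecting the sign change of the leading eigenvalue real part along a
branch (tolerance 1e−3 µA/cm²).  The stable-cycle folds use a hysteresis
protocol: an oscillating state is carried from the previous bias value,
integrated through a 5 s transient, and "sustained oscillation" means ≥ 3
activations in a 10 s test window; the boundary is bisected to 1e−3.  The
cycle-length curve is swept with the oscillating state carried between grid
points and ≥ 3 transient cycles discarded at each.

## Microstructure

The monolayer is a regular grid of nodes at 6 µm spacing, fully partitioned
into contiguous "cells".  The reference full scale is 920 × 920 nodes and
42,642 cells (5.5 × 5.5 mm, ~19.85 nodes/cell).  Generation is a stochastic
Voronoi mosaic: exactly `n_cells` seeds are placed on a jittered stratified
lattice whose x/y spacings are in the ratio of the target aspect ratio
(AR), every node is assigned to its nearest seed in an anisotropy-scaled
metric (x compressed by AR), and a repair pass keeps each cell's largest
4-connected component and reassigns orphan fragments to adjacent cells.
This reproduces the reference geometry statistics without further tuning:
~20 ± 4 nodes/cell, ~5.6–6 neighbors/cell (planar mosaic property), AR
1.02 ± 0.21 for the isotropic target and 2.96 ± 0.71 for the anisotropic
target 3 (cell length ~52 µm, width ~18 µm).  Cell "length" is the
bounding-box x-extent (the anisotropy axis is x throughout), "width" the
y-extent.

**Coupling graph.**  Grid edges within a cell get the ohmic slab
conductance `thickness/ρ` (intracellular resistivity ρ = 200 Ω·cm,
monolayer thickness 10 µm → 5 µS per link).  Grid edges between cells are
gap junctions: 0.04 nS per 6 µm border edge in isotropic tissue, 0.062 nS
(x-crossing, longitudinal) and 0.034 nS (y-crossing, transverse) in
anisotropic tissue.  Membrane area per node is the node footprint
(6 µm)², with Cm = 1 µF/cm².

**The single calibrated scalar.**  Printed per-edge gap-junction
conductances cannot be combined with a per-footprint membrane capacitance
without a normalization convention: taken at face value they give a
junction-limited sheet conductance of ~0.2 nS per square and a conduction
velocity below 1 cm/s.  Since the intracellular links are orders of
magnitude stronger than the junctions (cells are nearly isopotential), no
physically plausible thickness can change this — the thickness only scales
the intracellular term.  The model therefore carries one dimensionless
scale (`COUPLING_SCALE = 252`) multiplying the gap-junction conductances,
calibrated once so the isotropic plane-wave conduction velocity is
15.0 cm/s, and frozen.  The two anisotropic velocities are then
parameter-free predictions and come out at 25.5 and 10.2 cm/s against
reference values 24.3 and 10.4 — the continuum scaling
`CV ∝ sqrt(g · L_cell)` of the junction-limited medium reproduces the
printed anisotropy ratios to a few percent.

## Pacemaker placement

PM cells are placed sequentially on the cell-adjacency graph (cells are
adjacent when they share at least one grid-edge border; the same notion
defines cluster connectivity).  After a uniformly random first PM cell,
each step draws p ~ U[0,1] and picks uniformly from the aggregation set M1
(quiescent cells with ≥ 1 PM neighbor) if `p > p_thr`, else from the
nucleation set M2 (quiescent cells with no PM neighbor); when M2 is empty
only aggregation remains, and the density at which M2 first empties is
recorded as `d_aut_max`.  The process stops at `round(d_aut · n_cells)` PM
cells — the count is exact by construction.  `p_thr` is reported on the
p_thr^(1/4) scale because of its strongly nonlinear effect.  Because
placements are sequential, patterns over a common RNG stream are nested in
`d_aut`, which makes the largest-cluster size monotone in density — a
property the tests exploit.

Cluster analytics: connected components of the PM-induced subgraph
(scipy's sparse component labeling, cross-checked in the tests against a
hand-written union–find); `S_T_cluster` adds the quiescent cells enclosed
by the largest cluster, operationalized as quiescent cells unreachable by a
flood fill from the boundary cells over all non-largest-cluster cells;
porosity is `1 − mean(S_cluster)/mean(S_T_cluster)` over realizations.

## Monodomain tissue solver

The tissue equation per node is

    dV_i/dt = −(I_ion,i − Ibias,i)/Cm + Σ_j g_ij (V_j − V_i) / (Cm A_i),

with no-flux boundaries realized simply by the graph having no links beyond
the domain.  Time stepping is operator-split: a table-driven
Rush–Larsen/forward-Euler reaction sub-step (voltage-dependent rate
quantities linearly interpolated from 0.02 mV tables; numba-compiled), then
an implicit backward-Euler diffusion solve using a sparse LU factorization
computed once per run.  The implicit diffusion step is the load-bearing
choice: intracellular conductances exceed junctional ones by ~10³, putting
the explicit stability limit near 10⁻⁷ ms, while backward Euler is
unconditionally stable and exactly preserves both spatially uniform states
and the area-weighted voltage sum (its amplification matrix inherits the
Laplacian's null space and conservation structure — both are tested).
Defaults: dt = 0.01 ms for single cells and strips, 0.02 ms for long
monolayer runs (halving dt changes strip activation times by < 0.5 ms and
single-cell cycle lengths by < 0.1%).

Activation times are interpolated upward crossings of −40 mV with a
refractory lockout until the node repolarizes below threshold.  Plane-wave
protocols clamp the leading node line to +20 mV for 2 ms; conduction
velocity is 1/slope of a linear fit of mean activation time versus distance
over the central 60% of the strip.

## Analysis layer

Network beats are temporal clusters of the pooled activation times
separated by gaps larger than 40% of the median per-node inter-activation
interval (minimum 100 ms) — robust in the strongly coupled, reentry-free
regime this model operates in; beats are matched across nodes by rank, and
beats covering < 90% of nodes (partial beats clipped by the simulation
window, local non-propagating firing) are excluded from all statistics.  A
simulation is *spontaneous* if ≥ 2 complete beats occur within its
duration, *non-automatic* for one or zero.

Per beat: the activation map, its normalized form (minimum exactly 0), the
cycle-length map (difference of consecutive same-rank maps; its spatial
median is the beat's cycle length), and the synchronization-time map —
the magnitude of the activation-map spatial gradient (s/cm, the inverse
local conduction velocity), estimated by least-squares plane fits over a
circular window of radius 5 nodes (30 µm), interior windows with complete
data only; boundary nodes are excluded by convention.  The per-simulation
cycle length and synchronization time are means of the per-beat medians
with the first action potential discarded (the stated convention for every
average; where the printed normalization of the synchronization-time
average is ambiguous about including the first beat, we exclude it for
consistency with the analysis window).  The focus of a beat is its
earliest-activated node (ties: centroid of the minimal set snapped to the
nearest member), classified against a centered square of half the domain
side: central inside; exclusive left/right borders longitudinal
(`border_L`); exclusive top/bottom transverse (`border_T`); corners are
excluded from the border-foci anisotropy ratio `r = η_L/η_T` (reported as
infinite, flagged, when `η_T = 0`).

Group aggregation over the realizations of one (d_aut, p_thr^(1/4)) pair
uses the spontaneous simulations only: means and n−1 standard deviations of
cycle length and synchronization time (undefined for n ≤ 1), the n-of-N
occurrence count, and min-to-max percentage ranges across pairs
(`100·(max−min)/min`, an error when the minimum is 0).  Transition curves
give, per homogeneity level, the minimum density reaching [n > 0] and
[n = N].

## Scale presets and what desk-scale runs mean

Orchestrated sweeps are deterministic end to end: each (base seed, group,
pair, realization) spawns its own numpy SeedSequence streams for
tessellation and placement, resumed sweeps skip completed keys, and reruns
are byte-identical.  Presets: `full` (920×920 nodes, 10 s — the reference
scale; geometry and placement run in seconds, tissue electrophysiology at
this size needs a cluster), `desk` (184×184, 6 s), `mini` (40×40 ≈ 0.24 mm,
5 s), `micro` (24×24, 2 s; smoke tests).  Geometry, placement and cluster
statistics are exercised at full scale throughout; tissue
electrophysiology is validated on strips (CV anchors at the stated
0.5 × 5 mm protocol) and on the small monolayer presets.

The small presets are far below the medium's electrotonic space constant
(~2 mm), so a mini monolayer is nearly isopotential and behaves like one
cell whose effective bias is roughly `d_aut · Ibias_pm`: occurrence
thresholds sit at much higher densities than at full scale, and foci and
porosity effects are compressed.  The stochastic trend checks therefore
compare matched conditions at high density (strong-versus-weak occurrence,
monolayer-versus-cell cycle length, anisotropic-versus-isotropic
synchronization time) rather than reproducing full-scale occurrence maps;
those trends are scale-robust and all reproduce.  Conversely, the
cluster-size transition (below 10,000 to above 30,000 PM cells around
d_aut ≈ 0.5) is a placement property and is reproduced at the genuine full
scale.

## Known limitations

* The exact published parameter variant behind the reference bifurcation
  diagram is not restated in the source; our three-conductance calibration
  reproduces its anchors to ≤ 0.3% but not the finite cycle length at the
  lower fold (see above).
* The gap-junction normalization scalar is a units convention fitted to one
  velocity; absolute conductance values should not be interpreted
  physiologically.
* Homogeneous initial conditions and identical PM cells, as in the
  reference protocol: no cellular heterogeneity, fibroblasts, conduction
  breaks, curved fibers, bidomain effects or mechanical coupling.
* Beat grouping assumes the reentry-free, strongly coupled regime; it is
  not a general arrhythmia detector.
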