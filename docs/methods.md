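# Methods

## Model

Each cell of a 2D (100x100) or 3D (50x50x50) lattice carries one state
variable, the membrane potential `V_i` (mV, relative to the exterior).  Its
charge balance is

    C_i dV_i/dt = -I_dep(V_i) - I_pol(V_i) + sum_j G_ij (V_j - V_i)

with the sum over the Moore neighborhood (8 neighbors in 2D, 26 in 3D; von
Neumann adjacency is available) and open boundaries: the domain edge is an
electric wall, and optional interior walls are bands of removed cells.

The two channel currents are Boltzmann-gated ohmic currents

    I_dep = G0_dep (V - E_dep) / (1 + exp(-z (V + V_T)/V_T))
    I_pol = G0_pol (V - E_pol) / (1 + exp(+z (V + V_T)/V_T))

and the gap-junction conductance between neighbors combines the two cells'
voltage-gated single-cell conductances in series, attenuated by the
transjunctional voltage difference:

    G_i0  = G0_max / (1 + exp(z (V_i - V_half)/V_T))
    G_ij0 = G_i0 G_j0 / (G_i0 + G_j0)
    G_ij  = 2 G_ij0 / (1 + cosh((V_i - V_j)/V_0))

Units are fixed as pF / nS / mV / ms, so currents are in pA and no
conversion constants appear anywhere; the slow single-cell time constant
C/G0_pol = 100 ms is explicit.

At the population-mean parameters (C = 100 pF, G0_pol = 1 nS, G0_dep = 2 nS,
G0_max = 1.5 nS, z = 3, E_dep = 0, E_pol = -60 mV, V_T = 26 mV,
V_half = 0 mV, V_0 = 24 mV) the isolated cell is bistable: a polarized
attractor at -56.73 mV, a depolarized attractor at -1.78 mV, and the
separatrix at -34.81 mV.  A cell is counted as "depolarized" when
V > -35 mV (configurable).

## Quenched heterogeneity

Cell diversity is quenched disorder: each parameter is drawn once per cell
from Normal(mean, sd) and held fixed.  With the global variability
multiplier sigma (default 3), the spreads are 0.02*sigma relative for C,
G0_pol, G0_dep and G0_max; sigma mV absolute for E_dep, E_pol, V_T and
V_half; 0.1 absolute for z (not sigma-scaled, but dropped when sigma = 0 so
that sigma = 0 reproduces the means exactly); and zero for V_0.  Strictly
positive parameters are redrawn, not clipped, on a non-positive draw (at
sigma = 3 this essentially never fires; it matters only in large-sigma
sensitivity scans).

## Integration

Synchronous explicit Euler with dt = 1 ms.  The fastest coupled rate at the
mean parameters is (G0_dep + G0_pol + 8 G0_max)/C = 0.15/ms, so dt = 1 ms
resolves the stiffest time constant ~7x over and `run` enforces the
conservative bound dt < C_min/(G0_dep + G0_pol + degree*G0_max) (max over
cells).  G_ij is evaluated once per unordered pair at pre-step voltages and
applied with opposite signs to the two cells, so the exchange term
conserves total charge exactly (to round-off); halving dt changes a
standard run's final depolarized count by 0 and the voltage field by well
under 0.5 mV.  For the C = 10 pF experiments every rate grows tenfold and
dt is reduced to 0.1 ms.

Two kernels implement the identical update and are cross-checked against
each other and against a scalar per-cell oracle: a numba-compiled flat
loop (production) and a vectorized numpy path whose per-offset pair
contributions are reduced with a balanced summation, making mirror-image
summation orders differ only by commutations — a mirror-symmetric
configuration on a homogeneous lattice therefore stays bit-exactly
symmetric, which the tests exploit.  Sigmoid and cosh arguments are clamped
to +-500 before exponentiation; the pairwise cosh((V_i - V_j)/V_0) is
reconstructed from per-cell cosh/sinh of V/V_0 via the addition identity
(exact because V_0 carries no cell-to-cell variability).

Equilibria are located by a 1000-point sign scan of the isolated-cell
right-hand side over [-90, +20] mV, bisection to 1e-6 mV (|rhs| tolerance
1e-9 mV/ms), and stability classified by a centered finite difference with
step 1e-4 mV — far below the ~1 mV precision at which the attractors are
meaningfully quoted.

## Initial conditions and interventions

Quiescent tissue: V ~ Normal(-60, 3) mV per active cell.  Perturbations
depolarize either a uniformly random fraction of cells (round(f*N), drawn
without replacement) or a geometric patch — axis-aligned square/cube, or
circle/sphere membership by Euclidean distance <= R between integer cell
coordinates, anchored at the origin corner or at floor(shape/2) — by
redrawing the selected cells from Normal(0, 3) mV.  The 3 mV spread around
E_dep mirrors the quiescent initialization.  Interventions multiply
G0_pol / G0_dep / G0_max cell-wise at a scheduled time, instantaneously.

Walls are removed cells, not zero-conductance cells: they carry no state,
appear in no adjacency, and are excluded from all counts, which matches
the "electrically isolated" semantics and avoids degenerate series
conductances.  n equally spaced one-cell-thick bands split the domain into
n+1 isolated slabs.

## Outcome classification for threshold searches

The tissue dynamics is bistable at the domain scale: a perturbation either
collapses (depolarized count -> 0) or ignites a wave that converts the
whole electrically connected domain.  The measured front speed is ~4 cell
widths/s, so domain-wide conversion of a 100x100 tissue from a
near-threshold perturbation takes 15-35 s — classifying by "99% converted
at exactly 10 s" would measure a saturation-time artifact rather than the
chain-reaction threshold.  The searches therefore classify by the resolved
outcome:

* random seeding: success once the count reaches 50% of active cells
  (empirically irreversible at standard parameters), failure at count 0,
  horizon 30 s;
* geometric patches: success when the count reaches
  max(5x the initial patch, 2% of the domain) within 10 s, failure at
  count 0.  Ignition so defined commits: corner-patch runs that reach the
  ignition mark proceed to >=99% conversion when continued to 60 s (tested).

Thresholds are the 50%-success crossing of a bisection with n replicates
per probe (resolution 1 percentage point for fractions, 1 cell for patch
sizes); replicate seeds are shared across probe values (common random
numbers).

## Front velocity

A 50x200 strip is initialized with its 10 leftmost columns depolarized.
Snapshots every 0.5 s (0.05 s at 10 pF) give the front position — the
transverse mean of the largest depolarized column index — and the speed is
the least-squares slope over the middle 80% of usable positions (snapshots
with the front at the far boundary are dropped; at least three must
remain).  With 10 um cells, mm/s = cells/ms * 10.  Measured:
~0.043-0.047 mm/s at C = 100 pF (seed-dependent), ten times that at
C = 10 pF — reducing C rescales time in the charge balance and multiplies
every speed by the same factor.

## Problem sizes used by the test suite and the acceptance script

Deterministic quantities (equilibria, velocities) run at full size.  The
stochastic searches use: 2D critical fraction — 100x100, n = 20, 1-point
resolution; 3D critical fraction — 30^3 (reduced from 50^3; the threshold
is set by the neighbor count, not the domain size), n = 6, 3-point
resolution; 2D patch minima — n = 8 (tests) or n = 20 (acceptance script);
3D corner cube — 32^3 domain, n = 4.  The replicate-ensemble comparisons
(gap-junction sweep) use n = 50 on a reduced domain with common random
numbers.

## Known limitations and open points

* The generator emulates quenched electrical diversity only; real tissues
  add correlated spatial structure, cell geometry, division and motility,
  and multi-ion channel kinetics, none of which are modeled.  Passing
  tests show internal consistency of this idealized automaton, not
  fidelity to any particular tissue.
* Conductance-rescaling therapies behave asymmetrically and are weaker
  than a single-cell intuition suggests: at the mean parameters the
  depolarized attractor survives G0_pol x2 (it vanishes only at x2.54) and
  G0_dep x0.5 (vanishes at x0.394); doubling or halving only moves the
  separatrix from -34.8 to -20.0 mV.  A fully depolarized tissue under
  G0_pol x2 accordingly fails the "repolarized within 10 s" criterion in
  every tested replicate — any repolarization must nucleate slowly from
  the minority of cells whose sampled parameters happen to be
  monostable-polarized, and under G0_dep x0.5 the intrinsic currents halve
  while gap coupling does not, so the community effect pins the
  depolarized state outright.  A stronger rescaling (e.g. G0_pol x3)
  repolarizes the tissue within seconds (tested).
* Corner patches ignite at somewhat smaller sizes (side ~4-5, quarter-circle
  radius ~4-5) than centered ones, a stronger corner/center asymmetry than
  the 6/8 square and 6/4 radius pattern the ignition thresholds are often
  quoted at; boundary cells have fewer neighbors and so feel less
  community suppression.
* The time-stepping scheme and step are choices of this package (the
  update rule itself does not prescribe them); dt-refinement tests bound
  their influence.
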