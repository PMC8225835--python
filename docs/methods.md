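# Model and methods

`stratasim` simulates the interfollicular epidermis as an off-lattice
cell-centre model coupled to a deformable dermis.  This note records the
model equations, the unit system, the calibration procedure, the numerical
choices, and the limitations a user should know before trusting a result.

## Units

Length is measured in units of the undifferentiated cell radius R and time
in days.  The physical scale is set by two anchors: the cell diameter is
10 um (so R = 5 um), and the corneodesmosome decay timescale is calibrated
so that the mean time between cornification and desquamation is 14 days.
With the default differentiation speed this puts the whole-epidermis
turnover (basal birth to shedding) near 28 days.  Damping is absorbed into
the force constants (gamma = 1), so a force f moves a particle at f model
lengths per day; force constants have units of 1/day in this convention.

## Mechanical components

Three particle species obey overdamped dynamics x' = F (explicit Euler):

* **Dermal particles** on a close-packed slab (4 layers, spacing 2 R)
  interact through a piecewise-quadratic pair potential: linear repulsion
  below the rest separation r_eq and a quadratic adhesion well between
  r_eq and the cutoff r_cut = 1.5 r_eq (zero force at both ends, peak
  attraction midway).  The bottom layer is immobile and a rigid support
  plane at its height keeps anything from being squeezed below it — the
  slab rests on a hard substrate.  Dermal stiffness is controlled by the
  adhesion strength alone (`k_adh_derm * stiffness_mult`), which is how
  the stiffened-dermis experiment is implemented.
* **The basement membrane** is a periodic triangular lattice of particles
  carrying edge springs (energy k_stretch (l - l0)^2 / 2) and hinge
  bending (energy k_bend (1 - cos theta), theta the dihedral deviation
  from flat).  Rest lengths are taken from the constructed flat lattice,
  so the initial state has exactly zero elastic energy.  Membrane
  particles adhere to dermal particles through the same pair potential.
* **Cells** are spheroids with equatorial/polar semi-axes (a, c)
  satisfying a^2 c = R^3.  Cell-cell contacts use the same potential with
  r_eq = a_i + a_j, evaluated at the effective separation in which the
  z-component of the pair vector is stretched by (a_i + a_j)/(c_i + c_j);
  flattened cells therefore interact at a shorter vertical range.  The
  force is taken as the exact gradient of the pair energy in that
  rescaled metric (the z-force carries the squared ratio), which reduces
  to a central force for spheres and makes the overdamped dynamics a true
  gradient flow — the energy-descent test depends on this.

The cell/membrane interface uses the *local membrane plane* at the
nearest membrane vertex (vertex normal n, signed distance h): every cell
feels a one-sided harmonic barrier when |h| < c_i, and attached basal
cells additionally carry a bond spring -k (h - c_i) n with k = k_stem for
stem cells and k = k_TA < k_stem for TA cells.  A TA bond stretched past
`detach_gap` breaks permanently; stem bonds never break.  The plane form
matters: point-particle repulsion against membrane vertices lets crowded
cells slip through triangle interiors, which destroys the basal monolayer.

A speed clip (`vmax`) guards the integrator against rare large transient
forces (e.g. right after a division); it is inactive during normal motion.

## Cell lifecycle

Stem cells sit on a regular sub-lattice (default spacing 50 um) and divide
forever; divisions are asymmetric (the stem persists and emits a TA cell
with a fresh budget of `N_div` divisions), so the stem census is a
conserved quantity.  TA mothers are replaced by two TA daughters with one
fewer division each.  Cycle lengths are T_div times a lognormal variable
with mean 1 and CV `cycle_cv` (0.2), which desynchronises the tissue.
Only membrane-bound cells cycle; a cell pushed off the membrane by
division pressure detaches, stops cycling and starts differentiating —
crowding is the only thing that ends proliferation.

Because daughters are placed adjacent to the mother (one radius
apart, inside its footprint), each
membrane site is effectively held by one lineage which divides until its
budget runs out.  Exhausted TA cells remain as non-cycling basal fillers
until evicted, and this is how `N_div` shapes the supply rate: at
(N_div, T_div) = (8, 4.4) a much larger fraction of the basal layer is
exhausted than at (14, 4.0), which thins the suprabasal layers and
destabilises them, reproducing the published supply-rate dependence.

Differentiation is a scalar state w that starts at 0 on delamination and
grows as

    dw/dt = alpha (1 + beta_Ca Ca + beta_S S),

with type boundaries spinous < w1 <= granular < w2 <= cornified
(half-open).  The corn lesion doubles the division rate of the abnormal
lineage in the basal layer and doubles its differentiation speed in the
suprabasal layers.  The aspect ratio q = c/a falls linearly from 1 at
w = 0 to 0.25 at w = w2 and stays there; volume is conserved throughout.

## Calcium, stimulant, lipids, desquamation

Both signalling fields live on cells and exchange along the contact graph
(effective separation below 1.2 (a_i + a_j)) by graph-Laplacian diffusion
with linear decay.  A cornifying cell releases a fixed calcium dose Q_Ca
split equally among its neighbours (discarded with a warning if it has
none); cornified cells secrete the stimulant continuously into their
neighbours.  Calcium decays fast (lambda_Ca = 2/day) and therefore stays
localized just below the cornified layer; the stimulant decays slowly
(lambda_S = 0.4/day) and reaches deeper, so the two factors set the two
layer boundaries.

Granular cells produce lipid at `p_lip` up to `L_max`; the entire internal
store transfers to the released pool once — when the cell cornifies or
when its calcium crosses `Ca_lipid_threshold` (set above a single
neighbour dose, so early release requires simultaneous cornifications).
A cornified cell with L_out below half the maximum counts as
lipid-deficient.  `p_lip` is calibrated so that the deficiency threshold
falls between the granular-residence distributions of the two published
supply regimes: cells in the destabilised low-supply tissue sit closer to
the cornified layer, see more stimulant, cross w2 sooner and release less.

Corneodesmosome integrity decays as D' = -D/tau_desq after cornification;
a cornified cell is removed when D < D_th = 0.1 *and* no cell centre lies
above it within one equatorial radius laterally (surface exposure).  With
exposure rarely limiting in homeostasis, the mean lag is close to
tau_desq ln(1/D_th); tau_desq = 5.95 days is the value the bisection
calibration returns for the 14-day target, and `calibrate()` verifies it
is a fixed point.

## Evaluation functions

For each layer (granular, cornified) the domain is tiled into M1 x M2
subregions (half-open, so each cell lands in exactly one tile), and per
tile

    H_ij = 4 pi R^3 n_ij / (3 dx dy)        (flattening ignored)
    G_ij = z_max - z_min - H_ij             (cell-centre z)

H(t) and G(t) are tile means — empty tiles count as zero thickness for H
and are excluded from G (their extremes are undefined) — and E(t) is the
population standard deviation of H_ij.  Basal diagnostics count attached
cells, attached cells that can still divide, and division events per day;
the membrane deformation amplitude is max z - min z over membrane
particles.  Default tiles are about 40-50 um; the sampling cadence is
0.07 days (4001 samples over a 280-day run).

## Parameters that matter most

| parameter | default | meaning |
|---|---|---|
| N_div, T_div | 14, 4.0 d | TA division budget and cycle period (the supply-rate dials) |
| alpha | 0.095 /d | baseline differentiation speed; sets suprabasal transit and hence the 28-day turnover |
| beta_Ca, beta_S | 1, 4 | signal acceleration of differentiation |
| tau_desq, D_th | 5.95 d, 0.1 | desquamation clock (14-day lag anchor) |
| p_lip, L_max | 0.133 /d, 1 | lipid production; the deficiency discriminator |
| k_stem, k_TA, detach_gap | 60, 20, 0.75 R | differential adhesion; basal residence time |
| k_stretch, k_bend | 50, 2 | membrane elasticity; bending sets the buckling wavelength |
| k_adh_derm, stiffness_mult | 10, 1 | dermal cohesion; the stiffness experiment multiplies it |
| k_adh_md, membrane_gap | 5, 1.2 R | membrane-dermis tether strength and rest gap |
| dt, n_mech_per_tick | 0.0024 d, 9 | mechanics step and biology cadence |

## Numerics

* Explicit Euler with dt below 1/(8 k_max); the engine refuses parameter
  sets above the bound.  The signalling update is sub-cycled whenever the
  contact degree pushes the explicit diffusive bound below the biology
  tick.
* Neighbour search uses periodic k-d trees with a Verlet skin; dermis and
  membrane lists are rebuilt separately from cell lists (cells change
  population every few ticks, the substrate barely moves).
* Division, delamination, type transitions, field updates, lipid transfer
  and removal run on the biology tick (every 10 mechanics steps,
  0.02 days) in a fixed order; all randomness flows through one RNG
  stream, so runs are bit-reproducible for a given seed and snapshots
  resume exactly.
* Ties and degeneracies: coincident particles raise an integration error
  (the pair direction is undefined); degenerate membrane triangles raise;
  cells exactly on a tile edge belong to the upper tile (half-open
  convention); w exactly at a threshold belongs to the more differentiated
  type.

## Scaled-down study conditions

The published experiments use 280-day runs on larger domains.  The
package's `fixture_small` preset (80 x 80 um, (14, 4.0)) is the desk-scale
condition used by the test suite and the acceptance script: a 56-day
burn-in (two turnovers) followed by four turnovers of data, which yields
more than a thousand desquamations for the two timing anchors.  Regime
comparisons run 85 days so that the TA division budgets (N_div x T_div =
35-56 days) have time to bind; trend orderings, not the absolute heat-map
values, are the quantities compared at this scale.

## What the generator does and does not emulate

The synthetic world reproduces: stratified layers with columnar granular
and cornified organisation, dermal protrusions with stem cells on their
tips, supply-dependent layer stability, stiffness-dependent membrane
deformation, and corn formation from a single abnormal stem lineage.  It
does not include: hair follicles or appendages, explicit extracellular
matrix or fluid, transepidermal water loss (structure and lipids are the
barrier proxies), immune or wound responses, or the single-progenitor
division scenario (deliberately out of scope).  Mean turnover and the
cornification-removal lag are calibrated, so their agreement with the
anchors validates the calibration machinery, not the biology; the
substantive predictions are the orderings across conditions.

## Known limitations

* The membrane bond acts on the nearest-vertex local plane; when the
  nearest vertex switches, the bond energy jumps by a small amount, so
  exact energy descent holds for the continuum forces only (the descent
  test releases the bonds).
* The basal division frequency runs ~15-20% below n_proliferative/T_div
  because cells detached mid-cycle never execute their scheduled
  division; the published approximation holds at the 20% level, not
  exactly.
* At desk scale the granular layer is 1-2 cells thick, so layer metrics
  carry large temporal fluctuations; tests therefore compare
  time-averaged quantities across paired seeds.
* The corn lesion footprint is the convex hull of abnormal basal cells;
  with periodic boundaries this is only meaningful while the lesion stays
  compact around the domain centre (the preset guarantees this).
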