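# Methods

`marshnet` couples an idealized biogeomorphic simulator of a draining
intertidal platform with a raster/graph toolkit for measuring tidal
channel-network geometry. This note documents the model, its numerical
treatment, the parameter set, the experiment and analysis choices, and the
limits of what the test suite demonstrates.

## Model

The domain is a rectangular intertidal platform with shoreward coordinate
x (index i, increasing toward the single open outflow boundary) and
alongshore coordinate y (index j, both alongshore boundaries and the
landward boundary closed). Five prognostic fields live on a regular grid:
water layer thickness h, depth-averaged velocities u and v, sediment bed
elevation S above a consolidated reference bed, and vegetation stem
density B.

**Flow.** A steady continuous ebb discharge is modelled: a spatially and
temporally uniform source H_in (m/s) enters the continuity equation

    dh/dt = -d(uh)/dx - d(vh)/dy + H_in

and drains through the open boundary. Because bed evolution is slow
compared with the water layer, the water-surface tendency is identified
with dh/dt. The momentum balance carries pressure gradient
-g d(h+S)/dx, advection, quadratic bed friction -tau/(rho h), and eddy
viscosity D_U Lap(u):

    du/dt = -g d(h+S)/dx - u du/dx - v du/dy - tau_bx/(rho h) + D_U Lap(u)

with tau/rho = (g/C_z^2) |U| (u, v, |U|), Manning-Chezy C_z = h^(1/6)/n,
and roughness increasing linearly with stem density from the bare value
n_b to the fully vegetated n_v: n = n_b + (n_v - n_b) B/k. Wetting and
drying use a thin-film floor h >= H_c, so momentum stays defined on
emergent terrain. Waves, the flood phase and tidal oscillation are not
modelled.

**Bed.** Sediment elevation obeys a sedimentation/erosion/soil-creep
balance:

    dS/dt = S_in h_e/(Q_s + h_e)
          - E_S (1 - p_E B/k) S tau_b/rho
          + div(D_S grad S),            D_S = D_0 (1 - p_D B/k)

where h_e = h - H_c measures inundation. Sediment input saturates with
depth (half rate at h_e = Q_s). Erosion is proportional to S itself —
erodibility decreases with consolidation depth, which also means the bed
cannot erode below the reference level in the mean — and is reduced by a
fraction up to p_E under full vegetation cover. Slope-driven transport
(soil creep) is diffusion with a coefficient reduced by up to p_D by
root binding. Advective sediment transport and vegetation trapping are
deliberately absent; supply is spatially homogeneous.

**Vegetation.** Stem density follows logistic growth damped by
inundation, shear-stress mortality, and clonal diffusion:

    dB/dt = r B (1 - B/k) Q_q/(Q_q + h_e) - E_B B tau_b/rho
          + D_B Lap(B)

B = 0 is absorbing: establishment happens only in the initial condition,
where each cell independently becomes a full-density tussock (B = k) with
probability p_est.

**Feedback.** Vegetation slows flow (n_v), shields the bed (p_E) and
binds soil (p_D); flow concentrates between tussocks, scours channels,
and the elevated, better-drained platform favours further vegetation
growth. All three effects raise the ratio of channel-incision to
topographic-diffusion rates (the landscape Péclet number), which controls
how many nested orders of side channels can be incised. Lowering the bare
soil diffusivity D_0 raises the same ratio abiotically and is used as the
single control for "relative biogeomorphic feedback strength".

## Numerics

Forward Euler in time, central differences in space, on a collocated
grid. The update cycle per hydrodynamic step dt is strictly ordered:
thin-film clamp; momentum tendencies from the old state; u,v update;
velocity boundary conditions; scalar tendencies (continuity, bed,
vegetation) with the updated velocities; scalar updates; scalar boundary
conditions. Bed and vegetation tendencies are multiplied by the
morphological acceleration factor Phi (default: the 44712 s of one M2
tidal period), so one hydrodynamic second advances the morphological
clock by Phi seconds; all reported "simulated times" are accelerated
times. The bed equation has no advective term, so acceleration does not
interact with the CFL limit.

Only the topographic diffusion term uses the conservative
variable-coefficient flux form, with face diffusivities interpolated as
arithmetic means; D_B and D_U are constant and use the plain 5-point
Laplacian. The domain integral of the variable-coefficient operator
telescopes exactly on closed domains. Boundary conditions: open boundary
— linear extrapolation (zero second derivative) for u and v, zero
gradient for h and B, and S = 0 (erosion and deposition in balance, which
keeps the outlet incised); closed boundaries — reflected normal velocity,
copied tangential velocity, zero gradient for scalars. Advection is
central-difference as the canonical scheme; a first-order upwind switch
exists for robustness experiments but is off by default and not used by
any packaged experiment. B is clamped to [0, k] after each update
(forward Euler can undershoot an analytically positive solution); S is
not clamped — small negative excursions near the fixed outlet bed are
physically ambiguous in this model and are retained rather than hidden.

Degenerate inputs: tendencies abort with a diagnostic on any non-finite
value; `run` additionally checks the full state every 1000 steps. The
thin-film clamp adds water; the added volume is metered per step so mass
audits can exclude it. The discrete interior mass budget
d/dt(sum h dA) = H_in A - outflux holds to round-off whenever the clamp
is idle, with the outflux defined as the telescoping remainder of the
central-difference flux divergence at the open boundary.

Two engines compute identical physics: a reference vectorized numpy step
built from the individually tested operators, and a fused numba kernel
used by `run` that replicates the reference arithmetic per element. The
kernel caches h^(-1/3) between steps (two Newton updates per step; exact
recompute when a cell moves far, e.g. at clamping) instead of calling
`pow`, and is compiled with FMA contraction enabled, so the engines agree
to round-off (a few ulps per step; the suite bounds the divergence) but
not bit-for-bit. Within an engine, trajectories are bit-reproducible from
(config, seed), and checkpoint/resume reproduces an uninterrupted run
bit-for-bit (the Newton cache travels with the checkpoint). A single
seeded generator draws the initial tussocks in row-major cell order.

## Parameters

Defaults (SI units) are the default-simulation values: dt = 0.0125 s,
Phi = 44712 s (one M2 period, fixed constant), 50 yr end time (Julian
years; 50 yr = 35290 M2 periods after rounding), D_0 = 1e-7 m²/s,
D_B = 6e-9 m²/s, D_U = 0.5 m²/s, E_S = 2.5e-4 s/m², E_B = 1e-5 s/m²,
H_0 = 0.02 m, H_c = 1e-3 m, H_in = 1e-5 m/s, k = 1500 /m², n_b = 0.016,
n_v = 0.2 s·m^(-1/3), p_D = 0.99, p_E = 0.9, p_est = 0.002, Q_q = 0.02 m,
Q_s = 6e-4 m, rho = 1000 kg/m³, r = 3.2e-8 /s (≈ 1/yr), S_in = 5e-9 m/s.

Derived values are recomputable by `marshnet.params`: H_in from a tidal
prism of 0.75 m water column draining per M2 period (1.7e-5 m/s at two
significant figures; the stored default 1e-5 m/s is the empirically tuned
value), S_in from a reference input of 0.2 cm per tide reduced ten-fold
for the shallow steady-discharge water column and divided by the depth
factor h_e/(Q_s + h_e) at h = H_0 (5e-9 m/s at one significant figure),
and an order-of-magnitude E_S estimate from the pressure-gradient/friction
balance at a 1e-3 bed slope (≈ 3.4e-4 s/m²; the stored default 2.5e-4 is
the tuned value). The derivation functions document these calculations;
they are not used to re-fit anything at run time.

## Reduced-scale experiments

The packaged experiments run at 128 x 256 cells of 0.5 m (64 m x 128 m),
dt = 0.025 s, for 10 accelerated years — sized so a run takes minutes on
one CPU. Channel networks at this scale are young and small: the first
parallel channels appear within ~2 accelerated years, but no run (with or
without vegetation) develops a second-order side branch before roughly 7
accelerated years, so 10 years is the earliest window in which order
statistics can separate the two regimes; by then the vegetated run
carries second-order branches while the vegetation-deactivated run is
still a sparse first-order network. Results at this scale are qualitative
analogues of the full-scale (1024 x 2048, 50 yr) setting, not
reproductions: absolute drainage densities and Hack orders are smaller.

The vegetation-deactivated run freezes B at its initial sparse-tussock
field (dB/dt = 0) rather than removing vegetation entirely, so both runs
share the roughness heterogeneity that seeds channelization and differ
only in vegetation dynamics. The soil-cohesion sweep runs separate
constant-D_0 simulations at log-spaced stations (an in-domain gradient
run is supported but its adjacent strips interfere, so it is used for
visualization only).

Network extraction on these simulated marshes uses a median-neighborhood
window radius of 10 m (about the emergent channel spacing) and a residual
depth threshold of 0.02 m (platform relief is a couple of decimetres and
incipient channels a few centimetres deep). Both are explicit arguments
everywhere; nothing in the library hides them.

## Network analysis

Channel pixels are cells lying more than the threshold below the median
elevation in a circular window (missing data excluded). Unchanneled path
length is the exact Euclidean distance transform to the nearest channel
pixel. The mask is thinned to a one-pixel skeleton; pixels with other
than two neighbors become nodes (adjacent node pixels are clustered),
chains become sections, spurs shorter than twice the pixel size are
pruned as thinning artifacts, and sections are resampled at equidistant
0.5 m points. Each connected component is oriented away from its outlet
(preferring nodes on the open-boundary edge, then any raster edge, then
the lowest node). Loops — common in young braided networks — are cut at
the edges off the breadth-first orientation tree, leaving the spanning
drainage tree; the number of cut sections is recorded.

Watershed areas come from D8 steepest-descent accumulation after
priority-flood depression filling with an epsilon slope (which removes
pits and flats, so routing is total and deterministic; orthogonal
neighbors win gradient ties over diagonals). The area at a skeleton point
is the total accumulated area of its nearest cell.

Hack ordering walks upstream from the outlet: the tributary with the
greater maximum upstream length continues the parent's order, every other
tributary starts a new stream of order+1 (ties break on watershed area,
then section id). Under this convention higher order means finer scale.
Stream counts n_i count distinct streams (subbasins) per order;
bifurcation ratios are r_i = n_{i+1}/n_i; Hortonian drainage density is
total centerline length over basin area (the full raster area for
simulated marshes). Distribution comparisons use the empirical survival
function (exceedance) of watershed area and unchanneled path length and
the two-sample Kolmogorov-Smirnov similarity 1 - KS (p-value reported
alongside; both the exact and asymptotic p-value variants are exposed
because either convention is defensible). The elevation-vegetation
pattern correlation is the Pearson coefficient over all cells.

## Synthetic fixtures

The fixture generator produces inclined planes with carved channel
polylines of exactly known topology (straight channel, Y junction, a
nested three-order tree, a two-channel basin with an analytic D8
partition) plus random masks and the closed-form logistic and Gaussian
diffusion references. Channels are one pixel wide with strictly
descending beds and 45-degree branches so centerlines, junctions, orders
and drainage partitions are unambiguous. These fixtures validate the
analysis machinery exactly, but they do not emulate real marsh DTMs: no
noise, no flats, no width variation, no nodata holes beyond what tests
construct. Passing them shows the pipeline is correct, not that the
detection parameters are right for any particular survey.

## Known limitations

- The flow model is a steady ebb drainage; flood currents, tides and
  waves are absent, so flood-dominated network features are out of reach.
- Erosion proportional to S means the bed never scours below the
  reference plane; channel depth is relief built by differential
  accretion, which also makes young simulated channels shallow and makes
  the extraction threshold scale-dependent.
- At the reduced experiment scale the networks are young and small;
  order statistics saturate at 2-3 and are sensitive to extraction
  parameters in ways the full-scale setting is not.
- The two engines agree to round-off, not bitwise; cross-engine
  comparisons should use tolerances.
- Skeleton lengths underestimate carved path lengths by a few pixels per
  section (thinning pulls line ends back from mask ends).
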