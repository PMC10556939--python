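# Methods

## Problem

After open repair of a thoracoabdominal aortic aneurysm the prosthetic
trunk severs the segmental (intercostal/lumbar) arteries that feed the
spinal cord's collateral network. Surgeons can reattach them in several
topologies — direct anastomosis onto the trunk, a wide interposed side
graft, a loop of graft leaving and re-entering the trunk, or a blind-ended
stump graft — and clinical patency differs sharply between them. The
package's working hypothesis, shared with the clinical literature it
models, is that blood-flow *stagnation* in the reattachment predicts
thrombosis and loss of patency. Stagnation is quantified as the
**low-velocity volume (LVV)**: the fluid volume whose speed stays at or
below 0.03 m/s, evaluated through one systolic ejection. Companion metrics
are the low-velocity *area* on a plane section at 0.30 s of systole and
the blood volume delivered through each segmental artery.

## Geometry model

Designs are parametric constructive solids built from exact
signed-distance primitives (capped cylinders, spheres, half-spaces, arc
tubes); unions take pointwise minima, so the field stays 1-Lipschitz and
robustly voxelizable. Default dimensions: 24-mm trunk, 10-mm side
branches, 2-mm segmental arteries, 15-mm-diameter hemisphere stump; an
interposed branch defaults to 20 mm long (sweep: 10/20/30 mm and 6/8/10/12
mm diameter). The loop is a circular arc joining two trunk anastomoses
30 mm apart: *standard* is the minimal semicircle, *elongated* stretches
the arc to 1.5x the standard length, *curved* doubles the arc sagitta. The
2-mm artery leaves the top of the reattachment hardware (the arc apex for
loops, the distal cap for interposition, off-axis through the blind cap
for the end graft — leaving a stagnant shoulder).

Two geometric conventions matter for interpretation:

* **Fixed outlet standoff.** The artery's distal end is anatomically fixed
  relative to the aorta, so every design's segmental outlet plane sits
  40 mm above the trunk wall; the reattachment hardware occupies the
  proximal part of that path and the narrow 2-mm artery the remainder
  (direct 40 mm of artery, loop ~25 mm, interposition 20 mm at the default
  branch, end graft ~10 mm). Designs therefore trade wide-graft length
  against narrow-artery length, which is what differentiates their
  delivered flow volumes.
* **Analysis region.** Stagnation is scored over the reattachment
  subdomain — all fluid outside the trunk lumen (branch + artery) — with
  the whole-fluid variant also recorded. Cross-design "pattern"
  comparisons use the stagnant *fraction* of each design's own region,
  since absolute LVV scales with hardware lumen volume (a loop lumen is
  ~20x a direct site).

The pulsatile inlet is a half-sine systole: 0.35 s duration, 0.5 m/s peak
plug velocity, snapshot at 0.30 s. Measured waveforms can be supplied as
piecewise-linear tables. Branch takeoff angle defaults to 90 degrees from
the trunk axis and is sweepable; the 3-pair layout places three segmental
origins 15 mm apart, mirrored across the trunk.

## Discretization

The implicit solid is sampled on a uniform Cartesian grid (cells with
negative signed distance at their centre are fluid) with staggered (MAC)
variable placement: face-normal velocities, cell-centred pressure. Walls
are stair-stepped; boundary faces lying on a tagged cap become the
velocity inlet or pressure outlets. Stray fluid voxels disconnected from
the inlet are discarded (they would make the pressure problem singular).
Default spacing is 1.0 mm — deliberately coarser than a body-fitted
boundary-layer mesh; wall-shear quantities are not trustworthy at this
resolution and are not reported. The 2-mm artery is then only 2 cells
across (a warning is issued below 3): its viscous resistance is
under-resolved, which compresses absolute outflow volumes while preserving
cross-design ordering. 0.5/0.25 mm are available for convergence studies.

All built-in designs are mirror-symmetric about the trunk's sagittal
plane, so the pipeline solves the half-domain z >= 0 by default with an
even-ghost symmetry plane at z = 0; reported volumes, areas and fluxes are
rescaled to the full vessel. The half solve reproduces the full solve to
well under 1% (tested) at half the cost.

## Flow solver

Incompressible Newtonian blood (rho = 1000 kg/m^3, mu = 0.004 Pa s), rigid
no-slip walls, plug inlet velocity from the waveform, all outlets at a
common reference pressure (120 mmHg physically; the solver works in gauge
zero since only differences matter), fluid at rest at t = 0, time step
1 ms.

Each step runs an iterative predictor / pressure-correction (SIMPLE-family)
scheme:

1. **Momentum predictor** from the substep-start state with the current
   iterate's convection and diffusion (Picard linearisation): second-order
   upwind convection with a minmod limiter (the unlimited linear
   reconstruction is unbounded at stair-step corners), explicit diffusion
   with half-cell mirror ghosts so the no-slip wall sits exactly on the
   face, and the current pressure gradient.
2. **Pressure correction**: a 7-point Poisson problem with Neumann walls
   and half-cell Dirichlet outlets, factorised once per grid (sparse
   direct LU) and solved exactly each iteration, then face velocities
   corrected to a discretely divergence-free state (machine precision;
   global mass balance follows exactly).
3. **Under-relaxation** (0.7 velocity / 0.3 pressure) between iterates;
   iterations repeat until the global mass-balance residual and the
   relative change of the low-velocity volume both fall below 1e-3
   (defaults), the convergence notion the method is scored by.

Momentum is explicit, so the 1-ms step is split into substeps whenever the
advective Courant number exceeds 0.45, with a retry that doubles the
substep count if velocities grow mid-step; `advance_step`'s contract (one
full time step) is unchanged. Outlet normal velocities obey a convective
non-reflecting condition du/dt + U_c du/dn = 0 (U_c = current bulk outflow
speed, floored positive): an instantaneous zero-gradient copy reflects the
Womersley-type near-wall backflow of late systole (Womersley number ~18 in
the trunk) and rings violently; the convective form advects those
disturbances out. Tangential ghosts at open outlet edges are
zero-gradient rather than no-slip mirrors.

Determinism: the solver has no stochastic component; identical
configurations produce bitwise-identical series (tested). The
`SolverConfig.seed` field is reserved plumbing.

### Optional k-epsilon mode

A realizable k-epsilon closure (strain-dependent C_mu, eta-dependent
epsilon production, positivity floors) is available as a cross-check mode.
Because standard k-epsilon cannot relaminarize, the eddy viscosity is
ramped to zero where the local Reynolds number (speed x wall distance /
nu) is below the transitional 1000-2000 range; at the laminar-to-
transitional Reynolds numbers of these geometries (trunk ~3000 peak,
branches far lower) the mode stays inert by design and the default is
laminar. No log-law wall functions are applied.

## Stagnation metrics

Cell speeds average the two opposing face velocities per component;
threshold comparison is inclusive (<= 0.03 m/s). The plane section
defaults to the sagittal plane containing the trunk and branch axes, with
linear interpolation between the straddling cell layers. Outlet flow
volumes integrate tagged-face fluxes with the trapezoidal rule. A
brute-force cell-by-cell recount reproduces the LVV exactly (tested), and
the LVV is nondecreasing in the threshold by construction.

## Experiment pipeline

One transient solve per design variant at identical settings; each
comparison row records time-averaged and snapshot LVV, the stagnant
fraction, snapshot plane area, and segmental/trunk outflow volumes, plus a
hash of the full configuration. Rankings order by time-averaged LVV over
the systole (window configurable; the diameter sweep uses the first half
of systole for its early-phase claim, split at T/2). Completed runs are
memoised in-process by configuration hash. A failed solve marks its row
and the comparison continues.

## Problem sizes and what the desk-scale runs show

Default experiment fidelity is 1.0-mm spacing (13-16 k fluid cells per
single-pair design, ~350 time steps, roughly one to two minutes per design
on one CPU). At this fidelity the reproducible surface is *orderings and
patterns*, not absolute values: the four-design stagnation ranking (direct
< loop < interposition < end graft), the length sweep (10 < 20 < 30 mm,
hemisphere lowest), the early-systole diameter sweep (6 < 8 < 10 < 12 mm),
and the direct-vs-loop pattern similarity all reproduce. Delivered
segmental volumes order direct < interposition < end graft; the loop's
delivered volume comes out highest rather than second-lowest because, in
this parameterization, its two perpendicular limb mouths recover trunk
dynamic pressure (a pitot-chamber effect) that over-drives its artery —
a documented fidelity/parameterization limitation, not a solver defect.
Test fixtures use geometrically scaled-down variants (8-12-mm trunks,
shortened systoles) where the property under test allows it; claims that
depend on inertial late-systole dynamics are exercised at full study
conditions.

## Known limitations

* Stair-step walls: first-order wall treatment; no boundary layers, no
  wall shear stress, oscillatory shear index or residence-time metrics.
* The 2-mm artery at default spacing is marginally resolved; absolute
  outflow volumes are compressed relative to a resolved simulation.
* Rigid walls, Newtonian rheology, no peripheral resistance model, no
  fluid-structure interaction, single systole from rest (no periodic
  cycling), no thrombosis kinetics.
* The loop graft's artery taps the arc apex; where the artery joins the
  loop is not constrained by the source design drawings, and the delivered
  flow volume of the loop is sensitive to this choice (see above).
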