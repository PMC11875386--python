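# Methods

## Model overview

The pore space of a saturated soil volume is a binary 3D image (0 = pore,
1 = solid). Pore voxels become nodes of a graph G(V, E) with an edge for
every face-adjacent pair (6-connectivity); node ids follow raster order
(z outermost, then y, then x), so all vectors indexed by node are
reproducible. Voxels on the image boundary simply have fewer neighbours,
which realises a closed system (zero flux through the sample faces) with no
extra boundary machinery.

Two processes are composed by operator splitting:

1. **Graph diffusion** of dissolved organic matter (DOM). With per-node
   masses collected in M(t) and voxel volume normalised to 1 (so mass and
   concentration coincide), dM/dt = −D·Δ·M, where Δ = diag(deg) − A is the
   graph Laplacian. Row sums of Δ vanish, hence total mass is invariant.
2. **Decomposition kinetics** within each voxel over five carbon pools
   (MB, DOM, SOM, FOM, CO₂):

   - growth: Monod uptake v_DOM · x_DOM/(K_DOM + x_DOM) · x_MB, DOM → MB;
   - mortality: µ·x_MB, split β to DOM and 1−β to SOM;
   - respiration: ρ·x_MB, MB → CO₂;
   - hydrolysis: v_SOM·x_SOM and v_FOM·x_FOM, both → DOM.

   Every term moves carbon between pools, so each step conserves total
   carbon identically in the rate algebra; the tests assert closure to
   1e−12 relative per step and 1e−9 over whole multi-day runs.

## Parameters and units

| parameter | meaning | default | unit |
|---|---|---|---|
| D | DOM diffusion coefficient in water | 100950 | voxel²·day⁻¹ |
| ρ | respiration rate | 0.2 | day⁻¹ |
| µ | mortality rate | 0.5 | day⁻¹ |
| β | dead-biomass fraction recycled to DOM | 0.55 | — |
| v_DOM | maximal growth rate | 9.6 | day⁻¹ |
| K_DOM | DOM half-saturation | 0.001 | pool mass unit |
| v_SOM, v_FOM | hydrolysis rates | 0.01, 0.3 | day⁻¹ |

The biological defaults are the Arthrobacter sp. 9R set calibrated on
experimental growth/respiration curves. Rates are configured in day⁻¹ and
the diffusion coefficient in voxel²·day⁻¹ (the units the soil literature
reports); simulation clocks run in seconds. Every day/second conversion goes
through one constant (`poregraph.units.SECONDS_PER_DAY`), so the mixed unit
conventions cannot leak. Masses are abstract carbon masses (µg C by
convention); all dynamics except the Monod term are invariant to their
overall scale, and configured totals are therefore treated as model mass
rather than a physical sample inventory.

## Numerical choices

* **Explicit (forward-Euler) diffusion** is subject to the nonnegativity
  bound δt ≤ 1/(D·deg_max), exposed as `stable_timestep`. A step that drives
  any mass negative raises rather than clipping — clipping would silently
  destroy conservation. Values above −1e−12 relative to the state scale are
  treated as rounding noise.
* **Implicit (backward-Euler) diffusion** solves (I + D·δt·Δ)M′ = M, an SPD
  M-matrix system, with a Jacobi-preconditioned conjugate gradient
  (relative-residual tolerance 1e−10 by default, maxiter = max(1000, n)).
  The mass-conservation defect of one implicit step equals the residual
  component along the all-ones vector, so the coupled simulator tightens the
  tolerance to 1e−12 to keep whole-run drift below 1e−9 over hundreds of
  steps.
* **Kinetics steppers** take their dt in days (matching the day⁻¹ rates).
  Monod uptake is capped at the DOM present in the voxel so finite steps
  cannot overdraw the pool; dt ≤ 1/(ρ + µ + v_DOM) is a sufficient
  nonnegativity bound for every pool. The synchronous update reads all pools
  at time t; the asynchronous update applies growth → mortality →
  respiration → hydrolysis as whole-graph sweeps, each reading the state the
  previous process left. The two differ at O(dt²).
* **Operator splitting** advances transformation first, then diffusion
  (configurable), sub-stepping the smaller-dt process so both cover the same
  elapsed time per macro-step; both dts must divide the output cadence.

## Ball-network model and conductance learning

The coarse model covers the pore space with overlapping balls. Balls are
adjacent iff their centers are strictly closer than the sum of radii; each
edge carries the analytic sphere–sphere intersection-disc area S_ij (full
cross-section of the smaller ball when one contains the other; a
voxel-face-counted alternative is available behind `contact="voxel"`), the
center distance d_ij, and a conductance θ_ij initialised to S_ij/d_ij. The
flux between adjacent balls is −D_c·θ_ij·(m_i/v_i − m_j/v_j); explicit and
implicit steppers mirror the voxel schemes (the implicit system is solved in
concentration variables, where diag(v) + D_c·δt·L_θ is SPD).

**Ball volumes.** The constructor default is the analytic (4/3)πr³. For any
pipeline that exchanges mass with the voxel representation, the partition-
cell volume (number of voxels owned by the ball under the nearest-center
partition) must be used instead (`with_volumes(partition_volumes(...))`):
with analytic volumes the network equilibrium (equal m/v) disagrees with the
aggregated voxel equilibrium (equal mass per voxel), and a learner trained
against voxel-aggregated data then chases an incompressible residual.

**Learning.** Training pairs (X_p, Y_p) are ball-aggregated voxel-graph
states one recording interval apart, generated from seeded random mass
distributions. Two objectives are available: the mean squared residual of
the explicit one-step prediction of Y from X, and (default) of the implicit
relation reconstructing X from Y. Gradients are exact: with θ stored once
per undirected edge, ∂L/∂θ_ij collects the residual contributions of both
endpoints, (±2a/(lq))·Σ_p (c_i−c_j)(r_i−r_j); tests verify them against
central finite differences to 1e−5.

The update is normalized stochastic gradient descent: per epoch one batch
(default 4 pairs) is drawn, the gradient computed, normalized, and applied
with a learning rate starting at 0.1 and halved every 10 epochs;
conductances are clipped at zero after each step (negative conductance
breaks the SPD/conservation structure). The default normalization is
**per-coordinate** (each θ_ij moves by ±lr): full-vector Euclidean
normalization caps the total parameter displacement at Σ lr_e = 2·lr₀·T_half
= 2.0, which on realistic fixtures is smaller than the distance from the
geometric initialisation to the optimum, and the optimizer stalls an order
of magnitude or more above the reachable loss; the per-coordinate rule
converges coordinate-wise as the rate anneals and reproduces the rapid
few-epoch convergence the method is known for. Training progress is tracked
as the loss on a fixed probe batch of 4 pairs drawn once from the seed; the
schedule runs a fixed epoch budget (an "epoch" is one batch update), with an
optional plateau stop.

**Recording interval.** The one-step objectives are Euler surrogates of the
true interval map, so the recording interval must keep D_c·δt·λ ≲ 1 for the
network's fastest modes; at desk-scale geometries (balls a few voxels
across) this means recording every ~2 s at D_c = 100950 voxel²/day, whereas
geometries hundreds of voxels across tolerate ~10 s. The generator default
(30 scenarios, 10 s recording over 1200 s → 3600 pairs) reflects the
reference experiment; tests and the acceptance fixtures pass scaled-down
values explicitly.

**Known-truth recovery fixture.** The self-consistency test perturbs the
geometric initialisation by ±5% per edge before generating data. The bound
is deliberate: it keeps the init-to-truth distance within the displacement
budget of the prescribed learning-rate schedule, so the test exercises the
optimizer rather than the schedule's reach.

## Synthetic geometries

The generator produces what the experiments assume, at desk scale:

* **ball packings** — connected unions of random balls (radius ≥ 2 voxels so
  voxelization is non-degenerate). Connected packings are grown by
  attachment: each new ball is placed at 0.4–0.8 of the summed radii from a
  random existing ball, guaranteeing a strict overlap with a healthy lens,
  so the ball adjacency graph is connected by construction; the voxel graph
  of the union is verified to be a single component and the packing is
  resampled otherwise. Either a ball count or a porosity target (balls added
  until reached; accurate to ±3 points) drives the size.
* **chains** (L×1×1, the path graph with closed-form spectrum
  2 − 2cos(kπ/L)), **slabs** and **full cubes** for analytic validation.
* **random DOM fields** — a total drawn uniformly from a range, split by
  normalized i.i.d. uniform weights, total preserved exactly.

All generators are bit-reproducible under a fixed seed. What they do *not*
emulate: real soil morphology (anisotropy, correlated pore networks, surface
roughness, the wide pore-size spectra of µCT data) and partial saturation. A
green test therefore establishes correctness of the numerics and mappings on
connected geometries of comparable porosity, not fidelity to any particular
soil.

## Limitations

* Transport is diffusion only — no advection — and the system is two-phase
  (solid/water, fully saturated).
* Spatial resolution is the voxel; sub-voxel features are invisible.
* One microbial functional group; no temperature or moisture response.
* Ball sets are generated synthetically; extraction of maximal inscribed
  balls from real images is out of scope.
* The learned conductances transfer across diffusion coefficients and time
  steps (they enter only through D_c·δt·θ), but they are specific to the
  geometry they were trained on.
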