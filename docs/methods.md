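# Methods

This note documents the models behind `nestpore`, their assumptions, the
parameters that matter, and the numerical and design choices a maintainer
would want explained.  It states no result the test suite or
`scripts/acceptance.py` does not itself compute.

## The physical picture

Termite nest-wall material is a granular composite: soil pellets of radius
≈0.52 ± 0.44 mm pressed together while moist, so that they fuse.  Fusion
leaves two pore populations — small intra-pellet (inter-particle) pores of
mean inscribed radius ≈19 μm, and large inter-pellet voids in the 70–120 μm
range.  The Senegal-type wall combines both at ≈28% total porosity; the
Guinea-type wall is clay-rich, nearly free of micropores, porous at ≈15%
mostly through large pores, and crossed by shrinkage cracks.  Almost all of
the pore space (>90%) connects across a wall sample.  The package treats
three transport questions on such media, each on a labeled voxel image:
how permeable the wall is to air (ventilation), how fast CO₂ diffuses
through the connected pores (gas exchange), and how well the mineral
skeleton conducts heat (insulation).

## Voxel images

All stages share one carrier: a 3-D integer label lattice with isotropic
voxel size in μm, axes fixed as (z, y, x), and a label → phase-name table
(air, water, solid, quartz, clay, hematite, metallic).  Voxel centres sit
at `(index + 0.5)·h`.  Anisotropic input is rejected unless the caller
asks for nearest-neighbour resampling, because every solver and morphology
routine assumes a cubic lattice.  TIFF carries no physical spacing, so
every writer emits a JSON sidecar with the voxel size and phase table;
MHD/NRRD carry spacing natively.  Fields export as legacy ASCII VTK
structured points (readable by ParaView) with the voxel size as spacing.

## Synthetic media

No real micro-CT data ship with the package, so the generators are the
data source; their defaults are the study conditions they emulate.

* **Pellet pack** (`generate_pellet_pack`): spheres with radii drawn from
  the pellet distribution (default 0.52 ± 0.44 mm, truncated at 4 voxels)
  are placed by random sequential addition; centres may approach
  `pellet_overlap_factor × (r_i + r_j)/2`, emulating the fusion of moist
  pellets.  The factor defaults to 1.45: random sequential addition with
  1.6 jams near an inter-pellet void fraction of ~0.16, above the ~0.119
  the Senegal-like porosity split requires, while 1.45 reaches it reliably;
  the factor remains a parameter.  Placement stops when the inter-pellet
  void fraction reaches φ_macro = (φ_total − φ_micro)/(1 − φ_micro);
  exhausting the attempt budget raises an error naming the achieved
  porosity.  Micropores are then carved inside the pellet solid by
  thresholding Gaussian-filtered white noise (correlation length =
  micropore radius / voxel size) at exactly the intra-pellet porosity
  quantile.  The published data give only the total porosity (27.9 ± 2.9%)
  and the porosity of small-pore-only subsets (18.3%); the split between
  scales is therefore a free parameter, `micro_porosity`, defaulting to
  0.183.  Generated Senegal-like media come out at the target porosity
  ±1% (quantile construction), ≥97% axis-connected, with a bimodal
  inscribed-radius distribution.
* **Micropore matrix** (`generate_micropore_matrix`): the same carving
  process filling a whole block — the analogue of a cubical subset
  containing only small pores.  At the default 19.3 μm correlation length
  its medial-axis pore-radius mean lands within a few percent of 19.3 μm,
  which is why the correlation length is used directly without a shape
  factor.
* **Sphere pack** (`generate_sphere_pack`): solid grains (default radius
  65 ± 15 μm, a fine-sand scale) placed by RSA — the air-dried slurry
  ("random pack") control.  Hard-sphere RSA cannot pass ~38% solid, so
  porosities below ~0.62 need `overlap > 0`.
* **Cracked matrix** (`generate_cracked_matrix`): planar cracks of given
  aperture about random or axis-normal planes in a clay block, for the
  Guinea-like case; achieved crack porosity is recorded.
* **Analytic fixtures** (`generate_analytic_geometry`): tube, parallel
  plates, layered slab, spherical cavity, and the tetrahedral cell of four
  mutually tangent spheres whose central pore admits an inscribed sphere
  of radius (√(3/2) − 1)·R ≈ 0.2247·R.  Features below 4 voxels across are
  rejected as under-resolved.
* **Drained states** (`generate_drained_state`): morphological invasion
  percolation.  Air occupies pore voxels whose local thickness is at least
  the entry radius *and* that connect to the inlet face through such
  voxels (face connectivity, matching the solvers); the rest of the pore
  space stays water.  This is the capillary-equilibrium idealisation of
  drainage — no film flow, no trapping dynamics, no evaporation.

All generators are bit-deterministic under `MediumSpec.seed`
(`numpy.random.default_rng`).

## Morphology

* **Porosity**: pore voxels / all voxels; the attached uncertainty is the
  standard deviation of per-slice porosities along a chosen axis, the same
  slice-scatter convention used for tomographic samples.
* **Local thickness**: the maximal-inscribed-sphere field.  A sphere of
  radius `dt(y)` (Euclidean distance transform) centred at `y` covers `x`
  when `|x − y| < dt(y)`; the local thickness of `x` is the largest such
  `dt(y)`.  Implementation: iterate distinct distance-transform values
  descending; dilate the centre set `{dt ≥ r}` by a Euclidean ball of
  radius `r` via a second distance transform.  All comparisons use
  integer squared distances, so the result is exactly the brute-force
  sphere-fitting oracle (tested on 40³ lattices).  `max_radii` subsamples
  the radius list for large images, quantising the field to the retained
  radii.
* **Pore-size distributions**: reported under two weightings, because the
  published histograms do not state one — per-voxel (each pore voxel
  contributes its local thickness) and medial-axis (distance-transform
  radii on the topology-preserving skeleton, i.e. the inscribed spheres
  where they are seeded).  The medial-axis weighting is the one that
  matches inscribed-sphere population statistics such as the 19.3 μm
  small-pore mean.
* **Connectivity and percolation**: cluster labelling defaults to
  26-connectivity (the convention of the commercial toolkits such
  analyses are usually run in), while everything the transport solvers
  see uses face (6-) connectivity; both are exposed.  The percolation
  threshold is the largest radius r\* such that `{local thickness ≥ r*}`
  still spans the axis; spanning is monotone in r, so bisection over the
  sorted distinct radii returns the exact discrete argmax (verified
  against a linear scan).
* **Occupancy**: drained images are binned by the *dry* local-thickness
  field; per bin the fractions of water, spanning (connected) air and
  disconnected air sum to one.
* **Structure thickness**: the solid phase is dilated then eroded
  (Euclidean balls) to mask off near-boundary structures; widths of the
  surviving channels or walls are 2× the distance transform on the
  skeleton.
* **Segmentation**: only global thresholding (fixed or Otsu) is provided,
  as a surrogate for ingesting pre-segmented data; watershed pipelines for
  real grayscale scans are out of scope.

## Transport solvers

All three solvers apply Dirichlet conditions on the two boundary faces of
the chosen axis and no-flux/no-slip conditions elsewhere, and reference
their effective coefficient to the **total** cross-section (pores +
solid), consistent with Darcy's law.

**Stokes flow.**  At the measured pore scale the Reynolds number is of
order 10⁻⁷–10⁻⁶, so the steady creeping-flow limit −μ∇²u + ∇p = 0,
∇·u = 0 replaces time-stepping the Navier–Stokes equations: the steady
solutions coincide and the linear problem is far cheaper and
deterministic.  Marker-and-cell staggered discretisation (pressure at
pore-cell centres, velocities on faces) makes the discrete field
divergence-free.  No-slip walls enter tangentially through a reflected
ghost value (wall half a voxel from the face row) and normally through
zero face velocities.  The domain sides default to no-slip ("solid
walls"); a free-slip option turns the slit fixture into ideal plane
Poiseuille flow for validation.  Pressure boundary values live on ghost
centres half a voxel outside, so the effective sample length is
`(N+1)·h`; permeability is `k = U_D μ (N+1)h / ΔP`.  The saddle-point
system (symmetric indefinite, dimensionless) is solved by sparse LU below
2·10⁴ unknowns and otherwise by MINRES with a block-diagonal Jacobi/
Schur-surrogate preconditioner, to a coupled relative residual of 1e-8 by
default (1e-6 for the large stochastic media in the test suite).
Validation: tube vs Poiseuille πr⁴/(8A) and slit vs the cubic law within
5% at 12-voxel features, errors shrinking under refinement (r = 6, 12,
24); slice-wise flux constant to solver tolerance.  A non-spanning pore
space is a *signal* (k = 0, zero fields), not an exception.  The default
pressure drop is 1 Pa across the sample, matching the simulation
convention for the real walls, and results scale exactly linearly in ΔP.

**Diffusion and heat conduction** share one finite-volume kernel for
∇·(σ∇u) = 0 with per-voxel σ ≥ 0 and harmonic-mean face
transmissibilities (exact for series composites).  For CO₂, σ = D_c =
1.6×10⁻⁵ m²/s in pores and 0 in solid (no interfacial reaction); for
heat, σ is the phase conductivity — quartz 7.8, dry kaolinite clay 0.96,
hematite 6.4 W/m/K, air 0 (ideal insulator; κ_air = 0.026 available as a
sensitivity flag), water 0.6.  Metallic phases default to quartz's value
(none is published) and are overridable.  The steady Laplace solve
replaces time-stepping the parabolic equations — the reported quantities
are steady-state.  The SPD system is solved by Jacobi-preconditioned
conjugate gradients (rtol 1e-8, sparse direct below 2·10⁴ unknowns).
Conducting clusters touching neither Dirichlet face are indeterminate up
to a constant and carry no flux; they are reported at the mid-potential.
The maximum principle and the Wiener bounds (volume-weighted harmonic ≤
K ≤ arithmetic mean) hold to solver tolerance.  Heat-flux streamlines are
integrated by fixed-step midpoint Runge–Kutta through the trilinearly
interpolated cell-centred flux.  Temperature results default to a 1 K/cm
gradient; diffusion fluxes can be rescaled (linearity) to the
physiological condition of a 5% CO₂ change relative to 0.0164 mol/m³ per
cm of wall.

## Dimensionless layer

Wind of speed v exerts a dynamic pressure ΔP = ρv²/2; Darcy velocity
U_D = kΔP/(μΔx); mass Péclet Pe_m = U_D L / D_app; heat Péclet
Pe_h = U_D L / α with α = K/(ρ c_p); and inverting Pe_m = 1 gives the
critical wind speed v = √(2 D μ Δx/(ρ k L)).  Air properties (ρ = 1.2
kg/m³, μ = 1.8×10⁻⁵ Pa·s, c_p = 1005 J/kg/K) are fixed defaults — the
published analysis does not print them, and these textbook ambient values
reproduce the printed ΔP = 15 Pa at 5 m/s and the printed Pe_h bounds to
<1%.  The wall thickness plays both the Darcy length Δx and the Péclet
length L.  Published permeability/diffusivity ranges do not state which
extremes pair; `peclet_table` evaluates every pairing of the endpoints
and reports all of them, and the acceptance script uses the
transport-favourable pairing (max k, min D) that reproduces the printed
Senegal bounds.  The tetrahedral inscribed-radius uses the exact factor
√(3/2) − 1 = 0.22474 (printed rounded as 0.225).

## Problem sizes and what the tests show

The real scans are ~10⁹ voxels at 2–5 μm; the package's test and example
media are scaled so the suite runs on one CPU: default generator 160³ at
15 μm with true pellet sizes, test media 64³–80³ at 15 μm with pellets
shrunk to 0.18–0.28 mm so both pore scales stay resolved on the lattice
(the scale ratio between pellets and micropores is then ~9–15 rather than
the real ~27).  On such media the suite reproduces the *structure* of the
published findings — porosity and connectivity targets, bimodal pore
populations, permeability enhancement ≥10× and diffusivity enhancement
≥3× from the macropore network, conductivity falling with porosity — but
passing tests on synthetic media do not certify the generators against
real nest material: absolute permeabilities depend on absolute pore sizes
and on micropore resolution (1–2 voxels in the scaled media), and the
noise-based micropores lack the grain-contact microstructure of real
inter-particle porosity.

## Known limitations

No CT reconstruction or watershed segmentation of real scans; no
two-phase capillary dynamics (only morphological invasion); no transient
thermal response or heat capacity (steady conduction only); no inertial
or slip-flow corrections; pellet mechanics replaced by geometric overlap.
Cracked matrices use infinite planes rather than polygonal crack networks.
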