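# Methods

## Model overview

`dfba3d` couples two descriptions of a growing colony:

* **Chemicals** (glucose, acetate, oxygen) are concentration fields on
  a regular cubic lattice obeying ∂C/∂t = ∇·(D_eff ∇C) + R(C).
* **Cells** are per-phenotype biomass fields m_i (fg) on the same
  lattice, coupled to the chemicals through the reaction term
  R(C) = Σ_i m_i v_C,i / V, where the exchange fluxes v_C,i and the
  growth rate v_bm,i come from flux balance analysis.

Two phenotypes are tracked: glucose utilizers (aerobic growth with
acetate overflow, anaerobic fermentation when O₂ runs out) and acetate
utilizers (strictly aerobic growth on acetate).  Because solving a
linear program per lattice site per step is prohibitive, FBA solutions
are precomputed on a (carbon uptake, O₂ uptake) grid — 50 × 160 evenly
spaced nodes between zero and the maximal uptake rates — and read back
by bilinear interpolation during the run.

### Assumptions

* Quasi-steady intracellular metabolism (standard dynamic-FBA
  assumption): fluxes react instantly to the local environment.
* Cells neither diffuse nor swim; mass moves only by growth pushing.
* Biomass is treated as dry weight for the flux coupling (258 fg per
  cell is used as gDCW-equivalent, since FBA fluxes are per gDCW).
* Acetate is the only secreted species tracked; CO₂ and water are not
  part of the lattice mass balance.
* In the default "well-mixed air" mode, cell-free air sites hold O₂ at
  its boundary value rather than explicitly diffusing a gas phase.
  This avoids the severe explicit-stability cost of a fast gas-phase
  diffusivity while keeping the air an O₂ reservoir at the colony
  surface; an explicit `D_air` mode exists for sensitivity checks.

## Time stepping

Each outer step spans one FBA refresh interval (default 36 s):

1. per-site availabilities from Michaelis–Menten saturation capped by
   supply, |v| ≤ min(v_max·C/(Km+C), C·V/(m·Δt)) — the second term
   guarantees C ≥ 0;
2. table lookup, reaction and exponential growth (m·e^{v_bm Δt} is the
   exact one-step integral at frozen rate);
3. regulation (starvation timers, below);
4. overflow pushing wherever Σφ > 0.65: excess mass is exported in
   equal parts to non-agar face neighbors, preserving the donor's
   phenotype proportions, iterated to a 10⁻⁶ relative tolerance;
   mass crossing the domain boundary is absorbed;
5. diffusion of each species in stability-limited explicit substeps
   (dt = safety·dx²/6D, safety 0.9), with harmonic-mean face
   transmissibilities and Dirichlet resets of the boundary shell.

The ordering is a design choice (the coupling literature fixes none);
halving the FBA interval changes 6-hour colony volumes by well under
1%, which the test suite checks.  Everything is deterministic — no
random numbers are used anywhere — and repeated runs are bit-identical.
Mirror-symmetric initial states stay bit-identically symmetric: all
stencil and pushing sums are grouped per axis so that IEEE addition
commutativity applies exactly.

## Flux tables

### Genome-scale route

`fit_strain_parameters` adjusts a model's maximal O₂ uptake and
growth-associated maintenance (GAM, the ATP coefficient of the biomass
reaction) so that FBA at the measured glucose uptake reproduces the
measured growth and acetate rates: a coarse grid over v_O₂ ∈ [5, 40]
mmol/gDCW/hr and GAM ∈ [10, 130] mmolATP/gDCW followed by local
refinement, minimizing the summed absolute relative errors (aerobic
condition fits v_O₂ and GAM_aero; the anaerobic condition, with the O₂
exchange closed, fits GAM_anaero).  `build_flux_table` then solves one
LP per table node with the carbon and O₂ uptake bounds set to the node
values; infeasible nodes are stored as zero growth and zero exchange
(dormancy) rather than aborting.

### Surrogate route

Where genome-scale models are not available, an analytic surrogate is
anchored to the strain table.  For the glucose phenotype, with O₂
sufficiency f = min(1, o₂/v_O₂max), the carbon uptake capacity blends
as cap(f) = f·v_glc_aero + (1−f)·v_glc_anaero, the applied uptake is
g = min(avail, cap), and growth/acetate are linear in g with slopes
interpolated between the aerobic (μ_aero/v_glc_aero) and anaerobic
(μ_anaero/v_glc_anaero) operating points.  This reproduces both
measured operating points of every strain exactly and never exceeds
μ_aero.  (The product cap(f)·slope(f) is mildly non-monotone within
~0.05% of μ_aero near f = 1 — a property of the blend, not of LP
tables, whose monotonicity the tests verify against independent
re-solves.)  For the acetate phenotype, growth is yield·uptake with
uptake limited by O₂ at 2 mol O₂ per mol acetate and zero under
anoxia.

### Parameters without published values

* **Maximal acetate uptake**: 10 mmol/gDCW/hr, shared by all strains
  (strain-specific data do not exist); configurable everywhere.
* **Acetate biomass yield**: 0.025 gDCW/mmol, giving ~0.25/hr growth at
  maximal uptake — typical for aerobic acetate growth of E. coli.
* **Diffusivities** (μm²/s, agar and cell-free medium): glucose 600,
  acetate 1100, O₂ 2000 — textbook aqueous values at growth
  temperature.
* **Boundary/initial concentrations**: glucose 138.8 mM in the agar
  (2.5% w/v ÷ 180.16 g/mol), O₂ 0.21 mM (air-saturated), acetate 0.
  Agar boundary sites are held at their initial values (the substrate
  is a reservoir); non-agar boundary sites at the species' air value
  (0 for nutrients).
* **Michaelis constants** (mM): glucose 0.015, acetate 0.05, O₂ 0.005.
* **Regulation**: glucose utilizers convert to acetate utilizers after
  τ = 1800 s of continuous local starvation with C_glc < 0.01 mM and
  C_ace > 0.5 mM; the transition is irreversible by default (a config
  flag enables the reverse rule).  The published description of this
  rule is qualitative; these thresholds are this package's defaults and
  are echoed into every run's metadata.

## Geometries

Six parametric substrates: flat slab; wall (a 90° step of
glucose-bearing agar, seed offset o from the wall face); square plateau
(height h, width w); square hole (depth h, width w); concave and convex
surfaces with single-axis cylinder-like curvature κ = 1/radius (curved
along x, flat along y).  Features are rasterized by site-center
membership and rejected if they span fewer than two sites.  Colonies
are seeded with a single cell's mass (258 fg) on the surface at the
domain center (for the wall, at offset o on the floor; for the hole, on
the hole floor).

## Scaled-down study conditions

The original parametric studies ran 10 μm lattices over multi-mm
domains for 40–50 hours on GPUs.  This package's packaged studies
(`dfba3d.studies`, `scripts/acceptance.py`, the acceptance tests) use
desk-scale conditions chosen once:

* strain and geometry studies: 0.64 × 0.64 × 0.72 mm domain, 0.2 mm
  agar, dx = 40 μm, 40 h (geometry comparisons evaluated at 35 h);
* grid convergence: 0.4 × 0.4 × 0.56 mm domain, dx ∈ {28, 42, 70} μm,
  38 h, errors averaged over 28–38 h against the finest grid.

All physical constants are identical to the full-scale defaults; only
domain, resolution and duration are reduced.  Consequences to keep in
mind when interpreting results: onset of cross-feeding shifts later
(the colony must still grow several glucose penetration depths tall,
but lateral growth is truncated by the absorbing boundary at ~30 h);
acetate-capable fractions run somewhat above the full-scale 5–10% band
because the boundary preferentially removes glucose-utilizing periphery
mass; and the 40 μm lattice under-resolves the ~25 μm aerobic surface
layer, which is exactly the regime the convergence study quantifies.
Site counts and aspect ratios are coarse at dx = 40 μm, so extent-based
metrics (height, width, aspect) move in 40 μm quanta.

## What the surrogate tables do and do not emulate

The surrogate reproduces measured growth/acetate/O₂ exchange at the two
anchored operating points and interpolates smoothly between them, which
is sufficient for the transport-limited colony regime (site conditions
rarely sit far from the O₂-limited branch).  It does not emulate
secondary byproducts (formate, ethanol, succinate), realistic
proton/CO₂ balances, or alternate optima of genome-scale models.
Passing tests therefore validate the spatial coupling and the
cross-feeding mechanism, not genome-scale metabolic detail.

## Numerical choices and degenerate inputs

* Explicit FTCS with per-species substep counts; the stability bound
  dx²/6D is enforced (violations raise, never silently proceed).
* Harmonic-mean face transmissibilities make zero-diffusivity (phase
  forbidden) faces exact no-flux faces.
* Bilinear table interpolation can overshoot an uptake bound near table
  kinks; applied uptakes are re-clipped to the availabilities.
* Empty colonies return NaN sentinels from fraction/dimension/turnover
  metrics rather than raising.
* Pushing with zero eligible neighbors (a site walled in by agar)
  retains its excess and has its growth suppressed the next interval;
  global non-convergence after 10,000 sweeps aborts the run.
* Onset time is the first 1%-crossing of the acetate-capable volume
  fraction, linearly interpolated between samples ("onset" has no
  published numeric definition; 1% is this package's convention and the
  threshold is an argument).

## Known limitations

* No advection, chemotaxis, cell death or maintenance-only dormant
  metabolism (dormancy appears only as zero-growth table entries).
* No implicit or adaptive time stepping; very fine grids are expensive
  (cost grows ~dx⁻⁵).
* The well-mixed-air O₂ treatment slightly over-supplies O₂ to tall
  colonies compared to an explicit gas phase.
* Genome-scale table generation requires model files supplied by the
  user (BiGG identifiers iJO1366, iB21_1397, iEcolC_1368, iWFL_1372,
  iY75_1357); nothing is downloaded at run time.
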