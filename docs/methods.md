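# Model and methods

`biofilmsim` is an individual-based model (IbM) of a bacterial biofilm
growing from a single founder cell on a flat, inert substrate overlaid by a
nutrient solution.  It couples three ingredients: overdamped Brownian
dynamics of rod-shaped cells with steric and adhesive interactions, Monod
nutrient uptake that sets each cell's elongation rate, and a discretized
reaction–diffusion equation for the nutrient field.  Everything is in
reduced units: lengths in the cell diameter σ, time in τ, energy in ε,
concentration in the bulk value C0.

## Cells and mechanics

A cell is a spherocylinder of aspect ratio L\* = L/σ + 1, described by its
centre **r**, unit axis **ê** and L\*.  New-born cells have L\* = L0\* = 2.6
(typical of *Pseudomonas putida*-like rods) and divide at 2·L0\*.

Cells interact through a truncated-and-shifted Kihara potential evaluated
on the minimum distance d_m between their axis segments,

    U(d_m) = 4 ε_BB [ (σ/d_m)^12 − (σ/d_m)^6 + 0.0154 ],   d_m ≤ 2σ,

zero beyond.  The shift is (1/2)^6 − (1/2)^12 to three significant figures,
making U continuous at the cutoff; the form is repulsive at short range
with a shallow attractive well that gives colonies their cohesion.  Forces
act along the minimum-distance vector and are applied at the closest axis
points, which determines the torques.  Segment–segment closest points use
the standard clamped two-pass procedure; exactly parallel overlapping
segments take the midpoint of the overlap interval (an arbitrary but
symmetric tie-break — any point of the overlap gives the same distance and
force direction).

The substrate (plane z = 0) acts on the axis-to-plane distance
d_iw = r_z − ½(L\*−1)|ê_z|:

* repulsion, active for d_iw < d_rep = (2/5)^(1/6) σ_w, of magnitude
  (ε_rep/d_iw)[(6/5)(σ_w/d_iw)^10 − 3(σ_w/d_iw)^4] along +z, applied at the
  lowest axis point.  The prefactor is the division form ε_rep/d_iw: its
  bracket then vanishes exactly at d_rep, consistent with the stated
  activation range;
* adhesion, active for d_iw < d_c = σ_w + 0.5σ, a spring −ε_att L\* r_z ẑ
  modelling uniformly distributed surface adhesion factors, applied at the
  axis offset (L\*²/(12 r_z))(ê·ẑ)ê from the centre (measured from the cell
  centre along the axis).  For a horizontal cell the offset vanishes; for a
  tilted cell the resulting torque flattens it onto the substrate.

Defaults: ε_BB = ε, ε_rep = 100 ε, σ_w = (2/5)^(1/6) σ, ε_att = 20 ε.  Any
single force contribution is capped at 10⁴ ε/σ (with a logged count):
overdamped integration with finite Δt needs bounded forces, and the cap
only engages during pathological transient overlaps.

## Brownian dynamics

Positions advance by drift (D/k_BT)·F·Δt decomposed parallel/perpendicular
to the axis plus Gaussian noise of variance 2DΔt per component; the axis
advances by the torque drift (D_ϑ/k_BT)(T × ê)Δt plus rotational noise in
two perpendicular frame directions, then is renormalized (first-order Euler
update, no metric correction).  The length-dependent coefficients are rod
hydrodynamics fits in ln L\* and reciprocal powers of L\* (all three
coefficients decrease with rod length, and D_⊥ < D_∥ throughout the cell
cycle), scaled by D0 = D0\*·σ²/τ with D0\* = 0.1.

Choices worth noting:

* k_BT ≡ ε — the standard reduced-unit convention for this family of
  models; only the ratio D/k_BT enters the drift.
* Δt = 10⁻⁴ τ by default.  At this step the capped forces move a cell at
  most ~10⁻² σ per step, and the free-diffusion statistics (MSD and
  orientational decorrelation) reproduce theory within sampling error.
* The perpendicular frame (v̂₁, v̂₂) is built deterministically by
  Gram–Schmidt against the coordinate axis least aligned with ê; the noise
  distribution is invariant to this choice, and determinism makes runs
  bit-reproducible for a given seed.

## Nutrient field and growth

The box is divided into cubic compartments of edge h = 10.85 σ with uniform
concentration inside each.  The field obeys

    ∂C/∂t = D_N ∇²C − Σ_i μ_i / h³,

advanced with an explicit FTCS scheme (stability limit h²/6D_N ≈ 0.2 τ at
D_N\* = 1000, comfortably above Δt).  The outermost lateral and top layers
are Dirichlet boundaries at C0 (the "far away" bulk); the substrate is
zero-flux (mirror).  The sink divides each compartment's total uptake by h³
so that C0·h³ is the compartment nutrient content — the single conversion
constant that makes the discretized equation dimensionally consistent.  One
diffusion coefficient is used everywhere (bulk and colony interior): runs
show C = C0 at the colony boundary throughout, so a separate in-colony
value would only complicate the model.

Each cell takes up nutrient at the Monod rate μ_i = μ_max L\* C/(K_s + C)
(per-length uptake, half-saturated at C = K_s) and elongates at
v_i = v_eff μ_i / L\*, i.e. at the length-independent speed v_eff μ_max
when saturated.  v_eff = 0.9 is the fraction of uptake converted to
biomass.  All cells in one compartment see the same C, hence equal specific
growth.  If a compartment's requested uptake over Δt exceeds its content,
all resident cells are scaled down proportionally (before the diffusion
update, from the pre-diffusion concentration); the diffusion step
additionally clamps C ≥ 0 and reports actually-delivered uptake, so the
field can never go negative even when diffusion itself drains a
near-empty compartment within the same step.

Cells divide on reaching 2L0\*: two daughters of L\*/2 with the parent's
orientation, centred at ±L\*/4 along the axis, exactly tiling the parent's
end-to-end extent — biomass m = Σ L\* is continuous across divisions.
Excess elongation beyond the threshold within the triggering step is
discarded (below 0.002 % of L0\* per event at the default Δt).

## Observables

* biomass m(t) = Σ L\*_i; density ρ = m/V_e.
* Ellipsoid fit: 20·L\* random axis points per cell, mirrored through
  z = 0 (the colony is treated as half an ellipsoid symmetric about the
  substrate, which also forces the xz/yz inertia components to zero); the
  inertia tensor about the in-plane centre of mass is diagonalized and its
  eigenvalues mapped to semi-axes a ≥ b (in-plane) and c (vertical) with
  the uniform-solid relations I_aa = (b²+c²)/5 etc.  For effectively
  coplanar colonies c is floored at σ/2.
* V_e = (2/3)πabc; A_e is half the Thomsen-type approximate ellipsoid
  surface (exponent p = 1.6075; exact for a sphere, ≲1.1 % error
  otherwise); A_z defaults to the as-printed convention (π/4)ab, with the
  full-ellipse convention π·ab available as an option.
* Shape: T_p = (a²−b²)/(a²−c²) and B_p = (a²−b²)/(a²+b²).  T_p ∈ [0, 1]
  exactly when a ≥ b ≥ c (flat colonies, the regime the simulations
  produce); b < c gives T_p > 1 and a = c gives a signed infinity, both
  returned as such.
* Order: S2 is the largest eigenvalue of Q = (1/N)Σ(3êê−I)/2; g2(r)
  averages P₂(ê_i·ê_j) in bins of centre-to-centre distance (the
  inter-cell distance convention; empty bins are NaN).
* Radial profiles bin the first compartment layer above the substrate
  (concentration by compartment centre, growth rate by cell) by lateral
  distance from the biomass-weighted colony centre.

## Orchestration

One step runs forces → BD move → uptake/growth → division → diffusion; each
sub-update sees a consistent state and the ordering effect is O(Δt).  A run
starts from one horizontal cell (random azimuth) at the height where the
net wall force vanishes, in a uniform field at C0, and stops at a biomass
target (matching the biomass-indexed way results are reported) or a time
limit.  Observables are recorded on a logarithmic-in-biomass schedule
(factor 1.15 by default).  The nutrient grid keeps the colony at least
three compartments away from every Dirichlet face, expanding with new
C0-filled shells when needed; pre-existing values are preserved exactly.
Snapshots, grid dumps and observable tables are plain TSV with lossless
round-tripping, so analysis can be re-run offline (`analyze` recomputes
every frame from files; per-frame sampling seeds derive from the run seed
and frame index, making re-analysis bit-identical to in-run measurement).
Replicates derive their seeds from (seed, replicate index) and are averaged
frame-by-frame (the schedule is biomass-indexed, so frame k means the same
biomass target in every replicate).

## What the simulations cover, and problem sizes

The default stop criterion is m = 10³ (a few hundred cells, a few minutes
on one core at ~2.5 M steps); the hot loops (neighbour-list forces, BD
update, uptake, FTCS) are numba-compiled.  At this scale the model already
shows the expected phenomenology: exponential early growth at the rate
ln 2 · v_eff μ_max / ((1+K_s\*) L0\*), a monolayer-to-3D transition,
colonies flattening toward circular bases (T_p and B_p decreasing), mild
interior depletion at K_s\* = 10 with C = C0 outside the colony, and
decaying global nematic order.  The late-time t³ biomass scaling and the
g2(r) > 0.3 nematic-domain signature develop at biomass 10⁴–10⁵ (hours per
replicate) and are provided as explicit long-running checks in
`scripts/longrun_validation.py` rather than default tests.

## Known limitations

* No explicit extracellular polymer matrix, no separate in-colony
  diffusion coefficient, no cell death/detachment, no gene regulation, no
  hydrodynamic interactions between cells.
* The FTCS solver is explicit; very large D_N\* would force sub-cycling
  (the implementation refuses unstable steps instead of silently
  diverging).
* Division is checked once per step; orientation is inherited exactly at
  division (thermal rotation decorrelates daughters naturally).
* The ellipsoid fit assumes the colony is well described by a half
  ellipsoid; for very small N the semi-axis floor (σ/2) dominates.
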