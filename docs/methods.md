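# Methods

`cellstretch` simulates microextensometer stretching of a single-layered
plant epidermal tissue (the onion-peel system) with a cell-scale finite
element model, to separate the contribution of cell geometry and cellular
patterning from the cell wall's own material stiffness.  This note records
the model, its numerical treatment, the synthetic-data choices, and the
design decisions taken where the construction was genuinely open.

Units: lengths µm, moduli and pressures MPa, forces µN (1 MPa·µm² = 1 µN),
energies pJ.

## Tissue model

**Geometry.** The tissue is a monolayer of rounded-cuboid cells, 20 µm wide
and 20 µm deep, with length set by the aspect ratio (1:1 … 20:1).  Cell
files run along the longitudinal axis (x); a *staggered* tiling offsets
alternate files by half a cell length (the brick-like pattern of onion
epidermis), a *stacked* tiling aligns them.  Each 2D cell is extruded to a
closed triangulated box: outer and inner periclinal faces plus anticlinal
side walls, the walls subdivided at the extrusion-segment boundaries
(default five 4-µm segments) and at the edges of the *connection band*.
Adjacent cells are mechanically joined only inside this band — a strip
centred at mid-depth covering one third of the anticlinal depth — where the
two facing walls are fused into a single common wall shared by both cells.
Outside the band each cell keeps its own wall, so cells can separate and
round off like real epidermal cells.  Border-straddling cells are truncated
at the template boundary and closed flat.

**Rounding.** Cell sides and ends are rounded by damped uniform Laplacian
smoothing (step 0.5) of all vertices except the central extrusion segment
and the fused band.  Iteration counts are chosen per resolution tier so the
smoothed templates lose between roughly 15 and 20 % of their enclosed
volume, always below the one-fifth budget the generator enforces — uniform
Laplacian shrinkage grows with edge length, so coarser meshes get fewer
iterations.  The exact rounding recipe of the original template generator is
not specified anywhere; this choice is the package's own, the simulated
stresses are sensitive to it, and that sensitivity is why the reproduction
targets carry generous tolerance bands.  An optional lens-shaped taper of
the cell cross-sections (``rounding_taper``) is available for stronger
shaping.

**Wall material.**  Walls are hyperelastic membranes (3-node triangles, no
bending energy), Saint Venant–Kirchhoff (SVK) with Lamé coefficients
(λ, µ) ↔ (E, ν).  Two variants:

* isotropic SVK on the **Biot strain** `E_B = U − 1` (U from the polar
  decomposition of the in-plane tangent map F).  With ν = 0 the uniaxial
  nominal-stress response is exactly linear with slope E, which keeps the
  tissue-level nonlinearity purely geometric;
* transversely isotropic SVK on the **Green–Lagrange strain**
  `E_G = (FᵀF−1)/2`, an orthotropic quadratic energy
  `W = ½E_l E_ll² + ½E_t E_tt² + 2µ_eff E_lt²` in the per-triangle material
  frame whose longitudinal axis is the projection of global x onto the wall
  plane (walls perpendicular to x fall back to the transverse modulus).
  With ν = 0 there are no coupling terms; the shear modulus
  `µ_eff = √(E_l·E_t)/2` is symmetric in the two axes and reduces to the
  isotropic µ = E/2 when the moduli coincide.  The normal-direction modulus
  is carried as metadata only — a membrane cannot strain through its
  thickness.

Defaults follow the study conditions: E = 100 MPa isotropic, ν = 0; the
anisotropic runs use 30 MPa longitudinal / 100 MPa transverse.  The Biot
strain energy is evaluated in closed form through the invariants of
C = FᵀF (tr U = √(tr C + 2√det C) for 2×2 C), which is exact, avoids
per-element SVD in the hot loop, and makes frame indifference structural.

**Wall thickness** is the one parameter the source material does not state,
and the only free overall stiffness scale.  It is calibrated so that
pressurizing the staggered 5:1 template to 0.5 MPa expands the cells by
≈ 15 % in volume, and exposed in the configuration.

**Loads.** Turgor is the potential `−P·V_cell(u)` summed over cells, with
`V_cell` the divergence-theorem volume of the closed deformed surface — an
exact follower load, always normal to the deformed faces.  A wall fused
between two equally pressurized cells receives zero net pressure.
Turgid runs use P = 0.5 MPa; plasmolyzed runs use P = 0.01 MPa (not exactly
zero, keeping the walls faintly tensioned).

## Equilibrium solver

The total potential `Π(u) = Σ W·A₀·t − Σ P·V(u)` is minimized over nodal
displacements.  Generalized forces ∂Π/∂u are analytic (closed-form per
triangle); the Hessian is assembled by forward finite differences of the
analytic gradient (step 1e−5 µm), using a distance-2 graph coloring so a
full Hessian costs 3×(number of colors) gradient evaluations, and is then
symmetrized.  One increment of the pseudo-time implicit backward Euler
scheme is

    u ← u − dt·(1 + dt·ℍ)⁻¹·∂Π/∂u

on the unconstrained degrees of freedom; dt starts at 0.1, doubles after an
accepted step (approaching a full Newton step as dt → ∞, capped at 1e6) and
halves when the linear solve fails or the step misses an Armijo-type
sufficient decrease — which also handles indefinite Hessians without
modifying them.  Convergence is declared when the ∞-norm of the free
residual falls below the tolerance.

Membranes in compression wrinkle at mesh scale (zero bending stiffness →
near-zero transverse stiffness), which traps Newton-type steps on long
plateaus.  When the residual stagnates, the solver continues the descent
with a limited-memory quasi-Newton polish (L-BFGS on the analytic forces)
and returns to pseudo-time stepping afterwards.  The unit suite verifies
the two routes agree with finite differences of the energy to < 1e−5
relative, and that the fused numba kernels used in the hot loop match the
vectorized numpy reference to machine precision.

Tolerances: the library default is 1e−4 µN (free-residual ∞-norm).  The
packaged study runs use 0.01 µN, about 1e−4 of the summed end reactions at
the study template sizes; intermediate pressure-ramp steps are solved 20×
looser.  Rigid-body motion is removed by 3-2-1 pinning during free
pressurization, and by two interior pins during stretching (end clamps
constrain only the stretch-axis coordinate, which leaves two translations
and the rotation about the stretch axis free — the source describes no
removal mechanism, so this is an artifact decision).

## Virtual extensometer protocol

A run pressurizes the template (pressure ramped in two increments), then
clamps the stretch-axis coordinate of the end-node sets at their
pressurized positions and displaces one end in equal increments
(re-equilibrating after each) up to the target strain.  The reaction force
along the stretch axis, summed over the displaced nodes, is logged against
cumulative displacement.  Displacement and force are measured from the
pressurized equilibrium — whose end-to-end distance is also the strain
reference length — matching curves that start at ≈ 0 stress at 0 strain.
Lateral edges are free, allowing the transverse narrowing that produces the
geometric strain stiffening.  Tissue stress divides the summed force by the
template cross-section (width × 20 µm anticlinal depth); strain is quoted
in % of the reference length, and 20 % strain is the standard comparison
point.  Quantitative comparisons stretch to 20 %; curve panels may run to
50 %.

## Resolution tiers and problem sizes

Two tiers are built in.  The *full* tier mirrors the original template
sizes (300×300 µm extents, 600×600 for 20:1, 2 µm vertex spacing).  The
*coarse* tier — used by the packaged suite, the test suite and the
reproduction script — scales the problem to desk size while preserving
every modeled mechanism: vertex spacing 5 µm for aspect ratios ≤ 5 and
10 µm above, extents of about two cell lengths by four to six cell files,
and the same band layout.  The 5:1 condition, which carries the headline
quantitative comparisons, keeps the full five-segment wall subdivision
(seven wall strips once the band edges are inserted); the sweep conditions
use three strips, the central one being the band.  Finite template size
biases apparent stiffness upward (fewer compliant cell–cell interfaces per
clamped length, strongest in the transverse direction), and coarser hinge
resolution adds a further stiff bias; both push the coarse-tier stresses
above the full-scale values, which the reproduction bands absorb only
partly.

## Synthetic extensometer traces

The raw-curve generator emulates only the features the curve-analysis step
consumes: a flat toe region (slack straightening at near-zero force), a
linear elastic rise with slope `E_app·A/L`, and additive Gaussian force
noise, reproducible under a seed.  It deliberately omits plasticity, the
pre-rupture plateau and rupture itself — so passing round-trip tests shows
the normalization/toe/slope pipeline is correct, not that the model captures
late-stage wall mechanics.

## Anisotropy fitting

`fit_longitudinal_fraction` inverts tissue-level measurements: monotone
bisection over the wall modulus fraction E_long/E_trans ∈ (0, 1], each
candidate evaluated by a full pressurize+stretch pair.  Because the
anisotropic law uses the Green strain, each direction's 20 %-strain stress
is optionally divided by the Green/engineering secant factor (1 + ε/2,
i.e. 1.1 at 20 %) before the ratio is formed; the original linearization is
not defined, so this correction is the package's documented choice (at a
common reference strain it cancels in the ratio and is retained mainly for
comparing stresses across strain measures).  The fit stops within 5 %
relative of the target ratio or when the bracket shrinks below 0.01, and
reports boundary hits explicitly.

## Known limitations

* Membrane-only walls: no bending stiffness, hence mesh-scale wrinkling in
  compressed regions; wrinkle geometry is not physical, though its effect
  on macroscopic reactions is small.
* Purely elastic: no plasticity, creep or rupture, so simulated curves
  diverge from experiments beyond the elastic regime.
* The rounding recipe, wall thickness and border-cell handling are
  under-determined by the source; each is a documented package choice, and
  the reproduction bands absorb their influence.
* Coarse-tier values carry a systematic stiff bias (finite size +
  resolution), largest for transverse stretches.
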