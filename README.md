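# cellstretch

A virtual microextensometer for plant epidermal tissue.  `cellstretch`
builds idealized 3D templates of an onion-peel-like cell monolayer,
pressurizes the cells with turgor, stretches the tissue between virtual
clamps with a membrane finite-element model, and turns the logged reaction
forces into the stress–strain curves an extensometer would record.

It exists to answer a deceptively simple question: when a stretching
experiment says a tissue is stiffer in one direction, is that the cell
*wall* or the cell *geometry* talking?  Elongated, brick-patterned cells
make a tissue look much stiffer along the cell axis even when the wall
material is perfectly isotropic — so tissue-level stiffness ratios cannot
be read as wall anisotropy without a model like this one.  The package is
aimed at plant biomechanics researchers who want a lightweight, scriptable
counterpart to full FEM frameworks for this class of experiment.

## Model in brief

Cell walls are hyperelastic membranes (3-node triangles) with a Saint
Venant–Kirchhoff law: isotropic on the Biot strain `E_B = U − 1` (exactly
linear uniaxial response at ν = 0, slope E), or transversely isotropic on
the Green–Lagrange strain `E_G = (FᵀF − 1)/2` with independent in-plane
moduli `E_long`, `E_trans`.  Turgor enters the total potential as an exact
follower load,

    Π(u) = Σ_tri W(E*) · A₀ · t  −  Σ_cells P · V_cell(u),

with `V_cell` the divergence-theorem volume of each closed cell surface.
Equilibrium is found by pseudo-time implicit backward Euler,
`u ← u − dt·(1 + dt·ℍ)⁻¹·∂Π/∂u`, with analytic forces, an FD Hessian via
graph coloring, adaptive dt (→ Newton), and an L-BFGS fallback for
membrane-wrinkling plateaus.  Defaults follow the study conditions:
E = 100 MPa, ν = 0, P = 0.5 MPa turgid / 0.01 MPa plasmolyzed, cells 20 µm
wide and deep, connected to neighbors only over a mid-depth band of one
third of the cell depth.  Units: µm, MPa, µN.

See `docs/methods.md` for the full model description and design decisions.

## Worked example

Pressurize a small staggered 5:1 template and stretch it 20 % in both
directions:

```python
from cellstretch.experiments import stretch_study

res = stretch_study(aspect_ratio=5, staggered=True, pressure=0.5)
print(f"volume change on pressurization: {100 * res.volume_change:.1f}%")
for d in ("longitudinal", "transverse"):
    print(f"{d}: {res.stress[d]:.2f} MPa at 20% strain")
print(f"stiffness ratio: {res.ratio:.2f}")
```

which prints (coarse resolution tier, a few minutes on one CPU):

```
volume change on pressurization: 17.9%
longitudinal: 3.14 MPa at 20% strain
transverse: 0.76 MPa at 20% strain
stiffness ratio: 4.15
```

Reading: turgor inflates the cells by about a fifth of their volume; the
tissue then resists longitudinal stretching ~4× more strongly than
transverse stretching *with an isotropic wall* — the anisotropy is pure
geometry.  The transverse direction is also the one that loses almost all
its stiffness when turgor is removed (`pressure=0.01`).

The same machinery is scriptable from the shell:

```sh
cellstretch make-template --aspect 5 --staggered --coarse --out mesh.vtk
cellstretch run --config experiment.yaml --out results/
cellstretch fit-anisotropy --target-ratio 1.97 --pressure 0.01
cellstretch paper-suite --out results/suite
```

`fit-anisotropy` inverts the geometry: given a tissue-level stiffness
ratio measured on (for instance) plasmolyzed samples, it bisects the
wall's `E_long/E_trans` fraction until the simulated tissue reproduces it.

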