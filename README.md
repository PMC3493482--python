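# corticalmaps

Coordinated optimization of visual cortical maps: coupled Swift-Hohenberg
dynamics of an orientation-preference (OP) map and an ocular-dominance (OD)
map, the coupled amplitude equations with their closed-form stationary
pinwheel-crystal solutions, and the map-geometry statistics used to
characterize them.

## The scientific problem

Orientation preference in primary visual cortex is a complex field
z(**x**) — preferred orientation theta = arg(z)/2, selectivity |z| — whose
point singularities are *pinwheels*; ocular dominance is a real field
o(**x**) whose sign marks the dominant eye.  If cortical maps are optima of
an energy functional, which coupling energies between the maps can
stabilize pinwheels, and what map geometry do they predict?  Both maps obey
gradient descent of

E = ∫ [ −z̄ L z + |z|⁴/2 ] + ∫ [ −o L o / 2 + o⁴/4 − γ o ] + U[z, o],
L = r − (k_c² + ∇²)²,

with γ a contralateral bias and U one of the symmetry-allowed,
positive-definite inter-map coupling energies

* product type: U = c ∫ o² |z|²
* gradient type: U = c ∫ |∇o · ∇z|²

(plus their squares at higher order, supported for simulation).  Near
threshold, weakly nonlinear analysis reduces the dynamics to amplitude
equations on the hexagonal triad k₁ + k₂ + k₃ = 0.  The bias drives the OD
map through stripes → hexagonal ipsilateral blobs → constant, and coupling
to OD *hexagons* stabilizes hexagonal pinwheel crystals (hPWCs): the
**ipsi-center crystal** (product coupling; 6 pinwheels per unit cell — 2 at
OD maxima, 1 at the blob minimum, 3 at saddle points) and the **Braitenberg
crystal** (gradient coupling; 3 pinwheels per unit cell, the one at the
blob minimum carrying topological charge 1).  Strong low-order coupling
ultimately suppresses orientation selectivity altogether.

The package is for computational neuroscientists and pattern-formation
researchers who want these ground states, stability borders and phase
diagrams as reproducible, tested code: exact mode-projection amplitude
equations, closed-form branches, numerical continuation and stability,
spectral field simulation, and pinwheel/angle/contra-fraction analysis.

## Worked example

```python
import numpy as np
import corticalmaps as cm
from corticalmaps import map_analysis as ma

grid = cm.make_grid(192, 128, 2, 1)            # two hexagonal unit cells
params = cm.ModelParams(r_op=0.1, r_od=0.2, coupling_kind="product_low",
                        c=1.0, eta=0.5477, kc=grid.kc)

opmap, odmap = cm.fixture("hpwc_ipsi", grid, params)
pws = ma.find_pinwheels(opmap)
cls = ma.classify_pinwheel_positions(pws, odmap)
ang = ma.intersection_angles(opmap, odmap)

print("pinwheels per unit cell:", pws.per_unit_cell)
print("positions per cell:", {k: v // 2 for k, v in cls["counts"].items()})
print("dominant crossing angles:", np.round(ang.peak_angles[:4], 2))
```

prints

```
pinwheels per unit cell: 6.0
positions per cell: {'at_max': 2, 'at_min': 1, 'at_saddle': 3, 'near_border': 0, 'other': 0}
dominant crossing angles: [89.83 89.83 89.83 89.53]
```

The stable uniform solution of the
product-type coupling is the ipsi-center pinwheel crystal with 6 pinwheels
per unit cell — 2 at OD maxima, 1 at the ipsilateral blob center, 3 at OD
saddle points — and its dominant iso-orientation lines cross the OD borders
at right angles.  The rescaled bias `eta = 0.5477` places the OD map in the
middle of its hexagon (blob) stability band; `c = 1.0` lies between the
crystal's stability onset and its suppression border `3 r_op / r_od = 1.5`.

The OD subsystem on its own:

```python
from corticalmaps import od_subsystem as od
od.od_stability_borders(0.2)["stripe_loss"]["eta"]   # 0.4472 (= 1/sqrt 5)
od.contra_fraction("hexagons", od.gamma_for_eta(0.55, 0.2), 0.2)  # 0.7061
```

A command-line interface mirrors the library:
`corticalmaps simulate|analyze|od-borders|od-fraction|branch|phase-diagram`.

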