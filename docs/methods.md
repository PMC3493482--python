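# Methods

## Model

Two order-parameter fields describe the functional architecture of primary
visual cortex on a two-dimensional periodic domain: a complex field z(x)
whose argument (halved) is the preferred stimulus orientation theta in
[0, pi) and whose modulus is the orientation selectivity, and a real field
o(x) whose sign encodes ocular dominance (positive: contralateral eye,
negative: ipsilateral eye).  Both fields evolve by gradient descent of an
energy functional

    E = E_op[z] + E_od[o] + U[z, o],

whose single-field parts are of Swift-Hohenberg form with linear operator
L = r - (kc^2 + Laplacian)^2 and quartic saturation, so that each map in
isolation develops a repetitive pattern with typical wavelength
Lambda = 2 pi / kc.  The OD equation carries a constant bias gamma favoring
the contralateral eye.  The coupled dynamics is

    dz/dt = L_op z - |z|^2 z - dU/dconj(z)
    do/dt = L_od o - o^3 + gamma - dU/do .

Symmetry (translation, rotation, orientation shift z -> e^{i phi} z, eye
inversion o -> -o) admits two positive-definite coupling energy densities
at lowest order, and their squares at the next order:

    product type :  c o^2 |z|^2          (and  c o^4 |z|^4)
    gradient type:  c |grad o . grad z|^2 (and c |grad o . grad z|^4)

The low-order pair is treated both at field level and by weakly nonlinear
analysis; the high-order pair is supported at field level (energy and
functional derivatives for simulation) only.

## Ocular dominance subsystem

Shifting o by the constant delta that solves
delta^3 + (kc^4 - r_od) delta = gamma removes the constant term and leaves
a quadratic interaction -3 delta o~^2 with shifted control parameter
r~ = r_od - 3 delta^2.  Near threshold the triad k1 + k2 + k3 = 0 obeys

    dB1/dt = r~ B1 - 6 delta conj(B2 B3)
             - 3|B1|^2 B1 - 6 (|B2|^2 + |B3|^2) B1   (+ cyclic).

Stationary solutions: stripes B_st = sqrt(r~/3); hexagons
B_hex = (3|delta| + sqrt(9 delta^2 + 15 r~)) / 15 with phase sum pi for
contralateral bias (ipsilateral blobs in a contralateral sea); and the
constant (monocular) state o = delta.  Stability borders, exact in
delta^2 / r_od:

| border                | delta^2 / r_od |
|-----------------------|----------------|
| hexagons appear       | 1/51           |
| stripes destabilize   | 1/15           |
| constant stabilizes   | 1/3            |
| hexagons disappear    | 5/12           |

All OD quantities are parameterized by the rescaled bias
eta = |delta| sqrt(3 / r_od) (constant onset at eta = 1); borders in gamma
follow from the exact shift map, and the border shifts scale exactly as
sqrt(r_od).  The closed forms are validated against numerically bracketed
sign changes of finite-difference Jacobians of the amplitude equations
(translation zero modes deflated by restriction to their orthogonal
complement) and, for the hexagon fold, a simultaneous
(stationarity, marginality) root solve.

Contralateral area fractions: stripes arccos(-delta / 2 B_st) / pi (1/2 at
zero bias); hexagons via the circular-blob approximation -- the ipsilateral
disk radius is the zero of the field projected on an axis through the blob
center, x0 = (2/kc) arccos[(-1 + sqrt(3 + 2 d)) / 2], d = |delta| / 2 B_hex,
and the fraction is 1 - pi x0^2 / A_cell with A_cell = 8 pi^2 / (sqrt 3 kc^2).
The approximation is poorest at low bias where the blob is least circular,
but stays within about 0.3% of direct pixel counts across the entire
stability band (the tests enforce 1%).  Both fractions are independent of
r_od at fixed eta.

## Orientation-preference amplitude equations

Near threshold z is a superposition of six critical modes (the triad and
its opposites).  All projections -- the cubic |z|^2 z, the product-type
o^2 z, and the gradient-type div[(grad o . grad z) grad o] -- are evaluated
by exact enumeration of resonant wavevector combinations in integer triad
coordinates.  This reproduces the coupled amplitude equations including
every configuration-dependent resonant term, and every closed form below is
verified against these projections to a residual of 1e-10 or better.  The
backreaction of the weak OP modes on the OD pattern is neglected (the
analysis is done in the regime r_op << r_od where OP amplitudes are much
smaller than OD amplitudes); the OD amplitudes entering the OP equations
are the frozen stationary values of the OD subsystem.

Stationary families (closed forms):

* Stripes: single mode, A = sqrt(r_op).  Product coupling to OD stripes
  deforms them into an A+/A- pair (relative phase pi) with
  A+^2 + A-^2 = r - c (delta^2 + 2 B^2) and A+ A- = c B^2; the pair
  collapses at c = r / (delta^2 + 4 B^2) into the orientation-scotoma
  branch A+ = A- = sqrt((r - c (delta^2 + B^2)) / 3), which represents only
  two orthogonal orientations and vanishes at c = r / (delta^2 + B^2)
  = 3 r_op / r_od -- independent of the bias because
  delta^2 + B_st^2 = r_od / 3 exactly on the stripe branch.
* Rhombic pinwheel crystals: two mode pairs with a pi/2 relative phase,
  z = 2 a (cos k x + i cos k' x); the resonant pair interaction gives the
  effective cubic coefficient 5, a = sqrt(r/5), V = -2 r^2 / 5 (stripes,
  V = -r^2/2, are always preferred uncoupled).  Coupled rhombic and
  stripe-like branches with coupling-dependent phases are followed by
  Newton continuation with adaptive step halving.
* Uniform hexagonal pinwheel crystals: z = 2 A sum_j w^{1-j} cos(k_j x + psi),
  w = e^{2 pi i / 3}.  Stationarity holds for arbitrary amplitude phase only
  at psi = 0 or psi = pi/2; the cubic coefficient of the family is 9 and the
  coupling contributes a linear coefficient L (computed by projecting the
  interaction term onto the family), so A = sqrt((r_op + L)/9).  With OD
  hexagons at contralateral bias:

      product type : L(psi=pi/2) = -c (delta^2 - 2 delta B + 5 B^2)
                                 = -c r_od / 3   (exact identity on the
                                   hexagon branch -> bias-independent
                                   existence border c = 3 r_op / r_od)
                     L(psi=0)    = -c (delta^2 + 2 delta B + 3 B^2)
      gradient type: L(psi=0)    = -(3/2) c kc^4 B^2
                     L(psi=pi/2) = -2 c kc^4 B^2

  Numerical linear stability (12-dimensional finite-difference Jacobians,
  symmetry tangents deflated) identifies psi = pi/2 as the stable family of
  the product coupling -- the ipsi-center crystal, 6 pinwheels per unit
  cell: 2 at OD maxima, 1 at the blob minimum, 3 at saddles -- and psi = 0
  as the stable family of the gradient coupling -- the Braitenberg crystal,
  3 pinwheels per unit cell, the one at the blob minimum a double zero of
  charge +-1.  The handedness convention makes that charge +1.

## Numerical choices

* Domain: periodic rectangle, Lx = n_x Lambda, Ly = n_y 2 Lambda / sqrt 3,
  with n_x even so all triad wavevectors are exact Fourier modes (a 2 x 1
  grid covers exactly two hexagonal unit cells by area).  Oblique lattice
  coordinates were rejected to keep standard FFT plumbing; exact mode
  commensurability is what makes synthesis and projection mutually inverse
  to round-off.
* Time integration: first-order exponential time differencing (exact
  diagonal linear propagator, explicit nonlinear terms), fixed step with an
  energy-descent watchdog that aborts when the total energy rises beyond
  tolerance.  Products are dealiased by padded FFTs (3/2 rule for cubic
  terms, 2x padding for the high-order couplings).  Default stopping rule:
  relative L2 field change per unit time below 1e-7.
* Newton solver: least-squares (minimum-norm) steps on the 12 real
  amplitude coordinates, tolerance 1e-12; continuation halves its step on
  failure and stops where convergence is lost.
* Pinwheel detection: plaquette winding of arg z with differences wrapped
  to (-pi, pi]; sub-pixel positions from bilinear zero crossings of Re z
  and Im z; windings closer than Lambda/20 merge into one pinwheel (this
  assembles the Braitenberg charge-1 double zero from its two same-sign
  plaquettes).  A winding is accepted only where both Re z and Im z change
  sign inside the plaquette, and globally phase-degenerate maps
  (z = e^{i alpha} times a real field, e.g. the orientation-scotoma states,
  whose zeros are lines) are recognized by the rank of the second-moment
  matrix of (Re z, Im z) and report no pinwheels.  If a zero falls
  numerically on a grid node -- where arg z is undefined -- the
  band-limited field is resampled on the half-shifted lattice (exact
  spectral shift).  OD critical points use the same winding
  applied to d_x o + i d_y o on the half-shifted lattice, require sign
  changes of both gradient components inside a plaquette (so 1-D stripe
  fields, whose extrema are lines, yield no isolated points), and are
  classified by the interpolated Hessian.
* Intersection angles: the o = 0 contour is sampled by marching squares;
  at each point the angle between the border tangent (perpendicular to the
  spectrally evaluated grad o) and the iso-orientation direction
  (perpendicular to grad theta = Im(conj(z) grad z) / 2|z|^2) is folded
  into [0, 90] degrees and weighted by |grad theta|, emphasizing the
  high-gradient regions that carry reliable angle information.  For the
  hexagonal crystals the angle equals 90 degrees exactly on the crystal's
  mirror lines, which are simultaneously the local maxima of |grad theta|
  along the border (the dominant iso-orientation lines visible in the map);
  these crossings are perpendicular at every bias.  Generic crossings
  between mirror lines dip a few degrees below 90, so the full weighted
  histogram has its mode in the top bin with mean around 86-88 degrees.
  The reported `peak_angles` are the angles at those gradient-maximal
  crossings.
* Overrepresented orientations: circular local maxima of the orientation
  histogram with prominence at least 30% of the histogram range; a flat
  (stripe-ramp) distribution reports none.
* Phase diagrams: bias axis in eta, coupling axis rescaled as
  chat = c r_od / (3 r_op) (product type; suppression at chat = 1) or
  chat = c kc^4 B_hex^2 / r_op (gradient type; all OP borders then
  bias-independent), making the diagrams independent of r_op.  Borders are
  refined by bisection on the largest non-symmetry eigenvalue.

## What the synthetic fields do and do not emulate

The closed-form planforms are exact stationary states of the truncated
(third-order) amplitude equations, synthesized on commensurate grids.  They
emulate the crystalline ground states of the coordinated-optimization
model near threshold: ideal periodic pinwheel lattices with perfectly
locked OP-OD geometry.  They do not emulate the spatially aperiodic,
defect-laden layout of biological maps, finite-range correlations,
measurement noise, or wavelength disparity between the two maps; passing
tests on these fields demonstrates correctness of the model analysis, not
realism of the crystals as descriptions of experimental cortex (the model
itself predicts crystals, which is part of its scientific point).

Simulated attractors depend on the basin of the random initial condition:
besides stripes, rhombic pinwheel crystals are stable uncoupled states, and
on small commensurate domains random noise frequently crystallizes into
them.  The zero-bias simulations therefore use documented seeds (the
phenomenology protocol fixes one initial condition and varies bias and
coupling).  Phenomenology runs use r_op << r_od (r_op = 0.05, r_od = 0.2)
because the frozen-OD amplitude analysis requires the OP modes to be much
smaller than the OD modes; with comparable control parameters the
backreaction suppresses the OD pattern and changes the attractor
repertoire.

## Problem sizes

Desk-scale geometry checks use 192 x 128 grids covering two unit cells.
Simulation-based checks use 128 x 128 grids over 6 x 4 cells with
r_op = 0.1 (phenomenology) or r_op = 0.01 (amplitude-equation agreement),
chosen so the whole suite completes in a few minutes on one CPU.

## Known limitations

* Amplitude-equation support covers the two low-order couplings; the
  high-order couplings are field-level only.
* Detuned OP/OD wavelengths, non-periodic boundaries, and stochastic or
  non-gradient dynamics are out of scope.
* The rhombic angle is arbitrary in the uncoupled theory but only
  triad-commensurate angles can be synthesized on the default grids.
* The perpendicular (Ice-cube) stripe solution of the gradient coupling
  lies off the hexagonal mode lattice; it is represented with a rotated
  mode frame and simulated on square grids.
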