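# Methods

This note records the modelling assumptions, parameter choices and
numerical decisions behind `cardiomefi`, in the order the pipeline runs.

## Scope and overall design

The package simulates the systolic phase of a left ventricle — from an
end-diastolic state through isovolumic contraction and ejection until the
aortic valve closes — with the three classical ingredients coupled in a
staggered loop: monodomain electrophysiology, active-stress hyperelastic
wall mechanics, and a lumped afterload. Intraventricular 3D blood flow
and aortic-valve fluid–structure interaction are deliberately out of
scope: the cavity is represented by a 0D surrogate in which the cavity
pressure is a single scalar coupled to a two-element Windkessel through
an ideal valve. This preserves every constitutive and electrophysiological
ingredient while keeping runs at desk scale (seconds to minutes on one
CPU). Diastolic filling is not modelled; the end-diastolic configuration
is treated as an effectively prestressed initial state, obtained by a
short quasi-static equilibration of the generated geometry at the
end-diastolic pressure (default 10 mmHg) with zero active stress. No
unloaded-configuration recovery is attempted.

## Parameterized geometry

The wall is generated from elliptical cross-sections along the long axis
(nine levels by default), with the base plane at Z = 0 and the apex at
Z = Z_apex > 0. The endocardial surface is the smooth (monotone-cubic,
PCHIP) interpolant through the level ellipses with an ellipsoidal apex
cap; default cross-section aspect ratio (minor/major) is 0.9. The
epicardium is offset along the endocardial normal by a thickness map

    t(θ) = c0 + c1 cos θ + c2 cos 2θ,

with coefficients chosen so the circumferential mean equals the card's
average thickness exactly while θ = 0 / π hit the printed maximum /
minimum. Near the apex the offset direction blends toward "radial from
the osculating centre" of the apex cap; this keeps the offset surface
fold-free when the wall is thick relative to the apex curvature radius
(relevant for the thick-walled remodelling cases) at the price of a
slightly non-normal offset in the last ~30° of the meridian.

Because the closed-form link between the printed dimensions and the
end-diastolic volume is not available, an outer calibration loop
uniformly rescales the endocardial semi-axes — long axis fixed — until
the *meshed* cavity volume (divergence theorem over the triangulated
endocardium plus a basal cap fan) matches the card EDV to 0.2%, well
inside the 1% contract. The apex-to-base length is exact by
construction: the epicardial apex sits at Z_apex = long axis.

The LVOT is an optional short axial extension (18% of the long axis)
morphing the basal endocardial ellipse into a circle of the card's
outlet radius, with an optional tilt. The outlet radius and tilt are not
part of the printed per-case table; the package uses 10 mm / 0° as the
single documented default (8 mm for the small-cavity case, 10° tilt for
the tilted-outflow case). The coupled driver runs without the LVOT
extension; the base ring is the fixed boundary.

Meshing uses a structured (meridian × circumference × transmural) grid
subdivided into tetrahedra by the Kuhn/Freudenthal rule, which is
conforming across the periodic seam and at the collapsed apex pole
(degenerate cells are dropped). Resolutions: `tiny` (12×8×2, ~1.1k tets),
`coarse` (16×12×2, ~2.2k tets), `medium`, `fine`. These are one to two
orders below clinical-imaging-grade meshes; the verification suite
therefore checks printed dimensions, convergence trends and invariants
rather than mesh-converged field values.

The aortic root builder produces surface geometry only (three congruent
120°-sector leaflets on a radius-R cylinder, logarithmic guide curve
z ∝ ln(1 + k v)/ln(1 + k), belly sag factor a, free-edge centre at 0.8 H).
It feeds the leaflet material law and geometric checks; no leaflet
mechanics or contact is solved.

## Fiber architecture

Directions come from a harmonic field (P1 Laplace, U = 0 epicardium,
U = 1 endocardium, natural elsewhere): e = −∇U/|∇U| is the transmural
axis. The transmural *coordinate* β defaults to the Euclidean distance
ratio D_epi/(D_epi + D_end) evaluated by exact point-to-triangle
distances (the harmonic field is available as an alternative; the two
agree within 0.05 sup-norm on slab and annulus benchmarks). The helix
angle interpolates linearly across the wall between ±60° at the base and
tapers linearly to zero at the apex. The local frame is a1 = e,
a2 = apicobasal projected into the wall, a3 = a1 × a2 (circumferential);
the fiber is a3 rotated by θ about a1 *toward* a2 — the sign convention
is a recorded choice, since handedness is not fixed by the angle rule
alone. The sheet is the transmural axis and the sheet-normal completes
the right-handed triad; "sheet ⊥ both surfaces" admits two readings and
this one is used consistently in conductivity and active stress.
Elements whose transmural axis is parallel to the apicobasal axis fall
back to the neighbour average. Elements intersecting a 1-cm-diameter
cylinder about the long axis at the apex are flagged isotropic: their
conductivity becomes the eigenvalue mean and their active stress the
trace-preserving isotropic tensor.

## Electrophysiology

Kinetics are the two-variable phenomenological excitation model with
α = 0.01, c = 8, b = 0.15, γ = 0.002, μ₁ = 0.2, μ₂ = 0.3 — the standard
published constants for this model family (the source derivation prints
none). The stretch-activated current G_s (λ_f − 1)(φ − φ_s) uses
G_s = 1, φ_s = 0.6 by default and is gated twice: by the potential
threshold and by an activation window defined as the interval between
the local φ-upcrossing and φ-downcrossing of 0.5 (the window form is
under-specified in the source; this indicator realization is the
package's choice). Fiber stretch λ_f = √(ā·C·ā) is supplied by the
mechanics state, averaged to nodes.

The dimensional mapping Φ = β_φ φ + δ_φ is calibrated per parameter set
by simulating one single-cell action potential and solving the two-point
system Φ(0) = −80 mV, Φ(φ_peak) = +20 mV. Dimensionless time τ converts
to milliseconds via t = β_t τ with
β_t = t_β [1 − τ₀ (t_a − t₀)/(t₁ − t₀)] and t_a = t_α (1 − Z/Z_apex);
defaults t_β = 12 ms, τ₀ = 0.2, t₀ = 0, t₁ = t_α = 30 ms were chosen
once so the single-cell action-potential duration lands at ~250 ms (a
systolic interval) and basal tissue runs on a slightly faster clock than
the apex. All are configurable.

Propagation uses P1 finite elements with mass lumping and semi-implicit
stepping (diffusion implicit via a pre-factorized operator, reaction
explicit; default dt = 0.1 ms, halved automatically on instability).
Conductivities are 0.6/0.2/0.1 mm²/ms along-fiber / cross-fiber /
transmural as printed; the monodomain square-root law then fixes the
along/cross conduction-velocity ratio at √3 ≈ 1.73, which the suite
asserts. (A 3:1 velocity ratio would require a 9:1 conductivity ratio;
the printed conductivities are taken as authoritative.) The assembled
stiffness receives an M-matrix correction by default — positive
off-diagonal entries are clipped into the diagonal, preserving row sums —
because anisotropic P1 stiffness on the obtuse tets of the structured LV
mesh otherwise violates the discrete maximum principle and lets the
mapped potential undershoot the −80 mV floor by ~2 mV. The correction
adds slight crosswind smearing; conduction speeds measured on refined
cables are unaffected at the stated tolerances. Stimuli follow the
septal + apical endocardial protocol (2.5-ms pulse) or, alternatively, a
rectangular basal patch raised to −10 mV as the initial condition.

## Passive and active mechanics

The myocardial strain energy combines the standard compressible
neo-Hookean matrix ½μ(I₁ − 3) − μ ln J + ½λ ln²J (μ = 0.5 MPa,
λ = 0.2 MPa as printed — see Limitations) with the HGO exponential fiber
term using isochoric invariants and dispersion κ. Fiber recruitment is
tension-only, gated on the effective fiber strain Ē ≥ 0 (equivalent to
the classic Ī₄ ≥ 1 criterion at κ = 0 and exactly direction-free at full
dispersion κ = 1/3). The matrix form with the *full* first invariant is
the only member of the printed family that leaves the reference state
stress-free, which the test suite requires; the printed isochoric
variant remains available behind an audit flag. The leaflet law is the
exponential-matrix HGO with two in-plane families (C10 = 3.47 kPa
stress-like, C01 = 30.03 exponent, k₁ = 74.5 kPa, k₂ = 63.19, κ = 0.2;
the swapped role assignment is selectable because the printed units
permit both) plus a configurable volumetric penalty ½κ_vol(J − 1)², since
the in-plane law carries no volumetric term. The second Piola–Kirchhoff
stress is evaluated analytically and verified against central finite
differences of W to 10⁻⁶ relative on random admissible deformations.

The solid solver is total-Lagrangian P1 with one-point quadrature.
Element tangents are obtained by vectorized forward differencing of the
element force (h = 10⁻⁶ mm), which at 12 extra force evaluations per
assembly is cheap and accurate enough for Newton; the factorized tangent
is reused across iterations (modified Newton) and refreshed when the
residual contraction stalls. Cavity pressure is a follower load on the
deformed endocardial facets with its own differenced load stiffness.
Convergence is declared at 10⁻⁶ relative residual; quasi-static loading
uses adaptive bisection cutback. Boundary conditions: all basal nodes
rigidly fixed; roller (in-plane) constraints on arbitrary planes are
supported through per-node basis rotation and are used by the
spherical-shell benchmark. Dynamics use implicit Newmark
(β = 0.25, γ = 0.5) with optional mass-proportional damping; density is
1.055 mg/mm³. The coupled driver runs quasi-statically — inertial terms
are negligible at the desk-scale contraction rates, and the Newmark path
is exercised by the vibration benchmarks.

Active stress follows dσ_a/dt = ε(Φ)[k(Φ − Φ_r) − σ_a] with the Gompertz
rate ε(Φ) = ε₀ + (ε₁ − ε₀) exp(−exp(−ζ(Φ − Φ_t))) (the printed
amplitude variant ε₀ + ε₁ is selectable). Defaults ε₀ = 0.005/ms,
ε₁ = 0.05/ms, ζ = 0.2/mV, Φ_t = −55 mV give a ~20 ms rise and ~200 ms
decay, so stress lags potential as required. The update is the exact
exponential integrator for frozen Φ (unconditionally stable). The scalar
is distributed as σ_a(η₁ ā⊗ā + η₂ s̄⊗s̄ + η₃ n̄⊗n̄) with η = (0.1, 0.2,
0.6); η₃ sweeps over 0.3–0.8 drive the torsion study. The gain k is in
kPa/mV; since the printed passive stiffness is very high, physiologic
ejection fractions require k of order tens (the default k = 15 kPa/mV is
the package's own coarse-model calibration to a stable mid-range run,
EF ≈ 39% on the `tiny` mesh).

## Cavity coupling and afterload

Per coupling step (default 2.5 ms; EP substeps at 0.25 ms): monodomain →
active stress → mechanics + 0D cavity. While the valve is closed the
cavity pressure is found by secant iteration so the deformed cavity
volume (divergence theorem on the displaced endocardium) stays at its
hold value; sub-iterations stop at 10⁻⁴ relative, at most 20 per step.
The valve opens when the isovolumic pressure reaches the aortic pressure
(Windkessel state, initialized at the 80-mmHg diastolic anchor) and
closes when the outflow reverses, after which the run continues
isovolumically. During ejection the scalar pressure is iterated to
satisfy P = Q R_c + P_Wk with Q = −dV/dt and the Windkessel advanced by
RK4 over the same step (120 mmHg is the systolic sanity anchor, not
enforced). The trace records volumes, pressures, flow, potential and
active-stress summaries, von Mises and principal-strain maxima, apex
trajectory, ring-averaged torsion (mean circumferential rotation of a
thin apical ring minus a basal ring, excluding nodes within 3 mm of the
axis), and the cumulative active-stress work −∫S_act : dE dV, which
bounds the stroke work from above in the energy-sanity check.

The outlet waveform export differentiates the volume trace centrally,
divides by the LVOT area, and is the 0D stand-in for the 3D outflow
velocity field that full fluid models would consume.

## Calibration utilities

`calibrate_k_for_ef` is a guarded bisection on the monotone EF(k)
response over a bounded bracket (default 5–45 kPa/mV), reporting the
achieved EF and the search history; if the target is unreachable inside
the bracket it reports the best achievable value and raises. At desk
resolution the model saturates near EF ≈ 66% before thin apex elements
invert, so clinical-table targets near 70% are generally reported as
best-achievable rather than met — a direct consequence of the printed
(very stiff) passive moduli combined with coarse meshes.
`sweep_eta3_torsion` runs the η₃ sweep and returns peak apical torsion
per value; at desk scale the peak twist is a few degrees (the trend, not
the magnitude, is the validated quantity).

## What the generator does and does not emulate

The synthetic geometry reproduces printed global dimensions (EDV, long
axis, internal diameter, thickness extremes/mean) and smooth transmural
structure. It contains no papillary muscles, trabeculae, mitral
apparatus, or segmentation-derived surface irregularity, and the
thickness map varies only circumferentially. Passing tests therefore
demonstrate correctness of the numerics and the printed-parameter
pipeline on idealized anatomy, not fidelity to any individual patient
anatomy or to imaging-derived fiber fields.

## Numerical summary (default problem sizes)

| stage | size | cost (1 CPU) |
|---|---|---|
| geometry + fibers, coarse | ~2.2k tets | < 1 s |
| single-cell calibration | adaptive ODE | < 0.1 s |
| monodomain beat, coarse, 450 ms | 579 nodes × 4500 steps | ~4 s |
| coupled systole, tiny, 420 ms | ~1.1k tets × 168 steps | ~30 s |
| verification suite | — | ~3 min |

## Known limitations

- The 0D cavity surrogate cannot produce intracavitary flow patterns,
  vortices, or valve-leaflet dynamics; only global hemodynamics (PV
  loop, EF, outflow waveform) are meaningful.
- The printed passive moduli (μ = 0.5 MPa against k₁ = 1.685 kPa) make
  the wall orders of magnitude stiffer than ex-vivo myocardium; they are
  kept as printed and the active gain carries the burden, so absolute
  stress levels should be read comparatively, not physiologically.
- Coarse meshes under near-maximal contraction can invert thin apex
  elements; the solver reports this instead of silently regularizing.
- Torsion magnitudes at desk resolution are several-fold below
  physiological twist; only the monotone η₃ trend is asserted.
- The electromechanical delay is exposed but defaults to zero (its value
  is not printed); the Purkinje system is absent and activation relies
  on the endocardial stimulus protocol.
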