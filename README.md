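# cardiomefi

Desk-scale left-ventricle electromechanics in Python: parameterized LV
geometry and fiber architecture, anisotropic monodomain electrophysiology
with mechano-electrical feedback, active-stress hyperelastic wall
mechanics, and a two-element Windkessel afterload, coupled in a staggered
systolic loop with a lumped (0D) cavity surrogate in place of 3D
intraventricular flow.

It is written for cardiovascular modellers who want a transparent,
fully-scriptable reference implementation of the standard
excitation–contraction–ejection pipeline — small enough to run on a
laptop, complete enough to study how geometry, fiber architecture and
contractility parameters shape ejection, apex motion and torsion.

## The model

**Geometry.** The ventricular wall is generated from elliptical
cross-sections stacked along the long axis (base plane at Z = 0, apex at
Z = Z_apex): the endocardium is a smooth surface through the section
ellipses closed by an ellipsoidal apex cap, the epicardium is offset by a
circumferentially varying thickness map t(θ) whose mean and extremes
match the clinical card (WTavg, WTmin, WTmax). An outer loop rescales the
endocardial semi-axes until the meshed cavity volume equals the target
EDV. Five case cards spanning concentric/eccentric remodelling patterns
are built in.

**Fibers.** A harmonic (Laplace) field with U = 0 on the epicardium and
U = 1 on the endocardium supplies the transmural direction e = −∇U/|∇U|;
the transmural coordinate is the distance ratio β = D_epi/(D_epi + D_end).
The helix angle follows the rule-based profile

    θ(β, Z) = [β θ_endo + (1 − β) θ_epi] (1 − Z/Z_apex),

with θ_epi = −60° and θ_endo = +60° at the base. Per-element orthonormal
(fiber ā, sheet s̄, sheet-normal n̄) triads are built by rotating the
circumferential axis about the transmural axis; a 1-cm-diameter cylinder
at the apex is treated as isotropic.

**Electrophysiology.** Two-variable excitable-media kinetics (potential
φ, recovery r) of the Aliev–Panfilov family,

    ∂φ/∂τ = ∇·(D∇φ) − c φ(φ−α)(φ−1) − rφ − I_stretch,
    ∂r/∂τ = [γ + μ₁ r/(μ₂ + φ)] [−r − c φ(φ − b − 1)],

with the stretch-activated (Frank–Starling-type) current
I_stretch = θ G_s (λ_f − 1)(φ − φ_s) gated by the activation window and
the potential threshold. The conductivity tensor has eigenvalues
0.6 / 0.2 / 0.1 mm²/ms along the fiber, across the fiber and through the
wall. The dimensional potential Φ = β_φ φ + δ_φ is calibrated so the cell
rest and peak land exactly on −80 and +20 mV, and dimensionless time maps
to milliseconds through a local scale β_t that depends on an apicobasal
activation-time profile.

**Mechanics.** Total-Lagrangian P1 tetrahedra with a compressible
neo-Hookean matrix plus Holzapfel–Gasser–Ogden fiber stiffening
(k₁ = 1.685 kPa, k₂ = 15.779, dispersion κ ∈ [0, 1/3]); aortic-leaflet
tissue uses an exponential matrix with two in-plane HGO families at the
material-point level. Contraction enters through the second
Piola–Kirchhoff stress as σ_a(η₁ ā⊗ā + η₂ s̄⊗s̄ + η₃ n̄⊗n̄) with
dσ_a/dt = ε(Φ)[k(Φ − Φ_r) − σ_a] and a Gompertz-sigmoid rate ε(Φ), so
active stress lags the electrical upstroke.

**Afterload.** A two-element Windkessel (C = 3.128 mL/mmHg,
R_p = 0.6652, R_c = 0.0914 mmHg·s/mL, RK4 in time) closes the loop:
while the 0D aortic valve is shut the cavity pressure is the scalar that
holds the cavity volume fixed; during ejection pressure and outflow are
made mutually consistent with P_Ao = Q R_c + P_Wk.

## Worked example

`examples/coupled_systole.py` runs one complete systole of Case 1 at the
smallest desk-scale resolution (~30 s on one CPU):

```text
EDV  118.3 mL   ESV   71.7 mL   SV  46.6 mL
ejection fraction:      39.4 %
peak cavity pressure:  124.1 mmHg
stroke work:            14160 mmHg mL
peak apical torsion:    2.60 deg
apex longitudinal path: -24.9 .. +0.1 mm
```

The ventricle fills to its end-diastolic volume, builds pressure
isovolumically until it exceeds the 80-mmHg aortic pressure, ejects
against the Windkessel up to a ~124 mmHg systolic peak, and the valve
closes when outflow reverses. EF rises monotonically with the saturated
active-stress gain `k` (see `cardiomefi.driver.calibrate_k_for_ef`), and
peak torsion rises monotonically with the sheet-normal weight `η₃`.

The other scripts in `examples/` each exercise one capability (geometry,
fibers, single-cell AP, monodomain activation, material laws, Windkessel,
aortic leaflets) and print the quantities they compute. A thin CLI wraps
the same calls: `cardiomefi geometry --case 1 --out mesh.vtu`,
`cardiomefi ep`, `cardiomefi mefi`, ….

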