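"""Stress response of the myocardial and leaflet material laws.

Both tissues combine an isotropic matrix with exponentially stiffening
collagen-fiber families (the HGO construction); the leaflet carries two
in-plane families (radial + circumferential) and an exponential matrix.
"""

import numpy as np

from cardiomefi import (LeafletMaterial, MyocardiumMaterial,
                        pk2_stress_leaflet, pk2_stress_myocardium,
                        strain_energy_myocardium)

a0 = np.array([1.0, 0.0, 0.0])
a1 = np.array([0.0, 1.0, 0.0])
myo, leaf = MyocardiumMaterial(), LeafletMaterial()

print("uniaxial fiber stretch (isochoric), myocardium:")
for lam in (1.0, 1.05, 1.10, 1.15):
    F = np.diag([lam, 1 / np.sqrt(lam), 1 / np.sqrt(lam)])
    W = strain_energy_myocardium(F, myo, [a0])
    S = pk2_stress_myocardium(F, myo, [a0])
    print(f"  stretch {lam:.2f}: W = {float(W):9.3f} kPa, "
          f"S_ff = {float(S[0, 0]):9.3f} kPa")

print("equibiaxial in-plane stretch, leaflet:")
for lam in (1.0, 1.04, 1.08):
    F = np.diag([lam, lam, 1 / lam ** 2])
    S = pk2_stress_leaflet(F, leaf, [a0, a1])
    print(f"  stretch {lam:.2f}: S_rr = {float(S[0, 0]):9.2f} kPa")
# Both laws are stress-free at the reference state and stiffen
# exponentially with stretch -- the signature J-shaped soft-tissue
# response.
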