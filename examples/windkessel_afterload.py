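"""Two-element Windkessel afterload driven by a half-sine ejection pulse.

The stored pressure obeys C dP/dt + P/Rp = Q; the aortic pressure adds
the characteristic-resistance drop Q Rc.  Printed constants:
C = 3.128 mL/mmHg, Rp = 0.6652, Rc = 0.0914 mmHg s/mL.
"""

import numpy as np

from cardiomefi import WindkesselParams, windkessel_step

params = WindkesselParams()
dt, T_ej, T_cycle = 1e-3, 0.3, 0.8
P_wk, records = 80.0, []
for i in range(int(T_cycle / dt)):
    t = i * dt
    q = lambda trel, t=t: 300.0 * max(np.sin(np.pi * (t + trel) / T_ej), 0.0) \
        if (t + trel) < T_ej else 0.0
    P_wk, P_ao = windkessel_step(P_wk, q, dt, params)
    records.append((t + dt, P_wk, P_ao))

rec = np.array(records)
print(f"peak aortic pressure:     {rec[:, 2].max():6.1f} mmHg")
print(f"end-diastolic pressure:   {rec[-1, 2]:6.1f} mmHg")
print(f"ejected volume:           {300.0 * 2 * T_ej / np.pi:6.1f} mL")
# A ~57 mL half-sine ejection raises the aortic pressure to a systolic
# peak near 110 mmHg, after which the Windkessel decays with time
# constant Rp C ~ 2.1 s toward diastole.
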