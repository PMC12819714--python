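"""Two-element Windkessel afterload with characteristic resistance, and
pressure-volume loop analytics.

The stored (Windkessel) pressure obeys C dP_Wk/dt + P_Wk/Rp = Q_Ao,
integrated with classical fourth-order Runge-Kutta; the aortic pressure
adds the characteristic-resistance drop at the same time step,
P_Ao = Q_Ao Rc + P_Wk.  Native clinical units: mmHg, mL, s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class WindkesselParams:
    C: float = 3.128        # arterial compliance, mL/mmHg
    Rp: float = 0.6652      # peripheral resistance, mmHg s/mL
    Rc: float = 0.0914      # characteristic resistance, mmHg s/mL

    def validate(self) -> None:
        if min(self.C, self.Rp, self.Rc) <= 0:
            raise ValueError("Windkessel parameters must be positive")


def windkessel_step(P_wk: float, Q_ao, dt: float,
                    params: WindkesselParams | None = None):
    """One RK4 step of the stored pressure; returns (P_wk', P_ao').

    ``Q_ao`` may be a constant (mL/s) or a callable Q(t_rel) evaluated at
    the RK4 substage offsets within the step; ``dt`` in seconds.
    """
    p = params or WindkesselParams()
    p.validate()
    if dt <= 0:
        raise ValueError("dt must be positive")
    q = Q_ao if callable(Q_ao) else (lambda _t: Q_ao)

    def f(t, y):
        return (q(t) - y / p.Rp) / p.C

    k1 = f(0.0, P_wk)
    k2 = f(dt / 2, P_wk + dt / 2 * k1)
    k3 = f(dt / 2, P_wk + dt / 2 * k2)
    k4 = f(dt, P_wk + dt * k3)
    P_new = P_wk + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
    P_ao = q(dt) * p.Rc + P_new
    return P_new, P_ao


def ejection_fraction(edv: float, sv: float) -> float:
    """EF (%) = 100 SV / EDV, reported to one decimal."""
    if edv <= 0:
        raise ValueError("EDV must be positive")
    if not 0 <= sv <= edv:
        raise ValueError("need 0 <= SV <= EDV")
    return round(100.0 * sv / edv, 1)


@dataclass
class PVLoopMetrics:
    edv: float          # mL
    esv: float          # mL
    sv: float           # mL
    ef: float           # %
    stroke_work: float  # mmHg mL


def pv_loop(volume_ml: np.ndarray, pressure_mmhg: np.ndarray) -> PVLoopMetrics:
    """Loop metrics from sampled (V, P) records of one cycle (or systolic
    segment): extrema volumes, EF, and stroke work as the loop integral
    of P dV (trapezoid; positive for the usual counterclockwise loop)."""
    V = np.asarray(volume_ml, float)
    P = np.asarray(pressure_mmhg, float)
    if V.size < 3 or V.size != P.size:
        raise ValueError("need at least 3 matched (V, P) samples")
    edv, esv = float(V.max()), float(V.min())
    sv = edv - esv
    ef = ejection_fraction(edv, sv)
    # closed-loop trapezoid integral of P dV, traversed and closed
    Vc = np.append(V, V[0])
    Pc = np.append(P, P[0])
    work = -float(np.sum(0.5 * (Pc[1:] + Pc[:-1]) * np.diff(Vc)))
    return PVLoopMetrics(edv=edv, esv=esv, sv=sv, ef=ef, stroke_work=work)
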