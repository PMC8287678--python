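"""Analytic pulsatile-flow wall shear (Womersley solution).

Evaluates the exact wall shear of laminar flow in a rigid cylinder driven by
a steady plus oscillatory pressure gradient.  The steady term is the
Poiseuille value G R / 2; each harmonic carries a Bessel-function factor that
attenuates and phase-shifts the quasi-steady response as the Womersley
number alpha grows.  This closed form is the oracle the time-integration
operators (TAWSS, OSI) are tested against.
"""

import numpy as np

from apexshear import synthetic_data as sd

blood = sd.BloodProperties()  # 1056 kg/m^3, 0.0035 Pa s
radius = 1.5e-3  # m, middle-cerebral-artery scale
period = 0.9  # s

alpha = radius * np.sqrt(2 * np.pi / period * blood.density / blood.viscosity)
print(f"Womersley number alpha = {alpha:.2f} at R = {radius * 1e3:.1f} mm, T = {period} s")

times = np.linspace(0.0, period, 9)
steady = sd.womersley_wall_shear(radius, blood, [(1000.0, 0.0)], period, times)
print(f"steady gradient 1000 Pa/m -> wall shear {steady[0]:.4f} Pa "
      f"(Poiseuille G R / 2 = {1000.0 * radius / 2:.4f} Pa)")

pulsatile = sd.womersley_wall_shear(
    radius, blood, [(1000.0, 0.0), (800.0, 0.0)], period, times)
quasi_steady = 1000.0 * radius / 2 + 800.0 * radius / 2 * np.cos(2 * np.pi * times / period)
print("\n  t (s)   tau exact (Pa)   quasi-steady (Pa)")
for t, te, tq in zip(times, pulsatile, quasi_steady):
    print(f"  {t:5.3f}   {te:12.4f}    {tq:12.4f}")
print("\nthe gap between the columns is the inertial (finite-alpha) attenuation "
      "and phase lag of the oscillatory component")
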