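"""Locate the liquid-vapor critical point from coexistence densities.

Builds a synthetic coexistence table from the combined
law-of-rectilinear-diameters + three-term Wegner expansion (exponents
beta = 0.325, Delta = 0.50), adds 1% density noise, and refits the five
free parameters (T_c, rho_c, B_0, B_1, C_2) by nonlinear least squares.
"""

import numpy as np

from triwater import critical_point_fit, gen_coexistence_table

true = dict(T_c=630.0, rho_c=0.327, B_0=0.9, B_1=0.2, C_2=0.25)
temperatures = np.arange(350.0, 621.0, 10.0)

table = gen_coexistence_table(temperatures=temperatures, noise=0.01, seed=4, **true)
fit = critical_point_fit(table)

print("parameter   fitted     true")
print(f"T_c      {fit.T_c:9.2f} {true['T_c']:8.1f}  K")
print(f"rho_c    {fit.rho_c:9.4f} {true['rho_c']:8.3f}  g/cm^3")
print(f"B_0      {fit.B_0:9.3f} {true['B_0']:8.3f}")
print(f"B_1      {fit.B_1:9.3f} {true['B_1']:8.3f}")
print(f"C_2      {fit.C_2:9.3f} {true['C_2']:8.3f}")
print(f"residual {fit.residual:9.2e}")
print(
    "\nWith 1% density noise the fitted T_c typically lands within a few"
    "\nkelvin of the truth, matching the +-4 K scale quoted for this kind"
    "\nof coexistence analysis."
)
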