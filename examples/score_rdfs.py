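"""Score a candidate water model against reference structure + observables.

Generates target RDFs, density and dielectric constant for OPC3 from the
analytic surrogate at 280/298/343 K, then scores SPC against them with
the composite squared-cost transport + relative-error metric
(weights 0.5 / 0.3 / 0.2).  A smaller total is a better model; 0 means a
perfect match of every target.
"""

from triwater import preset, score_multi, surrogate_state_point

temperatures = (280.0, 298.0, 343.0)
target = [surrogate_state_point(preset("OPC3"), t) for t in temperatures]
candidate = [surrogate_state_point(preset("SPC"), t) for t in temperatures]

breakdown = score_multi(candidate, target)
print("SPC scored against OPC3-derived targets")
print(f"  RDF transport term   {breakdown.emd_term:.4f}  (weight 0.5)")
print(f"  density term         {breakdown.rho_term:.4f}  (weight 0.3)")
print(f"  dielectric term      {breakdown.eps_term:.4f}  (weight 0.2)")
print(f"  total score          {breakdown.total:.4f}")
print()
for (t, pair), v in sorted(breakdown.emd_by_pair_and_T.items()):
    print(f"  normalized EMD g_{pair} @ {t:g} K: {v:.4f}")
print(
    "\nThe dielectric term dominates: eps is quadratic in the molecular"
    "\ndipole, and SPC's 2.27 D sits well below OPC3's 2.43 D."
)
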