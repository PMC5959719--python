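"""Acid-quench / NH4Cl assay: surface vs internal probe pools.

Simulates a bouton whose probe is 60% on the plasma membrane and partitions
the fluorescence into surface (rest - acid) and internal (NH4Cl - rest)
pools.
"""

from svtrace import generate_pool_trace, surface_internal_ratio

trace, epochs = generate_pool_trace(surface_fraction=0.6, seed=0)
meas = surface_internal_ratio(trace, epochs)

print(f"epoch means: rest {meas.f_rest:.1f}, acid {meas.f_acid:.1f}, NH4Cl {meas.f_nh4:.1f} a.u.")
print(f"surface pool {meas.surface:.1f} a.u., internal pool {meas.internal:.1f} a.u.")
print(f"fractions: surface {meas.surface_fraction:.3f}, internal {meas.internal_fraction:.3f}")
# a V0a1-like probe: ~60% surface, ~40% internal
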