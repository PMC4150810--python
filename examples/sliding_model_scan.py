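"""The sliding (non-specific binding) mechanism cannot ratchet the TF off.

For one (K, k1) condition: fit the free dissociation rate on naked DNA,
then couple the sliding lattice to a synthetic 35-kBT unwrapping landscape
and maximize the off-rate over the steric clearance d.  Even at the
maximizing clearance the fold change stays below one order of magnitude
(here it is actually below one: the nucleosome suppresses the occupancy of
the fast-dissociating non-specific positions) -- the model's negative
result.  The full 35-condition scan is ``nucoff.scan_nonspecific`` with the
default grids.
"""

import nucoff as nc

K, k1 = 1000.0, 1e5  # specificity ratio and sliding step rate (1/s)
ks_off = nc.fit_ks_off(K, k1, target_off=0.0034)
print(f"fitted specific-site dissociation rate ks_off = {ks_off:.4g} 1/s")
print(f"(non-specific dissociation = K * ks_off = {K * ks_off:.4g} 1/s)")

landscape = nc.synthetic_landscape(147, 35.0)  # linear stand-in, kBT
best = None
for d in range(0, 22):
    spec = nc.LatticeSpec(K=K, k1=k1, ks_off=ks_off, d=d)
    off = nc.lattice_off_rate(spec, landscape)
    if best is None or off > best[1]:
        best = (d, off)
d_best, off = best
print(f"\nmax over clearance d: d = {d_best}, off-rate = {off:.4g} 1/s")
print(f"fold change vs naked DNA = {off / 0.0034:.2f} (< 10: no large ratchet)")
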