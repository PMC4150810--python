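"""Unwrapping free-energy landscapes and the rates derived from them.

The landscape dG(n) (kBT per n base pairs unwrapped) sets single-bp
unwrap/rewrap rates by local detailed balance, and coarse-grained rates
k5-k8 for the dimeric model by lumping the steps between three wrap extents.
"""

import nucoff as nc

landscape = nc.synthetic_landscape(n_max=147, total_dG=35.0, shape="linear")
print(f"linear landscape: dG(147) = {landscape.dG[147]:.1f} kBT "
      f"({landscape.dG[1]:.3f} kBT per bp)")

ku, kr = nc.step_rates(landscape, 1)
print(f"single-bp step: k_unwrap = {ku:.4g} 1/s, k_rewrap = {kr:.4g} 1/s")

w = nc.coarse_rates_from_landscape(landscape, n_full=34, n_part=19)
print(f"\ncoarse rates between wrap extents n_full=34, n_part=19, n_wrap=0:")
print(f"  ddG = dG(34) - dG(19) = {w.ddg:.3g} kBT")
for name, meaning in [
    ("k5", "rewrap n_full -> n_part"),
    ("k6", "unwrap n_part -> n_full"),
    ("k7", "rewrap n_part -> fully wrapped"),
    ("k8", "unwrap fully wrapped -> n_part"),
]:
    print(f"  {name} = {getattr(w, name):10.4g} 1/s  ({meaning})")
print("k6/k5 equals exp(-ddG): detailed balance at the coarse level.")
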