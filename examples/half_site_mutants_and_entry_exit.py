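"""Predictions: half-site mutants and a site straddling the entry-exit end.

Mutating either half of the binding site removes the dimeric ratchet: the
reduced 3-state model releases at ~k3 (the single-monomer release rate)
regardless of which half is mutated and almost independently of the
unwrapping free energy.  A site half outside the positioning sequence is an
intermediate case whose off-rate depends on the full landscape.
"""

import numpy as np

import nucoff as nc
from nucoff.landscape import FreeEnergyLandscape

params = nc.fit_naked_dimeric()

for variant in ("near_dyad_mutated", "far_mutated", "naked_half_site"):
    off = nc.mutant_half_site_off_rate(params, variant, ddg=6.0)
    print(f"{variant:18s}: off-rate = {off:.4g} 1/s "
          f"({off / 0.0034:.0f}-fold vs intact naked site)")
print(f"single-monomer release rate k3 = {params.k3:.4g} 1/s")

# entry-exit site: outer half always bindable, inner half needs 10 bp of
# unwrapping; here a synthetic landscape costing 6 kBT over those 10 bp
landscape = FreeEnergyLandscape(np.arange(31) * 0.6)
off = nc.entry_exit_off_rate(params, landscape,
                             outside_span=(-10, -1), inside_span=(1, 10))
print(f"\nentry-exit site off-rate = {off:.4g} 1/s "
      f"({off / 0.0034:.0f}-fold; landscape-dependent)")
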