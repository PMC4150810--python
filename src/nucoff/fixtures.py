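"""Bundled plain-text test/demo inputs, regenerated deterministically.

Everything is written by code at run time (no data files ship with the
package): synthetic landscapes at the realistic 30-40 kBT overall scale, toy
generators with known decay rates, and a tiny joint sliding-lattice instance
together with the decay rate of its densely eigensolved generator.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .dimeric import build_naked_generator, fit_naked_dimeric
from .landscape import synthetic_landscape, write_landscape
from .markov import Generator, generator_to_tsv, slowest_decay_rate
from .nonspecific import LatticeSpec, build_nucleosome_lattice

__all__ = ["make_fixtures", "TINY_LATTICE"]

#: geometry of the tiny joint-lattice instance (small enough to enumerate by
#: hand and to eigensolve densely)
TINY_LATTICE = dict(
    K=100.0, k1=1000.0, ks_off=0.05, L=16, site_start=9, site_end=12,
    footprint=4, d=1, conc=0.0, n_max=10, total_dG=3.0, k0=500.0,
)


def make_fixtures(outdir, seed: int = 0) -> dict[str, str]:
    """Write the fixture set into ``outdir``; idempotent for a fixed seed.

    Returns a mapping of fixture name to file path.  ``seed`` is recorded in
    the manifest; the fixtures themselves are deterministic.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, str] = {}

    for total in (30, 35, 40):
        path = outdir / f"landscape_linear_{total}.tsv"
        write_landscape(synthetic_landscape(147, float(total), "linear"), path)
        written[f"landscape_linear_{total}"] = str(path)
    path = outdir / "landscape_dyad_barrier.tsv"
    write_landscape(
        synthetic_landscape(147, 35.0, "linear_with_dyad_barrier", barrier_height=5.0),
        path,
    )
    written["landscape_dyad_barrier"] = str(path)

    # toy generators with known slowest decay rates
    two_state = Generator(
        ("bound", "free"), np.array([[-0.5, 0.0], [0.5, 0.0]]),
        absorbing=frozenset({"free"}),
    )
    path = outdir / "generator_two_state.tsv"
    generator_to_tsv(two_state, path)
    written["generator_two_state"] = str(path)

    chain = Generator(
        ("a", "b", "c"),
        np.array([[-1.0, 0.2, 0.0], [1.0, -1.2, 0.0], [0.0, 1.0, 0.0]]),
        absorbing=frozenset({"c"}),
    )
    path = outdir / "generator_three_state_chain.tsv"
    generator_to_tsv(chain, path)
    written["generator_three_state_chain"] = str(path)

    naked = build_naked_generator(fit_naked_dimeric(), conc=0.0)
    path = outdir / "generator_naked_dimeric.tsv"
    generator_to_tsv(naked, path)
    written["generator_naked_dimeric"] = str(path)

    # tiny joint-lattice instance with its dense-oracle decay value
    t = TINY_LATTICE
    spec = LatticeSpec(
        K=t["K"], k1=t["k1"], ks_off=t["ks_off"], L=t["L"],
        site_start=t["site_start"], site_end=t["site_end"],
        footprint=t["footprint"], d=t["d"], conc=t["conc"],
    )
    lmb = synthetic_landscape(t["n_max"], t["total_dG"], "linear")
    gen = build_nucleosome_lattice(spec, lmb, k0=t["k0"], truncation_margin=None)
    decay = slowest_decay_rate(
        Generator(gen.labels, gen.as_dense(), gen.absorbing), method="dense"
    ).off_rate
    manifest = dict(TINY_LATTICE)
    manifest["dense_oracle_decay_per_s"] = decay
    manifest["n_states"] = gen.n_states
    manifest["seed"] = seed
    path = outdir / "tiny_lattice.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    written["tiny_lattice"] = str(path)
    return written
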