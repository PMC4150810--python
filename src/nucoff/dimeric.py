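"""Dimeric transcription-factor binding: naked DNA and nucleosome models.

A homodimeric TF such as LexA binds two adjacent half-sites.  On naked DNA
the model has four states (both halves bound, either single half bound, and
unbound) with rates

* ``k1`` - a singly-bound monomer rebinds its free half-site,
* ``k2`` - the fully bound dimer releases one half-site,
* ``k3`` - a singly-bound TF releases its last half-site,
* ``k4`` - association of a free TF to one half-site (per unit concentration).

The overall off-rate (slowest nonzero decay eigenvalue of the generator with
association zeroed) has the closed form

    1/2 * [(k1 + 2 k2 + k3) - sqrt((k1 + 2 k2 + k3)^2 - 8 k2 k3)]

which, together with the measured half-site affinity penalty
(``k1/k2 = 1000``), the monomer-symmetry assumption ``k2 = k3`` and the
overall dissociation constant, pins down all four rates from the single
measured naked-DNA off-rate.

Next to a nucleosome the same TF rates combine with the coarse-grained
wrap/unwrap rates k5-k8 of :class:`nucoff.landscape.WrapRates` into a
seven-state model: when the dyad-proximal half-site releases, the nucleosome
can rewrap onto it and block rebinding, ratcheting the TF off.  The detected
off state (TF free, nucleosome fully wrapped) is made absorbing by zeroing
``k8``; the naked off state likewise by zeroing ``k4``.  The one parameter
the nucleosomal off-rate is sensitive to is the unwrapping free-energy
difference ddG between the full-site- and half-site-exposing extents.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .landscape import (
    DEFAULT_K0,
    FreeEnergyLandscape,
    WrapRates,
    coarse_rates,
    step_rates,
)
from .markov import Generator, OffRateResult, slowest_decay_rate

__all__ = [
    "NAKED_STATES",
    "NUCLEOSOME_STATES",
    "MUTANT_VARIANTS",
    "DimericParams",
    "NucleosomeOffRate",
    "closed_form_naked_off_rate",
    "fit_naked_dimeric",
    "build_naked_generator",
    "build_nucleosome_generator",
    "nucleosome_off_rate",
    "ddg_scan",
    "mutant_half_site_off_rate",
    "entry_exit_off_rate",
]

#: naked-DNA states: dimer fully bound, one half bound (two symmetric
#: flavours), unbound
NAKED_STATES = ("full", "half_a", "half_b", "free")

#: nucleosome states in the fixed model order (roman numerals I..VII of the
#: kinetic scheme): TF fully bound / bound to the dyad-distal half / bound to
#: the dyad-proximal half / free, all at full-site unwrapping n_full; then TF
#: on the distal half / TF free at half-site unwrapping n_part; then TF free
#: with the nucleosome fully wrapped (the detected high-FRET off state)
NUCLEOSOME_STATES = (
    "full@n_full",
    "distal_half@n_full",
    "proximal_half@n_full",
    "free@n_full",
    "distal_half@n_part",
    "free@n_part",
    "free@wrapped",
)

MUTANT_VARIANTS = ("near_dyad_mutated", "far_mutated", "naked_half_site")


@dataclass(frozen=True)
class DimericParams:
    """Fitted rate set of the dimeric model.

    ``ratio = k1/k2`` is the half-site affinity penalty and ``kd_full`` the
    overall dissociation constant (nM) the association rate was inferred
    from; ``k4_per_conc`` has units 1/(s nM).
    """

    k1: float
    k2: float
    k3: float
    k4_per_conc: float
    ratio: float
    kd_full: float

    def __post_init__(self):
        for name in ("k1", "k2", "k3", "k4_per_conc"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def naked_off_rate(self) -> float:
        """Overall off-rate from naked DNA implied by k1..k3."""
        return closed_form_naked_off_rate(self.k1, self.k2, self.k3)


@dataclass(frozen=True)
class NucleosomeOffRate:
    off_rate: float
    fold_change: float
    result: OffRateResult


def closed_form_naked_off_rate(k1: float, k2: float, k3: float) -> float:
    """Closed-form slowest decay rate of the 4-state naked model (k4 = 0)."""
    if min(k1, k2, k3) < 0:
        raise ValueError("rates must be non-negative")
    s = k1 + 2.0 * k2 + k3
    if s == 0.0:
        return 0.0
    disc = s * s - 8.0 * k2 * k3
    # algebraically (s - sqrt(disc))/2; the rationalized form avoids the
    # cancellation when 8*k2*k3 << s^2 (k1 dominating, the common regime)
    return 4.0 * k2 * k3 / (s + np.sqrt(disc))


def fit_naked_dimeric(
    target_off: float = 0.0034,
    ratio: float = 1000.0,
    kd_full: float = 0.07,
) -> DimericParams:
    """Fit k1..k4 from the measured naked-DNA off-rate.

    Solves ``closed_form(ratio*k, k, k) = target_off`` for ``k`` by monotone
    bracketing on k in [1e-8, 1e8] 1/s (the closed form is homogeneous of
    degree one in the rates, hence strictly increasing in k at fixed ratio),
    then sets ``k4_per_conc = k2*k3 / (k1 * kd_full)`` so the four-state
    equilibrium reproduces ``kd_full``.
    """
    if target_off <= 0:
        raise ValueError("target_off must be positive")
    if ratio <= 0 or kd_full <= 0:
        raise ValueError("ratio and kd_full must be positive")

    def resid(log_k: float) -> float:
        k = 10.0**log_k
        return closed_form_naked_off_rate(ratio * k, k, k) - target_off

    lo, hi = -8.0, 8.0
    if resid(lo) > 0 or resid(hi) < 0:
        raise ValueError(
            f"no root for target_off={target_off:g} with ratio={ratio:g} "
            "in k = 1e-8..1e8 1/s"
        )
    log_k = brentq(resid, lo, hi, rtol=1e-15, xtol=1e-300)
    k = 10.0**log_k
    k4 = k * k / (ratio * k * kd_full)
    return DimericParams(
        k1=ratio * k, k2=k, k3=k, k4_per_conc=k4, ratio=ratio, kd_full=kd_full
    )


def build_naked_generator(params: DimericParams, conc: float = 0.0) -> Generator:
    """The printed 4-state naked-DNA rate matrix at TF concentration ``conc``.

    ``conc = 0`` zeroes the association rate k4, which makes the unbound
    state absorbing (the off state of the dissociation experiment).
    """
    if conc < 0:
        raise ValueError("conc must be non-negative")
    k1, k2, k3 = params.k1, params.k2, params.k3
    k4 = params.k4_per_conc * conc
    R = np.array(
        [
            [-2 * k2, k1, k1, 0.0],
            [k2, -(k1 + k3), 0.0, k4],
            [k2, 0.0, -(k1 + k3), k4],
            [0.0, k3, k3, -2 * k4],
        ]
    )
    absorbing = frozenset({"free"}) if k4 == 0 else frozenset()
    return Generator(NAKED_STATES, R, absorbing=absorbing)


def build_nucleosome_generator(
    params: DimericParams,
    wrap: WrapRates,
    conc: float = 0.0,
    absorbing: bool = True,
) -> Generator:
    """The 7-state nucleosome rate matrix.

    With ``absorbing=True`` the rate ``k8`` (unwrapping out of the fully
    wrapped, TF-free state) is zeroed so that the detected high-FRET off
    state is the steady state; no other rate is touched.
    """
    if conc < 0:
        raise ValueError("conc must be non-negative")
    k1, k2, k3 = params.k1, params.k2, params.k3
    k4 = params.k4_per_conc * conc
    k5, k6, k7 = wrap.k5, wrap.k6, wrap.k7
    k8 = 0.0 if absorbing else wrap.k8
    R = np.array(
        [
            [-2 * k2, k1, k1, 0.0, 0.0, 0.0, 0.0],
            [k2, -(k1 + k3 + k5), 0.0, k4, k6, 0.0, 0.0],
            [k2, 0.0, -(k1 + k3), k4, 0.0, 0.0, 0.0],
            [0.0, k3, k3, -(2 * k4 + k5), 0.0, k6, 0.0],
            [0.0, k5, 0.0, 0.0, -(k3 + k6), k4, 0.0],
            [0.0, 0.0, 0.0, k5, k3, -(k4 + k6 + k7), k8],
            [0.0, 0.0, 0.0, 0.0, 0.0, k7, -k8],
        ]
    )
    absorbing_set = frozenset({"free@wrapped"}) if absorbing else frozenset()
    return Generator(NUCLEOSOME_STATES, R, absorbing=absorbing_set)


def nucleosome_off_rate(
    params: DimericParams,
    ddg: float,
    n_full: int = 34,
    n_part: int = 19,
    conc: float = 0.0,
    k0: float = DEFAULT_K0,
) -> NucleosomeOffRate:
    """Overall off-rate from the nucleosome at free-energy penalty ``ddg``.

    Builds the coarse wrap rates directly from ``ddg`` (landscape-free scan
    mode), makes the fully wrapped TF-free state absorbing, and reports the
    slowest decay together with its fold change over the naked-DNA off-rate
    implied by the fitted parameters.
    """
    wrap = coarse_rates(ddg, n_full=n_full, n_part=n_part, k0=k0)
    gen = build_nucleosome_generator(params, wrap, conc=conc, absorbing=True)
    res = slowest_decay_rate(gen)
    naked = params.naked_off_rate
    return NucleosomeOffRate(
        off_rate=res.off_rate, fold_change=res.off_rate / naked, result=res
    )


def ddg_scan(
    params: DimericParams,
    ddg_values=None,
    n_full: int = 34,
    n_part: int = 19,
    conc: float = 0.0,
    k0: float = DEFAULT_K0,
) -> pd.DataFrame:
    """Off-rate versus ddG; defaults to the 5..7 kBT range in 0.25 steps."""
    if ddg_values is None:
        ddg_values = np.arange(5.0, 7.0 + 1e-9, 0.25)
    rows = []
    for ddg in np.asarray(ddg_values, float):
        r = nucleosome_off_rate(
            params, ddg, n_full=n_full, n_part=n_part, conc=conc, k0=k0
        )
        rows.append((ddg, r.off_rate, r.fold_change))
    return pd.DataFrame(rows, columns=["ddg_kBT", "off_rate_s", "fold_change"])


def mutant_half_site_off_rate(
    params: DimericParams,
    variant: str,
    ddg: float = 6.0,
    n_full: int = 34,
    n_part: int = 19,
    conc: float = 0.0,
    k0: float = DEFAULT_K0,
) -> float:
    """Off-rate with one half-site mutated away (single-monomer binding).

    With only one intact half-site the seven states reduce to three: TF
    bound to the intact half (at the unwrapping extent that exposes it), TF
    free with the nucleosome still at that extent, and the fully rewrapped
    TF-free off state (absorbing).  ``variant``:

    * ``"near_dyad_mutated"`` - the intact half is the dyad-distal one,
      exposed already at ``n_part``; the rewrap step past the site is k7.
    * ``"far_mutated"`` - the intact half is the dyad-proximal one, exposed
      only at ``n_full``; the rewrap step past the site is k5.
    * ``"naked_half_site"`` - no nucleosome: a bound/unbound two-state
      model whose decay is exactly k3.
    """
    if variant not in MUTANT_VARIANTS:
        raise ValueError(f"variant must be one of {MUTANT_VARIANTS}")
    k3 = params.k3
    k4 = params.k4_per_conc * conc
    if variant == "naked_half_site":
        R = np.array([[-k3, k4], [k3, -k4]])
        gen = Generator(("bound", "free"), R)
        return slowest_decay_rate(gen).off_rate
    wrap = coarse_rates(ddg, n_full=n_full, n_part=n_part, k0=k0)
    rewrap = wrap.k7 if variant == "near_dyad_mutated" else wrap.k5
    # bound -> free (k3), free -> bound (k4*conc), free -> rewrapped past the
    # site (absorbing; the reverse unwrap is zeroed as the off state)
    R = np.array(
        [
            [-k3, k4, 0.0],
            [k3, -(k4 + rewrap), 0.0],
            [0.0, rewrap, 0.0],
        ]
    )
    gen = Generator(
        ("bound", "free_unwrapped", "free_wrapped"),
        R,
        absorbing=frozenset({"free_wrapped"}),
    )
    return slowest_decay_rate(gen).off_rate


def entry_exit_off_rate(
    params: DimericParams,
    landscape: FreeEnergyLandscape,
    outside_span: tuple[int, int] = (-10, -1),
    inside_span: tuple[int, int] = (1, 10),
    conc: float = 0.0,
    k0: float = DEFAULT_K0,
) -> float:
    """Off-rate for a binding site straddling the entry-exit boundary.

    One half-site (``outside_span``, negative coordinates) lies outside the
    positioning sequence and is always bindable; the other (``inside_span``)
    lies just inside and is exposed once ``n_in = inside_span[1]`` base pairs
    are unwrapped.  The wrap coordinate moves base pair by base pair on the
    supplied landscape while the TF is bound only to the outer half or fully
    unbound; rewrapping below ``n_in`` is sterically blocked while the inner
    half is occupied.  The off state (TF free, nucleosome fully wrapped) is
    absorbing.  The result depends on the full landscape between 0 and
    ``n_in``, not on a single free-energy difference.
    """
    if outside_span[1] >= 1 or outside_span[0] > outside_span[1]:
        raise ValueError("outside_span must lie before the positioning sequence")
    if inside_span[0] < 1 or inside_span[0] > inside_span[1]:
        raise ValueError("inside_span must lie within the positioning sequence")
    n_in = inside_span[1]
    if n_in > landscape.n_max:
        raise ValueError(f"inside_span needs n_max >= {n_in}")
    if conc < 0:
        raise ValueError("conc must be non-negative")
    k1, k2, k3 = params.k1, params.k2, params.k3
    k4 = params.k4_per_conc * conc
    n_top = landscape.n_max

    labels = (
        ["full", "inner_only"]
        + [f"outer_only@{n}" for n in range(n_top + 1)]
        + [f"free@{n}" for n in range(n_top + 1)]
    )
    idx = {lab: i for i, lab in enumerate(labels)}
    N = len(labels)
    R = np.zeros((N, N))

    def add(dst: str, src: str, rate: float) -> None:
        i, j = idx[dst], idx[src]
        R[i, j] += rate
        R[j, j] -= rate

    ns = np.arange(1, n_top + 1)
    k_un, k_re = step_rates(landscape, ns, k0=k0)
    # full dimer: both halves bound, wrap pinned at n_in
    add(f"outer_only@{n_in}", "full", k2)  # inner half releases
    add("inner_only", "full", k2)  # outer half releases
    add("full", "inner_only", k1)  # outer half is always available
    add(f"free@{n_in}", "inner_only", k3)
    add(f"full", f"outer_only@{n_in}", k1)  # inner half exposed: rebind
    for n in range(n_top + 1):
        add(f"free@{n}", f"outer_only@{n}", k3)
        # free@0 is the absorbing off state: no association out of it
        if k4 > 0 and n > 0:
            add(f"outer_only@{n}", f"free@{n}", k4)
    if k4 > 0:
        add("inner_only", f"free@{n_in}", k4)
    # base-by-base wrap dynamics; the unwrap step out of free@0 is zeroed
    # (absorbing), and rewrap is never blocked while only the outer half
    # (outside the positioning sequence) is occupied
    for n in range(1, n_top + 1):
        add(f"outer_only@{n}", f"outer_only@{n-1}", k_un[n - 1])
        add(f"outer_only@{n-1}", f"outer_only@{n}", k0)
        if n > 1:
            add(f"free@{n}", f"free@{n-1}", k_un[n - 1])
        add(f"free@{n-1}", f"free@{n}", k0)
    gen = Generator(tuple(labels), R, absorbing=frozenset({"free@0"}))
    return slowest_decay_rate(gen).off_rate
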