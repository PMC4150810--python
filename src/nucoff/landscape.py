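"""Nucleosome unwrapping free-energy landscape and wrap/unwrap rates.

Nucleosomal DNA unwraps and rewraps base pair by base pair from the
entry-exit ends.  The landscape ``dG(n)`` gives the Gibbs free energy (in
units of kBT; kBT == 1 throughout the package) of having ``n`` base pairs
unwrapped, anchored at ``dG(0) = 0`` for the fully wrapped nucleosome.
Single-base-pair kinetics follow a local-detailed-balance rule: rewrapping
occurs at a base rate ``k0`` (default 1e5 1/s) and unwrapping at ``k0``
times the Boltzmann factor of the free-energy step.

The published landscape of the strong 601 positioning sequence is not
bundled; :func:`synthetic_landscape` generates stand-ins with the realistic
overall scale of 30-40 kBT across 147 bp, optionally with a barrier near the
dyad.

For the coarse-grained dimeric model, unwrapping is tracked at three extents
only (fully wrapped ``n_wrap``, half-site exposing ``n_part``, full-site
exposing ``n_full``) and the base-pair steps are lumped into the four rates
k5-k8 of :class:`WrapRates`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DEFAULT_K0",
    "FreeEnergyLandscape",
    "WrapRates",
    "LandscapeParseError",
    "load_landscape",
    "write_landscape",
    "synthetic_landscape",
    "step_rates",
    "coarse_rates",
    "coarse_rates_from_landscape",
]

#: base rate of single-bp wrapping fluctuations (1/s)
DEFAULT_K0 = 1e5


class LandscapeParseError(ValueError):
    pass


@dataclass(frozen=True)
class FreeEnergyLandscape:
    """dG(n) in kBT for n = 0 .. n_max base pairs unwrapped; dG(0) = 0."""

    dG: np.ndarray

    def __post_init__(self):
        dG = np.asarray(self.dG, float)
        if dG.ndim != 1 or len(dG) < 2:
            raise ValueError("landscape needs dG values for n = 0 .. n_max, n_max >= 1")
        if not np.all(np.isfinite(dG)):
            raise ValueError("landscape contains non-finite free energies")
        if dG[0] != 0.0:
            raise ValueError("landscape must be anchored at dG(0) = 0")
        object.__setattr__(self, "dG", dG)

    @property
    def n_max(self) -> int:
        """Total wrappable base pairs."""
        return len(self.dG) - 1

    def __len__(self) -> int:
        return len(self.dG)


def load_landscape(path) -> FreeEnergyLandscape:
    """Read a two-column (n, dG in kBT) whitespace-delimited table.

    ``n`` must be contiguous integers starting at 0; the free energies are
    re-anchored so that dG(0) = 0, so pre-shifted tables load identically.
    Lines starting with ``#`` are ignored.
    """
    ns: list[int] = []
    gs: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text or text.startswith("#"):
                continue
            parts = text.split()
            if len(parts) != 2:
                raise LandscapeParseError(
                    f"{path}:{lineno}: expected two columns, got {len(parts)}"
                )
            try:
                n = int(parts[0])
                g = float(parts[1])
            except ValueError:
                raise LandscapeParseError(
                    f"{path}:{lineno}: non-numeric row {text!r}"
                ) from None
            ns.append(n)
            gs.append(g)
    if not ns:
        raise LandscapeParseError(f"{path}: no data rows")
    expected = list(range(len(ns)))
    if ns != expected:
        missing = sorted(set(expected) - set(ns))
        detail = f"missing n = {missing}" if missing else f"got n sequence {ns[:5]}..."
        raise LandscapeParseError(
            f"{path}: n must be contiguous from 0; {detail}"
        )
    dG = np.asarray(gs, float)
    return FreeEnergyLandscape(dG - dG[0])


def write_landscape(landscape: FreeEnergyLandscape, path) -> None:
    with open(path, "w") as fh:
        fh.write("# n_unwrapped_bp\tdG_kBT\n")
        for n, g in enumerate(landscape.dG):
            fh.write(f"{n}\t{g:.17g}\n")


def synthetic_landscape(
    n_max: int = 147,
    total_dG: float = 35.0,
    shape: str = "linear",
    barrier_height: float = 5.0,
    barrier_center: float | None = None,
    barrier_width: float = 8.0,
) -> FreeEnergyLandscape:
    """Deterministic stand-in landscape.

    ``shape="linear"`` gives dG(n) = n * total_dG / n_max, the constant-slope
    idealization of a positioning sequence with an overall unwrapping free
    energy of ``total_dG`` (30-40 kBT is the realistic range for strong
    positioning sequences over 147 bp).  ``shape="linear_with_dyad_barrier"``
    adds a Gaussian bump (default centered at the dyad) to mimic locally
    strong histone-DNA contacts.
    """
    if n_max <= 0:
        raise ValueError("n_max must be positive")
    if total_dG <= 0:
        raise ValueError("total_dG must be positive")
    n = np.arange(n_max + 1, dtype=float)
    dG = n * total_dG / n_max
    if shape == "linear":
        pass
    elif shape == "linear_with_dyad_barrier":
        center = n_max / 2 if barrier_center is None else float(barrier_center)
        dG = dG + barrier_height * np.exp(-((n - center) ** 2) / (2 * barrier_width**2))
        dG = dG - dG[0]
    else:
        raise ValueError(f"unknown landscape shape {shape!r}")
    return FreeEnergyLandscape(dG)


def step_rates(
    landscape: FreeEnergyLandscape, n, k0: float = DEFAULT_K0
):
    """Single-bp unwrap/rewrap rates for the step (n-1) -> n.

    ``k_unwrap = k0 * exp(-(dG(n) - dG(n-1)))`` and ``k_rewrap = k0``; the
    ratio obeys detailed balance with respect to the landscape.  ``n`` may be
    a scalar or an integer array with 1 <= n <= n_max.
    """
    n_arr = np.asarray(n)
    if not np.issubdtype(n_arr.dtype, np.integer):
        raise ValueError("n must be integer base-pair indices")
    if np.any(n_arr < 1) or np.any(n_arr > landscape.n_max):
        raise ValueError(
            f"n must be in 1..{landscape.n_max}, got {n_arr[(n_arr < 1) | (n_arr > landscape.n_max)]}"
        )
    step = landscape.dG[n_arr] - landscape.dG[n_arr - 1]
    k_unwrap = k0 * np.exp(-step)
    k_rewrap = np.broadcast_to(np.asarray(k0, float), k_unwrap.shape)
    if np.isscalar(n):
        return float(k_unwrap), float(k0)
    return k_unwrap, k_rewrap.copy()


@dataclass(frozen=True)
class WrapRates:
    """Coarse-grained nucleosome wrap/unwrap rates for the dimeric model.

    ``k5`` rewraps from the full-site-exposing extent ``n_full`` to the
    half-site-exposing extent ``n_part`` (``k5 = k0 / (n_full - n_part)``:
    the event lumps that many sequential single-bp steps), ``k6`` is the
    reverse unwrapping (``k5 * exp(-ddg)`` with ``ddg = dG(n_full) -
    dG(n_part)``, the one parameter the dimeric off-rate is sensitive to),
    and ``k7``/``k8`` likewise connect ``n_part`` with the fully wrapped
    extent ``n_wrap``.
    """

    k5: float
    k6: float
    k7: float
    k8: float
    n_full: int
    n_part: int
    n_wrap: int
    ddg: float
    k0: float = DEFAULT_K0

    def __post_init__(self):
        if not (self.n_full > self.n_part > self.n_wrap >= 0):
            raise ValueError(
                f"need n_full > n_part > n_wrap >= 0, got "
                f"({self.n_full}, {self.n_part}, {self.n_wrap})"
            )
        for name in ("k5", "k6", "k7", "k8"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def coarse_rates(
    ddg: float,
    n_full: int = 34,
    n_part: int = 19,
    n_wrap: int = 0,
    k0: float = DEFAULT_K0,
    dg_part_wrap: float = 0.0,
) -> WrapRates:
    """Build :class:`WrapRates` directly from the free-energy difference.

    ``ddg`` (kBT) is dG(n_full) - dG(n_part).  ``dg_part_wrap`` is
    dG(n_part) - dG(n_wrap); it only enters ``k8``, which is zeroed anyway
    whenever the fully wrapped, TF-free state is the detected off state, so
    its default of 0 is inconsequential for off-rate calculations.
    """
    if not np.isfinite(ddg):
        raise ValueError("ddg must be finite")
    if not (n_full > n_part > n_wrap >= 0):
        raise ValueError(
            f"need n_full > n_part > n_wrap >= 0, got ({n_full}, {n_part}, {n_wrap})"
        )
    k5 = k0 / (n_full - n_part)
    k7 = k0 / (n_part - n_wrap)
    k6 = k5 * np.exp(-ddg)
    k8 = k7 * np.exp(-dg_part_wrap)
    return WrapRates(
        k5=k5, k6=k6, k7=k7, k8=k8,
        n_full=int(n_full), n_part=int(n_part), n_wrap=int(n_wrap),
        ddg=float(ddg), k0=float(k0),
    )


def coarse_rates_from_landscape(
    landscape: FreeEnergyLandscape,
    n_full: int = 34,
    n_part: int = 19,
    n_wrap: int = 0,
    k0: float = DEFAULT_K0,
) -> WrapRates:
    """Coarse rates with both free-energy differences read off a landscape."""
    if n_full > landscape.n_max:
        raise ValueError(f"n_full={n_full} exceeds landscape n_max={landscape.n_max}")
    ddg = float(landscape.dG[n_full] - landscape.dG[n_part])
    dg_pw = float(landscape.dG[n_part] - landscape.dG[n_wrap])
    return coarse_rates(
        ddg, n_full=n_full, n_part=n_part, n_wrap=n_wrap, k0=k0, dg_part_wrap=dg_pw
    )
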