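"""Continuous-time Markov chain machinery for kinetic rate matrices.

A kinetic model is a generator matrix ``R`` acting on a column vector of
state concentrations, ``dX/dt = R X``.  Column ``i`` holds the rates out of
state ``i``: entry ``(j, i)`` is the transition rate from ``i`` to ``j`` and
the diagonal entry closes the column to zero so that total probability is
conserved.  The experimentally observed dissociation rate of such a model is
the magnitude of its slowest nonzero decay eigenvalue, once the detected
"off" state has been made absorbing by zeroing its outgoing rates.

The eigenvalue extraction is exact (dense) for small systems and uses
shift-invert Arnoldi around zero for large sparse systems, with a LAPACK
banded LU backing the inversion whenever the generator is narrowly banded
(the natural state ordering of the sliding-lattice models gives bandwidths
two orders of magnitude below the matrix size).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.linalg import lapack

__all__ = [
    "Generator",
    "OffRateResult",
    "GeneratorError",
    "NoDecayError",
    "MultipleSteadyStatesError",
    "validate_generator",
    "slowest_decay_rate",
    "steady_state",
    "generator_to_tsv",
    "generator_from_tsv",
]

#: an eigenvalue counts as "zero" below this multiple of the largest |diagonal|
_ZERO_EIGEN_REL = 1e-10

#: column sums must vanish to within this multiple of the largest |entry|
_COLSUM_REL = 1e-9


class GeneratorError(ValueError):
    """Structurally invalid rate matrix (shape/labels)."""


class NoDecayError(ValueError):
    """The generator has no nonzero eigenvalue (no dynamics to decay)."""


class MultipleSteadyStatesError(ValueError):
    """The null space of the generator is more than one-dimensional."""

    def __init__(self, zero_eigen_count: int):
        self.zero_eigen_count = zero_eigen_count
        super().__init__(
            f"generator has {zero_eigen_count} zero eigenvalues; "
            "the steady state is not unique"
        )


@dataclass(frozen=True)
class Generator:
    """Labeled CTMC generator.

    Parameters
    ----------
    labels:
        Ordered state names, one per matrix column.
    rates:
        Square matrix, dense ``ndarray`` or scipy sparse, with entry
        ``(j, i)`` the rate (1/s) from state ``i`` to state ``j``.
    absorbing:
        Labels whose outgoing rates were zeroed to create an absorbing
        ("off") state.  Informational; the zeroing itself is done by the
        model builders, never by deleting rows or columns.
    """

    labels: tuple[str, ...]
    rates: np.ndarray | sp.spmatrix
    absorbing: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        labels = tuple(str(s) for s in self.labels)
        object.__setattr__(self, "labels", labels)
        n = len(labels)
        if self.rates.shape != (n, n):
            raise GeneratorError(
                f"rates shape {self.rates.shape} does not match {n} labels"
            )
        if len(set(labels)) != n:
            raise GeneratorError("state labels must be unique")
        unknown = set(self.absorbing) - set(labels)
        if unknown:
            raise GeneratorError(f"absorbing labels not in state set: {sorted(unknown)}")
        object.__setattr__(self, "absorbing", frozenset(self.absorbing))

    @property
    def n_states(self) -> int:
        return len(self.labels)

    @property
    def is_sparse(self) -> bool:
        return sp.issparse(self.rates)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown state label {label!r}") from None

    def as_dense(self) -> np.ndarray:
        return self.rates.toarray() if self.is_sparse else np.asarray(self.rates, float)


@dataclass(frozen=True)
class OffRateResult:
    """Slowest-decay extraction result.

    ``off_rate`` is |lambda| of the nonzero eigenvalue of smallest magnitude
    (1/s); ``zero_eigen_count`` the dimension of the (numerically) zero
    eigenspace; ``spectrum_gap`` the ratio of the second-slowest to slowest
    nonzero magnitudes (``inf`` when only one nonzero mode exists); and
    ``complex_warning`` flags a slowest eigenvalue with a significant
    imaginary part.
    """

    off_rate: float
    zero_eigen_count: int
    spectrum_gap: float
    complex_warning: bool = False


def validate_generator(generator: Generator) -> list[str]:
    """Check the generator invariants; return a list of violation messages.

    An empty list means the matrix is a valid CTMC generator: non-negative
    off-diagonal rates, non-positive diagonal, and columns summing to zero
    (probability conservation).  Structural problems (non-square matrix,
    duplicate labels) raise :class:`GeneratorError` at construction instead.
    """
    R = generator.rates
    labels = generator.labels
    n = generator.n_states
    problems: list[str] = []

    if generator.is_sparse:
        coo = R.tocoo()
        off = coo.col != coo.row
        bad = off & (coo.data < 0)
        for r, c, v in zip(coo.row[bad], coo.col[bad], coo.data[bad]):
            problems.append(
                f"negative off-diagonal rate {v:g} from {labels[c]!r} to {labels[r]!r}"
            )
        diag = R.diagonal()
        colsum = np.asarray(R.sum(axis=0)).ravel()
        scale = np.max(np.abs(coo.data)) if coo.nnz else 0.0
    else:
        R = np.asarray(R, float)
        offmask = ~np.eye(n, dtype=bool)
        bad = np.argwhere(offmask & (R < 0))
        for r, c in bad:
            problems.append(
                f"negative off-diagonal rate {R[r, c]:g} "
                f"from {labels[c]!r} to {labels[r]!r}"
            )
        diag = np.diag(R)
        colsum = R.sum(axis=0)
        scale = np.max(np.abs(R)) if n else 0.0

    for i in np.nonzero(diag > 0)[0]:
        problems.append(f"positive diagonal entry {diag[i]:g} in column {labels[i]!r}")

    tol = _COLSUM_REL * scale if scale > 0 else 1e-15
    for i in np.nonzero(np.abs(colsum) > tol)[0]:
        problems.append(
            f"column {labels[i]!r} sums to {colsum[i]:g} (|sum| > {tol:g}); "
            "probability is not conserved"
        )
    return problems


def _zero_tol(generator: Generator) -> float:
    diag = generator.rates.diagonal()
    scale = float(np.max(np.abs(diag))) if len(diag) else 0.0
    return _ZERO_EIGEN_REL * scale if scale > 0 else 1e-300


def _dense_slowest(generator: Generator) -> OffRateResult:
    R = generator.as_dense()
    tol = _zero_tol(generator)
    eig = np.linalg.eigvals(R)
    mags = np.abs(eig)
    zero = mags < tol
    nonzero = eig[~zero]
    if nonzero.size == 0:
        raise NoDecayError("all eigenvalues are zero: the generator has no decay")
    order = np.argsort(np.abs(nonzero))
    lam = nonzero[order[0]]
    complex_warning = abs(lam.imag) > 1e-6 * abs(lam.real)
    if complex_warning:
        warnings.warn(
            f"slowest decay eigenvalue {lam:g} has a significant imaginary part",
            RuntimeWarning,
            stacklevel=3,
        )
    gap = (
        float(np.abs(nonzero[order[1]]) / np.abs(lam))
        if nonzero.size > 1
        else float("inf")
    )
    return OffRateResult(
        off_rate=float(np.abs(lam)),
        zero_eigen_count=int(zero.sum()),
        spectrum_gap=gap,
        complex_warning=bool(complex_warning),
    )


def _banded_opinv(Q: sp.csc_matrix):
    """LAPACK banded LU of ``Q`` as a LinearOperator, or None if not banded.

    Worth using when the band storage is small relative to a full LU; the
    heuristic accepts matrices whose bandwidth is below ~15% of the size.
    """
    n = Q.shape[0]
    coo = Q.tocoo()
    if coo.nnz == 0:
        return None
    kl = int(np.max(coo.row - coo.col))
    ku = int(np.max(coo.col - coo.row))
    if kl < 0 or ku < 0 or (kl + ku) > 0.15 * n:
        return None
    ab = np.zeros((2 * kl + ku + 1, n))
    ab[kl + ku + coo.row - coo.col, coo.col] = coo.data
    lu, piv, info = lapack.dgbtrf(ab, kl, ku)
    if info != 0:
        return None

    def solve(x):
        y, info_ = lapack.dgbtrs(lu, kl, ku, np.real(x), piv)
        if info_ != 0:
            raise RuntimeError(f"dgbtrs failed with info={info_}")
        return y

    return spla.LinearOperator((n, n), matvec=solve)


def _sparse_slowest(generator: Generator) -> OffRateResult:
    R = sp.csc_matrix(generator.rates)
    n = R.shape[0]
    # after structurally absorbing states are removed, a zero eigenvalue of
    # the remaining block can only come from a component disconnected from
    # absorption; genuine decay rates may lie many orders of magnitude below
    # the fastest rates, so the cutoff here is at the machine-precision
    # floor of the eigensolve rather than the generic zero tolerance
    diag = R.diagonal()
    scale = float(np.max(np.abs(diag))) if n else 0.0
    tol = 100.0 * np.finfo(float).eps * scale if scale > 0 else 1e-300

    # states with an all-zero column are structurally absorbing; each
    # contributes exactly one zero eigenvalue and the remaining spectrum is
    # that of the principal submatrix on the other states
    colmax = np.zeros(n)
    coo = R.tocoo()
    np.maximum.at(colmax, coo.col, np.abs(coo.data))
    keep = colmax > 0
    n_absorbing = int((~keep).sum())
    if keep.sum() == 0:
        raise NoDecayError("all eigenvalues are zero: the generator has no decay")
    Q = R[keep][:, keep].tocsc()
    m = Q.shape[0]
    if m <= 50:
        eig = np.linalg.eigvals(Q.toarray())
        mags = np.abs(eig)
        extra_zero = int((mags < tol).sum())
        if extra_zero:
            raise MultipleSteadyStatesError(n_absorbing + extra_zero)
        order = np.argsort(mags)
        lam = eig[order[0]]
        gap = float(mags[order[1]] / mags[order[0]]) if m > 1 else float("inf")
    else:
        k = min(2, m - 2)
        opinv = _banded_opinv(Q)
        v0 = np.ones(m) / np.sqrt(m)  # fixed start vector: deterministic output
        try:
            eig = spla.eigs(
                Q, k=k, sigma=0, which="LM", OPinv=opinv, v0=v0,
                return_eigenvectors=False,
            )
        except RuntimeError as err:  # pragma: no cover - degenerate input
            if "singular" in str(err).lower():
                raise MultipleSteadyStatesError(n_absorbing + 1) from err
            raise
        except spla.ArpackNoConvergence:
            eig = spla.eigs(
                Q,
                k=k,
                sigma=0,
                which="LM",
                OPinv=opinv,
                v0=v0,
                ncv=min(m - 1, 80),
                return_eigenvectors=False,
            )
        mags = np.abs(eig)
        order = np.argsort(mags)
        lam = eig[order[0]]
        if np.abs(lam) < tol:
            raise MultipleSteadyStatesError(n_absorbing + 1)
        gap = float(mags[order[1]] / mags[order[0]]) if k > 1 else float("inf")
    complex_warning = abs(lam.imag) > 1e-6 * abs(lam.real)
    if complex_warning:
        warnings.warn(
            f"slowest decay eigenvalue {lam:g} has a significant imaginary part",
            RuntimeWarning,
            stacklevel=3,
        )
    return OffRateResult(
        off_rate=float(np.abs(lam)),
        zero_eigen_count=max(n_absorbing, 1),
        spectrum_gap=gap,
        complex_warning=bool(complex_warning),
    )


def slowest_decay_rate(generator: Generator, method: str = "auto") -> OffRateResult:
    """Magnitude of the nonzero eigenvalue of smallest magnitude.

    This is the slowest exponential decay rate of the model and corresponds
    to the experimentally measured off-rate once the detection state is
    absorbing.  The result is invariant under any reordering of the states.

    Parameters
    ----------
    method:
        ``"auto"`` follows the storage of the rate matrix: dense eigensolve
        for dense input, shift-invert Arnoldi (with a dense fallback for
        tiny transient blocks) for sparse input.  ``"dense"`` and
        ``"sparse"`` force the respective path.
    """
    if method not in ("auto", "dense", "sparse"):
        raise ValueError(f"unknown method {method!r}")
    if method == "dense":
        return _dense_slowest(generator)
    if method == "auto" and not generator.is_sparse:
        return _dense_slowest(generator)
    return _sparse_slowest(generator)


def steady_state(generator: Generator) -> np.ndarray:
    """Normalized null vector of the generator (the long-time state).

    Raises :class:`MultipleSteadyStatesError` when the zero eigenspace has
    dimension above one (e.g. several disconnected absorbing components).
    Entries are clipped to zero below -1e-12 rounding noise.
    """
    R = generator.as_dense()
    tol = _zero_tol(generator)
    eig, vec = np.linalg.eig(R)
    zero = np.abs(eig) < tol
    count = int(zero.sum())
    if count == 0:
        raise NoDecayError("generator has no zero eigenvalue; not a closed system")
    if count > 1:
        raise MultipleSteadyStatesError(count)
    v = np.real(vec[:, np.nonzero(zero)[0][0]])
    v = v / v.sum()
    if np.any(v < -1e-12):
        raise ValueError(f"steady state has negative entries: min {v.min():g}")
    return np.clip(v, 0.0, None)


def generator_to_tsv(generator: Generator, path) -> None:
    """Write the generator as a labeled plain-text matrix (TSV)."""
    R = generator.as_dense()
    with open(path, "w") as fh:
        fh.write("state\t" + "\t".join(generator.labels) + "\n")
        for lab, row in zip(generator.labels, R):
            fh.write(lab + "\t" + "\t".join(f"{v:.17g}" for v in row) + "\n")


def generator_from_tsv(path, absorbing: frozenset[str] = frozenset()) -> Generator:
    """Read a generator written by :func:`generator_to_tsv`."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if not header or header[0] != "state":
            raise GeneratorError(f"{path}: first header field must be 'state'")
        labels = tuple(header[1:])
        rows = []
        row_labels = []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            row_labels.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    if tuple(row_labels) != labels:
        raise GeneratorError(f"{path}: row labels do not match column labels")
    return Generator(labels, np.array(rows, float), absorbing=absorbing)
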