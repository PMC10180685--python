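"""Spatial weight matrices for areal models.

Construction of contiguity weights on regular lattices, row standardization,
GAL / edge-list I/O, and fast evaluation of ``ln|det(I - c*W)|`` from cached
eigenvalues — the term that dominates repeated likelihood evaluation in
spatial autoregressive fitting.  The weight matrix always has a zero
diagonal; after row standardization every non-isolated row sums to one, so
``W y`` is the neighborhood average of ``y``.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpatialWeights",
    "build_lattice_weights",
    "row_standardize",
    "log_det_factor",
    "read_weights",
    "write_weights",
    "InvalidLatticeError",
    "InvalidWeightsError",
    "SingularityError",
    "WeightsIOError",
]


class InvalidLatticeError(ValueError):
    """Lattice dimensions cannot produce a connected neighbor structure."""


class InvalidWeightsError(ValueError):
    """Weight matrix violates a structural requirement (sign, diagonal)."""


class SingularityError(ValueError):
    """I - c*W is singular (or unstable) at the requested coefficient."""


class WeightsIOError(ValueError):
    """A weights file is malformed or referentially inconsistent."""


@dataclass
class SpatialWeights:
    """An n x n spatial weight matrix with cached spectrum.

    Parameters
    ----------
    matrix
        Dense ``(n, n)`` array with an exactly zero diagonal.
    row_standardized
        Whether each non-isolated row sums to one.
    labels
        Optional unit identifiers, one per row.

    Eigenvalues are computed lazily on first use and cached: the matrix is
    fixed across likelihood evaluations and Monte-Carlo replicates, so the
    one-time ``O(n^3)`` decomposition amortizes to nothing.
    """

    matrix: np.ndarray
    row_standardized: bool = False
    labels: list[str] | None = None
    _eigenvalues: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise InvalidWeightsError(f"weight matrix must be square, got {self.matrix.shape}")
        if np.any(np.diagonal(self.matrix) != 0.0):
            raise InvalidWeightsError("weight matrix diagonal must be exactly zero")
        if not np.all(np.isfinite(self.matrix)):
            raise InvalidWeightsError("weight matrix contains non-finite entries")
        if self.labels is not None and len(self.labels) != self.n:
            raise InvalidWeightsError("labels length does not match matrix order")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def eigenvalues(self) -> np.ndarray:
        """Full spectrum of the matrix (complex dtype if non-symmetric)."""
        if self._eigenvalues is None:
            m = self.matrix
            if np.allclose(m, m.T):
                self._eigenvalues = np.linalg.eigvalsh(m)
            else:
                self._eigenvalues = np.linalg.eigvals(m)
        return self._eigenvalues

    def stability_interval(self) -> tuple[float, float]:
        """Open interval of c for which I - c*W is guaranteed non-singular.

        Determined by the real eigenvalues: ``(1/omega_min, 1/omega_max)``.
        For a row-standardized connected contiguity matrix the upper end is 1.
        """
        real = np.real(self.eigenvalues[np.abs(np.imag(self.eigenvalues)) < 1e-10])
        lo = -np.inf if not np.any(real < 0) else 1.0 / real.min()
        hi = np.inf if not np.any(real > 0) else 1.0 / real.max()
        return (lo, hi)


def build_lattice_weights(R: int, T: int, contiguity: str = "rook") -> SpatialWeights:
    """Row-standardized contiguity weights on an R x T regular grid.

    ``rook`` joins cells sharing an edge (up to 4 neighbors), ``queen`` also
    joins diagonal cells (up to 8).  Units are labeled ``"r{i}c{j}"`` in
    row-major order.
    """
    if R < 1 or T < 1 or R * T < 2:
        raise InvalidLatticeError(
            f"lattice {R}x{T} has no neighbor pairs; need at least two cells"
        )
    if contiguity not in ("rook", "queen"):
        raise InvalidLatticeError(f"unknown contiguity rule: {contiguity!r}")
    n = R * T
    mat = np.zeros((n, n))
    if contiguity == "rook":
        offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        offsets = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)]
    for i in range(R):
        for j in range(T):
            a = i * T + j
            for di, dj in offsets:
                ii, jj = i + di, j + dj
                if 0 <= ii < R and 0 <= jj < T:
                    mat[a, ii * T + jj] = 1.0
    labels = [f"r{i}c{j}" for i in range(R) for j in range(T)]
    return row_standardize(SpatialWeights(mat, labels=labels))


def row_standardize(w: SpatialWeights) -> SpatialWeights:
    """Divide each nonzero row by its sum; isolate rows stay zero (warned)."""
    if np.any(w.matrix < 0):
        raise InvalidWeightsError("row standardization requires nonnegative weights")
    sums = w.matrix.sum(axis=1)
    isolates = np.flatnonzero(sums == 0)
    if isolates.size:
        names = (
            [w.labels[i] for i in isolates] if w.labels is not None else isolates.tolist()
        )
        warnings.warn(f"{isolates.size} isolate unit(s) with no neighbors: {names}")
    denom = np.where(sums == 0, 1.0, sums)
    return SpatialWeights(w.matrix / denom[:, None], row_standardized=True, labels=w.labels)


def log_det_factor(w: SpatialWeights, coef: float) -> float:
    """``ln|det(I - coef * W)|`` via the cached spectrum.

    Equals ``sum_i ln(1 - coef * omega_i)``; with complex eigenvalue pairs the
    imaginary parts of the complex logarithms cancel because the determinant
    is real.  Raises :class:`SingularityError` outside the stability interval.
    """
    lo, hi = w.stability_interval()
    if not (lo < coef < hi):
        raise SingularityError(
            f"coefficient {coef} outside stability interval ({lo:.4g}, {hi:.4g}); "
            "I - c*W singular or indefinite"
        )
    terms = np.log(1.0 - coef * w.eigenvalues.astype(complex))
    total = terms.sum()
    if abs(total.imag) > 1e-8:
        raise SingularityError(
            f"log-determinant has non-real residue {total.imag:.3g}; "
            "det(I - c*W) is not positive at this coefficient"
        )
    return float(total.real)


def read_weights(path, format: str = "gal") -> SpatialWeights:
    """Read a spatial weights file.

    ``gal``: neighbor-list format — a header line with the unit count,
    then alternating ``label k`` / ``k neighbor labels`` lines.  Produces
    binary weights (standardize separately).  An asymmetric list is warned
    about and symmetrized by union.

    ``edge_csv``: columns ``from,to,weight`` (header required).
    """
    if format == "gal":
        return _read_gal(path)
    if format == "edge_csv":
        return _read_edge_csv(path)
    raise WeightsIOError(f"unknown weights format: {format!r}")


def _read_gal(path) -> SpatialWeights:
    with open(path) as fh:
        tokens_by_line = [ln.split() for ln in fh if ln.strip()]
    if not tokens_by_line:
        raise WeightsIOError(f"empty GAL file: {path}")
    header = tokens_by_line[0]
    # both "n" and the 4-token "0 n shapefile key" header dialects occur
    n = int(header[1]) if len(header) == 4 else int(header[0])
    body = tokens_by_line[1:]
    # blank lines are skipped, so a unit with zero neighbors occupies a
    # single "label 0" line
    cursor = 0
    entries: list[tuple[str, list[str]]] = []
    for _ in range(n):
        if cursor >= len(body):
            raise WeightsIOError(f"GAL body truncated: expected {n} units")
        lab, k = body[cursor][0], int(body[cursor][1])
        cursor += 1
        neigh: list[str] = []
        if k > 0:
            if cursor >= len(body):
                raise WeightsIOError(f"unit {lab!r}: neighbor line missing")
            neigh = body[cursor]
            cursor += 1
            if len(neigh) != k:
                raise WeightsIOError(
                    f"unit {lab!r}: declared {k} neighbors, listed {len(neigh)}"
                )
        entries.append((lab, neigh))
    labels = [lab for lab, _ in entries]
    index = {lab: i for i, lab in enumerate(labels)}
    if len(index) != n:
        raise WeightsIOError("duplicate unit labels in GAL file")
    mat = np.zeros((n, n))
    for i, (lab, neigh) in enumerate(entries):
        for nb in neigh:
            if nb not in index:
                raise WeightsIOError(f"unit {lab!r} references unknown neighbor {nb!r}")
            mat[i, index[nb]] = 1.0
    if not np.array_equal(mat, mat.T):
        warnings.warn("asymmetric GAL neighbor list; symmetrizing by union")
        mat = np.maximum(mat, mat.T)
    np.fill_diagonal(mat, 0.0)
    return SpatialWeights(mat, labels=labels)


def _read_edge_csv(path) -> SpatialWeights:
    edges = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"from", "to", "weight"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise WeightsIOError(f"edge CSV must have columns {sorted(required)}")
        for row in reader:
            edges.append((row["from"], row["to"], float(row["weight"])))
    labels = sorted({e[0] for e in edges} | {e[1] for e in edges})
    index = {lab: i for i, lab in enumerate(labels)}
    mat = np.zeros((len(labels), len(labels)))
    for a, b, wt in edges:
        if a == b:
            raise WeightsIOError(f"self-edge on unit {a!r} not allowed")
        mat[index[a], index[b]] = wt
    return SpatialWeights(mat, labels=labels)


def write_weights(w: SpatialWeights, path, format: str = "gal") -> None:
    """Write weights as GAL (binary adjacency) or edge-list CSV."""
    labels = w.labels if w.labels is not None else [str(i) for i in range(w.n)]
    if format == "gal":
        with open(path, "w") as fh:
            fh.write(f"{w.n}\n")
            for i, lab in enumerate(labels):
                nb = [labels[j] for j in np.flatnonzero(w.matrix[i])]
                fh.write(f"{lab} {len(nb)}\n")
                fh.write(" ".join(nb) + "\n")
    elif format == "edge_csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["from", "to", "weight"])
            for i in range(w.n):
                for j in np.flatnonzero(w.matrix[i]):
                    writer.writerow([labels[i], labels[j], repr(float(w.matrix[i, j]))])
    else:
        raise WeightsIOError(f"unknown weights format: {format!r}")
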