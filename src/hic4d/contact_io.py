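"""Reading, writing and assembling Hi-C contact maps.

A contact map is a symmetric, non-negative ``n x n`` matrix of interaction
frequencies between fixed-width genomic bins, tagged with a real-valued time
(e.g. the day within a differentiation time course). Two plain-text formats
are supported:

dense
    ``n`` whitespace-delimited rows of ``n`` numbers.
triple
    rows of ``bin_i bin_j value`` with 0-based indices; one triangle suffices.

Bins whose entire row is zero carry no experimental signal and are flagged in
a per-bin boolean mask. A time series additionally tracks the bins that are
empty at *every* time point (``common_mask``); those bins are excluded from
restraint building and from map comparisons downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import FormatError

__all__ = [
    "ContactMap",
    "TimeSeriesHiC",
    "read_contact_map",
    "write_contact_map",
    "assemble_series",
    "symmetrize",
]

_SYM_TOL = 1e-9


def symmetrize(matrix: np.ndarray) -> np.ndarray:
    """Return ``(A + A.T) / 2``. Idempotent on symmetric input."""
    return (matrix + matrix.T) / 2.0


@dataclass
class ContactMap:
    """One intrachromosomal Hi-C contact matrix at one time point.

    Parameters
    ----------
    matrix
        Symmetric non-negative ``n x n`` interaction frequencies.
    bin_size
        Genomic bin width in base pairs. Bin ``b`` covers the half-open
        interval ``[b * bin_size, (b + 1) * bin_size)``.
    time
        Real-valued time tag (e.g. day).
    chrom
        Chromosome label.
    mask
        Per-bin boolean, ``True`` where the bin has no data in this map.
    """

    matrix: np.ndarray
    bin_size: int
    time: float
    chrom: str = "chr"
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise FormatError(f"contact matrix must be square, got {self.matrix.shape}")
        if self.matrix.shape[0] < 2:
            raise ValueError("contact map needs at least 2 bins")
        if self.mask is None:
            self.mask = ~self.matrix.any(axis=1)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != (self.n,):
                raise ValueError("mask length must equal bin count")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def validate(self) -> None:
        """Check the post-load invariants (symmetry, sign, finiteness)."""
        if not np.allclose(self.matrix, self.matrix.T, atol=_SYM_TOL):
            raise ValueError("matrix is not symmetric")
        if np.isnan(self.matrix).any():
            raise ValueError("matrix contains NaN")
        if (self.matrix < 0).any():
            raise ValueError("matrix contains negative values")

    def copy(self) -> "ContactMap":
        return replace(self, matrix=self.matrix.copy(), mask=self.mask.copy())


@dataclass
class TimeSeriesHiC:
    """Contact maps of one chromosome sorted by strictly increasing time."""

    maps: list[ContactMap]
    common_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.common_mask is None:
            self.common_mask = np.logical_and.reduce([m.mask for m in self.maps])

    @property
    def n(self) -> int:
        return self.maps[0].n

    @property
    def bin_size(self) -> int:
        return self.maps[0].bin_size

    @property
    def chrom(self) -> str:
        return self.maps[0].chrom

    @property
    def times(self) -> np.ndarray:
        return np.array([m.time for m in self.maps])

    def __len__(self) -> int:
        return len(self.maps)

    def drop_time(self, time: float) -> "TimeSeriesHiC":
        """Return a new series with the map at ``time`` removed."""
        kept = [m for m in self.maps if m.time != time]
        if len(kept) == len(self.maps):
            raise ValueError(f"no map at time {time}")
        return assemble_series(kept)


def _load_dense(path) -> np.ndarray:
    try:
        matrix = np.loadtxt(path, dtype=float, ndmin=2)
    except ValueError as exc:  # ragged rows
        raise FormatError(f"cannot parse dense matrix from {path}: {exc}") from None
    if matrix.shape[0] != matrix.shape[1]:
        raise FormatError(
            f"dense matrix in {path} is not square: {matrix.shape[0]} rows x "
            f"{matrix.shape[1]} columns"
        )
    return matrix


def _load_triple(path, n: int | None) -> np.ndarray:
    rows = np.loadtxt(path, dtype=float, ndmin=2)
    if rows.size == 0:
        raise FormatError(f"{path} contains no triples")
    if rows.shape[1] != 3:
        raise FormatError(f"triple format needs 3 columns, got {rows.shape[1]}")
    i = rows[:, 0].astype(int)
    j = rows[:, 1].astype(int)
    if (i < 0).any() or (j < 0).any():
        raise IndexError("negative bin index in triple file")
    inferred = int(max(i.max(), j.max())) + 1
    if n is None:
        n = inferred
    elif inferred > n:
        raise IndexError(f"triple index {inferred - 1} >= declared n={n}")
    matrix = np.zeros((n, n))
    matrix[i, j] = rows[:, 2]
    matrix[j, i] = rows[:, 2]
    return matrix


def read_contact_map(
    path,
    format: str = "dense",
    *,
    bin_size: int,
    time: float,
    chrom: str = "chr",
    n: int | None = None,
) -> ContactMap:
    """Load one contact map from a plain-text file.

    NaN entries are zeroed (and surface in the mask if the whole row is
    empty); an asymmetric dense matrix is symmetrized as ``(A + A.T) / 2``
    with a warning; negative entries are an error.

    Parameters
    ----------
    format
        ``"dense"`` or ``"triple"``.
    n
        Declared bin count for the triple format; inferred from the largest
        index when omitted.
    """
    if format == "dense":
        matrix = _load_dense(path)
    elif format == "triple":
        matrix = _load_triple(path, n)
    else:
        raise ValueError(f"unknown format {format!r}")

    matrix = np.nan_to_num(matrix, nan=0.0)
    if (matrix < 0).any():
        raise ValueError(f"negative interaction frequency in {path}")
    if not np.allclose(matrix, matrix.T, atol=_SYM_TOL):
        warnings.warn(f"asymmetric matrix in {path}; symmetrizing as (A+A.T)/2")
        matrix = symmetrize(matrix)
    cmap = ContactMap(matrix=matrix, bin_size=bin_size, time=time, chrom=chrom)
    cmap.validate()
    return cmap


def write_contact_map(cmap: ContactMap, path, format: str = "dense") -> None:
    """Write a map back to text. Masked rows are written as zeros.

    Round trip: ``read_contact_map(write_contact_map(m))`` reproduces the
    matrix entrywise within 1e-9.
    """
    matrix = cmap.matrix.copy()
    matrix[cmap.mask, :] = 0.0
    matrix[:, cmap.mask] = 0.0
    if format == "dense":
        np.savetxt(path, matrix, fmt="%.12g")
    elif format == "triple":
        i, j = np.nonzero(np.triu(matrix))
        with open(path, "w") as fh:
            for a, b in zip(i, j):
                fh.write(f"{a} {b} {matrix[a, b]:.12g}\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def assemble_series(maps: list[ContactMap]) -> TimeSeriesHiC:
    """Sort maps by time and compute the common (all-times-empty) bin mask.

    Raises on fewer than two maps, inconsistent shape/bin size/chromosome,
    or duplicate time tags.
    """
    if len(maps) < 2:
        raise ValueError("a time series needs at least 2 maps")
    ref = maps[0]
    for m in maps[1:]:
        if m.n != ref.n:
            raise FormatError(f"inconsistent bin counts: {m.n} vs {ref.n}")
        if m.bin_size != ref.bin_size:
            raise ValueError("inconsistent bin sizes")
        if m.chrom != ref.chrom:
            raise ValueError("inconsistent chromosome labels")
    ordered = sorted(maps, key=lambda m: m.time)
    times = [m.time for m in ordered]
    if len(set(times)) != len(times):
        raise ValueError(f"duplicate time tags: {times}")
    return TimeSeriesHiC(maps=ordered)
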