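"""Synthetic contact maps from a fitted structure, plus the naive baseline.

Extraction inverts the restraint conversion: from the frame nearest the
requested time, every off-diagonal pair receives ``IF = d ** (-1/gamma)``.
A map extracted at a time whose real data entered the fit is called a
*reconstruction*; at a withheld time, an *interpolation*. The naive baseline
is plain entrywise linear interpolation between the two flanking real maps.

Extracted values live on the model's internal distance scale; downstream
comparisons use rank or Pearson statistics, which do not depend on it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contact_io import ContactMap
from .model4d import Structure4D, interpolation_weights
from .restraints import DEFAULT_GAMMA

__all__ = ["SyntheticMap", "extract_map", "naive_interpolation"]


@dataclass
class SyntheticMap(ContactMap):
    """A contact map derived from a model rather than an experiment."""

    provenance: str = "reconstructed"  # reconstructed | interpolated | baseline
    source_time: float = float("nan")


def distances_to_contacts(d: np.ndarray, gamma: float = DEFAULT_GAMMA) -> np.ndarray:
    """``IF = d ** (-1/gamma)`` on the off-diagonal; zero diagonal."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    out = np.zeros_like(d)
    off = ~np.eye(d.shape[0], dtype=bool)
    out[off] = np.maximum(d[off], 1e-12) ** (-1.0 / gamma)
    return out


def extract_map(
    structure: Structure4D,
    t: float,
    gamma: float = DEFAULT_GAMMA,
    *,
    provenance: str = "reconstructed",
) -> SyntheticMap:
    """Extract the synthetic contact map at the grid time nearest ``t``.

    Raises when ``t`` falls outside the grid range. Masked bins are zeroed
    and stay masked.
    """
    k = structure.frame_index(t)
    matrix = distances_to_contacts(structure.distance_matrix(k), gamma)
    matrix[structure.mask, :] = 0.0
    matrix[:, structure.mask] = 0.0
    return SyntheticMap(
        matrix=matrix,
        bin_size=structure.bin_size,
        time=float(structure.grid[k]),
        chrom=structure.chrom,
        mask=structure.mask.copy(),
        provenance=provenance,
        source_time=float(structure.grid[k]),
    )


def naive_interpolation(
    map_a: ContactMap, map_b: ContactMap, t: float
) -> SyntheticMap:
    """Entrywise linear interpolation between two real maps at an interior
    time, using the same convex weights as the model."""
    if map_a.matrix.shape != map_b.matrix.shape:
        raise ValueError(
            f"shape mismatch: {map_a.matrix.shape} vs {map_b.matrix.shape}"
        )
    w1, w2 = interpolation_weights(t, map_a.time, map_b.time)
    matrix = w1 * map_a.matrix + w2 * map_b.matrix
    return SyntheticMap(
        matrix=matrix,
        bin_size=map_a.bin_size,
        time=t,
        chrom=map_a.chrom,
        mask=map_a.mask | map_b.mask,
        provenance="baseline",
        source_time=t,
    )
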