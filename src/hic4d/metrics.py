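"""Comparison metrics for contact maps and structures.

Maps are compared on their vectorized upper triangles (diagonal excluded,
masked bins dropped) with Spearman (SRC) and Pearson (PCC) correlation.
Structures are compared per matched time point on their pairwise-distance
vectors (rotation/translation invariant) and, after Procrustes
superposition, by the disparity M² — the residual sum of squares once both
point sets are centered, scaled to unit trace norm and optimally rotated
(reflections allowed, since chirality is unidentifiable from distances).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import procrustes as _scipy_procrustes
from scipy.stats import pearsonr, spearmanr

from .contact_io import ContactMap, TimeSeriesHiC
from .errors import DegenerateDataError
from .model4d import FitConfig, Structure4D, fit

__all__ = [
    "ComparisonReport",
    "compare_maps",
    "procrustes_disparity",
    "compare_structures_4d",
    "reduce_resolution",
    "interpolation_experiment",
]


@dataclass
class ComparisonReport:
    src: float
    pcc: float
    n_pairs: int
    disparity: float | None = None


def _upper_triangle(cmap: ContactMap, drop: np.ndarray) -> np.ndarray:
    keep = ~drop
    sub = cmap.matrix[np.ix_(keep, keep)]
    iu, ju = np.triu_indices(sub.shape[0], k=1)
    return sub[iu, ju]


def compare_maps(
    map_a: ContactMap,
    map_b: ContactMap,
    mask_policy: str = "union",
    log: bool = False,
) -> ComparisonReport:
    """SRC and PCC over upper-triangle entries of two same-shape maps.

    ``mask_policy="union"`` drops bins masked in either map; ``"none"``
    keeps everything. ``log`` compares ``log1p`` of the entries instead of
    raw values (rank-preserving, so SRC is unaffected).
    """
    if map_a.matrix.shape != map_b.matrix.shape:
        raise ValueError("maps have different shapes")
    if mask_policy == "union":
        drop = map_a.mask | map_b.mask
    elif mask_policy == "none":
        drop = np.zeros(map_a.n, dtype=bool)
    else:
        raise ValueError(f"unknown mask_policy {mask_policy!r}")
    va = _upper_triangle(map_a, drop)
    vb = _upper_triangle(map_b, drop)
    if va.size < 2:
        raise DegenerateDataError("fewer than 2 comparable entries")
    if log:
        va, vb = np.log1p(va), np.log1p(vb)
    return ComparisonReport(
        src=float(spearmanr(va, vb).statistic),
        pcc=float(pearsonr(va, vb).statistic),
        n_pairs=int(va.size),
    )


def procrustes_disparity(struct_a: np.ndarray, struct_b: np.ndarray) -> float:
    """Disparity M² after optimal similarity superposition of two point sets.

    Both sets are centered and scaled to unit trace norm, then optimally
    rotated (reflection allowed); M² is the residual sum of squared
    distances, in [0, 2]. Symmetric in its arguments and invariant to
    similarity transforms of either one.
    """
    a = np.asarray(struct_a, dtype=float)
    b = np.asarray(struct_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("structures must have the same shape")
    try:
        _, _, disparity = _scipy_procrustes(a, b)
    except ValueError as exc:
        raise DegenerateDataError(f"degenerate input to Procrustes: {exc}") from None
    return float(disparity)


def _distance_vector(coords: np.ndarray) -> np.ndarray:
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    iu, ju = np.triu_indices(coords.shape[0], k=1)
    return d[iu, ju]


def compare_structures_4d(
    a: Structure4D, b: Structure4D, time_tol: float = 1e-9
) -> dict:
    """Per-matched-time SRC/PCC of pairwise-distance vectors plus M², and
    their averages over the matched times."""
    rows = []
    for k, t in enumerate(a.grid):
        hits = np.where(np.abs(b.grid - t) <= time_tol)[0]
        if hits.size == 0:
            continue
        m = int(hits[0])
        va = _distance_vector(a.coords[k])
        vb = _distance_vector(b.coords[m])
        rows.append({
            "time": float(t),
            "src": float(spearmanr(va, vb).statistic),
            "pcc": float(pearsonr(va, vb).statistic),
            "disparity": procrustes_disparity(a.coords[k], b.coords[m]),
        })
    if not rows:
        raise ValueError("no common grid times")
    return {
        "per_time": rows,
        "mean_src": float(np.mean([r["src"] for r in rows])),
        "mean_pcc": float(np.mean([r["pcc"] for r in rows])),
        "mean_disparity": float(np.mean([r["disparity"] for r in rows])),
    }


def reduce_resolution(structure: Structure4D, factor: int) -> Structure4D:
    """Coarsen bins by averaging the coordinates of every ``factor``
    consecutive bins per frame; a trailing remainder forms a partial group."""
    if factor < 2:
        raise ValueError("factor must be >= 2")
    n = structure.n
    if factor > n:
        raise ValueError(f"factor {factor} exceeds bin count {n}")
    edges = np.arange(0, n, factor)
    frames = np.stack([
        np.array([
            structure.coords[k, start:start + factor].mean(axis=0)
            for start in edges
        ])
        for k in range(structure.g)
    ])
    mask = np.array([
        structure.mask[start:start + factor].all() for start in edges
    ])
    return Structure4D(
        coords=frames, grid=structure.grid.copy(),
        bin_size=structure.bin_size * factor, chrom=structure.chrom, mask=mask,
    )


def interpolation_experiment(
    series: TimeSeriesHiC,
    holdout_time: float,
    config: FitConfig | None = None,
    granularity: int | None = None,
) -> dict:
    """Fit with one interior time point withheld and score the interpolation.

    The model is fitted on the remaining maps over the *full* time grid (so
    the held-out time stays a grid point), the synthetic map is extracted
    there, and compared against the held-out truth, the two adjacent real
    maps, and the naive entrywise-linear baseline. ``beat_baseline`` is
    decided on SRC, ties going to the baseline.
    """
    from .extraction import extract_map, naive_interpolation
    from .restraints import build_restraints

    config = config or FitConfig()
    times = series.times
    if holdout_time not in times:
        raise ValueError(f"{holdout_time} is not an observed time")
    if holdout_time in (times[0], times[-1]):
        raise ValueError("cannot hold out an endpoint: no flanking restraints")
    if granularity is None:
        granularity = len(series)

    truth = next(m for m in series.maps if m.time == holdout_time)
    reduced = series.drop_time(holdout_time)
    below = reduced.times[reduced.times < holdout_time].max()
    above = reduced.times[reduced.times > holdout_time].min()
    map_below = next(m for m in reduced.maps if m.time == below)
    map_above = next(m for m in reduced.maps if m.time == above)

    restraints = build_restraints(reduced, gamma=config.gamma, granularity=granularity)
    structure, trace = fit(restraints, config)
    interpolated = extract_map(
        structure, holdout_time, gamma=config.gamma, provenance="interpolated"
    )
    baseline = naive_interpolation(map_below, map_above, holdout_time)

    vs_truth = compare_maps(interpolated, truth)
    vs_baseline_truth = compare_maps(baseline, truth)
    result = {
        "holdout_time": float(holdout_time),
        "vs_truth": vs_truth,
        "vs_below": compare_maps(interpolated, map_below),
        "vs_above": compare_maps(interpolated, map_above),
        "baseline_vs_truth": vs_baseline_truth,
        "beat_baseline": bool(vs_truth.src > vs_baseline_truth.src),
        "model_distances": structure.distance_matrix(
            structure.frame_index(holdout_time)
        ),
        "structure": structure,
        "trace": trace,
    }
    return result
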