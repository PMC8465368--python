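"""Distance restraints and the discrete time grid.

Interaction frequencies are converted to target spatial distances with the
power law ``D = IF ** (-gamma)`` (gamma stored as the positive magnitude,
default 0.6), the inverse of the extraction-side relation
``IF = d ** (-1/gamma)``. The continuous time interval is discretized into
``g`` equally spaced grid times (the *granularity*) spanning the observed
range; every observed time must land on a grid point after snapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .contact_io import ContactMap, TimeSeriesHiC
from .errors import DegenerateDataError, GranularityError

__all__ = [
    "RestraintSet",
    "contacts_to_distances",
    "build_time_grid",
    "build_restraints",
    "DEFAULT_GAMMA",
]

DEFAULT_GAMMA = 0.6
#: observed times may move by at most this fraction of the grid spacing
SNAP_TOLERANCE = 0.25


@dataclass
class RestraintSet:
    """Per-observed-time target distances on a shared time grid.

    ``by_grid_index`` maps the grid position of each observed time to arrays
    ``(i, j, d)`` of bin pairs (``i < j``) and unit-max-rescaled target
    distances. ``scale`` records the global factor that was divided out, so
    distances can be reported on the original ``IF**(-gamma)`` scale.
    """

    n: int
    grid: np.ndarray
    observed_index: dict[float, int]
    by_grid_index: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]]
    scale: float
    gamma: float
    bin_size: int
    chrom: str
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.mask is None:
            self.mask = np.zeros(self.n, dtype=bool)

    @property
    def granularity(self) -> int:
        return len(self.grid)

    @property
    def observed_grid_indices(self) -> list[int]:
        return sorted(self.by_grid_index)

    def flanking_observed(self, t_index: int) -> tuple[int, int]:
        """Grid indices of the nearest observed times before and after an
        unobserved grid index."""
        obs = self.observed_grid_indices
        before = [k for k in obs if k < t_index]
        after = [k for k in obs if k > t_index]
        if not before or not after:
            raise ValueError(
                f"grid index {t_index} is not flanked by observed times"
            )
        return before[-1], after[0]


def contacts_to_distances(
    cmap: ContactMap, gamma: float = DEFAULT_GAMMA, *, rescale: bool = True
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Convert one map to per-pair target distances ``D = IF ** (-gamma)``.

    Pairs with zero interaction frequency carry no restraint and are dropped;
    masked bins and the diagonal are excluded. Returns ``(i, j, d, scale)``
    where ``d`` has been divided by ``scale`` so its maximum is 1 (skipped
    when ``rescale`` is false, in which case ``scale`` is 1).
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive (stored as a magnitude)")
    iu, ju = np.triu_indices(cmap.n, k=1)
    keep = (
        (cmap.matrix[iu, ju] > 0) & ~cmap.mask[iu] & ~cmap.mask[ju]
    )
    i, j = iu[keep], ju[keep]
    if i.size == 0:
        raise DegenerateDataError("no positive contacts: empty restraint set")
    d = cmap.matrix[i, j] ** (-gamma)
    scale = 1.0
    if rescale:
        scale = float(d.max())
        d = d / scale
    return i, j, d, scale


def build_time_grid(
    observed_times, granularity: int
) -> tuple[np.ndarray, dict[float, int]]:
    """Lay ``granularity`` equally spaced times over the observed range and
    snap each observed time to its nearest grid point.

    Raises :class:`GranularityError` when two observed times collide on one
    grid point or when snapping would move a time by more than 25% of the
    grid spacing.
    """
    times = np.asarray(sorted(observed_times), dtype=float)
    if len(times) < 2:
        raise ValueError("need at least 2 observed times")
    if granularity < max(2, len(times)):
        raise GranularityError(
            f"granularity {granularity} < number of observed times {len(times)}"
        )
    grid = np.linspace(times[0], times[-1], granularity)
    spacing = grid[1] - grid[0]
    observed_index: dict[float, int] = {}
    for tau in times:
        k = int(np.argmin(np.abs(grid - tau)))
        displacement = abs(grid[k] - tau)
        if displacement > SNAP_TOLERANCE * spacing:
            raise GranularityError(
                f"observed time {tau} is {displacement:.4g} from the nearest "
                f"grid time {grid[k]:.4g} (> {SNAP_TOLERANCE:.0%} of spacing "
                f"{spacing:.4g}); increase granularity"
            )
        if k in observed_index.values():
            raise GranularityError(
                f"two observed times snap to grid index {k}; granularity too coarse"
            )
        observed_index[float(tau)] = k
    return grid, observed_index


def build_restraints(
    series: TimeSeriesHiC,
    gamma: float = DEFAULT_GAMMA,
    granularity: int | None = None,
) -> RestraintSet:
    """Build the union of per-time restraints on a shared grid.

    Bins flagged in the series' common mask are excluded everywhere. A single
    global rescaling is applied across all times so the largest target
    distance equals 1.

    ``granularity`` defaults to the number of observed time points (every
    observed time becomes one grid point).
    """
    if granularity is None:
        granularity = len(series)
    grid, observed_index = build_time_grid(series.times, granularity)

    per_time = []
    scale = 0.0
    for cmap in series.maps:
        masked = cmap.copy()
        masked.mask = masked.mask | series.common_mask
        i, j, d, _ = contacts_to_distances(masked, gamma, rescale=False)
        per_time.append((cmap.time, i, j, d))
        scale = max(scale, float(d.max()))

    by_grid_index = {
        observed_index[t]: (i, j, d / scale) for t, i, j, d in per_time
    }
    return RestraintSet(
        n=series.n,
        grid=grid,
        observed_index=observed_index,
        by_grid_index=by_grid_index,
        scale=scale,
        gamma=gamma,
        bin_size=series.bin_size,
        chrom=series.chrom,
        mask=series.common_mask.copy(),
    )
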