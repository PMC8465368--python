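"""Toy 4D chromosomes and simulated Hi-C time series.

Two hand-constructed trajectories of an 11-bin, 50 kb chromosome evolving
over six days serve as ground truth for end-to-end testing. Both start as a
closed loop (a regular 11-gon of unit bonds, bins 0 and 10 in contact) and
end as a fully elongated straight chain, but take different paths:

``unravel``
    the loop is pulled open from both ends — the arms straighten early
    while the middle of the loop folds into a tight hairpin, keeping bins
    4 and 6 in contact through the middle of the process (strongest around
    day 3) before the fold releases.
``swing``
    the loop swings open about the hinge at bin 5 — the hinge angle
    releases fast (cubically), so bins 4 and 6 separate immediately and the
    chain opens like a pair of compasses.

The chain is inextensible: consecutive-bin bond lengths are exactly 1 in
every frame of both variants (each frame is built from per-vertex turning
angles of a unit-bond chain in the plane). The unravel hinge angle is
tabulated per day so that the end-to-end distance grows monotonically (the
ends are being pulled apart) and every pair distance changes smoothly
between adjacent days.

Simulated Hi-C converts each frame's distances with ``IF = d**(-1/gamma)``,
optionally followed by Poisson resampling of counts at a stated scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contact_io import ContactMap, TimeSeriesHiC, assemble_series
from .extraction import distances_to_contacts, extract_map
from .metrics import compare_maps, interpolation_experiment
from .model4d import FitConfig, Structure4D, fit
from .restraints import DEFAULT_GAMMA, build_restraints

__all__ = [
    "ToyTrajectory",
    "make_toy_trajectory",
    "simulate_hic",
    "end_to_end_recovery",
    "CONTACT_THRESHOLD_BONDS",
    "mid_loop_contact",
]

TOY_N_BINS = 11
TOY_BIN_SIZE = 50_000
TOY_DAYS = np.arange(6, dtype=float)

#: a pair is "in contact" when closer than this multiple of the bond length
CONTACT_THRESHOLD_BONDS = 1.5

# mid-loop hinge (vertex 5) turning angle per day for the unravel variant;
# day 0 uses the polygon angle, day 5 is fully straight
_UNRAVEL_HINGE = [None, 1.366, 1.725, 1.725, 1.52, 0.0]


@dataclass
class ToyTrajectory:
    """Ground-truth coordinates: 6 frames x 11 bins x 3."""

    coords: np.ndarray
    variant: str
    bin_size: int = TOY_BIN_SIZE
    times: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        if self.times is None:
            self.times = TOY_DAYS.copy()

    def distance_matrix(self, frame: int) -> np.ndarray:
        x = self.coords[frame]
        return np.linalg.norm(x[:, None, :] - x[None, :, :], axis=-1)

    def as_structure(self) -> Structure4D:
        return Structure4D(
            coords=self.coords.copy(), grid=self.times.copy(),
            bin_size=self.bin_size, chrom="toy",
        )


def _chain_from_turns(turns: np.ndarray) -> np.ndarray:
    """Positions of an 11-bead unit-bond chain in the plane from the turning
    angle applied at each interior vertex, centered at the centroid."""
    theta = np.cumsum(np.concatenate([[0.0], turns[1:]]))
    steps = np.stack(
        [np.cos(theta), np.sin(theta), np.zeros_like(theta)], axis=1
    )
    pos = np.concatenate([[[0.0, 0.0, 0.0]], np.cumsum(steps, axis=0)])
    return pos - pos.mean(axis=0)


def make_toy_trajectory(variant: str) -> ToyTrajectory:
    """Build one of the two deterministic 11-bin, 6-day trajectories."""
    if variant not in ("unravel", "swing"):
        raise ValueError(f"unknown variant {variant!r}")
    base = 2.0 * np.pi / TOY_N_BINS
    frames = []
    for day in range(6):
        u = day / 5.0
        if variant == "unravel":
            turns = np.full(10, base * (1.0 - u) ** 2)
            if day > 0:
                turns[5] = _UNRAVEL_HINGE[day]
        else:
            turns = np.full(10, base * (1.0 - u))
            turns[5] = base * (1.0 - u) ** 3
        frames.append(_chain_from_turns(turns))
    return ToyTrajectory(coords=np.array(frames), variant=variant)


def mid_loop_contact(distance_matrix: np.ndarray) -> bool:
    """Whether bins 4 and 6 are within the contact threshold, measured in
    units of the structure's own median bond length (scale-free)."""
    bond = float(np.median(np.diag(distance_matrix, k=1)))
    return bool(distance_matrix[4, 6] <= CONTACT_THRESHOLD_BONDS * bond)


def simulate_hic(
    trajectory: ToyTrajectory,
    gamma: float = DEFAULT_GAMMA,
    noise: str = "none",
    noise_scale: float = 100.0,
    seed: int = 0,
) -> TimeSeriesHiC:
    """Synthetic Hi-C per frame: ``IF = d**(-1/gamma)`` for all pairs.

    ``noise="poisson"`` resamples each entry as ``Poisson(scale * IF)/scale``
    (symmetrized), emulating finite read counts; ``scale`` must be positive.
    """
    rng = np.random.default_rng(seed)
    maps = []
    for k, t in enumerate(trajectory.times):
        matrix = distances_to_contacts(trajectory.distance_matrix(k), gamma)
        if noise == "poisson":
            if noise_scale <= 0:
                raise ValueError("noise_scale must be positive")
            counts = rng.poisson(matrix * noise_scale).astype(float)
            matrix = (counts + counts.T) / (2.0 * noise_scale)
            np.fill_diagonal(matrix, 0.0)
        elif noise != "none":
            raise ValueError(f"unknown noise model {noise!r}")
        maps.append(
            ContactMap(
                matrix=matrix, bin_size=trajectory.bin_size,
                time=float(t), chrom="toy",
            )
        )
    return assemble_series(maps)


def end_to_end_recovery(
    variant: str,
    config: FitConfig | None = None,
    holdout_days=(1, 2, 3, 4),
) -> dict:
    """Full pipeline on one toy variant: simulate noiseless Hi-C, fit,
    re-extract maps at all six days, and run the exclusion experiments.

    Returns a report with per-day reconstruction PCC/SRC, per-holdout
    interpolated PCC/SRC, and the day-3 mid-loop (bins 4/6) contact flags
    of the full-data and day-3-holdout models.
    """
    config = config or FitConfig()
    trajectory = make_toy_trajectory(variant)
    series = simulate_hic(trajectory, gamma=config.gamma)

    restraints = build_restraints(series, gamma=config.gamma)
    structure, trace = fit(restraints, config)

    report: dict = {
        "variant": variant,
        "full": {},
        "holdout": {},
        "loss_trace": trace,
        "contact_day3_full": mid_loop_contact(
            structure.distance_matrix(structure.frame_index(3.0))
        ),
    }
    for cmap in series.maps:
        synth = extract_map(structure, cmap.time, gamma=config.gamma)
        cmp = compare_maps(synth, cmap)
        report["full"][cmap.time] = {"pcc": cmp.pcc, "src": cmp.src}

    for day in holdout_days:
        result = interpolation_experiment(series, float(day), config)
        report["holdout"][float(day)] = result
        if day == 3:
            report["contact_day3_holdout"] = mid_loop_contact(
                result["model_distances"]
            )
    return report
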