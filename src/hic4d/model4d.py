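"""The 4D structure model: likelihood, smoothness penalty, optimizer.

A 4D structure is a ``g x n x 3`` array of bead coordinates — one 3D
conformation of the ``n`` binned chromosome per grid time. Fitting maximizes
a Gaussian restraint likelihood: at an observed time the squared residuals
between model Euclidean distances ``D_it`` and target distances ``H_it``
enter through the profiled log-likelihood, which (dropping additive
constants) is minimized as::

    L_t = (n_t / 2) * log( sum_i (H_it - D_it)^2 / n_t )

where the per-time standard deviation has been profiled out as the RMS
residual. Grid times without data borrow the restraint sets of the flanking
observed times ``a1 < t < a2`` with convex weights ``w1 = (t - a2)/(a1 -
a2)``, ``w2 = 1 - w1``. A smoothness penalty — the summed squared
displacement of every bead between consecutive frames — weighted by ``eta``
discourages uninformative frame-to-frame rotation. The total objective

    sum_t L_t + eta * D_moves

is minimized by block-coordinate gradient descent: each epoch takes one
gradient step per frame with a per-frame step size that starts at the
learning rate, backtracks on any increase and grows on success, so the
total loss is non-increasing by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DivergenceError
from .restraints import DEFAULT_GAMMA, RestraintSet

__all__ = [
    "Structure4D",
    "FitConfig",
    "FitTrace",
    "init_structure",
    "interpolation_weights",
    "data_loss",
    "smoothness_penalty",
    "total_loss",
    "fit",
    "gradient_check",
]

_TINY = 1e-300  # guards log() against an exactly perfect fit


@dataclass
class Structure4D:
    """Fitted (or ground-truth) coordinates: ``g`` frames x ``n`` bins x 3."""

    coords: np.ndarray
    grid: np.ndarray
    bin_size: int
    chrom: str = "chr"
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.grid = np.asarray(self.grid, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (g, n, 3)")
        if self.coords.shape[0] != len(self.grid):
            raise ValueError("coords frames must match grid length")
        if self.coords.shape[0] < 2 or self.coords.shape[1] < 1:
            raise ValueError("need at least 2 frames and 1 bin")
        if not np.isfinite(self.coords).all():
            raise ValueError("coords contain non-finite values")
        if self.mask is None:
            self.mask = np.zeros(self.n, dtype=bool)

    @property
    def g(self) -> int:
        return self.coords.shape[0]

    @property
    def n(self) -> int:
        return self.coords.shape[1]

    def frame_index(self, time: float, tol: float | None = None) -> int:
        """Grid index nearest ``time``; raises outside the grid range."""
        if time < self.grid[0] - 1e-9 or time > self.grid[-1] + 1e-9:
            raise ValueError(
                f"time {time} outside grid range [{self.grid[0]}, {self.grid[-1]}]"
            )
        k = int(np.argmin(np.abs(self.grid - time)))
        if tol is not None and abs(self.grid[k] - time) > tol:
            raise ValueError(f"no grid time within {tol} of {time}")
        return k

    def distance_matrix(self, frame: int) -> np.ndarray:
        """Pairwise Euclidean distances of one frame (zero diagonal)."""
        x = self.coords[frame]
        return np.linalg.norm(x[:, None, :] - x[None, :, :], axis=-1)

    def copy(self) -> "Structure4D":
        return replace(self, coords=self.coords.copy())

    # ---- text / archive I/O ------------------------------------------------

    def to_xyz(self, path) -> None:
        """Write all frames as multi-frame XYZ; the comment line carries the
        grid time, chromosome and bin size."""
        with open(path, "w") as fh:
            for k in range(self.g):
                fh.write(f"{self.n}\n")
                fh.write(
                    f"t={self.grid[k]:.10g} chrom={self.chrom} "
                    f"bin_size={self.bin_size}\n"
                )
                for x, y, z in self.coords[k]:
                    fh.write(f"C {x:.10g} {y:.10g} {z:.10g}\n")

    @classmethod
    def from_xyz(cls, path) -> "Structure4D":
        frames, grid = [], []
        chrom, bin_size = "chr", 1
        with open(path) as fh:
            lines = fh.read().split("\n")
        pos = 0
        while pos < len(lines) and lines[pos].strip():
            n = int(lines[pos])
            meta = dict(kv.split("=") for kv in lines[pos + 1].split())
            grid.append(float(meta["t"]))
            chrom = meta.get("chrom", chrom)
            bin_size = int(meta.get("bin_size", bin_size))
            block = [lines[pos + 2 + i].split()[1:4] for i in range(n)]
            frames.append(np.array(block, dtype=float))
            pos += 2 + n
        return cls(
            coords=np.array(frames), grid=np.array(grid),
            bin_size=bin_size, chrom=chrom,
        )

    def save_npz(self, path) -> None:
        np.savez(
            path, coords=self.coords, grid=self.grid,
            bin_size=self.bin_size, chrom=self.chrom, mask=self.mask,
        )

    @classmethod
    def load_npz(cls, path) -> "Structure4D":
        data = np.load(path, allow_pickle=False)
        return cls(
            coords=data["coords"], grid=data["grid"],
            bin_size=int(data["bin_size"]), chrom=str(data["chrom"]),
            mask=data["mask"],
        )


@dataclass
class FitConfig:
    """Hyperparameters of the optimizer.

    ``learning_rate`` (the initial per-frame step) and ``smoothness_weight``
    default to 1e-4 and 1000; 400 epochs suffice on the problem sizes the
    tool targets. ``half_n_weighting`` keeps the ``n_t/2`` coefficient of the
    Gaussian log-likelihood in front of each per-time loss term; without it
    the per-time terms are plain ``log(SSR/n_t)``. ``interp_mode`` selects
    how unobserved grid times borrow data: ``"blend_losses"`` forms the
    convex combination of the two flanking log-losses, ``"blend_targets"``
    fits the frame against linearly interpolated target distances.
    """

    learning_rate: float = 1e-4
    smoothness_weight: float = 1000.0
    epochs: int = 400
    seed: int = 0
    gamma: float = DEFAULT_GAMMA
    half_n_weighting: bool = True
    interp_mode: str = "blend_losses"
    shared_init: bool = True
    max_backtracks: int = 40
    step_growth: float = 1.25

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.smoothness_weight < 0:
            raise ValueError("smoothness_weight must be non-negative")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.interp_mode not in ("blend_losses", "blend_targets"):
            raise ValueError(f"unknown interp_mode {self.interp_mode!r}")


@dataclass
class FitTrace:
    """Per-epoch record of the objective decomposition."""

    total: np.ndarray
    data: np.ndarray
    penalty: np.ndarray

    def __len__(self) -> int:
        return len(self.total)


def interpolation_weights(t: float, a1: float, a2: float) -> tuple[float, float]:
    """Convex weights of the flanking observed times for an interior time.

    ``w1 = (t - a2) / (a1 - a2)`` and ``w2 = 1 - w1``; requires
    ``a1 < t < a2``.
    """
    if not (a1 < t < a2):
        raise ValueError(f"need a1 < t < a2, got a1={a1}, t={t}, a2={a2}")
    w1 = (t - a2) / (a1 - a2)
    return float(w1), float(1.0 - w1)


def _frame_components(
    restraints: RestraintSet, interp_mode: str
) -> list[list[tuple[np.ndarray, np.ndarray, np.ndarray, float]]]:
    """Per grid index, the list of ``(i, j, targets, weight)`` loss terms."""
    comps: list[list] = []
    for k in range(restraints.granularity):
        if k in restraints.by_grid_index:
            i, j, d = restraints.by_grid_index[k]
            comps.append([(i, j, d, 1.0)])
            continue
        k1, k2 = restraints.flanking_observed(k)
        w1, w2 = interpolation_weights(
            restraints.grid[k], restraints.grid[k1], restraints.grid[k2]
        )
        i1, j1, d1 = restraints.by_grid_index[k1]
        i2, j2, d2 = restraints.by_grid_index[k2]
        if interp_mode == "blend_losses":
            comps.append([(i1, j1, d1, w1), (i2, j2, d2, w2)])
        else:  # blend_targets: union of pairs, weighted-average distance
            merged: dict[tuple[int, int], float] = {}
            weight: dict[tuple[int, int], float] = {}
            for (ii, jj, dd, ww) in ((i1, j1, d1, w1), (i2, j2, d2, w2)):
                for a, b, v in zip(ii, jj, dd):
                    key = (int(a), int(b))
                    merged[key] = merged.get(key, 0.0) + ww * v
                    weight[key] = weight.get(key, 0.0) + ww
            pairs = sorted(merged)
            i = np.array([p[0] for p in pairs])
            j = np.array([p[1] for p in pairs])
            d = np.array([merged[p] / weight[p] for p in pairs])
            comps.append([(i, j, d, 1.0)])
    return comps


def _component_loss_grad(x, i, j, d, weight, half_n, want_grad=True):
    """Loss (and gradient wrt one frame's coords) of one restraint term."""
    diff = x[i] - x[j]
    dist = np.linalg.norm(diff, axis=1)
    nt = len(d)
    r = dist - d
    ssr = float(r @ r)
    pref = weight * (nt / 2.0 if half_n else 1.0)
    loss = pref * np.log(max(ssr, _TINY) / nt)
    if not want_grad:
        return loss, None
    coef = pref * (2.0 / max(ssr, _TINY)) * r / np.maximum(dist, 1e-12)
    contrib = coef[:, None] * diff
    grad = np.zeros_like(x)
    np.add.at(grad, i, contrib)
    np.add.at(grad, j, -contrib)
    return loss, grad


def data_loss(
    structure: Structure4D,
    restraints: RestraintSet,
    t_index: int,
    *,
    weighted: bool = False,
    interp_mode: str = "blend_losses",
) -> float:
    """Per-time data loss at one grid index.

    For an observed time this is ``log(sum (H - D)^2 / n_t)``; for an
    unobserved time the convex combination of the two flanking losses (or
    the loss against blended targets, per ``interp_mode``). ``weighted``
    applies the ``n_t/2`` likelihood coefficient used by the optimizer.
    """
    comps = _frame_components(restraints, interp_mode)[t_index]
    x = structure.coords[t_index]
    return float(sum(
        _component_loss_grad(x, i, j, d, w, weighted, want_grad=False)[0]
        for (i, j, d, w) in comps
    ))


def smoothness_penalty(structure: Structure4D) -> float:
    """Summed squared per-bead displacement between consecutive frames."""
    dm = np.diff(structure.coords, axis=0)
    return float((dm * dm).sum())


def total_loss(
    structure: Structure4D, restraints: RestraintSet, config: FitConfig
) -> float:
    """Full objective: summed per-time data losses plus the weighted
    smoothness penalty."""
    comps = _frame_components(restraints, config.interp_mode)
    loss = sum(
        _component_loss_grad(
            structure.coords[k], i, j, d, w, config.half_n_weighting,
            want_grad=False,
        )[0]
        for k, frame_comps in enumerate(comps)
        for (i, j, d, w) in frame_comps
    )
    return float(loss + config.smoothness_weight * smoothness_penalty(structure))


def _total_gradient(
    coords: np.ndarray, comps, eta: float, half_n: bool
) -> np.ndarray:
    grad = np.zeros_like(coords)
    for k, frame_comps in enumerate(comps):
        for (i, j, d, w) in frame_comps:
            _, g = _component_loss_grad(coords[k], i, j, d, w, half_n)
            grad[k] += g
    dm = np.diff(coords, axis=0)
    grad[:-1] -= 2.0 * eta * dm
    grad[1:] += 2.0 * eta * dm
    return grad


def init_structure(restraints: RestraintSet, seed: int = 0) -> Structure4D:
    """Random unfolded start: coordinates i.i.d. uniform on (0, 1), one draw
    per bin shared across all frames so the initial motion penalty is zero."""
    rng = np.random.default_rng(seed)
    base = rng.random((restraints.n, 3))
    coords = np.repeat(base[None, :, :], restraints.granularity, axis=0)
    return Structure4D(
        coords=coords.copy(), grid=restraints.grid.copy(),
        bin_size=restraints.bin_size, chrom=restraints.chrom,
        mask=restraints.mask.copy(),
    )


def fit(
    restraints: RestraintSet, config: FitConfig | None = None
) -> tuple[Structure4D, FitTrace]:
    """Minimize the total loss by per-frame gradient steps with backtracking.

    Each epoch sweeps the frames in order; a frame's step is accepted only if
    it lowers that frame's share of the objective (its data terms plus the
    motion penalty against its current neighbours), so the recorded total
    loss never increases. The per-frame step starts at ``learning_rate``,
    halves on rejection and grows by ``step_growth`` on acceptance.
    """
    config = config or FitConfig()
    comps = _frame_components(restraints, config.interp_mode)
    structure = init_structure(restraints, config.seed)
    X = structure.coords
    g = structure.g
    eta = config.smoothness_weight
    half_n = config.half_n_weighting
    alpha = np.full(g, config.learning_rate)

    def frame_obj(k, x, want_grad):
        loss = 0.0
        grad = np.zeros_like(x) if want_grad else None
        for (i, j, d, w) in comps[k]:
            l, gr = _component_loss_grad(x, i, j, d, w, half_n, want_grad)
            loss += l
            if want_grad:
                grad += gr
        if k > 0:
            dm = x - X[k - 1]
            loss += eta * float((dm * dm).sum())
            if want_grad:
                grad += 2.0 * eta * dm
        if k < g - 1:
            dm = x - X[k + 1]
            loss += eta * float((dm * dm).sum())
            if want_grad:
                grad += 2.0 * eta * dm
        return loss, grad

    totals, datas, penalties = [], [], []
    for epoch in range(config.epochs):
        for k in range(g):
            l0, grad = frame_obj(k, X[k], True)
            if not np.isfinite(l0):
                raise DivergenceError(epoch)
            for _ in range(config.max_backtracks):
                candidate = X[k] - alpha[k] * grad
                lc, _ = frame_obj(k, candidate, False)
                if np.isfinite(lc) and lc <= l0:
                    X[k] = candidate
                    alpha[k] *= config.step_growth
                    break
                alpha[k] *= 0.5
        pen = float((np.diff(X, axis=0) ** 2).sum())
        dat = sum(
            _component_loss_grad(X[k], i, j, d, w, half_n, want_grad=False)[0]
            for k in range(g)
            for (i, j, d, w) in comps[k]
        )
        tot = dat + eta * pen
        if not np.isfinite(tot):
            raise DivergenceError(epoch)
        totals.append(tot)
        datas.append(dat)
        penalties.append(pen)

    structure.coords = X
    trace = FitTrace(
        total=np.array(totals), data=np.array(datas), penalty=np.array(penalties)
    )
    return structure, trace


def gradient_check(
    structure: Structure4D,
    restraints: RestraintSet,
    config: FitConfig | None = None,
    h: float = 1e-6,
) -> float:
    """Max relative discrepancy between the analytic gradient of the total
    loss and central finite differences. Intended for small instances."""
    config = config or FitConfig()
    comps = _frame_components(restraints, config.interp_mode)
    coords = structure.coords.copy()
    analytic = _total_gradient(
        coords, comps, config.smoothness_weight, config.half_n_weighting
    )
    numeric = np.zeros_like(coords)
    probe = structure.copy()
    flat = probe.coords.reshape(-1)
    for idx in range(flat.size):
        orig = flat[idx]
        flat[idx] = orig + h
        up = total_loss(probe, restraints, config)
        flat[idx] = orig - h
        down = total_loss(probe, restraints, config)
        flat[idx] = orig
        numeric.reshape(-1)[idx] = (up - down) / (2 * h)
    denom = np.maximum(np.maximum(np.abs(analytic), np.abs(numeric)), 1e-6)
    return float(np.max(np.abs(analytic - numeric) / denom))
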