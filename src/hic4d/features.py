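"""Higher-order Hi-C features: A/B compartments and TAD borders.

Compartments follow the classic eigenvector pipeline: distance-normalize
the map (observed over expected), take the Pearson correlation matrix of
its rows, and call the sign of the first principal component — positive
bins form the A (active) compartment, negative the B (inactive)
compartment. The PC sign is intrinsically arbitrary; profiles are oriented
so that PC1 correlates positively with the per-bin total O/E signal.

TADs use the directionality index: for each bin, the contrast between
contact sums into the upstream window A and the downstream window B
(default 2 Mb each, truncated at chromosome ends)::

    DI = sign(B - A) * ((A - E)^2 / E + (B - E)^2 / E),   E = (A + B) / 2

A three-state Gaussian hidden Markov model (downstream-bias / none /
upstream-bias) is fitted to the DI track by EM and decoded with Viterbi;
a TAD border is placed at each transition into a downstream-biased run,
the conventional signature of a domain start.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from hmmlearn.hmm import GaussianHMM
from sklearn.decomposition import PCA

from .contact_io import ContactMap
from .errors import DegenerateDataError

__all__ = [
    "CompartmentProfile",
    "DirectionalityTrack",
    "TadSet",
    "oe_matrix",
    "ab_compartments",
    "compartment_trajectory",
    "directionality_index",
    "call_tads",
    "tad_border_overlap",
    "rebin_profile",
]

DEFAULT_DI_WINDOW_BP = 2_000_000
DEFAULT_BORDER_TOL_BINS = 3


@dataclass
class CompartmentProfile:
    """Per-bin PC1 values and A/B sign calls at one time point."""

    pc1: np.ndarray
    signs: np.ndarray  # "A", "B" or "" for masked bins
    explained_variance: float
    mask: np.ndarray
    time: float = float("nan")

    def sign_vector(self) -> np.ndarray:
        """Numeric encoding A=+1, B=-1, masked=0."""
        out = np.zeros(len(self.pc1))
        out[self.signs == "A"] = 1.0
        out[self.signs == "B"] = -1.0
        return out


@dataclass
class DirectionalityTrack:
    di: np.ndarray
    window_bp: int
    bin_size: int


@dataclass
class TadSet:
    borders: np.ndarray  # sorted bin indices
    states: np.ndarray  # "downstream", "none", "upstream" per bin
    converged: bool = True


def oe_matrix(cmap: ContactMap) -> np.ndarray:
    """Observed-over-expected matrix.

    The expected value of entry (i, j) is the mean contact frequency over
    all unmasked pairs at the same genomic separation ``|i - j|``. Entries
    on diagonals with zero expected value, and masked rows/columns, are 0.
    """
    n = cmap.n
    unmasked = ~cmap.mask
    if unmasked.sum() < 3:
        raise DegenerateDataError("need at least 3 unmasked bins")
    if not cmap.matrix[np.ix_(unmasked, unmasked)].any():
        raise DegenerateDataError("all-zero contact map")
    oe = np.zeros_like(cmap.matrix)
    idx = np.arange(n)
    sep = np.abs(idx[:, None] - idx[None, :])
    pair_ok = unmasked[:, None] & unmasked[None, :]
    for s in range(n):
        sel = (sep == s) & pair_ok
        if not sel.any():
            continue
        expected = cmap.matrix[sel].mean()
        if expected > 0:
            oe[sel] = cmap.matrix[sel] / expected
    return oe


def ab_compartments(cmap: ContactMap) -> CompartmentProfile:
    """Call A/B compartments from the PC1 of the O/E correlation matrix."""
    oe = oe_matrix(cmap)
    unmasked = np.where(~cmap.mask)[0]
    sub = oe[np.ix_(unmasked, unmasked)]
    if np.allclose(sub.std(axis=1), 0):
        raise DegenerateDataError("constant O/E rows: correlation undefined")
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(sub)
    corr = np.nan_to_num(corr, nan=0.0)

    pca = PCA(n_components=1)
    scores = pca.fit_transform(corr)[:, 0]
    # orient: PC1 should correlate positively with per-bin total O/E signal
    strength = sub.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        orient = np.corrcoef(scores, strength)[0, 1]
    if np.isfinite(orient) and orient < 0:
        scores = -scores

    pc1 = np.zeros(cmap.n)
    pc1[unmasked] = scores
    signs = np.full(cmap.n, "", dtype=object)
    signs[unmasked] = np.where(scores > 0, "A", "B")
    return CompartmentProfile(
        pc1=pc1,
        signs=np.asarray(signs),
        explained_variance=float(pca.explained_variance_ratio_[0]),
        mask=cmap.mask.copy(),
        time=cmap.time,
    )


def compartment_trajectory(profiles: list[CompartmentProfile]) -> np.ndarray:
    """Project the time series of A/B sign vectors onto their first two
    principal components; returns one 2D point per time point."""
    if len(profiles) < 3:
        raise DegenerateDataError("need at least 3 profiles for a trajectory")
    lengths = {len(p.pc1) for p in profiles}
    if len(lengths) != 1:
        raise ValueError("profiles have unequal bin counts")
    signs = np.stack([p.sign_vector() for p in profiles])
    return PCA(n_components=2).fit_transform(signs)


def rebin_profile(pc1: np.ndarray, factor: int = 2) -> np.ndarray:
    """Average ``factor`` consecutive PC1 values (e.g. 50 kb -> 100 kb);
    a trailing remainder is averaged as a final partial group."""
    edges = np.arange(0, len(pc1), factor)
    return np.array([pc1[s:s + factor].mean() for s in edges])


def directionality_index(
    cmap: ContactMap, window_bp: int = DEFAULT_DI_WINDOW_BP
) -> DirectionalityTrack:
    """Per-bin directionality index over symmetric up/downstream windows.

    Windows are truncated at the chromosome ends, so every bin keeps a
    value. DI is 0 where the two sums are equal (including empty bins).
    """
    if window_bp < cmap.bin_size:
        raise ValueError("window must be at least one bin wide")
    w = max(1, window_bp // cmap.bin_size)
    n = cmap.n
    di = np.zeros(n)
    for i in range(n):
        a = float(cmap.matrix[i, max(0, i - w):i].sum())
        b = float(cmap.matrix[i, i + 1:min(n, i + w + 1)].sum())
        e = (a + b) / 2.0
        if e <= 0 or a == b:
            continue
        di[i] = np.sign(b - a) * ((a - e) ** 2 / e + (b - e) ** 2 / e)
    return DirectionalityTrack(di=di, window_bp=window_bp, bin_size=cmap.bin_size)


def call_tads(
    track: DirectionalityTrack, seed: int = 0, n_iter: int = 200
) -> TadSet:
    """Decode TAD borders from the DI track with a 3-state Gaussian HMM.

    States are initialized at means (-s, 0, +s) with s = std(DI), shared
    variance and uniform transitions, fitted by EM and decoded by Viterbi.
    Deterministic for a given seed. If EM fails to converge within
    ``n_iter`` iterations the best-so-far decoding is returned with
    ``converged=False``.
    """
    di = np.asarray(track.di, dtype=float)
    if not np.isfinite(di).all():
        raise ValueError("DI track contains non-finite values")
    s = float(di.std())
    if s == 0:  # featureless track: nothing to segment
        return TadSet(
            borders=np.array([], dtype=int),
            states=np.full(len(di), "none", dtype=object),
        )

    model = GaussianHMM(
        n_components=3,
        covariance_type="tied",
        init_params="",
        params="stmc",
        n_iter=n_iter,
        random_state=seed,
    )
    model.startprob_ = np.full(3, 1.0 / 3.0)
    model.transmat_ = np.full((3, 3), 1.0 / 3.0)
    model.means_ = np.array([[-s], [0.0], [s]])
    model.covars_ = np.array([[s ** 2]])
    obs = di.reshape(-1, 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(obs)
        converged = bool(model.monitor_.converged)
        if not converged:
            warnings.warn("TAD HMM did not converge; using best-so-far fit")
        hidden = model.predict(obs)

    order = np.argsort(model.means_[:, 0])  # ascending mean
    label = np.full(3, "none", dtype=object)
    label[order[0]] = "upstream"  # most negative mean: upstream-biased
    label[order[2]] = "downstream"
    states = label[hidden]

    borders = [
        i for i in range(1, len(states))
        if states[i] == "downstream" and states[i - 1] != "downstream"
    ]
    return TadSet(
        borders=np.array(borders, dtype=int),
        states=states,
        converged=converged,
    )


def tad_border_overlap(
    set_a: TadSet, set_b: TadSet, tol_bins: int = DEFAULT_BORDER_TOL_BINS
) -> float:
    """Percent of borders in ``set_a`` with a border of ``set_b`` within
    ``tol_bins`` bins. Asymmetric when border counts differ."""
    if len(set_a.borders) == 0:
        raise DegenerateDataError("set_a has no borders: overlap undefined")
    if len(set_b.borders) == 0:
        return 0.0
    hits = sum(
        1 for b in set_a.borders
        if np.abs(set_b.borders - b).min() <= tol_bins
    )
    return 100.0 * hits / len(set_a.borders)
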