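import numpy as np
import pytest

from hic4d import (
    ContactMap,
    FitConfig,
    Structure4D,
    assemble_series,
    build_restraints,
    data_loss,
    fit,
    gradient_check,
    init_structure,
    interpolation_weights,
    simulate_hic,
    smoothness_penalty,
    total_loss,
)
from hic4d.model4d import _frame_components
from scipy.stats import spearmanr


def small_restraints(n=6, n_times=3, seed=0, granularity=None):
    """Random dense restraint set on a tiny chromosome."""
    rng = np.random.default_rng(seed)
    maps = []
    for t in range(n_times):
        a = rng.random((n, n)) * 5 + 0.2
        m = (a + a.T) / 2
        np.fill_diagonal(m, 0.0)
        maps.append(ContactMap(matrix=m, bin_size=1000, time=float(t)))
    return build_restraints(assemble_series(maps), granularity=granularity)


class TestInitStructure:
    def test_deterministic_given_seed(self):
        rs = small_restraints()
        a = init_structure(rs, seed=3)
        b = init_structure(rs, seed=3)
        np.testing.assert_array_equal(a.coords, b.coords)

    def test_different_seeds_differ(self):
        rs = small_restraints()
        a = init_structure(rs, seed=0)
        b = init_structure(rs, seed=1)
        assert not np.array_equal(a.coords, b.coords)

    def test_uniform_open_unit_interval_and_shared_frames(self):
        rs = small_restraints()
        s = init_structure(rs, seed=0)
        assert ((s.coords > 0) & (s.coords < 1)).all()
        for k in range(1, s.g):
            np.testing.assert_array_equal(s.coords[k], s.coords[0])


class TestInterpolationWeights:
    def test_midpoint_is_half_half(self):
        assert interpolation_weights(1.0, 0.0, 2.0) == (0.5, 0.5)

    def test_quarter_point(self):
        w1, w2 = interpolation_weights(0.5, 0.0, 2.0)
        assert (w1, w2) == pytest.approx((0.75, 0.25))

    @pytest.mark.parametrize("t", [0.1, 0.9, 1.3, 1.99])
    def test_weights_sum_to_one_and_positive(self, t):
        w1, w2 = interpolation_weights(t, 0.0, 2.0)
        assert w1 + w2 == 1.0
        assert 0 < w1 < 1 and 0 < w2 < 1

    def test_outside_interval_raises(self):
        with pytest.raises(ValueError):
            interpolation_weights(2.5, 0.0, 2.0)


class TestDataLoss:
    def _structure_with_residual(self, rs, r):
        """Shift every bead pair distance residual to roughly r by placing
        beads on a line: easier to use an exact construction on 2 bins."""
        # 2-bin maps: single restraint per time with known target
        return rs

    def test_unit_mean_square_residual_gives_zero(self):
        # two bins, one restraint with target d; place beads at d + 1 apart
        m = np.array([[0.0, 1.0], [1.0, 0.0]])
        maps = [ContactMap(matrix=m, bin_size=10, time=float(t)) for t in (0, 1)]
        rs = build_restraints(assemble_series(maps), granularity=2)
        target = rs.by_grid_index[0][2][0]
        coords = np.zeros((2, 2, 3))
        coords[:, 1, 0] = target + 1.0  # residual exactly 1, n_t = 1
        s = Structure4D(coords=coords, grid=rs.grid, bin_size=10)
        assert data_loss(s, rs, 0) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("r", [0.5, 2.0])
    def test_equal_residuals_closed_form(self, r):
        m = np.array([[0.0, 1.0], [1.0, 0.0]])
        maps = [ContactMap(matrix=m, bin_size=10, time=float(t)) for t in (0, 1)]
        rs = build_restraints(assemble_series(maps), granularity=2)
        target = rs.by_grid_index[0][2][0]
        coords = np.zeros((2, 2, 3))
        coords[:, 1, 0] = target + r
        s = Structure4D(coords=coords, grid=rs.grid, bin_size=10)
        assert data_loss(s, rs, 0) == pytest.approx(2 * np.log(abs(r)), rel=1e-9)

    def test_halving_residuals_decreases_loss(self):
        rs = small_restraints()
        s = init_structure(rs, seed=0)
        base = data_loss(s, rs, 0)
        # move each frame halfway toward satisfying its restraints is hard to
        # construct exactly; instead scale residuals via a 2-bin instance
        m = np.array([[0.0, 1.0], [1.0, 0.0]])
        maps = [ContactMap(matrix=m, bin_size=10, time=float(t)) for t in (0, 1)]
        rs2 = build_restraints(assemble_series(maps), granularity=2)
        target = rs2.by_grid_index[0][2][0]
        losses = []
        for r in (1.0, 0.5):
            coords = np.zeros((2, 2, 3))
            coords[:, 1, 0] = target + r
            s2 = Structure4D(coords=coords, grid=rs2.grid, bin_size=10)
            losses.append(data_loss(s2, rs2, 0))
        assert losses[1] < losses[0]
        assert np.isfinite(base)

    def test_unobserved_frame_blends_flanking_losses(self):
        rs = small_restraints(n_times=2, granularity=3)  # middle grid time unobserved
        s = init_structure(rs, seed=0)
        blended = data_loss(s, rs, 1)
        left = data_loss(s, rs, 0)
        # frames identical at init, so the blend of the two observed losses
        # evaluated on the same coordinates brackets the result
        right = data_loss(s, rs, 2)
        assert min(left, right) <= blended <= max(left, right)


class TestSmoothnessPenalty:
    def make(self, coords):
        return Structure4D(
            coords=np.asarray(coords, float),
            grid=np.arange(len(coords), dtype=float), bin_size=10,
        )

    def test_identical_frames_zero(self):
        s = self.make(np.zeros((3, 4, 3)))
        assert smoothness_penalty(s) == 0.0

    def test_unit_step_single_bin(self):
        c = np.zeros((2, 2, 3))
        c[1, 0, 0] = 1.0
        assert smoothness_penalty(self.make(c)) == pytest.approx(1.0)

    def test_three_frame_closed_form(self):
        c = np.zeros((3, 2, 3))
        c[:, 0, 0] = [0.0, 1.0, 3.0]  # steps of 1 and 2 -> 1 + 4
        assert smoothness_penalty(self.make(c)) == pytest.approx(5.0)


class TestGradient:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_finite_differences(self, seed):
        rs = small_restraints(n=5, n_times=2, seed=seed, granularity=4)
        s = init_structure(rs, seed=seed)
        s.coords += np.random.default_rng(seed).normal(0, 0.1, s.coords.shape)
        assert gradient_check(s, rs, FitConfig()) < 1e-4

    def test_penalty_gradient_linear_in_eta(self):
        from hic4d.model4d import _total_gradient

        rs = small_restraints(n=5, n_times=2, granularity=4)
        s = init_structure(rs, seed=0)
        s.coords += np.random.default_rng(0).normal(0, 0.1, s.coords.shape)
        comps = _frame_components(rs, "blend_losses")
        g0 = _total_gradient(s.coords, comps, 0.0, True)
        g1 = _total_gradient(s.coords, comps, 1.0, True)
        g2 = _total_gradient(s.coords, comps, 2.0, True)
        np.testing.assert_allclose(g2 - g0, 2 * (g1 - g0), atol=1e-10)

    def test_zero_eta_decouples_frames(self):
        """With eta=0 the gradient of one frame ignores all other frames."""
        from hic4d.model4d import _total_gradient

        rs = small_restraints(n=5, n_times=2, granularity=2)
        s = init_structure(rs, seed=0)
        comps = _frame_components(rs, "blend_losses")
        before = _total_gradient(s.coords, comps, 0.0, True)[0]
        perturbed = s.coords.copy()
        perturbed[1] += 0.3
        after = _total_gradient(perturbed, comps, 0.0, True)[0]
        np.testing.assert_array_equal(before, after)


class TestFit:
    def test_static_structure_recovery(self, static_series):
        """Restraints from one frozen conformation: the fitted model's
        distances should rank-match the targets at every frame."""
        rs = build_restraints(static_series)
        structure, trace = fit(rs, FitConfig(seed=0))
        for k in range(structure.g):
            i, j, d = rs.by_grid_index[k]
            model = structure.distance_matrix(k)[i, j]
            src = spearmanr(model, d).statistic
            assert src >= 0.95

    def test_loss_decreases_from_first_epoch(self, unravel_restraints):
        _, trace = fit(unravel_restraints, FitConfig(seed=0))
        assert trace.total[-1] < trace.total[0]

    def test_deterministic_given_seed(self):
        rs = small_restraints()
        a, _ = fit(rs, FitConfig(epochs=30, seed=5))
        b, _ = fit(rs, FitConfig(epochs=30, seed=5))
        np.testing.assert_array_equal(a.coords, b.coords)

    def test_invariance_of_loss_under_rigid_motion(self):
        """Global rotation + translation applied to every frame leaves both
        the data loss and the motion penalty unchanged."""
        rs = small_restraints()
        s = init_structure(rs, seed=0)
        s.coords += np.random.default_rng(0).normal(0, 0.05, s.coords.shape)
        cfg = FitConfig()
        base = total_loss(s, rs, cfg)
        theta = 0.7
        rot = np.array([
            [np.cos(theta), -np.sin(theta), 0],
            [np.sin(theta), np.cos(theta), 0],
            [0, 0, 1],
        ])
        moved = s.copy()
        moved.coords = s.coords @ rot.T + np.array([1.0, -2.0, 0.5])
        assert total_loss(moved, rs, cfg) == pytest.approx(base, rel=1e-9)
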