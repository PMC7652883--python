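"""Random starts, staticness detection, long runs and the stable-state census."""

import numpy as np
import pytest

from nednsim import (
    Composition,
    ModelParams,
    RawState,
    Trajectory,
    census,
    is_static,
    nedn_step,
    random_compositions,
    run_to_stability,
)
from nednsim.stability import bray_curtis
from tests.conftest import biased_starts


class TestRandomCompositions:
    def test_draws_live_on_the_simplex(self):
        for c in random_compositions(50, 5, seed=0):
            assert c.values.sum() == pytest.approx(1.0, abs=1e-12)
            # floored entries may land epsilon below 1e-6 after renormalization
            assert np.all(c.values >= 1e-6 * 0.999)

    def test_deterministic_given_seed(self):
        a = random_compositions(10, 13, shape=0.2, seed=3)
        b = random_compositions(10, 13, shape=0.2, seed=3)
        assert all(np.array_equal(x.values, y.values) for x, y in zip(a, b))

    def test_small_shape_gives_sparser_communities(self):
        """Monte-Carlo check: shape 0.2 concentrates mass on few genera,
        so its expected maximum coordinate beats shape 10's."""
        sparse = random_compositions(1000, 13, shape=0.2, seed=1)
        dense = random_compositions(1000, 13, shape=10.0, seed=2)
        max_sparse = np.mean([c.values.max() for c in sparse])
        max_dense = np.mean([c.values.max() for c in dense])
        assert max_sparse > max_dense + 0.2

    @pytest.mark.parametrize("n,k,shape", [(0, 5, 0.2), (5, 1, 0.2), (5, 5, 0.0)])
    def test_invalid_arguments_rejected(self, n, k, shape):
        with pytest.raises(ValueError):
            random_compositions(n, k, shape=shape, seed=0)


class TestIsStatic:
    def test_constant_trajectory_is_static(self):
        values = np.tile([0.3, 0.5], (150, 1))
        traj = Trajectory(("a", "b"), np.arange(150), values)
        assert is_static(traj)

    def test_oscillation_is_not_static(self):
        values = np.tile([0.3, 0.5], (150, 1))
        values[::2, 0] += 0.1
        traj = Trajectory(("a", "b"), np.arange(150), values)
        assert not is_static(traj)

    def test_tiny_drift_decided_by_explicit_variance_formula(self):
        """A 1e-8/day linear drift over the window: the oracle is the
        direct variance of an arithmetic progression."""
        window = 100
        drift = 1e-8 * np.arange(window)
        values = np.column_stack([0.3 + drift, 0.5 - drift])
        traj = Trajectory(("a", "b"), np.arange(window), values)
        var = drift.var()
        expected = 2 * var**2 < 1e-20
        assert is_static(traj, window=window) == expected
        # and the decision flips at a threshold straddling the statistic
        assert is_static(traj, window=window, threshold=2 * var**2 * 1.01)
        assert not is_static(traj, window=window, threshold=2 * var**2 * 0.99)

    def test_window_longer_than_trajectory_rejected(self):
        traj = Trajectory(("a",), np.arange(10), np.full((10, 1), 0.5))
        with pytest.raises(ValueError, match="window"):
            is_static(traj, window=100)

    def test_per_genus_reading_is_weaker_than_sum_reading(self):
        # amplitude chosen so each var^2 ~ 0.7e-20 but the sum exceeds 1e-20
        a = (0.7e-20) ** 0.25
        values = np.tile([0.3, 0.5], (150, 1))
        values[::2] += a
        values[1::2] -= a
        traj = Trajectory(("a", "b"), np.arange(150), values)
        assert not is_static(traj)
        assert is_static(traj, per_genus=True)


class TestRunToStability:
    def test_zero_dynamics_static_at_day_400(self):
        p = ModelParams(("a", "b"), np.zeros(2), np.zeros((2, 2)))
        x0 = Composition(("a", "b"), np.array([0.3, 0.6]))
        stable, traj = run_to_stability(x0, p)
        assert stable is not None
        assert len(traj) == 401
        assert np.array_equal(stable.values, x0.values)

    def test_logistic_fixed_point_reached(self):
        p = ModelParams(("a",), np.array([0.5]), np.zeros((1, 1)))
        stable, _ = run_to_stability(Composition(("a",), np.array([0.1])), p)
        assert stable is not None
        assert stable.values[0] == pytest.approx(1.0, abs=1e-9)

    def test_glv_oscillation_stays_unresolved(self):
        """The unconstrained map x(1 + 2.5(1-x)) cycles around its fixed
        point; without the overflow normalization it never settles."""
        p = ModelParams(("a",), np.array([2.5]), np.zeros((1, 1)))
        x0 = RawState(("a",), np.array([0.1]))
        stable, traj = run_to_stability(x0, p, model="glv", max_days=2000)
        assert stable is None
        assert len(traj) == 2001

    def test_normalization_absorbs_the_same_oscillation(self):
        """Under the floored/normalized update the overflow branch clamps
        the state to 1, which is a fixed point, so the run is static."""
        p = ModelParams(("a",), np.array([2.5]), np.zeros((1, 1)))
        stable, _ = run_to_stability(Composition(("a",), np.array([0.1])), p)
        assert stable is not None
        assert stable.values[0] == 1.0


def test_bray_curtis_matches_textbook_formula_on_hand_cases():
    u = np.array([0.5, 0.3, 0.2])
    v = np.array([0.2, 0.3, 0.5])
    # sum|u-v| = 0.6, sum(u+v) = 2.0
    assert bray_curtis(u, v) == pytest.approx(0.3, abs=1e-15)
    assert bray_curtis(u, u) == 0.0
    from scipy.spatial.distance import braycurtis

    assert bray_curtis(u, v) == pytest.approx(braycurtis(u, v), abs=1e-15)


class TestCensus:
    def test_identical_starts_collapse_to_one_status(self, two_basin_system):
        starts = [Composition(two_basin_system.genera,
                              np.array([0.4, 0.3, 0.2, 0.1]))] * 5
        result = census(starts, two_basin_system)
        assert result.n_statuses == 1
        assert result.frequencies.tolist() == [5]

    def test_two_basins_yield_two_statuses_with_basin_counts(self, two_basin_system):
        starts = biased_starts(12, 8, seed=0)
        result = census(starts, two_basin_system)
        # independent oracle: classify each start by its own simulation
        expected = []
        for s in starts:
            stable, _ = run_to_stability(s, two_basin_system)
            expected.append(0 if stable.values[:2].sum() > stable.values[2:].sum() else 1)
        assert result.n_statuses == 2
        assert sorted(result.frequencies.tolist(), reverse=True) == sorted(
            [expected.count(0), expected.count(1)], reverse=True
        )
        assert result.frequencies.tolist() == sorted(
            result.frequencies.tolist(), reverse=True
        )

    def test_every_stable_state_is_a_fixed_point(self, two_basin_system):
        starts = biased_starts(4, 4, seed=1)
        result = census(starts, two_basin_system)
        for s in result.stable_states:
            residual = np.abs(nedn_step(s, two_basin_system).values - s.values)
            assert residual.max() < 1e-8

    def test_grouping_invariant_under_start_order(self, two_basin_system):
        starts = biased_starts(6, 4, seed=2)
        a = census(starts, two_basin_system)
        b = census(starts[::-1], two_basin_system)
        assert a.frequencies.tolist() == b.frequencies.tolist()
        assert a.dominant_genus == b.dominant_genus

    def test_census_is_reproducible(self, two_basin_system):
        starts = biased_starts(5, 5, seed=3)
        a = census(starts, two_basin_system)
        b = census(starts, two_basin_system)
        assert np.array_equal(a.status_labels, b.status_labels)
        for pa, pb in zip(a.status_profiles, b.status_profiles):
            assert np.array_equal(pa.values, pb.values)

    def test_dominant_genus_labels_match_profiles(self, two_basin_system):
        starts = biased_starts(3, 3, seed=4)
        result = census(starts, two_basin_system)
        for profile, dom in zip(result.status_profiles, result.dominant_genus):
            assert profile.genera[int(np.argmax(profile.values))] == dom
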