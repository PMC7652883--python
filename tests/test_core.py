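"""Daily-update rules: hand oracles, invariants, and serialization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nednsim import (
    FLOOR,
    Composition,
    GenusMismatchError,
    ModelParams,
    RawState,
    Trajectory,
    defecation_step,
    glv_step,
    growth_step,
    nedn_step,
    simulate,
)


def zero_params(k=2, genera=None):
    genera = genera or tuple("ab"[:k]) if k <= 2 else tuple(f"g{i}" for i in range(k))
    return ModelParams(genera, np.zeros(k), np.zeros((k, k)))


class TestGrowthStep:
    def test_zero_dynamics_is_identity(self):
        x = Composition(("a", "b"), np.array([0.3, 0.7]))
        assert np.allclose(growth_step(x, zero_params()).values, [0.3, 0.7])

    def test_floor_engages_when_bracket_goes_negative(self):
        # 0.5 * (1 - 3*0.5) = -0.25 < 1e-6 for both genera
        p = ModelParams(("a", "b"), np.array([-3.0, -3.0]), np.zeros((2, 2)))
        x = Composition(("a", "b"), np.array([0.5, 0.5]))
        assert np.array_equal(growth_step(x, p).values, [FLOOR, FLOOR])

    def test_hand_oracle(self, two_genus_state, two_genus_params):
        # g1 = 0.4*(1 + 0.5*0.6 + 0.2*0.1), g2 = 0.2*(1 + 0.25*0.8 + 0.4*(-0.2))
        g = growth_step(two_genus_state, two_genus_params)
        assert np.allclose(g.values, [0.528, 0.224], atol=1e-15)

    def test_genus_mismatch_rejected(self, two_genus_params):
        x = Composition(("b", "a"), np.array([0.4, 0.2]))
        with pytest.raises(GenusMismatchError):
            growth_step(x, two_genus_params)


class TestDefecationStep:
    @pytest.mark.parametrize(
        "g_in,expected",
        [
            ([0.3, 0.4], [0.3, 0.4]),  # total 0.7 <= 1: identity
            ([0.8, 0.6], [0.8 / 1.4, 0.6 / 1.4]),  # total 1.4: divided down
        ],
    )
    def test_normalization_rule(self, g_in, expected):
        out = defecation_step(RawState(("a", "b"), np.array(g_in)))
        assert np.allclose(out.values, expected, atol=1e-15)

    def test_single_genus_at_exactly_one(self):
        out = defecation_step(RawState(("a",), np.array([1.0])))
        assert out.values[0] == 1.0

    def test_nonpositive_entry_rejected(self):
        with pytest.raises(ValueError, match="floor"):
            defecation_step(RawState(("a", "b"), np.array([0.5, -0.1])))


class TestNednStep:
    def test_composed_identity(self):
        x = Composition(("a", "b"), np.array([0.3, 0.7]))
        assert np.allclose(nedn_step(x, zero_params()).values, [0.3, 0.7])

    def test_hand_oracle_no_normalization(self, two_genus_state, two_genus_params):
        # total growth 0.752 <= 1, so defecation leaves the state unchanged
        out = nedn_step(two_genus_state, two_genus_params)
        assert np.allclose(out.values, [0.528, 0.224], atol=1e-15)

    def test_overflow_normalized_to_exactly_one(self):
        p = ModelParams(("a", "b"), np.array([3.0, 3.0]), np.zeros((2, 2)))
        x = Composition(("a", "b"), np.array([0.5, 0.4]))
        assert nedn_step(x, p).total == pytest.approx(1.0, abs=1e-15)


class TestGlvStep:
    def test_no_floor_allows_negative_abundance(self):
        p = ModelParams(("a", "b"), np.array([-3.0, -3.0]), np.zeros((2, 2)))
        x = RawState(("a", "b"), np.array([0.5, 0.5]))
        assert np.allclose(glv_step(x, p).values, [-0.25, -0.25], atol=1e-15)

    def test_nonfinite_input_rejected(self, two_genus_params):
        with pytest.raises(ValueError, match="finite"):
            glv_step(RawState(("a", "b"), np.array([np.inf, 0.1])), two_genus_params)


composition_values = st.lists(
    st.floats(1e-4, 1.0), min_size=3, max_size=3
).map(lambda v: np.array(v) / max(1.0, sum(v)))

small_param_values = st.lists(st.floats(-0.3, 0.3), min_size=12, max_size=12)


@settings(max_examples=200, derandomize=True)
@given(values=composition_values, raw=small_param_values)
def test_unconstrained_regime_equivalence(values, raw):
    """Where neither the floor nor the normalization engages, the floored/
    normalized update and the plain gLV update coincide."""
    genera = ("a", "b", "c")
    raw = np.array(raw)
    beta = raw[3:].reshape(3, 3)
    np.fill_diagonal(beta, 0.0)
    params = ModelParams(genera, raw[:3], beta)
    x = Composition(genera, values)
    g = glv_step(RawState(genera, values), params)
    if np.all(g.values > FLOOR) and g.values.sum() <= 1.0:
        assert np.allclose(nedn_step(x, params).values, g.values, rtol=0, atol=1e-12)


@settings(max_examples=100, derandomize=True)
@given(values=composition_values, raw=st.lists(st.floats(-3, 3), min_size=12, max_size=12))
def test_nedn_invariants_hold_for_any_parameters(values, raw):
    """Non-extinction and the simplex bound after a single day, anywhere in
    the parameter box."""
    genera = ("a", "b", "c")
    raw = np.array(raw)
    beta = raw[3:].reshape(3, 3)
    np.fill_diagonal(beta, 0.0)
    out = nedn_step(Composition(genera, values), ModelParams(genera, raw[:3], beta))
    assert np.all(out.values > 0)
    assert out.values.sum() <= 1.0 + 1e-12


def test_permutation_equivariance(two_genus_state, two_genus_params):
    """Relabelling genera permutes the output and nothing else."""
    out = nedn_step(two_genus_state, two_genus_params)
    perm = ("b", "a")
    out_perm = nedn_step(two_genus_state.reorder(perm), two_genus_params.reorder(perm))
    assert np.array_equal(out_perm.values, out.reorder(perm).values)


class TestSimulate:
    def test_zero_dynamics_constant_trajectory(self):
        x = Composition(("a", "b"), np.array([0.3, 0.7]))
        traj = simulate(x, zero_params(), 400)
        assert len(traj) == 401
        assert np.all(traj.values == traj.values[0])

    def test_single_genus_logistic_approaches_fixed_point(self):
        # discrete logistic with r = 0.5 < 2: monotone rise to x* = 1
        p = ModelParams(("a",), np.array([0.5]), np.zeros((1, 1)))
        traj = simulate(Composition(("a",), np.array([0.1])), p, 100)
        x = traj.values[:, 0]
        assert np.all(np.diff(x) > -1e-15)
        assert x[-1] == pytest.approx(1.0, abs=1e-6)

    def test_zero_days_rejected(self, two_genus_state, two_genus_params):
        with pytest.raises(ValueError, match="n_days"):
            simulate(two_genus_state, two_genus_params, 0)

    def test_glv_divergence_truncates_and_flags(self):
        # x(4 - 3x) from x=5 escapes doubly exponentially
        p = ModelParams(("a", "b"), np.array([3.0, 3.0]), np.zeros((2, 2)))
        x0 = RawState(("a", "b"), np.array([5.0, 5.0]))
        traj = simulate(x0, p, 200, model="glv")
        assert traj.diverged
        assert len(traj) < 201
        assert np.all(np.isfinite(traj.values))


class TestSerialization:
    def test_params_json_roundtrip_is_bit_exact(self, tmp_path, two_genus_params):
        rng = np.random.default_rng(7)
        beta = rng.uniform(-3, 3, (5, 5))
        np.fill_diagonal(beta, 0.0)
        p = ModelParams(tuple("abcde"), rng.uniform(-3, 3, 5), beta)
        p.to_json(tmp_path / "p.json")
        q = ModelParams.from_json(tmp_path / "p.json")
        assert q.genera == p.genera
        assert np.array_equal(q.alpha, p.alpha)
        assert np.array_equal(q.beta, p.beta)

    def test_params_tsv_roundtrip_is_bit_exact(self, tmp_path):
        rng = np.random.default_rng(3)
        beta = rng.uniform(-3, 3, (3, 3))
        np.fill_diagonal(beta, 0.0)
        p = ModelParams(("x", "y", "z"), rng.uniform(-3, 3, 3), beta)
        p.to_tsv(tmp_path / "p.tsv")
        q = ModelParams.from_tsv(tmp_path / "p.tsv")
        assert np.array_equal(q.alpha, p.alpha)
        assert np.array_equal(q.beta, p.beta)

    def test_trajectory_tsv_roundtrip(self, tmp_path, two_genus_state, two_genus_params):
        traj = simulate(two_genus_state, two_genus_params, 5)
        traj.to_tsv(tmp_path / "t.tsv")
        back = Trajectory.from_tsv(tmp_path / "t.tsv")
        assert back.genera == traj.genera
        assert np.array_equal(back.values, traj.values)


class TestValidation:
    def test_composition_rejects_nonpositive_values(self):
        with pytest.raises(ValueError, match="positive"):
            Composition(("a", "b"), np.array([0.5, 0.0]))

    def test_composition_rejects_total_above_one(self):
        with pytest.raises(ValueError, match="exceeds 1"):
            Composition(("a", "b"), np.array([0.7, 0.7]))

    def test_params_reject_nonzero_diagonal(self):
        with pytest.raises(ValueError, match="diagonal"):
            ModelParams(("a", "b"), np.zeros(2), np.array([[0.1, 0.0], [0.0, 0.0]]))

    def test_params_reject_out_of_box(self):
        with pytest.raises(ValueError, match=r"\[-3.0, 3.0\]"):
            ModelParams(("a", "b"), np.array([3.5, 0.0]), np.zeros((2, 2)))

    def test_free_parameter_count(self):
        k = 5
        genera = tuple(f"g{i}" for i in range(k))
        p = ModelParams(genera, np.zeros(k), np.zeros((k, k)))
        assert p.n_free_parameters == k + k * (k - 1)
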