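"""Spherical pattern search: adjustment geometry, dynamics, convergence."""

import numpy as np
import pytest

from scor import OrderedBiomarkerData, SCORConfig, make_objective, scor_fit, scor_maximize
from scor.optimizer import (IterationState, OptimizationTrace, _make_candidate,
                            adjustment_step, apply_sparsity, candidate_set,
                            scor_run)


def unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


def bisect_adjustment(beta, i, s, lo=-0.5, hi=0.5, tol=1e-13):
    """Independent oracle: root of the norm-restoration equation nearest 0,
    found by bisection on the bracket containing t=0's side change."""
    def g(t):
        cand = beta + t
        cand[i] = beta[i] + s
        return float(np.sum(cand ** 2) - 1.0)

    # scan outward from 0 for a sign change
    ts = np.linspace(lo, hi, 20001)
    vals = np.array([g(t) for t in ts])
    sign = np.sign(vals)
    flips = np.where(np.diff(sign) != 0)[0]
    assert flips.size, "oracle found no real root"
    # bracket whose endpoints are closest to zero
    best = flips[np.argmin(np.minimum(np.abs(ts[flips]), np.abs(ts[flips + 1])))]
    a, b = ts[best], ts[best + 1]
    for _ in range(200):
        m = 0.5 * (a + b)
        if g(a) * g(m) <= 0:
            b = m
        else:
            a = m
        if b - a < tol:
            break
    return 0.5 * (a + b)


class TestAdjustmentStep:
    def test_zero_step_gives_zero_adjustment(self, rng):
        for _ in range(10):
            beta = unit(rng.normal(size=4))
            assert adjustment_step(beta, 1, 0.0) == pytest.approx(0.0, abs=1e-15)

    def test_exploratory_move_stays_on_sphere(self):
        """Perturbing the 2nd coordinate of a near-unit 3-vector by 0.03
        and adjusting the others restores the norm to 1e-10."""
        beta = unit([0.289, -0.816, 0.5])
        t = adjustment_step(beta, 1, 0.03)
        assert t is not None
        cand = beta + t
        cand[1] = beta[1] + 0.03
        assert np.linalg.norm(cand) == pytest.approx(1.0, abs=1e-10)
        assert t == pytest.approx(bisect_adjustment(beta.copy(), 1, 0.03), abs=1e-9)

    def test_geometrically_impossible_move_has_no_root(self):
        # pushing coordinate 1 of (1, 0) to 1.5 leaves the sphere for good
        assert adjustment_step(np.array([1.0, 0.0]), 0, 0.5) is None

    def test_root_vanishes_as_step_shrinks(self, rng):
        """Once real roots appear, the selected root shrinks with the
        step and vanishes in the limit (the move becomes the identity)."""
        for _ in range(20):
            beta = unit(rng.normal(size=5))
            i = int(rng.integers(5))
            for sgn in (+1, -1):
                mags = []
                for k in range(2, 40):
                    t = adjustment_step(beta, i, sgn * 10.0 ** -k)
                    if t is not None:
                        mags.append(abs(t))
                assert len(mags) >= 5  # real roots for all small enough steps
                assert all(b <= a + 1e-15 for a, b in zip(mags, mags[1:]))
                assert mags[-1] < 1e-12

    def test_halving_eventually_yields_real_root(self, rng):
        """For any unit beta, coordinate and initial step, dividing the
        step by rho finitely many times produces a real adjustment."""
        rho = 2.0
        for _ in range(200):
            beta = unit(rng.normal(size=int(rng.integers(2, 7))))
            i = int(rng.integers(beta.size))
            s = float(rng.uniform(-2, 2)) or 0.5
            found = False
            for _k in range(300):
                if adjustment_step(beta, i, s) is not None:
                    found = True
                    break
                s /= rho
            assert found


class TestSparsity:
    def test_lambda_zero_keeps_everything(self):
        beta = unit([0.5, 0.5, 0.5, 0.5])
        active, out = apply_sparsity(beta, 2, 0.0)
        assert not active[2] and active.sum() == 3
        assert np.allclose(out, beta)

    def test_lambda_one_zeroes_all_but_target(self):
        beta = unit([0.9, 0.1, 0.3])
        active, out = apply_sparsity(beta, 0, 1.0)
        assert active.sum() == 0
        assert out[1] == 0 and out[2] == 0 and out[0] == beta[0]

    def test_sparse_move_lands_on_sphere(self):
        beta = unit([0.9, 0.1, np.sqrt(1 - 0.82)])
        cand = _make_candidate(beta, 0, 0.05, lam=0.2)
        assert cand is not None
        assert cand[1] == 0.0  # |0.1/||.||| < 0.2 zeroed
        assert np.linalg.norm(cand) == pytest.approx(1.0, abs=1e-10)


class TestCandidateSet:
    def test_count_and_norms(self, rng):
        beta = unit(rng.normal(size=3))
        state = IterationState(beta=beta, step=0.4, value=0.0)
        cands = candidate_set(state, SCORConfig())
        assert len(cands) <= 6
        for i, sign, c in cands:
            assert np.linalg.norm(c) == pytest.approx(1.0, abs=1e-8)

    def test_full_set_when_all_roots_real(self):
        beta = unit([1.0, 1.0, 1.0])
        state = IterationState(beta=beta, step=0.1, value=0.0)
        cands = candidate_set(state, SCORConfig())
        assert len(cands) == 6
        # deterministic order: ascending coordinate, "+" before "-"
        assert [(i, s) for i, s, _ in cands] == [(0, 1), (0, -1), (1, 1), (1, -1), (2, 1), (2, -1)]


class TestSearch:
    def test_linear_objective_reaches_axis(self):
        res = scor_maximize(lambda b: b[0], unit([1.0, 1.0, 1.0]))
        assert res.value == pytest.approx(1.0, abs=1e-5)
        assert np.allclose(res.beta, [1, 0, 0], atol=1e-3)

    def test_linear_objective_closed_form_maximizer(self):
        v = np.array([0.6, 0.8])
        res = scor_maximize(lambda b: v @ b, unit([1.0, 0.0]))
        assert np.allclose(res.beta, v, atol=1e-4)
        assert res.value == pytest.approx(1.0, abs=1e-6)

    def test_separable_data_attains_one(self, make_data):
        data = make_data([[0.0, 0.0], [0.2, -0.1]], [[3.0, 3.0], [4.0, 2.5]])
        res = scor_fit(data, "ehum")
        assert res.value == 1.0

    def test_visited_points_unit_norm_and_monotone_incumbent(self, rng, random_data):
        data = random_data(rng, M=2, d=4, n=8)
        base = make_objective("ehum", data)
        norms = []

        def recording(b):
            norms.append(np.linalg.norm(b))
            return base(b)

        res = scor_maximize(recording, np.full(4, 0.5))
        assert np.max(np.abs(np.array(norms) - 1.0)) <= 1e-8
        vals = res.trace.values
        assert all(b >= a for a, b in zip(vals, vals[1:]))
        assert res.value == pytest.approx(base(res.beta))

    def test_step_sequence_nonincreasing_within_run(self, rng, random_data):
        data = random_data(rng, M=2, d=3, n=6)
        f = make_objective("ehum", data)
        trace = OptimizationTrace()
        scor_run(np.full(3, 1.0 / np.sqrt(3)), f, SCORConfig(), trace)
        steps = trace.steps
        assert all(b <= a for a, b in zip(steps, steps[1:]))

    def test_single_iteration_cap(self, rng, random_data):
        data = random_data(rng, M=2, d=3, n=6)
        f = make_objective("ehum", data)
        trace = OptimizationTrace()
        scor_run(np.full(3, 1.0 / np.sqrt(3)), f,
                 SCORConfig(max_iter=1, max_runs=1), trace)
        assert len(trace.steps) == 1

    def test_termination_for_bounded_objectives(self, rng, random_data):
        data = random_data(rng, M=3, d=3, n=5)
        res = scor_fit(data, "ulba_pa")
        assert res.converged
        assert res.n_runs <= SCORConfig().max_runs

    def test_degenerate_one_dimensional_sphere(self, make_data):
        data = make_data([[2.0], [3.0]], [[0.0], [1.0]])  # decreasing marker
        res = scor_fit(data, "ehum")
        assert res.beta[0] == -1.0 and res.value == 1.0

    def test_off_sphere_start_normalized_with_warning(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="scor.optimizer"):
            res = scor_maximize(lambda b: b[0], np.array([2.0, 0.0]))
        assert "normalizing" in caplog.text
        assert res.value == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("kwargs", [
        {"s_initial": 0.0}, {"rho": 1.0}, {"phi": -1e-3},
        {"tol_fun": -1.0}, {"max_iter": 0}, {"s_initial": 1e-9},
    ])
    def test_invalid_configuration_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SCORConfig(**kwargs)

    def test_angular_grid_near_optimality(self, rng):
        """On d=2 the final training EHUM is within one counting quantum
        (one cross-group pair) of a dense angular grid's maximum."""
        quantum = 1.0 / 64
        for _ in range(10):
            g1 = rng.normal(0, 1, (8, 2))
            g2 = rng.normal(0.8, 1, (8, 2))
            data = OrderedBiomarkerData((g1, g2))
            res = scor_fit(data, "ehum")
            th = np.linspace(0, 2 * np.pi, 20000, endpoint=False)
            B = np.vstack([np.cos(th), np.sin(th)])
            grid = ((g2 @ B)[:, None, :] > (g1 @ B)[None, :, :]).mean((0, 1)).max()
            assert res.value >= grid - quantum - 1e-12
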