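import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from motion3c import (
    DirectionalSample,
    SimConfig,
    Step,
    decompose,
    delta_angle,
    directional_samples,
    extract_random,
    fit_bias_persistence,
    mean_module_to_msd,
    raw_bias,
    simulate_population,
    steps,
)


def mk_step(d, prev_dir=None):
    d = np.asarray(d, dtype=float)
    if prev_dir is not None:
        prev_dir = np.asarray(prev_dir, dtype=float)
        prev_dir = prev_dir / np.linalg.norm(prev_dir)
    return Step(track_id="t", t_start=0.0, d=d, prev_dir=prev_dir)


class TestRawBias:
    def test_cancellation_is_degenerate(self):
        rb = raw_bias([mk_step([1, 0]), mk_step([-1, 0])])
        np.testing.assert_array_equal(rb.vector, [0, 0])
        assert rb.degenerate and rb.beta == 0.0

    def test_mean_vector(self):
        rb = raw_bias([mk_step([2, 0]), mk_step([4, 0])])
        assert rb.module == pytest.approx(3.0)
        assert rb.beta == pytest.approx(0.0)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            raw_bias([])

    def test_biased_population_module_near_input(self):
        ts = simulate_population(SimConfig(b_module=8.0, seed=0))
        rb = raw_bias(steps(ts))
        assert rb.module == pytest.approx(8.0, abs=0.8)


class TestDirectionalSamples:
    @pytest.mark.parametrize(
        "d,beta,expected_db",
        [([3, 4], 0.0, 3.0), ([0, 5], math.pi / 2, 5.0)],
    )
    def test_projection(self, d, beta, expected_db):
        s = mk_step(d, prev_dir=[1, 0])
        (out,) = directional_samples([s], beta)
        assert out.d_b == pytest.approx(expected_db)

    def test_alpha_is_prev_direction_minus_beta(self):
        s = mk_step([1, 0], prev_dir=[1, 1])  # previous direction at 45°
        (out,) = directional_samples([s], 0.0)
        assert out.alpha_angle == pytest.approx(math.pi / 4)

    def test_steps_without_predecessor_excluded(self):
        out = directional_samples([mk_step([1, 0]), mk_step([1, 0], [0, 1])], 0.0)
        assert len(out) == 1


class TestFitBiasPersistence:
    def test_exact_linear_system(self):
        alphas = [0.0, math.pi / 2, math.pi, 3 * math.pi / 2]
        samples = [
            DirectionalSample(d_b=2 + 3 * math.cos(a), alpha_angle=a) for a in alphas
        ]
        b, b_se, p, p_se = fit_bias_persistence(samples)
        assert b == pytest.approx(2.0, abs=1e-12)
        assert p == pytest.approx(3.0, abs=1e-12)

    def test_constant_db_gives_zero_persistence(self):
        alphas = np.linspace(-math.pi, math.pi, 9)
        samples = [DirectionalSample(d_b=5.0, alpha_angle=a) for a in alphas]
        b, _, p, _ = fit_bias_persistence(samples)
        assert b == pytest.approx(5.0)
        assert p == pytest.approx(0.0, abs=1e-12)

    def test_rank_deficient_design_rejected(self):
        samples = [DirectionalSample(d_b=v, alpha_angle=0.1) for v in (1.0, 2.0, 3.0)]
        with pytest.raises(ValueError, match="rank"):
            fit_bias_persistence(samples)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_matches_normal_equations_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 40))
        alphas = rng.uniform(-math.pi, math.pi, n)
        db = rng.normal(scale=5.0, size=n)
        samples = [
            DirectionalSample(d_b=float(y), alpha_angle=float(a))
            for y, a in zip(db, alphas)
        ]
        b, b_se, p, p_se = fit_bias_persistence(samples)
        # closed-form two-parameter regression via the normal equations
        X = np.column_stack([np.ones(n), np.cos(alphas)])
        coef = np.linalg.solve(X.T @ X, X.T @ db)
        resid = db - X @ coef
        cov = (resid @ resid) / (n - 2) * np.linalg.inv(X.T @ X)
        assert b == pytest.approx(coef[0], abs=1e-9)
        assert p == pytest.approx(coef[1], abs=1e-9)
        assert b_se == pytest.approx(math.sqrt(cov[0, 0]), abs=1e-9)
        assert p_se == pytest.approx(math.sqrt(cov[1, 1]), abs=1e-9)


class TestExtractRandom:
    def test_zero_parameters_identity(self):
        sl = [mk_step([3, 4], [1, 0]), mk_step([1, 1], [0, 1])]
        vecs, r_mean = extract_random(sl, 0.0, 0.0, 0.0)
        np.testing.assert_allclose(vecs, [[3, 4], [1, 1]])
        assert r_mean == pytest.approx((5 + math.sqrt(2)) / 2)

    def test_reconstruction_identity(self):
        rng = np.random.default_rng(5)
        sl = [
            mk_step(rng.normal(size=2) * 8, rng.normal(size=2)) for _ in range(50)
        ]
        b, beta, p = 3.3, 0.7, 4.1
        vecs, _ = extract_random(sl, b, beta, p)
        u_b = np.array([math.cos(beta), math.sin(beta)])
        for s, r in zip(sl, vecs):
            np.testing.assert_allclose(
                b * u_b + p * s.prev_dir + r, s.d, atol=1e-12
            )


class TestDeltaAngle:
    @pytest.mark.parametrize(
        "beta_deg,expected_deg,out",
        [(10, 0, 10), (350, 0, 10), (180, 0, 180), (-90, 90, 180), (5, 355, 10)],
    )
    def test_wraparound(self, beta_deg, expected_deg, out):
        assert delta_angle(
            math.radians(beta_deg), math.radians(expected_deg)
        ) == pytest.approx(out)


class TestDecomposePipeline:
    def test_null_population(self):
        ts = simulate_population(SimConfig(seed=1))
        res = decompose(ts)
        assert abs(res.b) < 3 * res.b_se + 0.5
        assert abs(res.p) < 3 * res.p_se + 0.5
        assert res.r_mean == pytest.approx(8.86, rel=0.05)

    def test_recovers_combined_inputs(self):
        msd9 = mean_module_to_msd(9.0)
        vals = []
        for seed in range(3):
            ts = simulate_population(
                SimConfig(p_in=8.0, b_module=8.0, msd_random=msd9, seed=seed)
            )
            res = decompose(ts)
            vals.append((res.b, res.p))
        b, p = np.mean(vals, axis=0)
        assert b == pytest.approx(8.0, abs=1.5)
        assert p == pytest.approx(8.0, abs=1.5)

    def test_bias_does_not_inflate_vector_persistence(self):
        # the headline decoupling property: adding a bias leaves the fitted
        # persistence module near its input, unlike the Fürth time
        ps = []
        for b_in in (0.0, 8.0):
            res = decompose(
                simulate_population(SimConfig(p_in=8.0, b_module=b_in, seed=2))
            )
            ps.append(res.p)
        assert abs(ps[1] - ps[0]) < 2.5

    def test_delta_angle_reported_against_expected_direction(self):
        ts = simulate_population(SimConfig(b_module=8.0, b_angle=0.0, seed=3))
        res = decompose(ts, expected_direction=0.0)
        assert res.delta is not None and res.delta < 5.0

    def test_n_steps_used_excludes_first_steps(self):
        ts = simulate_population(SimConfig(n_cells=10, n_steps=6, seed=4))
        res = decompose(ts)
        assert res.n_steps_used == 10 * 5
        assert len(res.random_vectors) == res.n_steps_used
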