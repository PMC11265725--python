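import numpy as np
import pytest

from sec.block_grid import Block, decompose
from sec.eom_matcher import (
    Concentration,
    EomParams,
    classify_and_reweight,
    exponential_term,
    fitness,
    generation_rate,
    run_eom,
    update_concentration,
    update_pool,
)


def _conc(values, fit=float("nan"), origin=(0, 0)):
    values = np.asarray(values, dtype=float)
    return Concentration(
        block=Block(origin[0], origin[1], values.shape[0], float(values.std())),
        values=values,
        fitness=fit,
    )


def _flat(level, b=4):
    return np.full((b, b), float(level))


def _with_std(target, b=4):
    """A b*b grid whose population std is exactly `target`."""
    v = np.zeros((b, b))
    v[: b // 2] = 2.0 * target
    return v


class TestFitness:
    def test_equal_stds_give_zero(self):
        pop = [_conc(_with_std(5.0)) for _ in range(4)]
        assert fitness(pop[0], pop) == 0.0

    def test_hand_evaluated_example(self):
        current = _conc(_with_std(1.0))
        pop = [_conc(_with_std(1.0)), _conc(_with_std(3.0))]
        assert fitness(current, pop) == pytest.approx(2.0)

    def test_matches_loop_oracle(self, rng):
        pop = [_conc(rng.uniform(0, 255, (4, 4))) for _ in range(9)]
        for current in pop:
            oracle = sum((current.std - c.std) ** 2 for c in pop) / len(pop)
            assert fitness(current, pop) == pytest.approx(oracle, rel=1e-9)

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            fitness(_conc(_flat(1)), [])


class TestUpdatePool:
    def test_selects_four_lowest_fitness(self, rng):
        fits = [9.0, 1.0, 5.0, 3.0, 7.0]
        pop = [_conc(rng.uniform(0, 255, (4, 4)), f) for f in fits]
        pool = update_pool(pop)
        assert [m.fitness for m in pool.members] == [1.0, 3.0, 5.0, 7.0]

    def test_average_of_identical_blocks_is_that_block(self):
        pop = [_conc(_flat(30), float(i)) for i in range(4)]
        pool = update_pool(pop)
        np.testing.assert_allclose(pool.c_avg.values, _flat(30))

    def test_average_is_elementwise_mean(self, rng):
        pop = [_conc(rng.uniform(0, 255, (4, 4)), float(i)) for i in range(6)]
        pool = update_pool(pop)
        expected = np.mean([m.values for m in pool.members], axis=0)
        np.testing.assert_allclose(pool.c_avg.values, expected)

    def test_tie_broken_by_population_order(self):
        first = _conc(_flat(10), 1.0, origin=(0, 0))
        second = _conc(_flat(20), 1.0, origin=(0, 1))
        pop = [first, second, _conc(_flat(1), 2.0), _conc(_flat(2), 3.0)]
        pool = update_pool(pop)
        assert pool.c_eq1 is first

    def test_small_population_rejected(self):
        with pytest.raises(ValueError):
            update_pool([_conc(_flat(1), 0.0)] * 3)


class TestExponentialTerm:
    def test_sign_zero_convention(self):
        p = EomParams()
        assert exponential_term(0.5, 0.3, 10.0, p) == pytest.approx(-1.0)

    def test_lambda_zero_gives_a1_minus_a2(self):
        p = EomParams()
        assert exponential_term(0.9, 0.0, 50.0, p) == pytest.approx(1.0)

    def test_negative_branch(self):
        p = EomParams()
        assert exponential_term(0.1, 1.0, 0.0, p) == pytest.approx(-3.0)

    def test_canonical_variant_vanishes_at_zero_std(self):
        p = EomParams(f_variant="canonical")
        assert exponential_term(0.9, 1.0, 0.0, p) == 0.0

    def test_matches_formula_on_random_inputs(self, rng):
        p = EomParams()
        for _ in range(20):
            r, lam = rng.random(2)
            std = rng.uniform(0, 127)
            expected = p.a1 * np.sign(r - 0.5) * np.exp(-lam * std) - p.a2
            assert exponential_term(r, lam, std, p) == pytest.approx(expected)


class TestGenerationRate:
    def test_low_r2_zeroes_the_grid(self, rng):
        p = EomParams()
        g = generation_rate(0.7, 0.2, 0.5, rng.random((4, 4)), rng.random((4, 4)), 1.5, p)
        assert (g == 0).all()

    def test_high_r2_lambda_zero_scales_c_eq1(self, rng):
        p = EomParams()
        c1 = rng.random((4, 4))
        f = -2.0
        g = generation_rate(1.0, 0.9, 0.0, c1, rng.random((4, 4)), f, p)
        np.testing.assert_allclose(g, 0.5 * c1 * f)

    def test_tie_at_gp_takes_active_branch(self):
        p = EomParams()
        g = generation_rate(1.0, p.gp, 0.0, _flat(1), _flat(0), 1.0, p)
        assert (g != 0).all()

    def test_matches_elementwise_loop_oracle(self, rng):
        p = EomParams()
        c1, blk = rng.uniform(0, 255, (2, 4, 4))
        r1, r2, lam, f = 0.6, 0.8, 0.3, 1.7
        got = generation_rate(r1, r2, lam, c1, blk, f, p)
        for i in range(4):
            for j in range(4):
                gcp = 0.5 * r1 if r2 >= p.gp else 0.0
                assert got[i, j] == pytest.approx(gcp * (c1[i, j] - lam * blk[i, j]) * f)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            generation_rate(0.5, 0.9, 0.5, np.zeros((4, 4)), np.zeros((3, 3)), 1.0, EomParams())


class TestUpdateConcentration:
    def test_collapses_to_c_eq1_when_f_and_g_vanish(self, rng):
        p = EomParams()
        c1 = rng.random((4, 4))
        got = update_concentration(rng.random((4, 4)), c1, 0.0, np.zeros((4, 4)), 0.5, p)
        np.testing.assert_allclose(got, c1)

    def test_identical_block_and_pool_head_is_fixed_point(self, rng):
        p = EomParams()
        c1 = rng.random((4, 4))
        got = update_concentration(c1, c1, -1.7, np.zeros((4, 4)), 0.5, p)
        np.testing.assert_allclose(got, c1)

    def test_matches_elementwise_loop_oracle(self, rng):
        p = EomParams()
        blk, c1, g = rng.uniform(0, 255, (3, 4, 4))
        f, lam = -0.4, 0.6
        got = update_concentration(blk, c1, f, g, lam, p)
        for i in range(4):
            for j in range(4):
                expected = c1[i, j] + (c1[i, j] - blk[i, j]) * f + g[i, j] / lam * (1 - f)
                assert got[i, j] == pytest.approx(expected)

    def test_lambda_floor_guards_division(self):
        p = EomParams(lambda_floor=1e-6)
        got = update_concentration(_flat(0), _flat(0), 0.0, _flat(1), 0.0, p)
        np.testing.assert_allclose(got, _flat(1e6))

    def test_non_finite_inputs_rejected(self):
        p = EomParams()
        with pytest.raises(ValueError):
            update_concentration(_flat(np.inf), _flat(0), 0.0, _flat(0), 0.5, p)


class TestClassifyAndReweight:
    def _pool(self):
        pop = [_conc(_with_std(s, b=2), float(i)) for i, s in enumerate([5, 6, 7, 8])]
        return update_pool(pop)

    def test_member_whitens_and_clips(self):
        pool = self._pool()
        working = np.full((4, 4), 100.0)
        upd = _conc(_with_std(50.0, b=2), fit=1.0, origin=(1, 1))
        member = classify_and_reweight(upd, pool, working)
        assert member
        assert (working[1:3, 1:3] == 255.0).all()
        assert (working[0] == 100.0).all()

    def test_non_member_darkens_by_std_over_100(self):
        pool = self._pool()
        working = np.full((4, 4), 100.0)
        upd = _conc(_with_std(50.0, b=2), fit=99.0, origin=(0, 0))
        member = classify_and_reweight(upd, pool, working)
        assert not member
        assert working[0, 0] == pytest.approx(50.0)

    def test_zero_std_blackens_in_both_branches(self):
        pool = self._pool()
        for fit in (0.0, 99.0):
            working = np.full((4, 4), 200.0)
            upd = _conc(_flat(7.0, b=2), fit=fit, origin=(2, 2))
            classify_and_reweight(upd, pool, working)
            assert (working[2:4, 2:4] == 0.0).all()


class TestRunEom:
    def _textured(self, rng, n=64):
        return np.clip(rng.normal(100, 20, (n, n)), 0, 255)

    def test_fewer_than_four_candidates_declares_authentic(self, rng):
        gray = self._textured(rng)
        grid = decompose(gray, 8)
        grid.keypoint_counts[0, 0] = 1
        grid.keypoint_counts[5, 5] = 1
        out = run_eom(gray, grid, EomParams(seed=3))
        assert not out.binarized.any()
        assert (out.working == 0).all()

    def test_seeded_determinism(self, rng):
        gray = self._textured(rng)
        grid = decompose(gray, 8)
        grid.keypoint_counts[::6, ::6] = 1
        a = run_eom(gray, grid, EomParams(seed=11, max_iter=5))
        b = run_eom(gray, grid, EomParams(seed=11, max_iter=5))
        np.testing.assert_array_equal(a.working, b.working)
        np.testing.assert_array_equal(a.binarized, b.binarized)

    def test_working_image_stays_in_range(self, rng):
        gray = self._textured(rng)
        grid = decompose(gray, 8)
        grid.keypoint_counts[::4, ::4] = 1
        out = run_eom(gray, grid, EomParams(seed=5, max_iter=5))
        assert out.working.min() >= 0.0
        assert out.working.max() <= 255.0

    def test_binarization_consistent_with_threshold(self, rng):
        gray = self._textured(rng)
        grid = decompose(gray, 8)
        grid.keypoint_counts[::4, ::4] = 1
        params = EomParams(seed=5, max_iter=3)
        out = run_eom(gray, grid, params)
        np.testing.assert_array_equal(
            out.binarized, out.working >= params.white_black_threshold
        )

    def test_pool_ordering_invariant_each_iteration(self, rng):
        # pool fitnesses must come out sorted for any evaluated population
        pop = [_conc(rng.uniform(0, 255, (8, 8))) for _ in range(12)]
        for c in pop:
            c.fitness = fitness(c, pop)
        pool = update_pool(pop)
        fits = [m.fitness for m in pool.members]
        assert fits == sorted(fits)
        assert all(f >= 0 for f in fits)
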