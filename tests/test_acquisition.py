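"""Expected improvement, xi schedule, Latin hypercube, mixed-space suggestion."""

import numpy as np
import pytest

import rxnloop as rl
from rxnloop import acquisition, gp
from rxnloop.acquisition import XiSchedule, current_xi, expected_improvement

from conftest import random_space


class TestXiSchedule:
    def test_changeover_boundary_is_strict(self):
        sched = XiSchedule(1.0, 0.01, 48, 12)
        assert current_xi(sched, 47) == 1.0
        assert current_xi(sched, 48) == 0.01

    def test_third_loop_schedule(self):
        sched = XiSchedule(1.0, 0.02, 24, 12)
        assert current_xi(sched, 24) == 0.02

    def test_constant_schedule(self):
        sched = XiSchedule(0.5, 0.5, 10, 5)
        assert current_xi(sched, 0) == current_xi(sched, 100) == 0.5

    def test_invalid_schedules_rejected(self):
        with pytest.raises(ValueError):
            XiSchedule(0.01, 1.0, 48, 12)  # high < low
        with pytest.raises(ValueError):
            XiSchedule(1.0, 0.01, 10, 12)  # changeover < n_initial


class TestExpectedImprovement:
    def test_zero_std_no_improvement(self):
        assert expected_improvement(5.0, 0.0, 5.0, 0.1) == 0.0
        assert expected_improvement(4.0, 0.0, 5.0, 0.0) == 0.0

    def test_zero_std_positive_improvement(self):
        assert expected_improvement(7.0, 0.0, 5.0, 0.5) == pytest.approx(1.5)

    def test_symmetric_at_threshold(self):
        sigma = 2.7
        ei = expected_improvement(10.0, sigma, 9.0, 1.0)
        assert ei == pytest.approx(sigma / np.sqrt(2 * np.pi), rel=1e-12)

    def test_monte_carlo_agreement(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            mean, std = rng.uniform(-2, 2), rng.uniform(0.1, 3)
            f_best, xi = rng.uniform(-2, 2), rng.uniform(0, 1.5)
            draws = rng.normal(mean, std, size=400_000)
            mc = np.maximum(draws - f_best - xi, 0.0).mean()
            se = np.maximum(draws - f_best - xi, 0.0).std() / np.sqrt(draws.size)
            assert abs(expected_improvement(mean, std, f_best, xi) - mc) <= 3 * se + 1e-12

    def test_non_increasing_in_xi(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            mean, std, f_best = rng.uniform(-2, 2), rng.uniform(0, 2), rng.uniform(-2, 2)
            xi1, xi2 = sorted(rng.uniform(0, 2, size=2))
            assert expected_improvement(mean, std, f_best, xi2) <= expected_improvement(
                mean, std, f_best, xi1
            ) + 1e-12

    def test_non_decreasing_in_std_when_no_expected_gain(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            f_best, xi = rng.uniform(0, 2), rng.uniform(0, 1)
            mean = f_best + xi - rng.uniform(0, 2)  # mean - f* - xi <= 0
            s1, s2 = sorted(rng.uniform(0, 3, size=2))
            assert expected_improvement(mean, s2, f_best, xi) >= expected_improvement(
                mean, s1, f_best, xi
            ) - 1e-12

    def test_negative_std_rejected(self):
        with pytest.raises(ValueError):
            expected_improvement(0.0, -1.0, 0.0, 0.0)


class TestLatinHypercube:
    @pytest.mark.parametrize("n", [5, 12, 48])
    def test_continuous_stratification(self, cl1_space, n):
        design = rl.latin_hypercube(n, cl1_space, seed=3)
        for name in ("eq_bz", "eq_base", "conc"):
            p = cl1_space[name]
            u = np.array(
                [(c.values[name] - p.lower) / (p.upper - p.lower) for c in design]
            )
            strata = np.floor(u * n).astype(int)
            assert sorted(strata) == list(range(n))

    def test_single_point(self, cl1_space):
        (c,) = rl.latin_hypercube(1, cl1_space, seed=4)
        assert cl1_space.is_valid(c)

    def test_seed_determinism(self, cl1_space):
        d1 = rl.latin_hypercube(12, cl1_space, seed=5)
        d2 = rl.latin_hypercube(12, cl1_space, seed=5)
        assert d1 == d2

    def test_categorical_levels_cycled(self, cl1_space):
        # n > #levels: every solvent label appears at least once
        design = rl.latin_hypercube(20, cl1_space, seed=6)
        used = {c.values["solvent"] for c in design}
        assert used == set(cl1_space["solvent"].levels)

    def test_all_candidates_valid(self, cl1_space):
        for c in rl.latin_hypercube(12, cl1_space, seed=7):
            cl1_space.validate(c)


def _mini_history(space, n, seed, profile=None):
    from rxnloop.loop import ExperimentRecord
    from rxnloop.simulator import measure, species_fractions

    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        c = space.sample(rng)
        if profile is not None:
            score = measure(species_fractions(c, profile), "mono", 0.0, rng)
        else:
            score = float(rng.uniform(0, 100))
        records.append(
            ExperimentRecord(index=i + 1, candidate=c, fractions=None, score=score, phase="lhs")
        )
    return records


class TestSuggest:
    def test_suggestion_valid_and_distinct(self, tiny_space, profiles):
        history = _mini_history(tiny_space, 10, 0, profiles["glucoside"])
        X = tiny_space.normalize_many([r.candidate for r in history])
        model = gp.fit(X, [r.score for r in history], seed=1, cat_mask=tiny_space.onehot_mask, n_restarts=1)
        sched = XiSchedule(1.0, 0.01, 8, 5)
        cand = rl.suggest(model, tiny_space, sched, history, seed=2)
        tiny_space.validate(cand)
        d = np.linalg.norm(X - tiny_space.normalize(cand)[None, :], axis=1)
        assert d.min() > acquisition.DUP_TOL

    @pytest.mark.parametrize("seed", range(5))
    def test_fuzz_random_spaces(self, seed):
        rng = np.random.default_rng(100 + seed)
        space = random_space(rng)
        history = _mini_history(space, 6, seed)
        X = space.normalize_many([r.candidate for r in history])
        model = gp.fit(X, [r.score for r in history], seed=0, cat_mask=space.onehot_mask, n_restarts=0)
        cand = rl.suggest(model, space, XiSchedule(1.0, 0.01, 4, 2), history, seed=seed)
        space.validate(cand)

    def test_pure_exploration_limit_maximizes_std(self, tiny_space):
        # incumbent far above every reachable mean, huge xi: EI degenerates
        # and the suggestion must out-spread random candidates in std
        from rxnloop.loop import ExperimentRecord

        rng = np.random.default_rng(3)
        history = _mini_history(tiny_space, 8, 4)
        history[-1] = ExperimentRecord(
            index=8, candidate=history[-1].candidate, fractions=None, score=100.0, phase="lhs"
        )
        X = tiny_space.normalize_many([r.candidate for r in history])
        y = [r.score if r.index < 8 else 100.0 for r in history]
        y = [min(v, 5.0) for v in y[:-1]] + [100.0]
        model = gp.fit(X, y, seed=1, cat_mask=tiny_space.onehot_mask, n_restarts=1)
        sched = XiSchedule(50.0, 0.01, 100, 8)  # enormous exploration margin
        cand = rl.suggest(model, tiny_space, sched, history, seed=5)
        _, s_cand = model.standardized_predict(tiny_space.normalize(cand)[None, :])
        # comparison pool mirrors the explorer's candidate class: random
        # discrete identities at the incumbent's continuous settings
        best_prev = max(history, key=lambda r: r.score if r.score is not None else -1)
        rand = []
        for _ in range(1000):
            v = dict(tiny_space.sample(rng).values)
            for p in tiny_space.free_params:
                if p.kind == "continuous":
                    v[p.name] = best_prev.candidate.values[p.name]
            rand.append(rl.Candidate(v))
        _, s_rand = model.standardized_predict(tiny_space.normalize_many(rand))
        assert s_cand[0] >= np.quantile(s_rand, 0.95)

    def test_matches_dense_grid_argmax_in_one_dimension(self):
        space = rl.ReactionSpace(
            params=(rl.ParameterSpec("x", "continuous", lower=0.0, upper=1.0),)
        )
        history = _mini_history(space, 5, 6)
        X = space.normalize_many([r.candidate for r in history])
        y = [r.score for r in history]
        model = gp.fit(X, y, seed=2, n_restarts=1)
        sched = XiSchedule(1.0, 0.05, 3, 2)  # past changeover: exploitation
        cand = rl.suggest(model, space, sched, history, seed=7, n_starts=8, n_refine=8)
        grid = np.linspace(0, 1, 2001)[:, None]
        mu, sd = model.standardized_predict(grid)
        f_best = model.standardize_y(max(y))
        mu_obs = model.standardized_mean(X)
        ei = expected_improvement(mu, sd, float(mu_obs.max()), 0.05)
        best = grid[int(np.argmax(ei)), 0]
        assert abs(cand.values["x"] - best) <= 0.02 or ei.max() < 1e-10

    def test_space_with_no_free_parameters_rejected(self):
        space = rl.ReactionSpace(
            params=(rl.ParameterSpec("x", "continuous", lower=0.0, upper=1.0),)
        )
        with pytest.raises(rl.SpaceError):
            rl.restrict_space(space, fixes={"x": 0.5})

    def test_high_xi_disperses_more_than_low_xi(self, tiny_space, profiles):
        # frozen model; 20 consecutive suggestions under each regime
        history = _mini_history(tiny_space, 12, 8, profiles["glucoside"])
        X = tiny_space.normalize_many([r.candidate for r in history])
        model = gp.fit(X, [r.score for r in history], seed=3, cat_mask=tiny_space.onehot_mask, n_restarts=1)

        def dispersion(schedule, n_completed):
            hist = list(history)
            pts = []
            for k in range(20):
                c = rl.suggest(
                    model, tiny_space, schedule, hist, seed=50 + k, n_completed=n_completed
                )
                pts.append(tiny_space.normalize(c))
                from rxnloop.loop import ExperimentRecord

                hist.append(
                    ExperimentRecord(
                        index=len(hist) + 1, candidate=c, fractions=None, score=None, phase="lhs"
                    )
                )
            P = np.vstack(pts)
            d = np.linalg.norm(P[:, None] - P[None, :], axis=-1)
            return d[np.triu_indices(20, 1)].mean()

        high = dispersion(XiSchedule(1.0, 0.01, 1000, 12), n_completed=0)
        low = dispersion(XiSchedule(1.0, 0.01, 0, 0), n_completed=10_000)
        assert high > low
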