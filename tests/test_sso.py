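"""The SSO update mechanism, optimizer loop and level-experiment harness."""

import numpy as np
import pytest
from scipy import stats

from ssokd.sso import (SSOParams, intervals_from_probabilities, level_experiment,
                       random_search, sso_optimize, toy_fitness, update_solution,
                       update_variable)

BOUNDS7 = [(1, 8)] * 7


class TestIntervals:
    @pytest.mark.parametrize("probs,expected", [
        ((0.2, 0.4, 0.1, 0.3), (0.2, 0.6, 0.7)),
        ((0.7, 0.1, 0.1, 0.1), (0.7, 0.8, 0.9)),
        ((0.25, 0.25, 0.25, 0.25), (0.25, 0.5, 0.75)),
    ])
    def test_cumulative_mapping(self, probs, expected):
        assert np.allclose(intervals_from_probabilities(*probs), expected)

    def test_bad_sum_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            intervals_from_probabilities(0.2, 0.2, 0.2, 0.2)

    def test_zero_probability_rejected(self):
        with pytest.raises(ValueError, match="> 0"):
            intervals_from_probabilities(0.0, 0.5, 0.25, 0.25)


class TestUpdateVariable:
    params = SSOParams(cg=0.2, cp=0.6, cw=0.7)

    def test_interval_actions(self):
        rng = np.random.default_rng(0)
        args = dict(current=1, personal_best=2, global_best=3,
                    bounds=(1, 8), params=self.params, rng=rng)
        assert update_variable(rho=0.1, **args) == 3   # [0, Cg) -> gbest
        assert update_variable(rho=0.3, **args) == 2   # [Cg, Cp) -> pbest
        assert update_variable(rho=0.65, **args) == 1  # [Cp, Cw) -> current
        v = update_variable(rho=0.9, **args)           # [Cw, 1) -> random
        assert 1 <= v <= 8

    def test_action_frequencies_match_interval_widths(self):
        # 1e5 draws; sentinels chosen outside wide bounds so random draws
        # can never collide with them
        rng = np.random.default_rng(1)
        n = 100_000
        rho = rng.random(n)
        counts = {"gbest": 0, "pbest": 0, "current": 0, "random": 0}
        for r in rho:
            v = update_variable(-1, -2, -3, r, (1, 10 ** 6), self.params, rng)
            if v == -3:
                counts["gbest"] += 1
            elif v == -2:
                counts["pbest"] += 1
            elif v == -1:
                counts["current"] += 1
            else:
                counts["random"] += 1
        observed = [counts["gbest"], counts["pbest"], counts["current"],
                    counts["random"]]
        expected = np.array([0.2, 0.4, 0.1, 0.3]) * n
        _, p = stats.chisquare(observed, expected)
        assert p > 0.01


class _FixedRho:
    """Duck-typed RNG whose rho draws are constant."""

    def __init__(self, rho, inner_seed=0):
        self.rho = rho
        self.inner = np.random.default_rng(inner_seed)

    def random(self, n=None):
        return np.full(n, self.rho) if n is not None else self.rho

    def integers(self, lo, hi):
        return self.inner.integers(lo, hi)


class TestUpdateSolution:
    params = SSOParams(cg=0.2, cp=0.6, cw=0.7)

    def test_identity_interval_keeps_solution(self):
        x = np.array([1, 2, 3, 4, 5, 6, 7])
        out = update_solution(x, x + 1, x + 2, BOUNDS7, self.params,
                              _FixedRho(0.65))
        assert np.array_equal(out, x)

    def test_gbest_interval_copies_global_best(self):
        x = np.array([1, 2, 3, 4, 5, 6, 7])
        g = np.array([8, 7, 6, 5, 4, 3, 2])
        out = update_solution(x, x, g, BOUNDS7, self.params, _FixedRho(0.1))
        assert np.array_equal(out, g)

    def test_outputs_stay_within_bounds(self):
        rng = np.random.default_rng(2)
        x = np.array([4] * 7)
        for _ in range(1000):
            x = update_solution(x, x, x, BOUNDS7, self.params, rng)
            assert all(1 <= v <= 8 for v in x)


class TestOptimize:
    def test_constant_fitness_keeps_first_particle(self):
        params = SSOParams(n_gen=5, n_sol=4, seed=0)
        state = sso_optimize(lambda x: 0.5, BOUNDS7, params)
        assert state.gbest == 0.5
        # strict-improvement rule: G is the first evaluated particle
        rng = np.random.default_rng(0)
        init_first = np.array([rng.integers(lo, hi + 1) for lo, hi in BOUNDS7])
        assert np.array_equal(state.G, init_first)

    def test_history_monotone_nondecreasing(self):
        fit = toy_fitness((3, 7, 1, 5, 8, 2, 6), BOUNDS7)
        state = sso_optimize(fit, BOUNDS7, SSOParams(n_gen=20, n_sol=8, seed=3))
        assert np.all(np.diff(state.history) >= 0)
        assert len(state.history) == 8 + 20 * 8  # init + n_gen * n_sol evals

    def test_nonfinite_fitness_identifies_particle(self):
        with pytest.raises(ValueError, match="particle"):
            sso_optimize(lambda x: float("nan"), BOUNDS7,
                         SSOParams(n_gen=1, n_sol=2, seed=0))

    def test_near_unit_current_interval_freezes_at_best_initial(self):
        # current-action probability ~1: no particle should ever beat the
        # best initial fitness
        fit = toy_fitness((4, 4, 4, 4, 4, 4, 4), BOUNDS7)
        params = SSOParams(cg=1e-9, cp=2e-9, cw=1.0 - 1e-9,
                           n_gen=20, n_sol=6, seed=4)
        state = sso_optimize(fit, BOUNDS7, params)
        assert state.gbest == max(state.pbest_values)
        assert state.history[-1] == state.history[params.n_sol - 1]

    def test_finds_toy_optimum_in_most_seeds(self):
        # exploitative setting on the separable toy landscape
        target = (3, 7, 1, 5, 8, 2, 6)
        fit = toy_fitness(target, BOUNDS7)
        hits = sum(
            sso_optimize(fit, BOUNDS7,
                         SSOParams(cg=0.4, cp=0.75, cw=0.8,
                                   n_gen=30, n_sol=10, seed=s)).gbest == 1.0
            for s in range(10))
        assert hits >= 5

    def test_beats_random_search_at_equal_budget(self):
        fit = toy_fitness((3, 7, 1, 5, 8, 2, 6), BOUNDS7)
        diffs = []
        for s in range(20):
            params = SSOParams(cg=0.2, cp=0.6, cw=0.7, n_gen=30, n_sol=10,
                               seed=s)
            state = sso_optimize(fit, BOUNDS7, params)
            budget = len(state.history)
            diffs.append(state.gbest - random_search(fit, BOUNDS7, budget,
                                                     seed=10_000 + s))
        assert np.mean(diffs) >= 0


class TestLevelExperiment:
    fit = staticmethod(toy_fitness((3, 7, 1, 5, 8, 2, 6), BOUNDS7))

    def test_four_levels_five_repeats(self):
        levels = [SSOParams(cg=c[0], cp=c[1], cw=c[2], n_gen=10, n_sol=5)
                  for c in ((0.7, 0.8, 0.9), (0.1, 0.8, 0.9),
                            (0.1, 0.2, 0.9), (0.1, 0.2, 0.3))]
        out = level_experiment(levels, repeats=5, fitness=self.fit,
                               bounds=BOUNDS7, base_seed=0)
        assert sum(len(g) for g in out["groups"]) == 20
        for row, group in zip(out["summary"], out["groups"]):
            assert row["best"] == max(group)
            assert row["best"] >= row["average"]

    def test_duplicated_level_is_null_design(self):
        from ssokd.evaluation import one_way_anova
        level = SSOParams(cg=0.2, cp=0.6, cw=0.7, n_gen=5, n_sol=5)
        out = level_experiment([level, level], repeats=5, fitness=self.fit,
                               bounds=BOUNDS7, base_seed=1)
        # distinct seeds per (level, repeat): groups differ but share a mean
        res = one_way_anova(out["groups"])
        assert res["p"] > 0.01

    def test_requires_two_repeats(self):
        with pytest.raises(ValueError, match="repeats"):
            level_experiment([SSOParams()], repeats=1, fitness=self.fit,
                             bounds=BOUNDS7)

    def test_bad_interval_ordering_rejected(self):
        with pytest.raises(ValueError, match="Cg < Cp < Cw"):
            SSOParams(cg=0.6, cp=0.2, cw=0.7)
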