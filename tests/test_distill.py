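"""Distillation losses against independent arithmetic oracles, the grid
protocol and the comparability t-test."""

import numpy as np
import pytest
from scipy import stats

from ssokd.distill import (KDConfig, combined_loss, comparability_test,
                           distill, distillation_grid, hard_loss, soft_loss,
                           temperature_softmax)
from ssokd.fusion import FusionClassifier, TrainConfig, decode_solution


class TestTemperatureSoftmax:
    def test_symmetric_logits_give_half(self):
        for T in (0.5, 1.0, 7.0):
            assert np.allclose(temperature_softmax((0.0, 0.0), T), [0.5, 0.5])

    def test_t_one_is_standard_softmax(self):
        z = np.array([0.3, -1.2, 2.0])
        expected = np.exp(z) / np.exp(z).sum()
        assert np.allclose(temperature_softmax(z, 1.0), expected)

    def test_arithmetic_oracle(self):
        # logits (1,2,3) at T=2 -> exp(0.5,1.0,1.5)/sum
        e = np.exp([0.5, 1.0, 1.5])
        assert np.allclose(temperature_softmax((1, 2, 3), 2.0), e / e.sum())

    def test_sums_to_one(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = temperature_softmax(rng.normal(0, 5, 6), rng.uniform(0.1, 20))
            assert np.all(p > 0)
            assert abs(p.sum() - 1.0) < 1e-12

    def test_nonpositive_temperature(self):
        with pytest.raises(ValueError, match="temperature"):
            temperature_softmax((1.0, 2.0), 0.0)

    def test_entropy_nondecreasing_in_temperature(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            z = rng.normal(0, 3, 5)
            ent = []
            for T in (0.5, 1, 2, 5, 10, 50):
                p = temperature_softmax(z, T)
                ent.append(-np.sum(p * np.log(p)))
            assert np.all(np.diff(ent) >= -1e-12)


class TestSoftLoss:
    def test_self_distillation_equals_entropy(self):
        z = np.array([1.5, -0.5, 0.2])
        p = temperature_softmax(z, 3.0)
        entropy = -np.sum(p * np.log(p))
        assert np.isclose(soft_loss(z, z, 3.0), entropy)
        # cross-entropy >= entropy, equality iff q = p
        assert soft_loss(z, z + np.array([1.0, 0, 0]), 3.0) > entropy

    def test_large_temperature_approaches_log_n(self):
        z_t = np.array([2.0, -1.0, 0.5, 1.0])
        z_s = np.array([-3.0, 1.0, 0.0, 2.0])
        assert abs(soft_loss(z_t, z_s, 1e6) - np.log(4)) < 1e-4

    def test_arithmetic_oracle(self):
        # teacher (2,0), student (0,2), T=1: brute-force evaluation
        p = np.exp([2.0, 0.0]) / np.exp([2.0, 0.0]).sum()
        q = np.exp([0.0, 2.0]) / np.exp([0.0, 2.0]).sum()
        expected = -(p[0] * np.log(q[0]) + p[1] * np.log(q[1]))
        assert np.isclose(soft_loss((2, 0), (0, 2), 1.0), expected)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="shapes"):
            soft_loss((1, 2, 3), (1, 2), 1.0)

    def test_gradient_vanishes_when_student_matches_teacher(self):
        z = np.array([0.7, -1.1])
        eps = 1e-6
        for j in range(2):
            d = np.zeros(2)
            d[j] = eps
            g = (soft_loss(z, z + d, 4.0) - soft_loss(z, z - d, 4.0)) / (2 * eps)
            assert abs(g) < 1e-6


class TestHardLoss:
    def test_confident_correct_approaches_zero(self):
        assert hard_loss((20.0, -20.0), (1, 0)) < 1e-8

    def test_uniform_two_class_is_log_two(self):
        assert np.isclose(hard_loss((0.3, 0.3), (0, 1)), np.log(2))

    def test_arithmetic_oracle(self):
        # logits (1,3), true class 0 -> -log softmax_0 = log(1 + e^2)
        assert np.isclose(hard_loss((1.0, 3.0), (1, 0)), np.log(1 + np.e ** 2))

    def test_invalid_onehot(self):
        with pytest.raises(ValueError, match="one-hot"):
            hard_loss((1.0, 2.0), (1, 1))


class TestCombinedLoss:
    t_logits = np.array([1.2, -0.4])
    s_logits = np.array([0.1, 0.8])
    c = (0, 1)

    def test_endpoints(self):
        kd0 = KDConfig(alpha=0.0, temperature=4.0)
        kd1 = KDConfig(alpha=1.0, temperature=4.0)
        assert np.isclose(combined_loss(self.t_logits, self.s_logits, self.c, kd0),
                          hard_loss(self.s_logits, self.c))
        assert np.isclose(combined_loss(self.t_logits, self.s_logits, self.c, kd1),
                          soft_loss(self.t_logits, self.s_logits, 4.0))

    def test_linear_in_alpha(self):
        l0 = combined_loss(self.t_logits, self.s_logits, self.c,
                           KDConfig(alpha=0.0, temperature=4.0))
        l1 = combined_loss(self.t_logits, self.s_logits, self.c,
                           KDConfig(alpha=1.0, temperature=4.0))
        for a in (0.1, 0.25, 0.5, 0.75, 0.9):
            val = combined_loss(self.t_logits, self.s_logits, self.c,
                                KDConfig(alpha=a, temperature=4.0))
            assert np.isclose(val, (1 - a) * l0 + a * l1)

    def test_midpoint_is_mean(self):
        mid = combined_loss(self.t_logits, self.s_logits, self.c,
                            KDConfig(alpha=0.5, temperature=4.0))
        assert np.isclose(mid, 0.5 * (hard_loss(self.s_logits, self.c)
                                      + soft_loss(self.t_logits, self.s_logits, 4.0)))


class TestComparability:
    def test_zero_mean_differences_are_comparable(self):
        # diffs (0.01,-0.01,0.02,-0.02,0): t = 0 by the hand formula -> p = 1
        teacher = np.array([0.90, 0.90, 0.90, 0.90, 0.90])
        student = teacher + np.array([0.01, -0.01, 0.02, -0.02, 0.0])
        out = comparability_test(teacher, student)
        diffs = student - teacher
        t_hand = diffs.mean() / (diffs.std(ddof=1) / np.sqrt(len(diffs)))
        p_hand = 2 * stats.t.sf(abs(t_hand), len(diffs) - 1)
        assert np.isclose(out["t_statistic"], t_hand)
        assert np.isclose(out["p_value"], p_hand)
        assert out["verdict"] == "comparable"

    def test_consistent_gap_is_not_comparable(self):
        teacher = np.array([0.90, 0.91, 0.89, 0.90, 0.92])
        student = teacher - 0.05 + np.array([1, -1, 2, -2, 0]) * 1e-3
        out = comparability_test(teacher, student)
        assert out["p_value"] < 0.025
        assert out["verdict"] == "not comparable"

    def test_verdict_threshold_is_half_alpha(self):
        out = comparability_test((0.9, 0.91, 0.92, 0.89),
                                 (0.88, 0.93, 0.90, 0.91))
        assert out["threshold"] == 0.025
        assert (out["verdict"] == "comparable") == (out["p_value"] >= 0.025)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError, match="variance"):
            comparability_test((0.9, 0.9, 0.9), (0.85, 0.85, 0.85))

    def test_requires_pairs(self):
        with pytest.raises(ValueError):
            comparability_test((0.9,), (0.8,))


class TestDistillProtocol:
    def _setup(self, micro_arrays, seed=0):
        tc = TrainConfig(epochs=2, seed=seed)
        teacher = FusionClassifier(
            decode_solution((16, 20, 16, 20, 16, 20, 50),
                            backbone_name="tiny"),
            input_shape=(16, 16, 1), seed=seed)
        teacher.fit(micro_arrays.train, micro_arrays.validation, tc)
        return teacher, tc

    def test_alpha_zero_reproduces_hard_training_exactly(self, micro_arrays):
        teacher, tc = self._setup(micro_arrays)
        res, _ = distill(teacher, decode_solution((10, 20, 40, 20, 100, 20, 50)),
                         micro_arrays, tc, KDConfig(alpha=1e-12))
        # alpha ~ 0: same loss signal and same seed as the baseline
        assert res.delta == 0.0

    def test_delta_bookkeeping(self, micro_arrays):
        teacher, tc = self._setup(micro_arrays)
        res, _ = distill(teacher, decode_solution((10, 20, 40, 20, 100, 20, 50)),
                         micro_arrays, tc, KDConfig(alpha=0.7))
        assert np.isclose(res.delta,
                          res.student_accuracy_after - res.student_accuracy_before)

    def test_grid_shapes(self, micro_arrays):
        tc = TrainConfig(epochs=1, seed=0)
        teachers = {}
        for name in ("t1", "t2", "t3"):
            m = FusionClassifier(
                decode_solution((8, 20, 8, 20, 8, 20, 50),
                                backbone_name="tiny"),
                input_shape=(16, 16, 1), seed=hash(name) % 100)
            m.fit(micro_arrays.train, micro_arrays.validation, tc)
            teachers[name] = m
        students = {f"s{i}": decode_solution((4 + i, 20, 8, 20, 8, 20, 50))
                    for i in range(3)}
        results, report, models = distillation_grid(teachers, students,
                                                    micro_arrays, tc)
        assert len(results) == 9  # 3 teachers x 3 students
        assert len(report) == 9
        assert np.isclose(report.attrs["mean_delta_pct"],
                          report["delta_pct"].astype(float).mean(), atol=0.01)

    def test_single_pair_grid(self, micro_arrays):
        teacher, tc = self._setup(micro_arrays)
        results, report, _ = distillation_grid(
            {"t": teacher}, {"s": decode_solution((8, 20, 8, 20, 8, 20, 50))},
            micro_arrays, tc)
        assert len(results) == 1

    def test_empty_grid_rejected(self, micro_arrays):
        with pytest.raises(ValueError, match="at least one"):
            distillation_grid({}, {}, micro_arrays)
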