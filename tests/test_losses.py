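"""Unit and property tests for the distillation losses and schedules."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crossdistill.losses import (
    AnnealingSchedule,
    DistillationConfig,
    annealed_alpha,
    combined_loss,
    combined_loss_grad,
    distillation_loss,
    selective_combined_loss,
    softened_probabilities,
    student_loss,
)

finite_logits = st.lists(
    st.floats(min_value=-30, max_value=30, allow_nan=False), min_size=2, max_size=8
).map(np.array)


class TestSoftenedProbabilities:
    @pytest.mark.parametrize(
        "z, T, expected",
        [
            ([0.0, 0.0], 1.0, [0.5, 0.5]),
            ([math.log(2), 0.0], 1.0, [2 / 3, 1 / 3]),
            # dividing by T=2 halves the logits: softmax([1, 0])
            ([2.0, 0.0], 2.0, [0.731059, 0.268941]),
        ],
    )
    def test_closed_form(self, z, T, expected):
        np.testing.assert_allclose(
            softened_probabilities(np.array(z), T), expected, atol=1e-6
        )

    @given(z=finite_logits, T=st.floats(min_value=0.1, max_value=100))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_normalized_positive_and_shift_invariant(self, z, T):
        p = softened_probabilities(z, T)
        assert abs(p.sum() - 1.0) < 1e-6
        assert (p > 0).all()
        np.testing.assert_allclose(p, softened_probabilities(z + 17.3, T), atol=1e-9)

    def test_high_temperature_flattens_to_uniform(self, rng):
        z = rng.uniform(-50, 50, size=10)
        p = softened_probabilities(z, T=1e6)
        assert np.abs(p - 0.1).max() < 1e-3

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            softened_probabilities(np.array([0.0, 1.0]), T=0.0)
        with pytest.raises(ValueError):
            softened_probabilities(np.array([0.0, 1.0]), T=-1.0)
        with pytest.raises(ValueError):
            softened_probabilities(np.array([np.nan, 1.0]), T=1.0)


class TestDistillationLoss:
    def test_uniform_self_cross_entropy_is_ln2(self):
        z = np.array([0.0, 0.0])
        for T in (0.5, 1.0, 8.0):
            assert distillation_loss(z, z, T) == pytest.approx(math.log(2), abs=1e-12)

    def test_hand_computed_asymmetric_case(self):
        # p_t = [3/4, 1/4], p_s = [1/4, 3/4]
        oracle = -(0.75 * math.log(0.25) + 0.25 * math.log(0.75))
        got = distillation_loss(np.array([math.log(3), 0.0]), np.array([0.0, math.log(3)]), 1.0)
        assert got == pytest.approx(oracle, abs=1e-9)
        assert got == pytest.approx(1.111641, abs=1e-5)

    @given(z=finite_logits, T=st.floats(min_value=0.2, max_value=20))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_self_distillation_equals_entropy(self, z, T):
        p = softened_probabilities(z, T)
        entropy = -(p * np.log(p)).sum()
        assert distillation_loss(z, z, T) == pytest.approx(entropy, abs=1e-9)

    @given(zt=finite_logits, T=st.floats(min_value=0.2, max_value=20),
           data=st.data())
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_gibbs_inequality_minimum_at_teacher(self, zt, T, data):
        zs = data.draw(st.lists(
            st.floats(min_value=-30, max_value=30, allow_nan=False),
            min_size=len(zt), max_size=len(zt)).map(np.array))
        p = softened_probabilities(zt, T)
        entropy = -(p * np.log(p)).sum()
        assert distillation_loss(zt, zs, T) >= entropy - 1e-9

    def test_batched_mean_reduction(self, rng):
        zt = rng.normal(size=(5, 4))
        zs = rng.normal(size=(5, 4))
        per = [distillation_loss(zt[i], zs[i], 3.0) for i in range(5)]
        assert distillation_loss(zt, zs, 3.0) == pytest.approx(np.mean(per))

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            distillation_loss(np.zeros(3), np.zeros(4), 1.0)


class TestStudentLoss:
    def test_uniform_logits_give_ln2(self):
        for mode in ("paper_literal", "unit_temperature"):
            got = student_loss(np.array([0.0, 0.0]), np.array([1, 0]), 5.0, mode)
            assert got == pytest.approx(math.log(2), abs=1e-12)

    def test_confident_correct_and_wrong_predictions(self):
        z = np.array([10.0, -10.0])
        assert student_loss(z, np.array([1, 0]), 1.0) == pytest.approx(2.06e-9, rel=1e-2)
        assert student_loss(z, np.array([0, 1]), 1.0) == pytest.approx(20.0, rel=1e-6)

    def test_temperature_applies_only_in_paper_literal_mode(self):
        z = np.array([4.0, 0.0])
        y = np.array([1, 0])
        literal = student_loss(z, y, 4.0, "paper_literal")
        unit = student_loss(z, y, 4.0, "unit_temperature")
        assert literal == pytest.approx(student_loss(z / 4.0, y, 1.0))
        assert unit == pytest.approx(student_loss(z, y, 1.0))
        assert literal != pytest.approx(unit)

    def test_invalid_one_hot_rejected(self):
        z = np.zeros(3)
        for bad in ([1, 1, 0], [0, 0, 0], [0.5, 0.5, 0]):
            with pytest.raises(ValueError):
                student_loss(z, np.array(bad), 1.0)


class TestCombinedLoss:
    def test_alpha_endpoints_recover_pure_terms(self, rng):
        zt, zs = rng.normal(size=(2, 6))
        y = np.eye(6)[2]
        full = combined_loss(zt, zs, y, 1.0, 3.0)
        assert full.total == pytest.approx(distillation_loss(zt, zs, 3.0))
        none = combined_loss(zt, zs, y, 0.0, 3.0)
        assert none.total == pytest.approx(student_loss(zs, y, 3.0))

    def test_convex_combination_arithmetic(self):
        # L_D = 1.0, L_S = 2.0, alpha = 0.6 -> 1.4, independent of the logits
        bd = combined_loss(np.zeros(2), np.zeros(2), np.array([1, 0]), 0.6, 1.0)
        ln2 = math.log(2)
        assert bd.total == pytest.approx(0.6 * ln2 + 0.4 * ln2)
        assert 0.6 * 1.0 + 0.4 * 2.0 == pytest.approx(1.4)

    @given(a=st.floats(min_value=0, max_value=1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_affine_in_alpha(self, a):
        rng = np.random.default_rng(5)
        zt, zs = rng.normal(size=(2, 5))
        y = np.eye(5)[1]
        at0 = combined_loss(zt, zs, y, 0.0, 2.0).total
        at1 = combined_loss(zt, zs, y, 1.0, 2.0).total
        assert combined_loss(zt, zs, y, a, 2.0).total == pytest.approx(
            (1 - a) * at0 + a * at1, abs=1e-9
        )

    def test_breakdown_contract_per_example(self, rng):
        zt = rng.normal(size=(4, 3))
        zs = rng.normal(size=(4, 3))
        y = np.eye(3)[rng.integers(0, 3, 4)]
        alpha = np.array([0.0, 0.3, 0.8, 1.0])
        bd = combined_loss(zt, zs, y, alpha, 2.0)
        expect = alpha * bd.per_example_distillation + (1 - alpha) * bd.per_example_student
        np.testing.assert_allclose(bd.per_example_total, expect, atol=1e-12)
        assert bd.total == pytest.approx(expect.mean())

    def test_alpha_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            combined_loss(np.zeros(2), np.zeros(2), np.array([1, 0]), 1.5, 1.0)
        with pytest.raises(ValueError):
            DistillationConfig(alpha=-0.1)

    @pytest.mark.parametrize("T,mode,rescale", [
        (8.0, "paper_literal", False),
        (2.0, "unit_temperature", False),
        (4.0, "paper_literal", True),
    ])
    def test_gradient_matches_finite_differences(self, T, mode, rescale, rng):
        zt = rng.normal(size=(3, 4))
        zs = rng.normal(size=(3, 4))
        y = np.eye(4)[rng.integers(0, 4, 3)]
        base = lambda z: combined_loss(zt, z, y, 0.7, T, mode)  # noqa: E731
        g = combined_loss_grad(zt, zs, y, 0.7, T, mode, rescale_grad_t2=rescale)
        eps = 1e-6
        num = np.zeros_like(zs)
        for i in range(zs.shape[0]):
            for j in range(zs.shape[1]):
                zp, zm = zs.copy(), zs.copy()
                zp[i, j] += eps
                zm[i, j] -= eps
                num[i, j] = (base(zp).total - base(zm).total) / (2 * eps)
        if rescale:
            # rescaling multiplies only the distillation part by T^2
            g_plain = combined_loss_grad(zt, zs, y, 0.7, T, mode)
            g_d = (softened_probabilities(zs, T) - softened_probabilities(zt, T)) / T
            np.testing.assert_allclose(
                g, g_plain + 0.7 * (T * T - 1) * g_d / zs.shape[0], atol=1e-9
            )
        else:
            np.testing.assert_allclose(g, num, atol=1e-6)

    def test_pure_distillation_gradient_ignores_labels(self, rng):
        # with alpha=1 the hard labels drop out of the objective entirely
        zt = rng.normal(size=(6, 5))
        zs = rng.normal(size=(6, 5))
        labels = rng.integers(0, 5, 6)
        y1 = np.eye(5)[labels]
        y2 = np.eye(5)[np.roll(labels, 2)]
        g1 = combined_loss_grad(zt, zs, y1, 1.0, 8.0, "paper_literal")
        g2 = combined_loss_grad(zt, zs, y2, 1.0, 8.0, "paper_literal")
        np.testing.assert_array_equal(g1, g2)


class TestAnnealedAlpha:
    def test_endpoints_and_midpoint(self):
        sch = AnnealingSchedule(1.0, 0.4, 7)
        assert annealed_alpha(sch, 0) == pytest.approx(1.0)
        assert annealed_alpha(sch, 6) == pytest.approx(0.4)
        assert annealed_alpha(sch, 3) == pytest.approx(0.7)

    def test_single_iteration_returns_start(self):
        assert annealed_alpha(AnnealingSchedule(0.8, 0.2, 1), 0) == 0.8

    def test_exactly_linear_second_differences_vanish(self):
        sch = AnnealingSchedule(0.9, 0.1, 101)
        vals = np.array([annealed_alpha(sch, i) for i in range(101)])
        assert np.abs(np.diff(vals, 2)).max() < 1e-12
        assert vals.min() >= 0.1 - 1e-12 and vals.max() <= 0.9 + 1e-12

    def test_index_out_of_range_rejected(self):
        sch = AnnealingSchedule(1.0, 0.0, 5)
        with pytest.raises(IndexError):
            annealed_alpha(sch, 5)
        with pytest.raises(IndexError):
            annealed_alpha(sch, -1)

    def test_increasing_schedules_allowed(self):
        sch = AnnealingSchedule(0.2, 0.8, 4)
        assert [annealed_alpha(sch, i) for i in range(4)] == pytest.approx(
            [0.2, 0.4, 0.6, 0.8]
        )


class TestSelectiveCombinedLoss:
    def _batch(self, rng, n=4, c=5):
        zt = rng.normal(size=(n, c))
        zs = rng.normal(size=(n, c))
        labels = rng.integers(0, c, n)
        return zt, zs, np.eye(c)[labels], labels

    def test_bootstrap_phase_is_bit_identical_to_default(self, rng):
        zt, zs, y, _ = self._batch(rng)
        a = selective_combined_loss(zt, zs, y, 0.6, 4.0, in_bootstrap=True)
        b = combined_loss(zt, zs, y, 0.6, 4.0)
        assert a.total == b.total
        np.testing.assert_array_equal(a.per_example_total, b.per_example_total)

    def test_perfect_teacher_is_noop(self, rng):
        zs = rng.normal(size=(4, 5))
        labels = np.array([0, 2, 4, 1])
        y = np.eye(5)[labels]
        zt = y * 10.0  # teacher argmax equals the label everywhere
        sel = selective_combined_loss(zt, zs, y, 0.6, 4.0, in_bootstrap=False)
        assert sel.total == combined_loss(zt, zs, y, 0.6, 4.0).total

    def test_always_wrong_teacher_reduces_to_student_loss(self, rng):
        zs = rng.normal(size=(4, 5))
        labels = np.array([0, 2, 4, 1])
        y = np.eye(5)[labels]
        zt = np.eye(5)[(labels + 1) % 5] * 10.0
        sel = selective_combined_loss(zt, zs, y, 0.6, 4.0, in_bootstrap=False)
        assert sel.total == pytest.approx(student_loss(zs, y, 4.0))
        assert (sel.alpha_used == 0).all()

    def test_mixed_batch_per_example_arithmetic(self):
        zt = np.array([[5.0, 0.0], [5.0, 0.0]])  # teacher predicts class 0 twice
        zs = np.array([[1.0, -1.0], [0.5, 0.5]])
        y = np.array([[1, 0], [0, 1]])  # correct on ex 0, wrong on ex 1
        sel = selective_combined_loss(zt, zs, y, 0.6, 2.0, in_bootstrap=False)
        ld = [distillation_loss(zt[i], zs[i], 2.0) for i in range(2)]
        ls = [student_loss(zs[i], y[i], 2.0) for i in range(2)]
        expect = np.mean([0.6 * ld[0] + 0.4 * ls[0], ls[1]])
        assert sel.total == pytest.approx(expect)

    def test_argmax_ties_break_to_lowest_class(self):
        zt = np.array([[3.0, 3.0, 0.0]])  # tie between classes 0 and 1
        zs = np.array([[0.0, 0.0, 0.0]])
        y0 = np.array([[1, 0, 0]])
        y1 = np.array([[0, 1, 0]])
        sel0 = selective_combined_loss(zt, zs, y0, 0.6, 1.0, in_bootstrap=False)
        sel1 = selective_combined_loss(zt, zs, y1, 0.6, 1.0, in_bootstrap=False)
        assert sel0.alpha_used[0] == 0.6  # tie resolved to class 0: correct
        assert sel1.alpha_used[0] == 0.0
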