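"""CTC: collapse mapping, forward recursion vs enumeration, loss, decoders."""

import math

import numpy as np
import pytest

from conftest import random_row_stochastic
from tcncall.ctc import (
    ZeroProbabilityError,
    beam_search_decode,
    brute_force_probability,
    collapse,
    ctc_loss,
    ctc_loss_and_grad,
    ctc_probability,
    greedy_decode,
)
from tcncall.nn import log_softmax


def all_collapsed_sequences(T: int) -> set[str]:
    import itertools

    out = set()
    for s in itertools.product("ACGT-", repeat=T):
        out.add(collapse("".join(s)))
    return out


class TestCollapse:
    def test_merge_then_deblank(self):
        assert collapse("AA--G-C") == "AGC"

    def test_all_blanks_empty(self):
        assert collapse("-----") == ""

    def test_blank_separates_repeat(self):
        assert collapse("A-A") == "AA"

    def test_left_inverse_on_clean_sequences(self, rng):
        for _ in range(50):
            n = int(rng.integers(0, 12))
            seq = []
            for _ in range(n):  # no adjacent repeats, no blanks
                choices = [b for b in "ACGT" if not seq or b != seq[-1]]
                seq.append(str(rng.choice(choices)))
            s = "".join(seq)
            assert collapse(s) == s


class TestCtcProbability:
    def test_uniform_two_frame_worked_example(self):
        O = np.full((2, 5), 0.2)
        assert abs(ctc_probability(O, "A") - 0.12) < 1e-12

    def test_single_frame_single_path(self):
        O = np.array([[0.5, 0, 0, 0, 0.5]])
        assert ctc_probability(O, "A") == pytest.approx(0.5)

    def test_impossible_length_gives_zero(self, rng):
        O = random_row_stochastic(rng, 3)
        assert ctc_probability(O, "ACGT") == 0.0

    def test_forward_equals_brute_force(self, rng):
        """Forward recursion == literal path-sum enumeration, 200 random
        (matrix, label) instances with T <= 6."""
        for _ in range(200):
            T = int(rng.integers(1, 7))
            O = random_row_stochastic(rng, T)
            m = int(rng.integers(0, T + 1))
            y = "".join(rng.choice(list("ACGT"), size=m))
            assert abs(ctc_probability(O, y) - brute_force_probability(O, y)) < 1e-10

    def test_distribution_normalizes(self, rng):
        """P sums to 1 over all distinct collapsed sequences (B partitions
        the path space)."""
        for T in (1, 2, 3, 4):
            O = random_row_stochastic(rng, T)
            total = sum(ctc_probability(O, y) for y in all_collapsed_sequences(T))
            assert abs(total - 1.0) < 1e-9


class TestCtcLoss:
    def test_certain_label_zero_loss(self):
        O = np.zeros((1, 5))
        O[0, 0] = 1.0
        assert ctc_loss(O, "A") == pytest.approx(0.0)

    def test_uniform_worked_example(self):
        O = np.full((2, 5), 0.2)
        assert ctc_loss(O, "A") == pytest.approx(-math.log(0.12), abs=1e-9)

    def test_zero_probability_label_raises(self, rng):
        O = random_row_stochastic(rng, 2)
        with pytest.raises(ZeroProbabilityError):
            ctc_loss(O, "ACG")

    def test_gradient_matches_finite_differences(self, rng):
        logits = rng.normal(size=(2, 6, 5))
        labels = ["AC", "G"]

        def total(lg):
            losses, _ = ctc_loss_and_grad(log_softmax(lg, -1), labels)
            return losses.sum()

        _, grad = ctc_loss_and_grad(log_softmax(logits, -1), labels)
        eps = 1e-6
        for _ in range(25):
            b, t, k = rng.integers(2), rng.integers(6), rng.integers(5)
            pert = logits.copy()
            pert[b, t, k] += eps
            numeric = (total(pert) - total(logits)) / eps
            assert abs(numeric - grad[b, t, k]) < 1e-5

    def test_gradient_descent_decreases_loss(self, rng):
        """50 plain gradient steps on the logits of a fixed tiny instance
        shrink the loss monotonically."""
        logits = rng.normal(size=(1, 8, 5))
        label = ["ACG"]
        losses = []
        for _ in range(50):
            lo, grad = ctc_loss_and_grad(log_softmax(logits, -1), label)
            losses.append(lo[0])
            logits -= 0.05 * grad
        diffs = np.diff(losses)
        assert losses[-1] < losses[0]
        assert np.all(diffs <= 1e-9)

    def test_batched_matches_single(self, rng):
        T = 9
        O_batch = np.stack([random_row_stochastic(rng, T) for _ in range(3)])
        labels = ["ACG", "", "TTA"]
        losses, _ = ctc_loss_and_grad(np.log(O_batch), labels)
        for b, y in enumerate(labels):
            assert losses[b] == pytest.approx(-math.log(ctc_probability(O_batch[b], y)), abs=1e-9)


class TestGreedyDecode:
    def test_repeat_then_blank(self):
        O = np.zeros((3, 5))
        O[0, 0] = O[1, 0] = 1.0  # A, A
        O[2, 4] = 1.0  # blank
        assert greedy_decode(O) == "A"

    def test_all_blank_empty(self):
        O = np.zeros((4, 5))
        O[:, 4] = 1.0
        assert greedy_decode(O) == ""

    def test_blank_separated_repeat(self):
        O = np.zeros((3, 5))
        O[0, 0] = 1.0
        O[1, 4] = 1.0
        O[2, 0] = 1.0
        assert greedy_decode(O) == "AA"

    def test_tie_breaks_to_lowest_index(self):
        O = np.full((1, 5), 0.2)
        assert greedy_decode(O) == "A"


class TestBeamSearch:
    def test_beats_greedy_on_split_mass(self):
        """Two frames of (A:0.4, blank:0.6): P([A])=0.64 > P([])=0.36, so the
        beam returns A while the framewise argmax path collapses to nothing."""
        O = np.array([[0.4, 0, 0, 0, 0.6], [0.4, 0, 0, 0, 0.6]])
        bases, score = beam_search_decode(O, beam_width=10)
        assert bases == "A"
        assert math.exp(score) == pytest.approx(0.64)
        assert greedy_decode(O) == ""

    def test_exhaustive_width_matches_brute_force_argmax(self, rng):
        for _ in range(50):
            T = int(rng.integers(1, 5))
            O = random_row_stochastic(rng, T)
            best_y = max(
                all_collapsed_sequences(T),
                key=lambda y: brute_force_probability(O, y),
            )
            bases, _ = beam_search_decode(O, beam_width=5**T)
            assert bases == best_y

    def test_one_hot_matches_greedy(self, rng):
        for _ in range(10):
            T = int(rng.integers(1, 8))
            O = np.zeros((T, 5))
            O[np.arange(T), rng.integers(0, 5, size=T)] = 1.0
            for width in (1, 4, 50):
                assert beam_search_decode(O, width)[0] == greedy_decode(O)

    def test_score_nondecreasing_in_width(self, rng):
        for _ in range(10):
            O = random_row_stochastic(rng, 5)
            scores = [beam_search_decode(O, w)[1] for w in (1, 2, 4, 8, 16, 5**5)]
            assert all(b >= a - 1e-12 for a, b in zip(scores, scores[1:]))

    def test_width_must_be_positive(self, rng):
        with pytest.raises(ValueError):
            beam_search_decode(random_row_stochastic(rng, 2), 0)
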