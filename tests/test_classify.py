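"""Cosine matching, fall decision and confusion-count evaluation."""

import itertools

import numpy as np
import pytest

import hopfall as hf
from conftest import random_bipolar


class TestCosineSimilarity:
    def test_identical_and_antipodal(self, rng):
        a = random_bipolar(rng, 25)
        assert hf.cosine_similarity(a, a) == pytest.approx(1.0)
        assert hf.cosine_similarity(a, -a) == pytest.approx(-1.0)

    def test_hamming_closed_form_at_distance_five(self, rng):
        a = random_bipolar(rng, 25)
        b = a.copy()
        b[rng.choice(25, size=5, replace=False)] *= -1
        assert hf.cosine_similarity(a, b) == pytest.approx((25 - 10) / 25)

    def test_hamming_identity_exhaustive_n4(self):
        for a_bits in itertools.product([-1.0, 1.0], repeat=4):
            a = np.array(a_bits)
            for b_bits in itertools.product([-1.0, 1.0], repeat=4):
                b = np.array(b_bits)
                d_h = int((a != b).sum())
                assert hf.cosine_similarity(a, b) == pytest.approx((4 - 2 * d_h) / 4)

    def test_hamming_identity_random_pairs(self, rng):
        for _ in range(100):
            a, b = random_bipolar(rng, 25), random_bipolar(rng, 25)
            d_h = int((a != b).sum())
            assert hf.cosine_similarity(a, b) == pytest.approx((25 - 2 * d_h) / 25)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="zero vector"):
            hf.cosine_similarity(np.zeros(5), np.ones(5))
        with pytest.raises(ValueError, match="mismatch"):
            hf.cosine_similarity(np.ones(5), np.ones(6))


class TestClassifySample:
    def templates(self, fall_vec, rng):
        other = random_bipolar(rng, 25)
        return {
            "Fall": hf.PatternTemplate.from_vector(fall_vec, class_label="Fall"),
            "Walk": hf.PatternTemplate.from_vector(other, class_label="Walk"),
        }

    def test_exact_match_is_positive(self, rng):
        p = random_bipolar(rng, 25)
        res = hf.classify_sample(p, self.templates(p, rng), threshold=0.8)
        assert res.is_fall and res.confidence == pytest.approx(1.0)
        assert res.predicted_label == "Fall"

    def test_negation_is_negative(self, rng):
        p = random_bipolar(rng, 25)
        res = hf.classify_sample(-p, self.templates(p, rng), threshold=0.8)
        assert not res.is_fall and res.confidence == pytest.approx(-1.0)

    def test_hamming_five_below_threshold(self, rng):
        p = random_bipolar(rng, 25)
        probe = p.copy()
        probe[rng.choice(25, size=5, replace=False)] *= -1
        res = hf.classify_sample(probe, self.templates(p, rng), threshold=0.8)
        assert res.confidence == pytest.approx(0.6)
        assert not res.is_fall

    def test_missing_fall_template_rejected(self, rng):
        tpl = hf.PatternTemplate.from_vector(random_bipolar(rng, 25), class_label="Walk")
        with pytest.raises(ValueError, match="positive class"):
            hf.classify_sample(random_bipolar(rng, 25), {"Walk": tpl})

    def test_tie_breaks_lexicographically(self, rng):
        p = random_bipolar(rng, 25)
        tpls = {
            "Fall": hf.PatternTemplate.from_vector(p, class_label="Fall"),
            "Aaa": hf.PatternTemplate.from_vector(p, class_label="Aaa"),
        }
        assert hf.classify_sample(p, tpls).predicted_label == "Aaa"

    def test_threshold_bounds(self, rng):
        p = random_bipolar(rng, 25)
        with pytest.raises(ValueError, match="threshold"):
            hf.classify_sample(p, self.templates(p, rng), threshold=1.5)


class TestEvaluate:
    def test_balanced_half(self):
        decisions = [("Fall", True), ("Fall", False), ("Walk", True), ("Walk", False)]
        rep = hf.evaluate(decisions)
        assert (rep.tp, rep.fn, rep.fp, rep.tn) == (1, 1, 1, 1)
        assert rep.accuracy == pytest.approx(0.5)

    def test_perfect(self):
        decisions = [("Fall", True)] * 5 + [("Under", False)] * 5
        assert hf.evaluate(decisions).accuracy == pytest.approx(1.0)

    def test_sixteen_of_eighteen(self):
        decisions = (
            [("Fall", True)] * 8 + [("Walk", False)] * 8
            + [("Walk", True), ("Fall", False)]
        )
        assert hf.evaluate(decisions).accuracy == pytest.approx(16 / 18)

    def test_permutation_invariant(self, rng):
        decisions = [("Fall", bool(b)) for b in rng.integers(0, 2, 20)] + [
            ("Walk", bool(b)) for b in rng.integers(0, 2, 20)
        ]
        shuffled = list(decisions)
        rng.shuffle(shuffled)
        assert hf.evaluate(decisions) == hf.evaluate(shuffled)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            hf.evaluate([])


def test_threshold_monotonicity(rng):
    """Raising the threshold never gains TP and never loses TN."""
    fall_tpl = hf.PatternTemplate.from_vector(random_bipolar(rng, 25), class_label="Fall")
    samples = []
    for _ in range(40):
        label = "Fall" if rng.random() < 0.5 else "Walk"
        probe = fall_tpl.vector.astype(float).copy()
        probe[rng.choice(25, size=rng.integers(0, 12), replace=False)] *= -1
        samples.append((label, probe))
    prev_tp, prev_tn = None, None
    for thr in (0.2, 0.5, 0.8, 1.0):
        decisions = [
            (label, hf.classify_sample(v, {"Fall": fall_tpl}, threshold=thr).is_fall)
            for label, v in samples
        ]
        rep = hf.evaluate(decisions)
        if prev_tp is not None:
            assert rep.tp <= prev_tp and rep.tn >= prev_tn
        prev_tp, prev_tn = rep.tp, rep.tn
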