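"""Hebbian training, recall dynamics, energy and fixed-point structure."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import hopfall as hf
from conftest import random_bipolar

bipolar_pattern = st.lists(st.sampled_from([-1.0, 1.0]), min_size=4, max_size=16)


class TestTrainHebb:
    def test_all_ones_pattern(self):
        W = hf.train_hebb(np.ones(25), eta=1.0)
        off = W.w[~np.eye(25, dtype=bool)]
        assert (off == 1.0).all() and (np.diag(W.w) == 0).all()

    def test_sign_cancels(self, rng):
        p = random_bipolar(rng, 25)
        assert np.array_equal(hf.train_hebb(p).w, hf.train_hebb(-p).w)

    def test_two_pattern_hand_values(self):
        p1 = np.array([1.0, 1.0, -1.0, -1.0])
        p2 = np.array([1.0, -1.0, 1.0, -1.0])
        W = hf.train_hebb([p1, p2], eta=1.0)
        assert W.w[0, 1] == 0 and W.w[0, 2] == 0 and W.w[0, 3] == -2

    @given(st.lists(bipolar_pattern.filter(lambda p: len(p) == 8), min_size=1, max_size=4))
    def test_symmetric_zero_diagonal(self, patterns):
        W = hf.train_hebb([np.array(p) for p in patterns])
        assert np.allclose(W.w, W.w.T)
        assert (np.diag(W.w) == 0).all()

    def test_rejects_non_bipolar_and_mismatch(self):
        with pytest.raises(ValueError, match="bipolar"):
            hf.train_hebb(np.array([0.5, 1.0, -1.0]))
        with pytest.raises(ValueError, match="mismatch"):
            hf.train_hebb([np.ones(4), np.ones(5)])
        with pytest.raises(ValueError, match="eta"):
            hf.train_hebb(np.ones(4), eta=0.0)

    def test_eta_scales_weights(self, rng):
        p = random_bipolar(rng, 10)
        assert np.allclose(hf.train_hebb(p, eta=0.5).w * 2, hf.train_hebb(p, eta=1.0).w)


class TestRecall:
    def test_stored_pattern_is_immediate_fixed_point(self, rng):
        p = random_bipolar(rng, 25)
        W = hf.train_hebb(p)
        res = hf.recall(W, p, mode="sync")
        assert res.converged and res.sweeps == 1
        assert np.array_equal(res.v, p)
        assert np.allclose(hf.local_fields(W, p), 24.0 * p)

    def test_single_flip_corrected_in_one_sync_sweep(self, rng):
        p = random_bipolar(rng, 25)
        W = hf.train_hebb(p)
        probe = p.copy()
        probe[7] *= -1
        res = hf.recall(W, probe, mode="sync")
        assert np.array_equal(res.v, p) and res.sweeps <= 2

    def test_zero_weights_tie_rule_keeps_state(self, rng):
        W = hf.WeightMatrix(w=np.zeros((6, 6)))
        init = random_bipolar(rng, 6)
        for mode in ("async", "sync"):
            res = hf.recall(W, init, mode=mode)
            assert res.converged and np.array_equal(res.v, init)

    def test_tie_rule_down_forces_low(self):
        W = hf.WeightMatrix(w=np.zeros((3, 3)))
        res = hf.recall(W, np.ones(3), mode="sync", tie="down")
        assert (res.v == -1).all()

    def test_recall_is_eta_invariant(self, rng):
        p = random_bipolar(rng, 16)
        probe = p.copy()
        probe[:3] *= -1
        for eta in (0.1, 1.0, 7.5):
            res = hf.recall(hf.train_hebb(p, eta=eta), probe, mode="async", seed=3)
            assert np.array_equal(res.v, p)

    def test_input_validation(self):
        W = hf.train_hebb(np.ones(4))
        with pytest.raises(ValueError, match="bipolar"):
            hf.recall(W, np.array([0.0, 1.0, 1.0, 1.0]))
        with pytest.raises(ValueError, match="max_sweeps"):
            hf.recall(W, np.ones(4), max_sweeps=0)
        with pytest.raises(ValueError, match="mode"):
            hf.recall(W, np.ones(4), mode="jacobi")

    def test_async_energy_trace_monotone(self, rng):
        for trial in range(20):
            p = [random_bipolar(rng, 25) for _ in range(2)]
            W = hf.train_hebb(p)
            res = hf.recall(W, random_bipolar(rng, 25), mode="async", seed=trial)
            assert (np.diff(res.energy) <= 1e-9).all()


class TestEnergy:
    def test_stored_pattern_energy_closed_form(self, rng):
        p = random_bipolar(rng, 25)
        W = hf.train_hebb(p)
        assert hf.energy(W, p) == pytest.approx(-300.0)  # -(25^2 - 25)/2

    def test_negation_symmetry(self, rng):
        p = random_bipolar(rng, 12)
        W = hf.train_hebb([p, random_bipolar(rng, 12)])
        v = random_bipolar(rng, 12)
        assert hf.energy(W, v) == pytest.approx(hf.energy(W, -v))

    def test_external_input_breaks_symmetry(self, rng):
        W = hf.train_hebb(random_bipolar(rng, 6))
        v = random_bipolar(rng, 6)
        I = rng.normal(size=6)
        assert hf.energy(W, v, I) != pytest.approx(hf.energy(W, -v, I))

    def test_stored_pattern_minimizes_energy_small_net(self):
        p = np.array([1.0, -1.0, 1.0])
        W = hf.train_hebb(p)
        states = [np.array(s, dtype=float) for s in itertools.product([-1, 1], repeat=3)]
        energies = {tuple(s): hf.energy(W, s) for s in states}
        assert min(energies.values()) == pytest.approx(energies[tuple(p)])


class TestFixedPoints:
    def test_stored_pattern_and_negation(self, rng):
        p = random_bipolar(rng, 25)
        W = hf.train_hebb(p)
        assert hf.is_fixed_point(W, p)
        assert hf.is_fixed_point(W, -p)

    def test_heavy_corruption_engages_tie_rule(self, rng):
        """At m=12 flips the 13 clean neurons have zero field and are kept."""
        p = random_bipolar(rng, 25)
        W = hf.train_hebb(p)
        flips = rng.choice(25, size=12, replace=False)
        probe = p.copy()
        probe[flips] *= -1
        clean = np.setdiff1d(np.arange(25), flips)
        u = hf.local_fields(W, probe)
        assert np.allclose(u[clean], 0.0)
        res = hf.recall(W, probe, mode="sync", max_sweeps=1)
        assert np.array_equal(res.v[clean], probe[clean])

    def test_enumeration_matches_recall_immediacy(self, rng):
        """Brute-force fixed points == states recall leaves untouched (N=8)."""
        for trial in range(3):
            pats = [random_bipolar(rng, 8) for _ in range(2)]
            W = hf.train_hebb(pats)
            fixed = set(hf.enumerate_fixed_points(W))
            for bits in itertools.product([-1.0, 1.0], repeat=8):
                v = np.array(bits)
                res = hf.recall(W, v, mode="async", seed=trial)
                immediate = res.converged and np.array_equal(res.v, v) and res.sweeps == 1
                assert immediate == (tuple(int(x) for x in bits) in fixed)
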