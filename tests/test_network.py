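"""Two-branch network: forward contracts, stop-gradient, CORN head, loss."""

import math

import numpy as np
import pytest

from uncertram.network import (NetworkConfig, TramNetwork, corn_loss,
                               corn_predict, total_loss)
from uncertram.nn import Adam, Tensor, cross_entropy


def corn_loss_oracle(rank_logits, targets):
    """Looped reference: explicit conditional subsets and binary tasks."""
    rank_logits = np.asarray(rank_logits, dtype=float)
    targets = np.asarray(targets, dtype=int)
    K = rank_logits.shape[1] + 1
    total, terms = 0.0, 0
    for j in range(1, K):                        # binary task j
        for i in range(len(targets)):
            if targets[i] > j - 1:               # conditional subset
                f = rank_logits[i, j - 1]
                p = 1.0 / (1.0 + math.exp(-f))
                label = 1 if targets[i] > j else 0
                total += -math.log(p if label else 1.0 - p)
                terms += 1
    return total / terms


@pytest.fixture
def net(rng):
    return TramNetwork(NetworkConfig(embedding_dim=16), rng)


def small_batch(rng, n=4, size=16, p_dim=8):
    x = rng.normal(size=(n, 1, size, size))
    x_star = np.abs(rng.normal(size=(n, p_dim)))
    return x, x_star


class TestForward:
    def test_train_mode_produces_both_branches(self, net, rng):
        x, x_star = small_batch(rng)
        out = net.forward(x, x_star, mode="train")
        assert out.base_logits.shape == (4, 2)
        assert out.rank_logits.shape == (4, 7)       # K - 1
        assert out.privileged_embedding.shape == (4, 64)
        assert np.all(np.isfinite(out.rank_logits))

    def test_infer_mode_keeps_only_base_branch(self, net, rng):
        x, _ = small_batch(rng)
        out = net.forward(x, mode="infer")
        assert out.base_logits.shape == (4, 2)
        assert out.rank_logits is None

    def test_infer_is_deterministic(self, net, rng):
        x, _ = small_batch(rng)
        net.eval()
        a = net.forward(x, mode="infer").base_logits
        b = net.forward(x, mode="infer").base_logits
        np.testing.assert_array_equal(a, b)

    def test_privileged_length_mismatch_errors(self, net, rng):
        x, _ = small_batch(rng)
        with pytest.raises(ValueError, match="privileged"):
            net.forward(x, np.zeros((4, 5)), mode="train")

    def test_inference_independent_of_privileged_branch(self, net, rng):
        x, _ = small_batch(rng)
        net.eval()
        before = net.forward(x, mode="infer").base_logits
        for p in (net.privileged_encoder.parameters()
                  + net.privileged_predictor.parameters()):
            p.data += rng.normal(size=p.data.shape)
        after = net.forward(x, mode="infer").base_logits
        np.testing.assert_array_equal(before, after)


class TestStopGradient:
    def _step(self, net, rng, loss_fn):
        x, x_star = small_batch(rng)
        y = np.array([0, 1, 0, 1])
        ordinal = np.array([1, 5, 2, 8])
        opt = Adam([(net.encoder_parameters(), 1e-2),
                    (net.rest_parameters(), 1e-2)])
        outs = net.forward_tensors(Tensor(x), Tensor(x_star), mode="train")
        loss = loss_fn(outs, y, ordinal)
        opt.zero_grad()
        loss.backward()
        opt.step()

    @staticmethod
    def _snap(params):
        return [p.data.copy() for p in params]

    @staticmethod
    def _changed(params, snap):
        return any(not np.array_equal(p.data, s)
                   for p, s in zip(params, snap))

    def test_base_loss_only_updates_base_predictor_alone(self, net, rng):
        enc = self._snap(net.encoder_parameters())
        xi = self._snap(net.base_predictor.parameters())
        self._step(net, rng, lambda o, y, t:
                   total_loss(o["base_logits"], y, o["rank_logits"], t,
                              beta=0.0))
        assert not self._changed(net.encoder_parameters(), enc)
        assert self._changed(net.base_predictor.parameters(), xi)

    def test_privileged_loss_reaches_encoder_but_not_base_predictor(
            self, net, rng):
        enc = self._snap(net.encoder_parameters())
        xi = self._snap(net.base_predictor.parameters())
        phi_p = self._snap(net.privileged_encoder.parameters())
        delta = self._snap(net.privileged_predictor.parameters())
        self._step(net, rng,
                   lambda o, y, t: corn_loss(o["rank_logits"], t))
        assert self._changed(net.encoder_parameters(), enc)
        assert self._changed(net.privileged_encoder.parameters(), phi_p)
        assert self._changed(net.privileged_predictor.parameters(), delta)
        assert not self._changed(net.base_predictor.parameters(), xi)

    def test_full_loss_updates_all_components(self, net, rng):
        snaps = {name: self._snap(params) for name, params in [
            ("enc", net.encoder_parameters()),
            ("xi", net.base_predictor.parameters()),
            ("phi_p", net.privileged_encoder.parameters()),
            ("delta", net.privileged_predictor.parameters())]}
        self._step(net, rng, lambda o, y, t:
                   total_loss(o["base_logits"], y, o["rank_logits"], t,
                              beta=0.5))
        assert self._changed(net.encoder_parameters(), snaps["enc"])
        assert self._changed(net.base_predictor.parameters(), snaps["xi"])
        assert self._changed(net.privileged_encoder.parameters(),
                             snaps["phi_p"])
        assert self._changed(net.privileged_predictor.parameters(),
                             snaps["delta"])


class TestCorn:
    def test_exceed_probs_example(self):
        ranks, probs = corn_predict(np.array([2.0, 0.0, -2.0]))
        np.testing.assert_allclose(probs[0], [0.881, 0.440, 0.052], atol=1e-3)
        assert ranks[0] == 2

    def test_extreme_logits_hit_rank_bounds(self):
        assert corn_predict(np.full(7, -10.0))[0][0] == 1
        assert corn_predict(np.full(7, 10.0))[0][0] == 8

    def test_exceed_probs_non_increasing(self, rng):
        logits = rng.normal(scale=3.0, size=(200, 7))
        _, probs = corn_predict(logits)
        assert np.all(np.diff(probs, axis=1) <= 1e-15)

    def test_loss_single_example_lowest_rank(self):
        f = np.array([[0.3, -0.7, 1.2]])
        expected = -math.log(1.0 - 1.0 / (1.0 + math.exp(-0.3)))
        assert float(corn_loss(Tensor(f), np.array([1])).data) == \
            pytest.approx(expected)

    def test_loss_single_example_top_rank(self):
        f = np.array([[0.3, -0.7, 1.2]])
        expected = np.mean([-math.log(1 / (1 + math.exp(-v)))
                            for v in f[0]])
        assert float(corn_loss(Tensor(f), np.array([4])).data) == \
            pytest.approx(expected)

    def test_loss_matches_looped_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(1, 33))
            logits = rng.normal(scale=2.0, size=(n, 7))
            targets = rng.integers(1, 9, size=n)
            got = float(corn_loss(Tensor(logits), targets).data)
            assert got == pytest.approx(corn_loss_oracle(logits, targets),
                                        abs=1e-9)

    def test_confident_correct_predictions_drive_loss_to_zero(self):
        targets = np.array([1, 4, 8])
        logits = np.array([[-20.0] * 7,
                           [20, 20, 20, -20, -20, -20, -20],
                           [20.0] * 7])
        assert float(corn_loss(Tensor(logits), targets).data) < 1e-6

    def test_target_out_of_range_errors(self):
        with pytest.raises(ValueError):
            corn_loss(Tensor(np.zeros((1, 7))), np.array([9]))

    def test_head_recovers_ranks_on_separable_toy_problem(self, rng):
        # scalar feature in 8 bands; train a small ordinal head alone
        from uncertram.nn import Linear, ReLU, Sequential
        n = 512
        x = rng.uniform(0.0, 8.0, size=(n, 1))
        targets = np.clip(np.floor(x[:, 0]).astype(int) + 1, 1, 8)
        head = Sequential(Linear(1, 64, rng), ReLU(), Linear(64, 7, rng))
        opt = Adam([(head.parameters(), 1e-2)])
        for _ in range(1000):
            loss = corn_loss(head(Tensor(x)), targets)
            opt.zero_grad()
            loss.backward()
            opt.step()
        ranks, _ = corn_predict(head(Tensor(x)).data)
        assert (ranks == targets).mean() >= 0.95


class TestTotalLoss:
    def test_beta_zero_is_plain_cross_entropy(self, rng):
        logits = Tensor(rng.normal(size=(4, 2)))
        rank = Tensor(rng.normal(size=(4, 7)))
        y = np.array([0, 1, 1, 0])
        got = total_loss(logits, y, rank, np.array([1, 2, 3, 4]), beta=0.0)
        assert float(got.data) == pytest.approx(
            float(cross_entropy(logits, y).data))

    def test_weighted_sum_arithmetic(self, rng):
        logits = Tensor(rng.normal(size=(4, 2)))
        rank = Tensor(rng.normal(size=(4, 7)))
        y = np.array([0, 1, 1, 0])
        t = np.array([1, 5, 3, 8])
        l1 = float(cross_entropy(logits, y).data)
        l2 = float(corn_loss(rank, t).data)
        got = float(total_loss(logits, y, rank, t, beta=0.5).data)
        assert got == pytest.approx(l1 + 0.5 * l2)

    def test_binary_privileged_head_uses_cross_entropy(self, rng):
        logits = Tensor(rng.normal(size=(4, 2)))
        priv = Tensor(rng.normal(size=(4, 2)))
        y = np.array([0, 1, 1, 0])
        got = float(total_loss(logits, y, priv, y, beta=0.5,
                               privileged_head="binary").data)
        expected = (float(cross_entropy(logits, y).data)
                    + 0.5 * float(cross_entropy(priv, y).data))
        assert got == pytest.approx(expected)

    def test_perfect_predictions_drive_loss_to_zero(self):
        logits = Tensor(np.array([[20.0, -20.0], [-20.0, 20.0]]))
        rank = Tensor(np.array([[-20.0] * 7, [20.0] * 7]))
        y = np.array([0, 1])
        t = np.array([1, 8])
        assert float(total_loss(logits, y, rank, t, beta=0.5).data) < 1e-6
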