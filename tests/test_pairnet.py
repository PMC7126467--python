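"""Normalization contracts, residual identity, forward invariants, training."""

import numpy as np
import pytest

from strandpair import (ModelConfig, PairNet, PairingLabels, TrainConfig,
                        generate_dataset, predict, train)
from strandpair.features import FeatureTensor, separation_mask
from strandpair.model import BetaPairingModel
from strandpair.pairnet import (ConfigurationError, column_normalize,
                                instance_normalize, masked_normalize,
                                resnet_block, row_normalize)
from strandpair.synthetic import SimulationParams


def _full_mask(length):
    return np.ones((length, length), dtype=bool)


class TestNormalizations:
    def test_constant_channels_map_to_zero_pre_affine(self):
        # L = 10 so every row/column has >= 2 masked-in entries
        x = np.full((3, 10, 10), 2.5)
        mask = separation_mask(10)
        for fn in (row_normalize, column_normalize, instance_normalize):
            out = fn(x, mask)
            np.testing.assert_allclose(out, 0.0, atol=1e-9)

    def test_standardized_row_is_nearly_unchanged(self):
        row = np.array([-1.0, 1.0, -1.0, 1.0])
        x = np.tile(row, (1, 4, 1))  # every row already zero-mean unit-std
        out = row_normalize(x, _full_mask(4), epsilon=1e-5)
        assert np.max(np.abs(out - x)) < 1e-4

    def test_hand_arithmetic_two_by_two(self):
        # rows (1,3) and (2,6): means 2 and 4, population stds 1 and 2
        x = np.array([[[1.0, 3.0], [2.0, 6.0]]])
        out = row_normalize(x, _full_mask(2), epsilon=0.0)
        np.testing.assert_allclose(out, [[[-1.0, 1.0], [-1.0, 1.0]]], atol=1e-12)

    def test_column_normalize_is_transposed_row_normalize(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(4, 7, 7))
        cn = column_normalize(x, _full_mask(7))
        rn_t = row_normalize(x.transpose(0, 2, 1), _full_mask(7)).transpose(0, 2, 1)
        np.testing.assert_allclose(cn, rn_t, atol=1e-12)

    def test_single_column_passthrough(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(2, 5, 1))
        out = row_normalize(x, np.ones((5, 1), dtype=bool))
        np.testing.assert_allclose(out, x)  # rows have a single valid entry

    def test_instance_norm_statistics(self):
        rng = np.random.default_rng(2)
        x = rng.normal(2.0, 3.0, size=(3, 9, 9))
        mask = separation_mask(9)
        out = instance_normalize(x, mask, epsilon=1e-8)
        for c in range(3):
            vals = out[c][mask]
            assert abs(vals.mean()) < 1e-9
            assert abs(vals.std() - 1.0) < 1e-4

    def test_masked_out_pixels_do_not_influence_statistics(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(2, 8, 8))
        mask = separation_mask(8)
        out1 = instance_normalize(x, mask)
        x2 = x.copy()
        x2[:, ~mask] = 1e6  # perturb only masked-out pixels
        out2 = instance_normalize(x2, mask)
        np.testing.assert_allclose(out1[:, mask], out2[:, mask], atol=1e-9)


class TestResnetBlock:
    def _block_params(self, c, rng=None, zero=False):
        rng = rng or np.random.default_rng(0)
        conv = (lambda: np.zeros((c, c, 3, 3))) if zero else \
               (lambda: rng.normal(0, 0.1, size=(c, c, 3, 3)))
        return {"rn.g": np.ones(c), "rn.b": np.zeros(c),
                "cn.g": np.ones(c), "cn.b": np.zeros(c),
                "n1.g": np.ones(c), "n1.b": np.zeros(c),
                "W1": conv(), "b1": np.zeros(c),
                "in.g": np.ones(c), "in.b": np.zeros(c),
                "W2": conv(), "b2": np.zeros(c)}

    def test_zero_weights_give_exact_identity(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(8, 9, 9))
        cfg = ModelConfig(n_blocks=1, n_channels=8, in_channels=8)
        y = resnet_block(x, self._block_params(8, zero=True), separation_mask(9), cfg)
        np.testing.assert_array_equal(y, x)

    @pytest.mark.parametrize("length", [5, 17])
    @pytest.mark.parametrize("use_rncn", [True, False])
    def test_shape_preserved(self, length, use_rncn):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(6, length, length))
        cfg = ModelConfig(n_blocks=1, n_channels=6, use_rncn=use_rncn, in_channels=6)
        y = resnet_block(x, self._block_params(6, rng), separation_mask(length), cfg)
        assert y.shape == x.shape

    def test_finite_for_large_inputs(self):
        rng = np.random.default_rng(6)
        x = rng.normal(0, 1e3, size=(6, 11, 11))
        cfg = ModelConfig(n_blocks=1, n_channels=6, in_channels=6)
        y = resnet_block(x, self._block_params(6, rng), separation_mask(11), cfg)
        assert np.all(np.isfinite(y))

    def test_channel_mismatch_rejected(self):
        cfg = ModelConfig(n_blocks=1, n_channels=6, in_channels=6)
        with pytest.raises(ConfigurationError):
            resnet_block(np.zeros((4, 7, 7)), self._block_params(6),
                         separation_mask(7), cfg)


def _random_tensor(length, c, seed):
    rng = np.random.default_rng(seed)
    return FeatureTensor(channels=rng.normal(size=(c, length, length)).astype(np.float32),
                         channel_names=[f"c{k}" for k in range(c)],
                         mask=separation_mask(length))


class TestForward:
    def test_output_symmetric_probability_map(self):
        cfg = ModelConfig(n_blocks=2, n_channels=6, in_channels=5)
        net = PairNet(cfg, seed=0)
        t = _random_tensor(13, 5, 1)
        p = net.forward(t)
        assert np.all(p.probs >= 0) and np.all(p.probs <= 1)
        np.testing.assert_array_equal(p.probs, p.probs.T)

    def test_zero_head_gives_half_everywhere_valid(self):
        cfg = ModelConfig(n_blocks=1, n_channels=6, in_channels=5)
        net = PairNet(cfg, seed=0)
        net.params["out.W"][:] = 0.0
        net.params["out.b"][:] = 0.0
        t = _random_tensor(10, 5, 2)
        p = net.forward(t)
        assert np.all(p.probs[t.mask] == 0.5)
        assert np.all(p.probs[~t.mask] == 0.0)

    def test_sequence_reversal_flips_output_for_symmetric_kernels(self):
        # 180-degree rotation equivariance holds when every 3x3 kernel is
        # centro-symmetric; construct such weights and verify the flip.
        cfg = ModelConfig(n_blocks=2, n_channels=6, in_channels=5)
        net = PairNet(cfg, seed=3)
        for k, v in net.params.items():
            if v.ndim == 4:
                net.params[k] = ((v + v[:, :, ::-1, ::-1]) / 2).astype(v.dtype)
        t = _random_tensor(11, 5, 4)
        flipped = FeatureTensor(channels=t.channels[:, ::-1, ::-1].copy(),
                                channel_names=t.channel_names,
                                mask=t.mask[::-1, ::-1].copy())
        p = net.forward(t).probs
        pf = net.forward(flipped).probs
        np.testing.assert_allclose(pf, p[::-1, ::-1], atol=1e-5)

    def test_channel_mismatch_rejected(self):
        cfg = ModelConfig(n_blocks=1, n_channels=6, in_channels=5)
        with pytest.raises(ConfigurationError):
            PairNet(cfg, seed=0).forward(_random_tensor(9, 7, 5))


@pytest.fixture(scope="module")
def tiny_dataset():
    params = SimulationParams(length_range=(40, 55), n_strand_range=(2, 3),
                              fp_density=0.0, miss_rate=0.0, blur_sigma=0.0,
                              ss_error_rate=0.0, ss_jitter=0.0)
    proteins = generate_dataset(10, params, seed=42)
    m = BetaPairingModel.from_proteins(proteins)
    return list(zip(m.tensors, m.labels))


class TestTraining:
    def test_loss_decreases_on_noiseless_data(self, tiny_dataset):
        mcfg = ModelConfig(n_blocks=2, n_channels=8, in_channels=56)
        tcfg = TrainConfig(learning_rate=1e-3, n_folds=2, max_epochs=12,
                           patience=12, seed=0)
        _, histories = train(tiny_dataset, mcfg, tcfg)
        for fold in histories:
            assert fold, "fold skipped unexpectedly"
            assert fold[-1]["train_loss"] < fold[0]["train_loss"]

    def test_same_seed_reproduces_run(self, tiny_dataset):
        mcfg = ModelConfig(n_blocks=1, n_channels=6, in_channels=56)
        tcfg = TrainConfig(learning_rate=1e-3, n_folds=2, max_epochs=2,
                           patience=2, seed=7)
        _, h1 = train(tiny_dataset, mcfg, tcfg)
        _, h2 = train(tiny_dataset, mcfg, tcfg)
        f1a = [r["val_f1"] for fold in h1 for r in fold]
        f1b = [r["val_f1"] for fold in h2 for r in fold]
        assert f1a == pytest.approx(f1b, abs=1e-3)

    def test_single_fold_is_a_configuration_error(self):
        with pytest.raises(ConfigurationError):
            TrainConfig(n_folds=1)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train([], ModelConfig(n_blocks=1, n_channels=4, in_channels=5),
                  TrainConfig())

    def test_degenerate_fold_skipped_with_warning(self):
        # two proteins without any positive pair: every fold lacks positives
        tensors = [_random_tensor(12, 5, s) for s in (0, 1)]
        labels = [PairingLabels(length=12) for _ in range(2)]
        mcfg = ModelConfig(n_blocks=1, n_channels=4, in_channels=5)
        with pytest.warns(UserWarning, match="no positive"):
            with pytest.raises(ValueError, match="degenerate"):
                train(list(zip(tensors, labels)), mcfg,
                      TrainConfig(n_folds=2, max_epochs=1))


def test_rncn_does_not_reduce_heldout_f1():
    """Enabling row/column normalization should not hurt (and in practice
    helps) held-out F1 at desk scale; 3-seed median per configuration."""
    medians = {}
    for use_rncn in (True, False):
        f1s = []
        for seed in range(3):
            params = SimulationParams(length_range=(40, 70), n_strand_range=(2, 4))
            tr = BetaPairingModel.from_proteins(generate_dataset(40, params, seed=200 + seed))
            te = BetaPairingModel.from_proteins(generate_dataset(12, params, seed=900 + seed))
            res = tr.fit(ModelConfig(n_blocks=2, n_channels=8, use_rncn=use_rncn,
                                     in_channels=56),
                         TrainConfig(learning_rate=1e-3, n_folds=2, max_epochs=8,
                                     patience=8, seed=seed))
            rep = res.evaluate(te.tensors, te.labels)
            f1s.append(float(rep[rep["id"] == "pooled"].iloc[0]["f1"]))
        medians[use_rncn] = np.median(f1s)
    assert medians[True] >= medians[False]


class TestEnsemble:
    def test_single_model_ensemble_equals_forward(self):
        from strandpair.pairnet import EnsembleModel

        cfg = ModelConfig(n_blocks=1, n_channels=6, in_channels=5)
        net = PairNet(cfg, seed=0)
        ens = EnsembleModel(models=[net], config=cfg)
        t = _random_tensor(10, 5, 6)
        np.testing.assert_array_equal(predict(ens, t).probs, net.forward(t).probs)

    def test_mean_lies_within_member_envelope(self):
        from strandpair.pairnet import EnsembleModel

        cfg = ModelConfig(n_blocks=1, n_channels=6, in_channels=5)
        nets = [PairNet(cfg, seed=s) for s in range(3)]
        ens = EnsembleModel(models=nets, config=cfg)
        t = _random_tensor(10, 5, 7)
        members = np.stack([n.forward(t).probs for n in nets])
        p = predict(ens, t).probs
        assert np.all(p >= members.min(axis=0) - 1e-12)
        assert np.all(p <= members.max(axis=0) + 1e-12)
        np.testing.assert_array_equal(p, p.T)


def test_gradients_match_finite_differences():
    """Analytic backprop against central finite differences on a tiny net."""
    rng = np.random.default_rng(0)
    length = 10
    t = FeatureTensor(channels=rng.normal(size=(4, length, length)).astype(np.float32),
                      channel_names=list("abcd"), mask=separation_mask(length))
    labels = PairingLabels(length=length, pairs=frozenset({(0, 5), (2, 9)}))
    cfg = ModelConfig(n_blocks=1, n_channels=5, in_channels=4)
    net = PairNet(cfg, seed=1)
    net.params = {k: v.astype(np.float64) for k, v in net.params.items()}
    _, grads = net.loss_and_grads(t, labels, positive_weight=2.0)
    rng2 = np.random.default_rng(1)
    for name, arr in net.params.items():
        flat = arr.reshape(-1)
        for fi in rng2.choice(flat.size, size=min(3, flat.size), replace=False):
            h = 1e-6
            old = flat[fi]
            flat[fi] = old + h
            lp, _ = net.loss_and_grads(t, labels, positive_weight=2.0)
            flat[fi] = old - h
            lm, _ = net.loss_and_grads(t, labels, positive_weight=2.0)
            flat[fi] = old
            num = (lp - lm) / (2 * h)
            ana = grads[name].reshape(-1)[fi]
            assert num == pytest.approx(ana, abs=2e-7), name
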