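"""Network assembly: patch resampling, forward contract, loss, training."""

import numpy as np
import pytest

from angioseg import autodiff as ad
from angioseg.autodiff import AdamW, Tensor
from angioseg.network import (NetworkConfig, PatchEmbed, PatchExpand,
                              PatchMerge, TrainConfig, VesselSegNet,
                              combined_loss, load_checkpoint, save_checkpoint,
                              train_model)
from angioseg.phantoms import make_sample


@pytest.fixture(scope="module")
def phantom_pairs():
    samples = [make_sample(200 + i, 64, "easy") for i in range(4)]
    return [(s.image.astype(float), s.mask) for s in samples]


class TestPatchOps:
    def test_progressive_embedding_contract(self, rng):
        embed = PatchEmbed(96, rng)
        with ad.no_grad():
            out = embed(Tensor(rng.standard_normal((1, 512, 512, 1))))
        assert out.shape == (1, 128, 128, 96)

    def test_embedding_small_scale_arithmetic(self, rng):
        embed = PatchEmbed(16, rng)
        out = embed(Tensor(rng.standard_normal((2, 64, 64, 1))))
        assert out.shape == (2, 16, 16, 16)
        with pytest.raises(ValueError):
            embed(Tensor(rng.standard_normal((1, 30, 30, 1))))

    def test_merge_halves_and_doubles(self, rng):
        merge = PatchMerge(96, rng)
        out = merge(Tensor(rng.standard_normal((1, 8, 8, 96))))
        assert out.shape == (1, 4, 4, 192)
        with pytest.raises(ValueError):
            merge(Tensor(rng.standard_normal((1, 5, 6, 96))))

    def test_channel_sequence_through_three_merges(self, rng):
        x = Tensor(rng.standard_normal((1, 16, 16, 8)))
        cs = [x.shape[-1]]
        for _ in range(3):
            x = PatchMerge(x.shape[-1], rng)(x)
            cs.append(x.shape[-1])
        assert cs == [8, 16, 32, 64]

    def test_expand_doubles_and_halves(self, rng):
        expand = PatchExpand(64, rng, factor=2)
        out = expand(Tensor(rng.standard_normal((1, 4, 4, 64))))
        assert out.shape == (1, 8, 8, 32)

    def test_final_expand_four_times(self, rng):
        expand = PatchExpand(16, rng, factor=4)
        out = expand(Tensor(rng.standard_normal((1, 8, 8, 16))))
        assert out.shape == (1, 32, 32, 4)

    def test_merge_of_expand_preserves_shape(self, rng):
        x = Tensor(rng.standard_normal((1, 4, 4, 16)))
        y = PatchMerge(8, rng)(PatchExpand(16, rng)(x))
        assert y.shape == x.shape


class TestForward:
    def test_shape_contract_and_determinism(self, tiny_net_cfg):
        net = VesselSegNet(tiny_net_cfg, seed=3)
        img = make_sample(7, 64, "easy").image.astype(float)
        r1 = net.forward(img)
        r2 = net.forward(img)
        assert r1.prob.shape == (64, 64)
        assert r1.prob.min() >= 0 and r1.prob.max() <= 1
        assert set(np.unique(r1.mask)) <= {0, 1}
        assert np.array_equal(r1.prob, r2.prob)

    def test_indivisible_dims_rejected(self, tiny_net_cfg):
        net = VesselSegNet(tiny_net_cfg, seed=0)
        with pytest.raises(ValueError):
            net.forward(np.zeros((48, 48)))

    def test_baseline_arm_runs(self):
        cfg = NetworkConfig(embed_dim=16, mvsa_enabled=False,
                            kass_enabled=False, csif_enabled=False)
        net = VesselSegNet(cfg, seed=1)
        out = net.forward(np.full((64, 64), 128.0))
        assert out.prob.shape == (64, 64)

    def test_enabling_mvsa_adds_only_stage1_mvsa_parameters(self):
        base = NetworkConfig(embed_dim=16, mvsa_enabled=False)
        full = NetworkConfig(embed_dim=16, mvsa_enabled=True, mvsa_stages=(1,))
        names_off = {k for k, _ in VesselSegNet(base, seed=0).named_parameters()}
        names_on = {k for k, _ in VesselSegNet(full, seed=0).named_parameters()}
        added = names_on - names_off
        assert added and all(".mvsa." in n and n.startswith("enc_stages.0.")
                             for n in added)
        assert not (names_off - names_on)


class TestLoss:
    def test_perfect_hard_prediction_near_zero(self):
        t = np.zeros((1, 8, 8), dtype=float)
        t[0, 2:5, 2:5] = 1.0
        prob = Tensor(t[..., None])
        loss = combined_loss(prob, t).item()
        assert 0 <= loss < 1e-4

    def test_uniform_half_probability_bce_is_ln2(self):
        t = np.zeros((1, 8, 8))
        prob = Tensor(np.full((1, 8, 8, 1), 0.5))
        loss = combined_loss(prob, t, w1=1.0, w2=0.0).item()
        assert abs(loss - np.log(2)) < 1e-9

    def test_loss_nonnegative_and_shape_checked(self, rng):
        prob = Tensor(rng.uniform(0.01, 0.99, (1, 8, 8, 1)))
        t = (rng.uniform(size=(1, 8, 8)) < 0.3).astype(float)
        assert combined_loss(prob, t).item() >= 0
        with pytest.raises(ValueError):
            combined_loss(prob, np.zeros((1, 4, 4)))

    def test_overfitting_one_phantom_decreases_loss(self, phantom_pairs):
        img, mask = phantom_pairs[0]
        net = VesselSegNet(NetworkConfig(embed_dim=16), seed=5)
        opt = AdamW(net.parameters(), lr=1e-3)
        losses = []
        for _ in range(50):
            loss = combined_loss(net.forward_probs(img[None]), mask[None])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        assert losses[-1] < losses[0]
        chunks = [np.mean(losses[i:i + 10]) for i in range(0, 50, 10)]
        assert all(a > b for a, b in zip(chunks, chunks[1:]))


class TestTraining:
    def test_one_epoch_writes_checkpoint_and_log(self, phantom_pairs, tmp_path):
        cfg = TrainConfig(epochs=1, seed=11, out_dir=str(tmp_path / "run"))
        res = train_model(phantom_pairs, cfg,
                          net_cfg=NetworkConfig(embed_dim=16))
        assert res.checkpoint.exists()
        assert res.log_path.exists()
        assert len(res.history) == 1
        line = res.log_path.read_text().splitlines()[0]
        assert line.startswith("epoch 0 ") and "dsc" in line

    def test_fixed_seed_reproduces_loss_trajectory(self, phantom_pairs, tmp_path):
        logs = []
        for d in ("a", "b"):
            cfg = TrainConfig(epochs=2, seed=21, out_dir=str(tmp_path / d))
            res = train_model(phantom_pairs, cfg,
                              net_cfg=NetworkConfig(embed_dim=16))
            logs.append(res.log_path.read_text())
        assert logs[0] == logs[1]

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train_model([], TrainConfig(epochs=1))

    def test_checkpoint_roundtrip_preserves_predictions(self, phantom_pairs,
                                                        tmp_path):
        net = VesselSegNet(NetworkConfig(embed_dim=16), seed=9)
        # one optimisation step so non-trainable state (batch-norm running
        # statistics) moves off its initial values before saving
        img0, mask0 = phantom_pairs[0]
        opt = AdamW(net.parameters(), lr=1e-3)
        loss = combined_loss(net.forward_probs(img0[None]), mask0[None])
        loss.backward()
        opt.step()
        path = tmp_path / "ck.npz"
        save_checkpoint(path, net, extra={"note": "test"})
        net2, extra = load_checkpoint(path)
        assert extra["note"] == "test"
        img = phantom_pairs[0][0]
        assert np.array_equal(net.forward(img).prob, net2.forward(img).prob)
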