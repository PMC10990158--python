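"""Training objective, β schedule, and short sweep behavior."""

import numpy as np
import pytest

from dib.dib_objective import (
    DIBModel,
    SweepConfig,
    TabularDataset,
    dib_loss,
    make_beta_schedule,
    train_sweep,
)

LN2 = np.log(2.0)


@pytest.fixture(scope="module")
def and2_dataset(request):
    from dib.boolean_circuit import BooleanCircuit, truth_table

    return TabularDataset.from_truth_table(
        truth_table(BooleanCircuit(2, (("AND", (0, 1)),), 2))
    )


def _tiny_config(**kw):
    defaults = dict(
        n_steps=60,
        n_checkpoints=5,
        latent_dim=2,
        encoder_hidden=(8,),
        decoder_hidden=(16,),
    )
    defaults.update(kw)
    return SweepConfig(**defaults)


class TestBetaSchedule:
    def test_constant(self):
        np.testing.assert_allclose(make_beta_schedule(1, 1, 5), np.ones(5))

    def test_geometric(self):
        np.testing.assert_allclose(
            make_beta_schedule(1.0, 1e-4, 5), [1, 1e-1, 1e-2, 1e-3, 1e-4], rtol=1e-12
        )

    @pytest.mark.parametrize("bad", [(0, 1, 3), (1, -2, 3), (1, 1, 0)])
    def test_invalid_arguments(self, bad):
        with pytest.raises(ValueError):
            make_beta_schedule(*bad)


class TestDIBLoss:
    def test_initial_loss_is_label_cross_entropy(self, and2_dataset, rng):
        """Channels at the prior and a zero-init decoder give beta*0 + CE(uniform)."""
        model = DIBModel.build(and2_dataset, _tiny_config(), rng)
        loss = dib_loss(
            model,
            and2_dataset.features,
            and2_dataset.labels,
            beta=5.0,
            weights=and2_dataset.weights,
        )
        # zero-init decoder outputs the uniform distribution -> CE = ln 2
        assert loss == pytest.approx(np.log(2.0), abs=1e-9)

    def test_beta_zero_marginal_decoder_gives_label_entropy(self, and2_dataset, rng):
        model = DIBModel.build(and2_dataset, _tiny_config(), rng)
        marginal = and2_dataset.label_marginal()
        model.decoder.head.b.data[...] = np.log(marginal)
        loss = dib_loss(
            model,
            and2_dataset.features,
            and2_dataset.labels,
            beta=0.0,
            weights=and2_dataset.weights,
        )
        assert loss == pytest.approx(and2_dataset.label_entropy_bits() * LN2, abs=1e-9)

    def test_length_mismatch_rejected(self, and2_dataset, rng):
        model = DIBModel.build(and2_dataset, _tiny_config(), rng)
        with pytest.raises(ValueError):
            model.loss(
                and2_dataset.features,
                and2_dataset.labels[:2],
                1.0,
                np.random.default_rng(0),
            )

    def test_negative_beta_rejected(self, and2_dataset, rng):
        model = DIBModel.build(and2_dataset, _tiny_config(), rng)
        with pytest.raises(ValueError):
            model.loss(
                and2_dataset.features, and2_dataset.labels, -1.0, np.random.default_rng(0)
            )

    def test_gradient_matches_finite_differences(self, and2_dataset):
        """End-to-end check: the analytic gradient of the full loss is exact."""
        rng = np.random.default_rng(0)
        model = DIBModel.build(and2_dataset, _tiny_config(), rng)
        for p in model.parameters:
            p.data += rng.normal(0, 0.1, size=p.data.shape)
        p = model.channels[0].net.head.W

        def value():
            loss, _ = model.loss(
                and2_dataset.features,
                and2_dataset.labels,
                0.7,
                np.random.default_rng(11),
                weights=and2_dataset.weights,
            )
            return float(loss.data)

        loss, _ = model.loss(
            and2_dataset.features,
            and2_dataset.labels,
            0.7,
            np.random.default_rng(11),
            weights=and2_dataset.weights,
        )
        loss.backward()
        g = p.grad.copy()
        eps = 1e-6
        for idx in [(0, 0), (3, 1)]:
            p.data[idx] += eps
            fp = value()
            p.data[idx] -= 2 * eps
            fm = value()
            p.data[idx] += eps
            assert g[idx] == pytest.approx((fp - fm) / (2 * eps), rel=1e-4, abs=1e-8)


class TestTrainSweep:
    def test_strong_bottleneck_endpoint_is_closed(self, and2_dataset):
        """At large constant beta, every channel stays at (or returns to) the prior."""
        cfg = _tiny_config(beta_start=50.0, beta_end=50.0, n_steps=150)
        cks = train_sweep(and2_dataset, cfg, seed=0)
        assert cks[-1].kl_bits.sum() < 0.02

    def test_weak_bottleneck_reaches_label_entropy(self, and2_dataset):
        """AND-2 at tiny beta: predictive information approaches H(Y) = 0.811278."""
        from dib.mi_estimation import predictive_info

        cfg = SweepConfig(
            beta_start=1.0,
            beta_end=1e-4,
            n_steps=3000,
            n_checkpoints=10,
            latent_dim=4,
            encoder_hidden=(16,),
            decoder_hidden=(32,),
        )
        cks = train_sweep(and2_dataset, cfg, seed=0)
        model = DIBModel.build(and2_dataset, cfg, np.random.default_rng(0))
        model.load_checkpoint(cks[-1])
        info, acc = predictive_info(model, and2_dataset, n_samples=16, seed=0)
        assert info == pytest.approx(0.811278, abs=0.03)
        assert acc == 1.0

    def test_seeded_determinism(self, and2_dataset):
        cfg = _tiny_config()
        a = train_sweep(and2_dataset, cfg, seed=4)
        b = train_sweep(and2_dataset, cfg, seed=4)
        assert [ck.loss_nats for ck in a] == [ck.loss_nats for ck in b]
        for x, y in zip(a[-1].channel_snapshots, b[-1].channel_snapshots):
            for ax, ay in zip(x, y):
                np.testing.assert_array_equal(ax, ay)

    def test_checkpoints_cover_the_schedule(self, and2_dataset):
        cfg = _tiny_config(n_steps=100, n_checkpoints=8)
        cks = train_sweep(and2_dataset, cfg, seed=0)
        assert cks[0].step == 1
        assert cks[-1].step == 100
        assert all(a.step < b.step for a, b in zip(cks, cks[1:]))
        np.testing.assert_allclose(
            [ck.beta for ck in cks],
            make_beta_schedule(cfg.beta_start, cfg.beta_end, cfg.n_steps)[
                [ck.step - 1 for ck in cks]
            ],
        )

    def test_single_class_dataset_rejected(self):
        ds = TabularDataset(
            features=np.zeros((8, 2)), labels=np.zeros(8, dtype=int), feature_ids=["a", "b"]
        )
        with pytest.raises(ValueError):
            train_sweep(ds, _tiny_config(), seed=0)

    def test_grouped_bank_matches_per_channel_views(self, rng):
        """Continuous datasets use the stacked bank; its per-feature views
        must reproduce the grouped forward pass exactly."""
        x = rng.normal(size=(64, 6))
        y = (x[:, 1] > 0).astype(int)
        ds = TabularDataset(features=x, labels=y, feature_ids=[f"f{i}" for i in range(6)])
        model = DIBModel.build(ds, _tiny_config(), np.random.default_rng(3))
        assert model.grouped is not None
        for p in model.parameters:
            p.data += np.random.default_rng(4).normal(0, 0.2, size=p.data.shape)
        mean_t, scale_t = model.grouped.forward(x)
        for i, view in enumerate(model.channels):
            lat = view.encode(x[:, i])
            np.testing.assert_allclose(lat.mean, mean_t.data[i], atol=1e-12)
            np.testing.assert_allclose(lat.scale, scale_t.data[i], atol=1e-12)

    def test_grouped_checkpoint_round_trip(self, rng):
        x = rng.normal(size=(32, 4))
        y = (x[:, 0] > 0).astype(int)
        ds = TabularDataset(features=x, labels=y, feature_ids=list("abcd"))
        model = DIBModel.build(ds, _tiny_config(), np.random.default_rng(0))
        loss, parts = model.loss(x, y, 0.5, np.random.default_rng(1))
        ck = model.snapshot_checkpoint(1, 0.5, parts, float(loss.data))
        before = model.channels[2].encode(x[:, 2]).mean.copy()
        for p in model.parameters:
            p.data += 1.0
        model.load_checkpoint(ck)
        np.testing.assert_array_equal(model.channels[2].encode(x[:, 2]).mean, before)

    def test_minibatch_mode_runs(self, rng):
        n = 64
        x = rng.normal(size=(n, 3))
        y = (x[:, 0] > 0).astype(int)
        ds = TabularDataset(features=x, labels=y, feature_ids=["a", "b", "c"])
        cks = train_sweep(ds, _tiny_config(batch_size=16), seed=0)
        assert len(cks) >= 3
        assert np.isfinite(cks[-1].loss_nats)
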