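"""The Cox-loss networks: loss oracles, builders, gradients, training."""

import numpy as np
import pandas as pd
import pytest

from survtab.datatypes import FeatureMeta
from survtab.deep_survival import (
    NetworkSpec,
    breslow_neg_log_pl,
    build_densenet,
    build_feedforward,
    build_tabtransformer,
    overfitting_curves,
    train_risk_model,
)
from survtab.deep_survival import _loss_graph


def brute_force_loss(h, t, d, normalize):
    """Naive risk-set enumeration oracle for the Breslow loss."""
    total = 0.0
    for i in range(len(t)):
        if d[i] == 1:
            rs = [j for j in range(len(t)) if t[j] >= t[i]]
            total += np.log(np.sum(np.exp(np.asarray(h)[rs]))) - h[i]
    n_ev = int(np.sum(d))
    return total / n_ev if normalize and n_ev else total


class TestBreslowLoss:
    def test_single_event_subject_zero_loss(self):
        assert breslow_neg_log_pl([0.0], [1.0], [1]) == 0.0

    def test_two_subject_hand_enumeration(self):
        got = breslow_neg_log_pl([0.0, 0.0], [1.0, 2.0], [1, 1],
                                 normalize=False)
        assert got == pytest.approx(np.log(2), abs=1e-12)

    @pytest.mark.parametrize("normalize", [True, False])
    def test_matches_enumeration_oracle(self, normalize):
        for seed in range(50):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(2, 9))
            t = rng.integers(1, 5, n).astype(float)   # ties injected
            d = rng.integers(0, 2, n)
            if d.sum() == 0:
                d[0] = 1
            h = rng.standard_normal(n) * 2
            got = breslow_neg_log_pl(h, t, d, normalize=normalize)
            want = brute_force_loss(h, t, d, normalize)
            assert got == pytest.approx(want, abs=1e-10)

    def test_shift_invariance(self):
        rng = np.random.default_rng(3)
        h = rng.standard_normal(30)
        t = rng.uniform(1, 10, 30)
        d = rng.integers(0, 2, 30)
        d[0] = 1
        for c in (-50.0, 3.7, 200.0):
            assert breslow_neg_log_pl(h + c, t, d) == pytest.approx(
                breslow_neg_log_pl(h, t, d), abs=1e-8)

    def test_zero_events_warns(self):
        with pytest.warns(UserWarning, match="no events"):
            assert breslow_neg_log_pl([1.0, 2.0], [1.0, 2.0], [0, 0]) == 0.0

    def test_censored_subjects_enter_risk_sets_only(self):
        """Censored subjects contribute through risk-set membership alone.

        A censored subject with the LATEST time sits in every event's risk
        set, so dropping it changes the loss; one with the EARLIEST time
        (before every event) belongs to no risk set and is inert.
        """
        h = np.array([0.5, -0.2, 0.3, 0.8])
        t = np.array([1.0, 2.0, 3.0, 4.0])
        d_late = np.array([1, 1, 1, 0])
        full = breslow_neg_log_pl(h, t, d_late, normalize=False)
        drop_last = breslow_neg_log_pl(h[:3], t[:3], d_late[:3], normalize=False)
        assert full != pytest.approx(drop_last)
        d_early = np.array([0, 1, 1, 1])
        full2 = breslow_neg_log_pl(h, t, d_early, normalize=False)
        drop_first = breslow_neg_log_pl(h[1:], t[1:], d_early[1:],
                                        normalize=False)
        assert full2 == pytest.approx(drop_first, abs=1e-12)


class TestBuilders:
    def test_feedforward_parameter_count(self):
        net = build_feedforward(NetworkSpec(), 91)
        assert net.n_params() == 92 * 32 + 3 * (33 * 32) + 33

    def test_feedforward_eval_deterministic(self):
        net = build_feedforward(NetworkSpec(seed=1), 7)
        X = np.random.default_rng(0).standard_normal((5, 7))
        a = net.predict(X)
        b = net.predict(X)
        assert np.array_equal(a, b)
        assert a.shape == (5,) and np.isfinite(a).all()

    def test_densenet_concatenation_widths(self):
        net = build_densenet(NetworkSpec(), 91)
        assert net.layer_input_widths == [91, 99, 107, 115]
        assert net.head.W.data.shape[0] == 91 + 32

    def test_densenet_eval_deterministic(self):
        net = build_densenet(NetworkSpec(seed=2), 6)
        X = np.random.default_rng(1).standard_normal((4, 6))
        assert np.array_equal(net.predict(X), net.predict(X))

    def test_tabtransformer_shapes(self):
        meta = [FeatureMeta("b0", "binary"), FeatureMeta("b1", "binary"),
                FeatureMeta("c0", "continuous")]
        spec = NetworkSpec(embed_dim=64, n_heads=8, n_transformer_layers=2)
        net = build_tabtransformer(spec, meta)
        assert len(net.cat_idx) == 2
        assert net.head1.W.data.shape[0] == 2 * 64 + 1
        X = np.array([[1.0, 0.0, 0.3], [0.0, 1.0, -0.2]])
        out = net.predict(X)
        assert out.shape == (2,) and np.isfinite(out).all()

    def test_tabtransformer_token_permutation_equivariance(self):
        rng = np.random.default_rng(4)
        meta = ([FeatureMeta(f"b{i}", "binary") for i in range(5)]
                + [FeatureMeta("c0", "continuous")])
        spec = NetworkSpec(embed_dim=8, n_heads=2, n_transformer_layers=2,
                           seed=9)
        net = build_tabtransformer(spec, meta)
        X = np.hstack([rng.integers(0, 2, (6, 5)).astype(float),
                       rng.standard_normal((6, 1))])
        base = net.predict(X)
        perm = [3, 0, 4, 1, 2]
        net.permute_categorical(perm)
        Xp = np.hstack([X[:, :5][:, perm], X[:, 5:]])
        assert np.abs(net.predict(Xp) - base).max() < 1e-6

    def test_tabtransformer_no_categoricals_warns(self):
        meta = [FeatureMeta("c0", "continuous")]
        with pytest.warns(UserWarning, match="transformer stack skipped"):
            net = build_tabtransformer(NetworkSpec(embed_dim=8, n_heads=2), meta)
        assert np.isfinite(net.predict(np.array([[0.4]]))).all()

    def test_invalid_spec_named_field(self):
        with pytest.raises(ValueError, match="embed_dim"):
            NetworkSpec(embed_dim=30, n_heads=8)
        with pytest.raises(ValueError, match="dropout_rate"):
            NetworkSpec(dropout_rate=1.0)


class TestGradients:
    def test_autodiff_matches_finite_differences(self):
        """Central differences on random small batches, all architectures."""
        rng = np.random.default_rng(5)
        n = 10
        meta = ([FeatureMeta(f"b{i}", "binary") for i in range(3)]
                + [FeatureMeta(f"c{i}", "continuous") for i in range(2)])
        X = np.hstack([rng.integers(0, 2, (n, 3)).astype(float),
                       rng.standard_normal((n, 2))])
        t = rng.uniform(1, 10, n)
        d = rng.integers(0, 2, n)
        d[0] = 1
        nets = [
            build_feedforward(NetworkSpec(seed=1, hidden_width=6, n_hidden=2), 5),
            build_densenet(NetworkSpec(seed=2, growth_rate=3, n_hidden=2), 5),
            build_tabtransformer(
                NetworkSpec(seed=3, embed_dim=4, n_heads=2,
                            n_transformer_layers=1), meta),
        ]
        for net in nets:
            def loss():
                return _loss_graph(net.forward(X, train=False), t, d, True)

            L = loss()
            L.backward()
            for p in net.params():
                g = p.grad if p.grad is not None else np.zeros_like(p.data)
                for ij in list(np.ndindex(*p.data.shape))[:2]:
                    orig = p.data[ij]
                    eps = 1e-6
                    p.data[ij] = orig + eps
                    lp = loss().data
                    p.data[ij] = orig - eps
                    lm = loss().data
                    p.data[ij] = orig
                    fd = (lp - lm) / (2 * eps)
                    assert abs(fd - g[ij]) < 1e-5


class TestTraining:
    def _linear_data(self, seed, n=300):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((n, 5))
        beta = np.array([1.0, -1.0, 0.5, -0.5, 0.25])
        T = -np.log(rng.uniform(size=n)) / (0.1 * np.exp(X @ beta))
        C = np.minimum(15.0, rng.exponential(25.0, n))
        return X, np.minimum(T, C), (T <= C).astype(int)

    def test_loss_decreases(self):
        X, t, d = self._linear_data(7)
        spec = NetworkSpec(epochs=40, learning_rate=1e-3, seed=11,
                           gaussian_noise_std=0.05)
        tm = train_risk_model(build_feedforward(spec, 5), (X, t, d),
                              (X, t, d), spec)
        assert tm.history.train_loss.iloc[-1] < tm.history.train_loss.iloc[0]
        assert len(tm.history) == 40

    def test_same_seed_same_curves(self):
        X, t, d = self._linear_data(8)
        spec = NetworkSpec(epochs=10, learning_rate=1e-3, seed=12)
        a = train_risk_model(build_feedforward(spec, 5), (X, t, d), (X, t, d),
                             spec)
        b = train_risk_model(build_feedforward(spec, 5), (X, t, d), (X, t, d),
                             spec)
        pd.testing.assert_frame_equal(a.history, b.history)

    def test_batched_mode_trains(self):
        X, t, d = self._linear_data(9, n=400)
        spec = NetworkSpec(epochs=20, learning_rate=1e-3, seed=13,
                           batch_mode="risk-set-batched", batch_size=128)
        tm = train_risk_model(build_feedforward(spec, 5), (X, t, d), (X, t, d),
                              spec)
        assert tm.history.train_loss.iloc[-1] < tm.history.train_loss.iloc[0]

    def test_no_training_events_rejected(self):
        X, t, d = self._linear_data(10)
        spec = NetworkSpec(epochs=2, seed=1)
        with pytest.raises(ValueError, match="event"):
            train_risk_model(build_feedforward(spec, 5), (X, t, d * 0),
                             (X, t, d), spec)

    def test_overfitting_curves_table(self):
        X, t, d = self._linear_data(11, n=100)
        rng = np.random.default_rng(0)
        Xwide = rng.standard_normal((100, 30))
        spec = NetworkSpec(epochs=30, learning_rate=3e-3, seed=14,
                           dropout_rate=0.0, gaussian_noise_std=0.0)
        tm = train_risk_model(build_feedforward(spec, 30),
                              (Xwide[:70], t[:70], d[:70]),
                              (Xwide[70:], t[70:], d[70:]), spec)
        table, gaps = overfitting_curves({("feedforward", "d0"): tm})
        assert len(table) == 30 * 2
        assert set(table.split.unique()) == {"train", "valid"}
        # overfit-prone tiny-n, wide-feature fixture: positive final gap
        assert gaps.loc["feedforward"] > 0


class TestCheckpoint:
    def test_save_load_roundtrip(self, tmp_path):
        from survtab.deep_survival import TrainedRiskModel

        rng = np.random.default_rng(21)
        X = rng.standard_normal((60, 4))
        t = rng.uniform(1, 10, 60)
        d = rng.integers(0, 2, 60)
        d[0] = 1
        spec = NetworkSpec(epochs=5, learning_rate=1e-3, seed=22)
        tm = train_risk_model(build_feedforward(spec, 4), (X, t, d), (X, t, d),
                              spec)
        p = tmp_path / "model.json"
        tm.save(p)
        back = TrainedRiskModel.load(p)
        assert np.allclose(back.predict(X), tm.predict(X), atol=1e-12)
        pd.testing.assert_frame_equal(back.history, tm.history)

    def test_tabtransformer_roundtrip(self, tmp_path):
        from survtab.deep_survival import TrainedRiskModel

        meta = [FeatureMeta("b0", "binary"), FeatureMeta("c0", "continuous")]
        spec = NetworkSpec(embed_dim=4, n_heads=2, n_transformer_layers=1,
                           seed=23, epochs=1)
        net = build_tabtransformer(spec, meta)
        X = np.array([[1.0, 0.2], [0.0, -0.4], [1.0, 1.3]])
        tm = TrainedRiskModel(
            model=net, spec=spec,
            history=pd.DataFrame({"epoch": [0], "train_loss": [1.0],
                                  "valid_loss": [1.0]}))
        p = tmp_path / "tt.json"
        tm.save(p)
        back = TrainedRiskModel.load(p)
        assert np.allclose(back.predict(X), net.predict(X), atol=1e-12)
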