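import numpy as np
import pytest

import nirquant as nq
from nirquant.errors import (ConfigurationError, DimensionError, DomainError,
                             TrainingDivergedError)
from nirquant.nn import (ARCH_DEFAULTS, InceptionModule, ResidualBlock,
                         TrainingConfig, build_model, train, validation_split)


class TestBuildModel:
    @pytest.mark.parametrize("arch", nq.ARCHITECTURES)
    def test_single_linear_output(self, arch):
        net = build_model(arch, 125, seed=0)
        assert net.output_dim == 1
        assert net.n_params > 0
        out = net.forward(np.zeros((3, 125)))
        assert out.shape == (3, 1)

    @pytest.mark.parametrize("arch", nq.ARCHITECTURES)
    def test_builds_on_ft_nir_length(self, arch):
        assert build_model(arch, 1102, seed=0).output_dim == 1

    def test_unknown_architecture(self):
        with pytest.raises(ConfigurationError):
            build_model("vgg", 125)

    def test_too_short_input_reports_minimal_length(self):
        with pytest.raises(ConfigurationError, match="minimal"):
            build_model("s_alexnet", 16)

    def test_residual_block_is_identity_when_convs_zeroed(self):
        net = build_model("resnet", 125, seed=1)
        block = next(l for l in net.body.layers
                     if isinstance(l, ResidualBlock) and l.projection is None)
        for conv in block.convs:
            conv.W.data[...] = 0.0
            conv.b.data[...] = 0.0
        x = np.random.default_rng(0).normal(size=(2, 32, 30))
        assert np.allclose(block.forward(x, training=False), x)

    def test_inception_channels_sum_over_branches(self):
        net = build_model("googlenet", 125, seed=1)
        modules = [l for l in net.body.layers if isinstance(l, InceptionModule)]
        assert len(modules) == 2
        for mod in modules:
            c_out, _ = mod.out_shape((mod.branches[0].layers[0].in_channels, 50))
            assert c_out == sum(mod.branch_channels)
        assert modules[0].branch_channels == (16, 32, 8, 8)
        assert modules[1].branch_channels == (32, 48, 12, 12)


class TestTrainingConfig:
    def test_published_defaults(self):
        # batch, epochs, learning rate and patience per architecture
        assert ARCH_DEFAULTS["simple_cnn"] == dict(
            batch_size=128, max_epochs=1000, learning_rate=5e-3, patience=200)
        assert ARCH_DEFAULTS["s_alexnet"] == dict(
            batch_size=16, max_epochs=300, learning_rate=1e-5, patience=300)
        for arch in ("resnet", "googlenet"):
            assert ARCH_DEFAULTS[arch] == dict(
                batch_size=160, max_epochs=1000, learning_rate=1e-5, patience=200)
        assert TrainingConfig.for_arch("simple_cnn").n_repeats == 11

    def test_validation_split_arithmetic(self):
        fit, val = validation_split(315, 0.10, 42)
        assert val.size == 32 and fit.size == 283
        for n in (10, 45, 100, 137, 450):
            fit, val = validation_split(n, 0.10, 0)
            assert val.size == n - int(np.floor(0.9 * n))
            assert np.array_equal(np.sort(np.concatenate([fit, val])), np.arange(n))


@pytest.fixture(scope="module")
def tiny_task(noisefree_micro_dataset):
    ds = noisefree_micro_dataset
    return nq.snv_matrix(ds.X), ds.y


@pytest.fixture(scope="module")
def quick_model(noisefree_micro_dataset):
    ds = noisefree_micro_dataset
    X = nq.snv_matrix(ds.X)
    cfg = TrainingConfig.for_arch("simple_cnn", n_repeats=1, max_epochs=150,
                                  batch_size=16, seed=5)
    return train(None, X, ds.y, cfg), X, ds.y


class TestTrainingProtocol:
    def test_constant_targets_learned(self, tiny_task):
        X, _ = tiny_task
        y = np.full(X.shape[0], 7.0)
        cfg = TrainingConfig.for_arch("simple_cnn", n_repeats=1, max_epochs=120,
                                      batch_size=16, seed=0)
        trained = train(None, X, y, cfg)
        assert np.all(np.abs(trained.predict(X) - 7.0) < 0.1)

    def test_early_stopping_bookkeeping(self, tiny_task):
        X, y = tiny_task
        cfg = TrainingConfig.for_arch("simple_cnn", n_repeats=1, max_epochs=60,
                                      batch_size=16, patience=10, seed=1)
        trained = train(None, X, y, cfg)
        assert trained.epochs_run <= cfg.max_epochs
        # restored weights achieve the best recorded validation loss
        assert trained.best_validation_loss == pytest.approx(
            min(trained.history["val_loss"]))
        assert trained.best_validation_loss <= trained.history["val_loss"][-1] + 1e-12

    def test_repeats_accumulate_epochs_and_select_best(self, tiny_task):
        X, y = tiny_task
        cfg = TrainingConfig.for_arch("simple_cnn", n_repeats=3, max_epochs=8,
                                      batch_size=16, seed=2)
        trained = train(None, X, y, cfg)
        assert len(trained.repeat_epochs) == 3
        assert trained.epochs_run == sum(trained.repeat_epochs)
        assert trained.best_validation_loss == pytest.approx(
            min(trained.history["val_loss"]))

    def test_determinism_across_runs(self, tiny_task):
        X, y = tiny_task
        cfg = TrainingConfig.for_arch("simple_cnn", n_repeats=1, max_epochs=10,
                                      batch_size=16, seed=3)
        a = train(None, X, y, cfg)
        b = train(None, X, y, cfg)
        assert np.allclose(a.history["val_loss"], b.history["val_loss"], rtol=1e-12)
        assert np.allclose(a.predict(X), b.predict(X), rtol=1e-12)

    def test_divergence_raises_with_epoch(self, tiny_task):
        X, y = tiny_task
        cfg = TrainingConfig.for_arch("simple_cnn", n_repeats=1, max_epochs=5,
                                      batch_size=16, learning_rate=1e120, seed=4)
        with np.errstate(over="ignore", invalid="ignore"):
            with pytest.raises(TrainingDivergedError) as err:
                train(None, X, y, cfg)
        assert err.value.epoch < 5


class TestPredict:
    def test_convergence_on_noisefree_training_rows(self, quick_model):
        trained, X, y = quick_model
        assert nq.rmse(y, trained.predict(X)) < 1.0

    def test_empty_input(self, quick_model):
        trained, X, _ = quick_model
        out = trained.predict(np.empty((0, X.shape[1])))
        assert out.shape == (0,)

    def test_row_permutation_equivariance(self, quick_model):
        trained, X, _ = quick_model
        perm = np.random.default_rng(0).permutation(X.shape[0])
        assert np.allclose(trained.predict(X[perm]), trained.predict(X)[perm])

    def test_shape_mismatch_rejected(self, quick_model):
        trained, X, _ = quick_model
        with pytest.raises(DimensionError):
            trained.predict(np.zeros((2, X.shape[1] + 1)))

    def test_predictions_finite_and_unclipped(self, quick_model):
        trained, X, _ = quick_model
        p = trained.predict(X)
        assert np.all(np.isfinite(p))


class TestCapacity:
    """Each architecture can fit the noise-free task near-perfectly.

    This probes expressiveness, so the optimizer runs at the fast learning
    rate; the published per-architecture protocols are exercised elsewhere.
    """

    @pytest.mark.parametrize("arch", nq.ARCHITECTURES)
    def test_training_mse_below_half(self, arch, noisefree_micro_dataset):
        ds = noisefree_micro_dataset
        X = nq.snv_matrix(ds.X)
        cfg = TrainingConfig.for_arch(
            arch, learning_rate=5e-3, n_repeats=1, max_epochs=200,
            batch_size=16, patience=200, seed=6)
        trained = train(None, X, ds.y, cfg)
        assert min(trained.history["train_loss"]) < 0.5
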