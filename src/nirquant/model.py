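"""Model/Results interface over the full calibration workflow.

``AdulterationRegressor`` holds the (optionally SNV-scaled, optionally
train/test split) spectra and the training configuration; ``fit()`` runs the
training protocol and returns ``RegressionFitResults`` carrying the fitted
predictor, its history, train/test metrics, the coefficient profile and a
printable summary, in the spirit of statsmodels model/results pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .axes import SpectralAxis
from .dataset import SpectralDataset, SplitIndices, split_train_test
from .errors import DomainError
from .interpret import (CoefficientProfile, ImportantFeatures, mean_coefficients,
                        select_important)
from .metrics import RegressionMetrics, compute_metrics
from .nn import TrainedRegressor, TrainingConfig, build_model, train
from .preprocess import snv_matrix


class AdulterationRegressor:
    """A deep NIR calibration model for percent-adulteration regression.

    Parameters
    ----------
    X, y
        n x m spectra (SNV-scaled unless ``apply_snv``) and percent targets.
    arch
        One of ``simple_cnn``, ``s_alexnet``, ``resnet``, ``googlenet``.
    config
        TrainingConfig; defaults to the architecture's published protocol
        (``TrainingConfig.for_arch(arch)``).
    split
        Optional SplitIndices; when present, fit() trains on the train rows
        and the results expose held-out test metrics.
    axis
        Optional SpectralAxis for labelled coefficient profiles.
    """

    def __init__(self, X, y, arch: str = "simple_cnn",
                 config: TrainingConfig | None = None,
                 split: SplitIndices | None = None,
                 axis: SpectralAxis | None = None,
                 apply_snv: bool = False):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[0] != y.size:
            raise DomainError(f"X {X.shape} incompatible with {y.size} targets")
        self.X = snv_matrix(X) if apply_snv else X
        self.y = y
        self.arch = arch
        self.config = config or TrainingConfig.for_arch(arch)
        if self.config.arch != arch:
            raise DomainError(
                f"config.arch {self.config.arch!r} does not match arch {arch!r}")
        self.split = split
        self.axis = axis

    @classmethod
    def from_dataset(cls, dataset: SpectralDataset, arch: str = "simple_cnn",
                     config: TrainingConfig | None = None,
                     apply_snv: bool = True, train_fraction: float = 0.70,
                     split_seed: int = 42) -> "AdulterationRegressor":
        """Build from a SpectralDataset with the standard 70/30 split.

        SNV is applied unless the dataset is already preprocessed.
        """
        do_snv = apply_snv and not dataset.snv_applied
        split = split_train_test(dataset.n, train_fraction, split_seed)
        return cls(dataset.X, dataset.y, arch=arch, config=config, split=split,
                   axis=dataset.axis, apply_snv=do_snv)

    @property
    def X_train(self) -> np.ndarray:
        return self.X[self.split.train_idx] if self.split is not None else self.X

    @property
    def y_train(self) -> np.ndarray:
        return self.y[self.split.train_idx] if self.split is not None else self.y

    @property
    def X_test(self) -> np.ndarray | None:
        return self.X[self.split.test_idx] if self.split is not None else None

    @property
    def y_test(self) -> np.ndarray | None:
        return self.y[self.split.test_idx] if self.split is not None else None

    def fit(self, n_repeats: int | None = None, seed: int | None = None,
            max_epochs: int | None = None) -> "RegressionFitResults":
        """Run the training protocol and evaluate on the held-out rows."""
        from dataclasses import replace
        cfg = self.config
        if n_repeats is not None:
            cfg = replace(cfg, n_repeats=n_repeats)
        if seed is not None:
            cfg = replace(cfg, seed=seed)
        if max_epochs is not None:
            cfg = replace(cfg, max_epochs=max_epochs)
        first = build_model(cfg.arch, self.X.shape[1], seed=cfg.seed)
        trained = train(first, self.X_train, self.y_train, cfg)
        return RegressionFitResults(model=self, trained=trained)


@dataclass
class RegressionFitResults:
    """Fitted predictor plus its diagnostics, metrics and interpretation."""

    model: AdulterationRegressor
    trained: TrainedRegressor
    _train_metrics: RegressionMetrics | None = field(default=None, repr=False)
    _test_metrics: RegressionMetrics | None = field(default=None, repr=False)

    # -- predictions and metrics -------------------------------------------
    def predict(self, X) -> np.ndarray:
        return self.trained.predict(X)

    @property
    def epochs_run(self) -> int:
        return self.trained.epochs_run

    @property
    def history(self) -> dict:
        return self.trained.history

    @property
    def train_metrics(self) -> RegressionMetrics:
        if self._train_metrics is None:
            m = self.model
            self._train_metrics = compute_metrics(m.y_train, self.predict(m.X_train))
        return self._train_metrics

    @property
    def test_metrics(self) -> RegressionMetrics | None:
        if self._test_metrics is None and self.model.split is not None:
            m = self.model
            self._test_metrics = compute_metrics(m.y_test, self.predict(m.X_test))
        return self._test_metrics

    def regression_line(self, subset: str = "test") -> tuple[float, float]:
        """(slope, intercept) of predicted vs existing on a subset."""
        m = self.model
        if subset == "train":
            e, p = m.y_train, self.predict(m.X_train)
        elif subset == "test":
            if m.split is None:
                raise DomainError("no test split available")
            e, p = m.y_test, self.predict(m.X_test)
        else:
            raise DomainError(f"subset must be 'train' or 'test', got {subset!r}")
        slope, intercept = np.polyfit(e, p, 1)
        return float(slope), float(intercept)

    # -- interpretation -----------------------------------------------------
    def coefficients(self, epsilon: float | None = None,
                     keep_per_spectrum: bool = False) -> CoefficientProfile:
        """Mean perturbation weights over the training spectra."""
        kw = {} if epsilon is None else {"epsilon": epsilon}
        return mean_coefficients(self.trained, self.model.X_train,
                                 axis=self.model.axis,
                                 keep_per_spectrum=keep_per_spectrum, **kw)

    def important_features(self, threshold_fraction: float = 0.50,
                           epsilon: float | None = None) -> ImportantFeatures:
        return select_important(self.coefficients(epsilon=epsilon),
                                threshold_fraction)

    # -- reporting ----------------------------------------------------------
    def summary(self) -> str:
        """Printable per-run report: protocol, epochs, metrics, quality band."""
        cfg = self.trained.config
        lines = [
            "NIR adulteration regression results",
            "=" * 51,
            f"architecture:    {self.trained.arch}",
            f"input length:    {self.trained.input_length}",
            f"parameters:      {self.trained.network.n_params}",
            f"protocol:        batch {cfg.batch_size}, lr {cfg.learning_rate:g}, "
            f"max {cfg.max_epochs} epochs, patience {cfg.patience}",
            f"repeats:         {cfg.n_repeats} (epochs run, cumulative: {self.epochs_run})",
            f"best val MSE:    {self.trained.best_validation_loss:.4g}",
            "-" * 51,
        ]
        tr = self.train_metrics
        lines.append(f"train  R2 {tr.r2:7.4f}  RMSE {tr.rmse:6.3f}  "
                     f"Bias {tr.bias:+7.3f}              (n={tr.n})")
        te = self.test_metrics
        if te is not None:
            lines.append(f"test   R2 {te.r2:7.4f}  RMSE {te.rmse:6.3f}  "
                         f"Bias {te.bias:+7.3f}  RPD {te.rpd:7.3f}  (n={te.n})")
            lines.append(f"RPD quality band: {te.band}")
        lines.append("=" * 51)
        return "\n".join(lines)

    # -- plotting (conveniences, matplotlib imported lazily) ----------------
    def plot_regression(self, ax=None):
        """Existing-vs-predicted scatter for train and test with fit lines."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        m = self.model
        ax.scatter(m.y_train, self.predict(m.X_train), s=12, alpha=0.6, label="train")
        if m.split is not None:
            ax.scatter(m.y_test, self.predict(m.X_test), s=12, alpha=0.6,
                       marker="^", label="test")
        lim = [min(m.y.min(), 0), m.y.max() * 1.05]
        ax.plot(lim, lim, "k--", lw=1)
        ax.set_xlabel("existing adulteration (%)")
        ax.set_ylabel("predicted adulteration (%)")
        ax.set_title(f"{self.trained.arch} regression")
        ax.legend()
        return ax

    def plot_coefficients(self, threshold_fraction: float = 0.50, ax=None):
        """Mean coefficient profile with the signed 50% cutoffs marked."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        prof = self.coefficients()
        feats = select_important(prof, threshold_fraction)
        x = prof.axis.values
        ax.plot(x, prof.mean_weights, lw=1)
        ax.axhline(feats.positive_cutoff, color="r", ls=":", lw=1)
        ax.axhline(feats.negative_cutoff, color="r", ls=":", lw=1)
        if feats.indices.size:
            ax.scatter(x[feats.indices], prof.mean_weights[feats.indices],
                       color="r", s=14, zorder=3)
        ax.set_xlabel(f"axis ({prof.axis.unit})")
        ax.set_ylabel("mean weight")
        ax.set_title(f"{self.trained.arch} regression coefficients")
        return ax
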