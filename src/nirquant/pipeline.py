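"""End-to-end study orchestration: simulate -> SNV -> split -> train ->
evaluate -> interpret -> report, with config, seed discipline and a manifest.

A study run writes, per architecture: a training-history CSV, an
existing-vs-predicted scatter CSV (with the regression line recomputed from
the persisted pairs), a coefficient profile CSV and an important-features
report; plus one metrics table across architectures, a best-regressor
summary, and a JSON manifest listing every output with its checksum.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .axes import MICRO_NIR
from .dataset import SpectralDataset, split_train_test, write_dataset_csv
from .errors import ConfigurationError, DomainError, PipelineStageError
from .interpret import important_features_frame, select_important
from .metrics import metrics_table
from .model import AdulterationRegressor
from .nn import ARCH_DEFAULTS, TrainingConfig
from .preprocess import snv_dataset
from .simulate import (ComponentLibrary, DesignSpec, NoiseModel, default_library,
                       derive_seed, generate_design)

log = logging.getLogger("nirquant")


@dataclass
class StudyConfig:
    """One study's configuration (published protocol constants as defaults)."""

    design: DesignSpec = field(default_factory=DesignSpec)
    noise: NoiseModel = field(default_factory=NoiseModel)
    library: ComponentLibrary = field(default_factory=default_library)
    architectures: tuple = ("simple_cnn",)
    train_fraction: float = 0.70
    split_seed: int = 42
    apply_snv: bool = True
    n_repeats: int | None = None          # None -> architecture default (11)
    max_epochs: int | None = None         # None -> architecture default
    threshold_fraction: float = 0.50
    epsilon: float = 1e-6
    master_seed: int = 42
    quick: bool = False
    make_plots: bool = False

    def training_config(self, arch: str) -> TrainingConfig:
        overrides: dict = {"seed": derive_seed(self.master_seed, "train", arch)}
        if self.quick:
            overrides["n_repeats"] = 1
            overrides["max_epochs"] = min(200, ARCH_DEFAULTS[arch]["max_epochs"])
        if self.n_repeats is not None:
            overrides["n_repeats"] = self.n_repeats
        if self.max_epochs is not None:
            overrides["max_epochs"] = self.max_epochs
        return TrainingConfig.for_arch(arch, **overrides)

    def to_dict(self) -> dict:
        return {
            "design": self.design.to_dict(),
            "noise": self.noise.to_dict(),
            "library": self.library.to_dict(),
            "split": {"train_fraction": self.train_fraction, "seed": self.split_seed},
            "training": {"architectures": list(self.architectures),
                         "n_repeats": self.n_repeats, "max_epochs": self.max_epochs,
                         "apply_snv": self.apply_snv, "quick": self.quick},
            "interpretation": {"threshold_fraction": self.threshold_fraction,
                               "epsilon": self.epsilon},
            "output": {"make_plots": self.make_plots},
            "master_seed": self.master_seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d or {})
        kw: dict = {}
        if "design" in d:
            kw["design"] = DesignSpec.from_dict(d["design"])
        if "noise" in d:
            kw["noise"] = NoiseModel.from_dict(d["noise"])
        if "library" in d:
            kw["library"] = ComponentLibrary.from_dict(d["library"])
        tr = d.get("training", {})
        if "architectures" in tr:
            kw["architectures"] = tuple(tr["architectures"])
        for k in ("n_repeats", "max_epochs"):
            if tr.get(k) is not None:
                kw[k] = tr[k]
        if "apply_snv" in tr:
            kw["apply_snv"] = tr["apply_snv"]
        if "quick" in tr:
            kw["quick"] = tr["quick"]
        sp = d.get("split", {})
        if "train_fraction" in sp:
            kw["train_fraction"] = sp["train_fraction"]
        if "seed" in sp:
            kw["split_seed"] = sp["seed"]
        ip = d.get("interpretation", {})
        if "threshold_fraction" in ip:
            kw["threshold_fraction"] = ip["threshold_fraction"]
        if "epsilon" in ip:
            kw["epsilon"] = ip["epsilon"]
        if "master_seed" in d:
            kw["master_seed"] = d["master_seed"]
        out = d.get("output", {})
        if "make_plots" in out:
            kw["make_plots"] = out["make_plots"]
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


@dataclass
class RunManifest:
    """Inventory of one study run: config snapshot, seeds, versions, outputs."""

    config: dict
    master_seed: int
    stage_seeds: dict
    versions: dict
    started: str
    finished: str = ""
    files: dict = field(default_factory=dict)
    metrics: dict = field(default_factory=dict)

    def register(self, path: Path) -> None:
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        self.files[Path(path).name] = digest

    def save(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True))
        return path


def _now() -> str:
    return time.strftime("%Y-%m-%dT%H:%M:%S")


def run_study(config: StudyConfig, outdir) -> RunManifest:
    """Run the full pipeline for one instrument-adulterant dataset.

    Any stage failure aborts with the stage name; the partial manifest is
    attached to the raised exception as ``exc.manifest``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=config.to_dict(), master_seed=config.master_seed,
        stage_seeds={"design": config.design.seed, "split": config.split_seed,
                     "train": {a: config.training_config(a).seed
                               for a in config.architectures}},
        versions={"nirquant": _pkg_version, "numpy": np.__version__,
                  "pandas": pd.__version__},
        started=_now())
    stage = "simulate"
    try:
        t0 = time.time()
        dataset = generate_design(config.design, config.library, config.noise)
        data_csv = outdir / "dataset.csv"
        side = write_dataset_csv(dataset, data_csv)
        manifest.register(data_csv)
        manifest.register(side)
        log.info("stage=simulate seed=%s n=%d m=%d took=%.2fs",
                 config.design.seed, dataset.n, dataset.m, time.time() - t0)

        stage = "preprocess"
        pre = snv_dataset(dataset) if config.apply_snv else dataset

        stage = "split"
        split = split_train_test(dataset.n, config.train_fraction, config.split_seed)

        rows = {}
        for arch in config.architectures:
            stage = f"train[{arch}]"
            t0 = time.time()
            tcfg = config.training_config(arch)
            model = AdulterationRegressor(pre.X, pre.y, arch=arch,
                                          config=tcfg, split=split,
                                          axis=dataset.axis)
            res = model.fit()
            log.info("stage=%s seed=%d epochs=%d took=%.2fs", stage, tcfg.seed,
                     res.epochs_run, time.time() - t0)

            stage = f"evaluate[{arch}]"
            rows[arch] = {"epoch": res.epochs_run, "train": res.train_metrics,
                          "test": res.test_metrics}
            hist = pd.DataFrame(res.history)
            hist.insert(0, "epoch", np.arange(1, len(hist) + 1))
            p = outdir / f"history_{arch}.csv"
            hist.to_csv(p, index=False)
            manifest.register(p)

            scat = pd.DataFrame({
                "existing": np.concatenate([model.y_train, model.y_test]),
                "predicted": np.concatenate([res.predict(model.X_train),
                                             res.predict(model.X_test)]),
                "subset": ["train"] * len(model.y_train) + ["test"] * len(model.y_test),
            })
            p = outdir / f"scatter_{arch}.csv"
            scat.to_csv(p, index=False, float_format="%.12g")
            manifest.register(p)
            for subset in ("train", "test"):
                slope, intercept = res.regression_line(subset)
                manifest.metrics.setdefault(arch, {})[f"{subset}_line"] = \
                    {"slope": slope, "intercept": intercept}
            manifest.metrics[arch]["train"] = res.train_metrics.as_dict()
            manifest.metrics[arch]["test"] = res.test_metrics.as_dict()
            manifest.metrics[arch]["epochs_run"] = res.epochs_run

            stage = f"interpret[{arch}]"
            prof = res.coefficients(epsilon=config.epsilon)
            feats = select_important(prof, config.threshold_fraction)
            p = outdir / f"coefficients_{arch}.csv"
            prof.to_frame(selected=feats.indices).to_csv(p, index=False,
                                                         float_format="%.12g")
            manifest.register(p)
            p = outdir / f"important_features_{arch}.csv"
            important_features_frame(feats).to_csv(p, index=False)
            manifest.register(p)

            if config.make_plots:
                stage = f"plot[{arch}]"
                import matplotlib
                matplotlib.use("Agg")
                import matplotlib.pyplot as plt
                ax = res.plot_regression()
                ax.figure.savefig(outdir / f"regression_{arch}.png", dpi=120)
                plt.close(ax.figure)
                ax = res.plot_coefficients(config.threshold_fraction)
                ax.figure.savefig(outdir / f"coefficients_{arch}.png", dpi=120)
                plt.close(ax.figure)

        stage = "report"
        table = metrics_table(rows)
        p = outdir / "metrics.csv"
        table.to_csv(p, index=False, float_format="%.6g")
        manifest.register(p)
    except Exception as exc:
        manifest.finished = _now()
        raise PipelineStageError(stage, exc, manifest) from exc

    manifest.finished = _now()
    manifest.save(outdir / "manifest.json")
    return manifest


def report_tables(manifests, outdir=None) -> pd.DataFrame:
    """Best regressor per dataset by test RPD (ties: lower test RMSE, then name).

    ``manifests`` is an iterable of RunManifest (or manifest dicts).
    """
    manifests = list(manifests)
    if not manifests:
        raise DomainError("no manifests to report on")
    recs = []
    for man in manifests:
        d = dataclasses.asdict(man) if isinstance(man, RunManifest) else man
        design = d["config"]["design"]
        candidates = []
        for arch, met in d["metrics"].items():
            te = met["test"]
            candidates.append((-te["rpd"], te["rmse"], arch, te))
        candidates.sort()
        _, _, best_arch, te = candidates[0]
        recs.append({"Adulteration Material": design["adulterant"],
                     "Instrument": design["instrument"],
                     "Best Regressor": best_arch, "RPD": te["rpd"]})
    df = pd.DataFrame.from_records(recs)
    if outdir is not None:
        p = Path(outdir) / "best_regressors.csv"
        df.to_csv(p, index=False, float_format="%.6g")
    return df
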