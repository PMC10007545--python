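"""End-to-end experiment driver: synthesize/load -> preprocess -> (augment) ->
bispectrum -> CNN -> forest -> evaluation.

A single global seed fans out to per-stage seeds through named SeedSequence spawn
keys, so any stage can be re-run independently and reproducibly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import augment as aug
from . import bdf as bdfmod
from .bispectrum import signal_to_image
from .cnn import CNNSpec, HeartLungCNN, TrainingConfig
from .metrics import ConfusionMatrix, MetricsReport, confusion, holdout_split, kfold_cv, macro_report
from .preprocess import clean
from .synthetic import gen_dataset
from .vocab import CLASSES

_STAGES = ("synth", "augment", "split", "cnn", "bdf")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    if stage not in _STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    ss = np.random.SeedSequence(entropy=global_seed, spawn_key=(_STAGES.index(stage),))
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class ExperimentResult:
    report: MetricsReport
    cm: ConfusionMatrix
    cnn_report: MetricsReport | None = None
    cnn_cm: ConfusionMatrix | None = None
    cnn_train_accuracy: float | None = None
    model: HeartLungCNN | None = field(default=None, repr=False)
    forest: bdfmod.Forest | None = field(default=None, repr=False)
    loss_history: list[float] = field(default_factory=list, repr=False)


def images_from_records(records, max_lag: int = 127, segments: int = 1):
    """RawRecords -> stacked float image tensor plus label/source arrays."""
    signals = [clean(r) for r in records]
    return images_from_signals(signals, max_lag=max_lag, segments=segments)


def images_from_signals(signals, max_lag: int = 127, segments: int = 1):
    imgs = [signal_to_image(s, max_lag=max_lag, segments=segments) for s in signals]
    x = np.stack([im.pixels for im in imgs])
    y = np.array([im.label for im in imgs])
    src = np.array([im.source_id for im in imgs])
    return x, y, src


def _fit_eval(x, y, src, train_idx, test_idx, cnn_epochs, cnn_batch, n_trees,
              bagging, bag_fraction, seed, with_cnn_baseline):
    """Train CNN + forest on train_idx, predict test_idx."""
    model = HeartLungCNN(CNNSpec(), seed=stage_seed(seed, "cnn"))
    cfg = TrainingConfig(epochs=cnn_epochs, batch_size=cnn_batch,
                         seed=stage_seed(seed, "cnn"))
    model.train_classifier(x[train_idx], y[train_idx], cfg)

    feats_train = model.features(x[train_idx])
    feats_test = model.features(x[test_idx])
    forest = bdfmod.fit_forest(feats_train, y[train_idx], n_trees=n_trees,
                               bagging=bagging, bag_fraction=bag_fraction,
                               source_ids=src[train_idx],
                               seed=stage_seed(seed, "bdf"))
    y_pred, _ = bdfmod.predict(forest, feats_test)
    extras = {}
    if with_cnn_baseline:
        cnn_idx = model.predict(x[test_idx])
        extras["cnn_pred"] = np.array([CLASSES[i] for i in cnn_idx])
        train_pred = model.predict(x[train_idx])
        extras["cnn_train_acc"] = float(
            np.mean(np.array([CLASSES[i] for i in train_pred]) == y[train_idx]))
    return model, forest, np.asarray(y_pred), extras


def run_experiment(n_per_class: int = 100, cnn_epochs: int = 25, n_trees: int = 100,
                   seed: int = 1, protocol: str = "holdout", train_frac: float = 0.8,
                   k_folds: int = 10, bagging: str = "bdf", bag_fraction: float = 1.0,
                   cnn_batch: int = 128, use_augmentation: bool = False,
                   balance_plan: dict | None = None, vae_epochs: int = 200,
                   stratify: bool = True, with_cnn_baseline: bool = True,
                   records=None) -> ExperimentResult:
    """Run the full pipeline on surrogate (or caller-provided) records.

    Defaults are the desk-scale configuration: 100 records/class, 25 CNN epochs,
    100 trees, stratified 80/20 hold-out.
    """
    if records is None:
        records, _ = gen_dataset(n_per_class, seed=stage_seed(seed, "synth"))
    signals = [clean(r) for r in records]
    if use_augmentation:
        plan = aug.AugmentationPlan(balance_plan) if balance_plan \
            else aug.AugmentationPlan.default()
        signals = aug.balance(signals, plan, seed=stage_seed(seed, "augment"),
                              epochs=vae_epochs)
    x, y, src = images_from_signals(signals)

    if protocol == "holdout":
        tr, te = holdout_split(y, train_frac=train_frac,
                               seed=stage_seed(seed, "split"), stratify=stratify)
        model, forest, y_pred, extras = _fit_eval(
            x, y, src, tr, te, cnn_epochs, cnn_batch, n_trees, bagging,
            bag_fraction, seed, with_cnn_baseline)
        cm = confusion(y[te], y_pred)
        result = ExperimentResult(report=macro_report(cm), cm=cm, model=model,
                                  forest=forest, loss_history=model.loss_history)
        if with_cnn_baseline:
            result.cnn_cm = confusion(y[te], extras["cnn_pred"])
            result.cnn_report = macro_report(result.cnn_cm)
            result.cnn_train_accuracy = extras["cnn_train_acc"]
        return result

    if protocol == "cv10":
        def trainer(train_idx, test_idx):
            _, _, y_pred, _ = _fit_eval(x, y, src, train_idx, test_idx, cnn_epochs,
                                        cnn_batch, n_trees, bagging, bag_fraction,
                                        seed, False)
            return y_pred
        mean_report, fold_reports = kfold_cv(y, trainer, k=k_folds,
                                             seed=stage_seed(seed, "split"),
                                             stratify=stratify)
        # aggregate confusion over folds is not defined for the mean report; keep a
        # placeholder identity-free matrix of zeros with the mean report
        zero = ConfusionMatrix(np.zeros((len(CLASSES), len(CLASSES)), dtype=np.int64))
        res = ExperimentResult(report=mean_report, cm=zero)
        res.fold_reports = fold_reports
        return res

    raise ValueError("protocol must be 'holdout' or 'cv10'")
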