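"""Repeated random-split evaluation with diagnostic metrics.

The protocol: draw a stratified train/test split at fixed per-class
training counts, fit the classifier on the training half, predict the
held-out half, and tabulate the binary confusion matrix with cancer as
the positive class.  Repeat over several seeds (five by default) and
average the per-split metrics arithmetically.  The pooled-count variant
(metrics computed on the summed confusion matrix) is reported alongside,
clearly labelled, because the two conventions differ whenever split
compositions differ.

Metrics (reported as percentages):

    sensitivity = TP/(TP+FN)   specificity = TN/(TN+FP)
    PPV = TP/(TP+FP)           NPV = TN/(TN+FN)
    accuracy = (TP+TN)/total

A metric whose denominator is zero is flagged undefined (``None``), never
silently NaN-propagated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classifier import EWHKClassifier
from .dataset import SpectraDataset
from .exceptions import EwhkError, ValidationError

__all__ = [
    "ConfusionMatrix",
    "EvaluationReport",
    "metrics",
    "confusion_matrix",
    "random_split",
    "repeated_evaluation",
    "compare_models",
    "make_classifier",
]

METRIC_NAMES = ("sensitivity", "specificity", "ppv", "npv", "accuracy")


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts; entries are reals so averages are valid."""

    tp: float
    fp: float
    fn: float
    tn: float
    positive_label: str = "cancer"

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValidationError("confusion-matrix entries must be >= 0")
        if self.total == 0:
            raise ValidationError("confusion matrix is empty")

    @property
    def total(self) -> float:
        return self.tp + self.fp + self.fn + self.tn


def metrics(cm: ConfusionMatrix) -> dict[str, float | None]:
    """Five diagnostic metrics in percent; None where the denominator is 0."""

    def ratio(num: float, den: float) -> float | None:
        return 100.0 * num / den if den > 0 else None

    return {
        "sensitivity": ratio(cm.tp, cm.tp + cm.fn),
        "specificity": ratio(cm.tn, cm.tn + cm.fp),
        "ppv": ratio(cm.tp, cm.tp + cm.fp),
        "npv": ratio(cm.tn, cm.tn + cm.fn),
        "accuracy": ratio(cm.tp + cm.tn, cm.total),
    }


def confusion_matrix(y_true, y_pred, positive_label: str = "cancer") -> ConfusionMatrix:
    """Tabulate binary confusion counts; everything != positive is negative."""
    y_true = np.asarray(y_true, dtype=object)
    y_pred = np.asarray(y_pred, dtype=object)
    if y_true.shape != y_pred.shape:
        raise ValidationError("y_true and y_pred length mismatch")
    pos_t = y_true == positive_label
    pos_p = y_pred == positive_label
    return ConfusionMatrix(
        tp=float(np.sum(pos_t & pos_p)),
        fp=float(np.sum(~pos_t & pos_p)),
        fn=float(np.sum(pos_t & ~pos_p)),
        tn=float(np.sum(~pos_t & ~pos_p)),
        positive_label=positive_label,
    )


def random_split(
    ds: SpectraDataset, train_per_class: dict[str, int], seed: int
) -> tuple[SpectraDataset, SpectraDataset]:
    """Stratified split at fixed per-class training counts; rest is test.

    Sampling is without replacement and deterministic per seed.  Every
    class present in the dataset must appear in ``train_per_class``.
    An empty test set is allowed but flagged with a warning.
    """
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for label in ds.classes:
        if label not in train_per_class:
            raise ValidationError(f"no training count given for class {label!r}")
        rows = np.flatnonzero(ds.labels == label)
        count = int(train_per_class[label])
        if not 0 <= count <= rows.size:
            raise ValidationError(
                f"requested {count} training samples for class {label!r}, "
                f"only {rows.size} available"
            )
        perm = rng.permutation(rows)
        train_idx.append(perm[:count])
        test_idx.append(perm[count:])
    train_idx = np.sort(np.concatenate(train_idx))
    test_idx = np.sort(np.concatenate(test_idx))
    if test_idx.size == 0:
        warnings.warn("split leaves an empty test set", stacklevel=2)
        return ds.subset(train_idx), None
    return ds.subset(train_idx), ds.subset(test_idx)


def make_classifier(config: dict):
    """Build a classifier from a config dict: {"model": "ewhk"|"hknn"|"svm", ...}.

    ewhk/hknn accept k and lam; svm is a linear-kernel support vector
    machine from scikit-learn (C=1.0 unless overridden) used purely as a
    comparison baseline.
    """
    cfg = dict(config)
    model = cfg.pop("model", "ewhk")
    if callable(model):  # custom factory, e.g. degenerate baselines
        return model(**cfg)
    if model in ("ewhk", "hknn"):
        return EWHKClassifier(k=cfg.pop("k", 5), lam=cfg.pop("lam", 1.0), mode=model)
    if model == "svm":
        from sklearn.svm import SVC

        return SVC(kernel=cfg.pop("kernel", "linear"), C=cfg.pop("C", 1.0))
    raise ValidationError(f"unknown model {model!r}")


@dataclass(frozen=True)
class SplitResult:
    seed: int
    cm: ConfusionMatrix
    metrics: dict[str, float | None]


@dataclass(frozen=True)
class EvaluationReport:
    """Per-split confusion matrices/metrics plus the two averaging views."""

    per_split: tuple[SplitResult, ...]
    averaged: dict[str, float | None]          # arithmetic mean of per-split metrics
    averaged_cm: ConfusionMatrix               # mean of per-split confusion entries
    pooled: dict[str, float | None]            # metrics on summed counts, labelled distinctly
    pooled_cm: ConfusionMatrix
    split_spec: dict = field(default_factory=dict)

    def to_frame(self, model: str = "") -> pd.DataFrame:
        """Long-form table: one row per split plus 'avg' and 'pooled' rows."""
        rows = []
        for res in self.per_split:
            rows.append({"model": model, "split": res.seed,
                         "tp": res.cm.tp, "fp": res.cm.fp,
                         "fn": res.cm.fn, "tn": res.cm.tn, **res.metrics})
        rows.append({"model": model, "split": "avg",
                     "tp": self.averaged_cm.tp, "fp": self.averaged_cm.fp,
                     "fn": self.averaged_cm.fn, "tn": self.averaged_cm.tn,
                     **self.averaged})
        rows.append({"model": model, "split": "pooled",
                     "tp": self.pooled_cm.tp, "fp": self.pooled_cm.fp,
                     "fn": self.pooled_cm.fn, "tn": self.pooled_cm.tn,
                     **self.pooled})
        return pd.DataFrame(rows)


def _mean_defined(values: list[float | None]) -> float | None:
    defined = [v for v in values if v is not None]
    return float(np.mean(defined)) if defined else None


def repeated_evaluation(
    ds: SpectraDataset,
    classifier_config: dict,
    train_per_class: dict[str, int],
    n_repeats: int = 5,
    seeds=None,
    positive_label: str = "cancer",
) -> EvaluationReport:
    """Run the repeated random-split protocol for one classifier config.

    Seeds default to 1..n_repeats.  Averaged metrics are the arithmetic
    mean of per-split metrics; the pooled view recomputes metrics on the
    summed confusion matrix.
    """
    if seeds is None:
        seeds = list(range(1, n_repeats + 1))
    seeds = [int(s) for s in seeds]
    if not seeds:
        raise ValidationError("need at least one split seed")

    results = []
    for i, seed in enumerate(seeds):
        try:
            train, test = random_split(ds, train_per_class, seed)
            if test is None:
                raise ValidationError("empty test set")
            clf = make_classifier(classifier_config)
            clf.fit(train.absorbance, train.labels)
            pred = clf.predict(test.absorbance)
            cm = confusion_matrix(test.labels, pred, positive_label)
        except EwhkError as exc:
            raise type(exc)(f"split {i} (seed {seed}): {exc}") from exc
        results.append(SplitResult(seed=seed, cm=cm, metrics=metrics(cm)))

    averaged = {name: _mean_defined([r.metrics[name] for r in results])
                for name in METRIC_NAMES}
    averaged_cm = ConfusionMatrix(
        tp=float(np.mean([r.cm.tp for r in results])),
        fp=float(np.mean([r.cm.fp for r in results])),
        fn=float(np.mean([r.cm.fn for r in results])),
        tn=float(np.mean([r.cm.tn for r in results])),
        positive_label=positive_label,
    )
    pooled_cm = ConfusionMatrix(
        tp=sum(r.cm.tp for r in results), fp=sum(r.cm.fp for r in results),
        fn=sum(r.cm.fn for r in results), tn=sum(r.cm.tn for r in results),
        positive_label=positive_label,
    )
    return EvaluationReport(
        per_split=tuple(results),
        averaged=averaged,
        averaged_cm=averaged_cm,
        pooled=metrics(pooled_cm),
        pooled_cm=pooled_cm,
        split_spec={"train_per_class": dict(train_per_class), "seeds": seeds,
                    "positive_label": positive_label},
    )


def compare_models(
    ds: SpectraDataset,
    configs: list[dict],
    train_per_class: dict[str, int],
    n_repeats: int = 5,
    seeds=None,
    positive_label: str = "cancer",
) -> pd.DataFrame:
    """Averaged metrics per model, one row each, on identical splits.

    All configs see the same seeds, hence the same train/test partitions:
    a paired comparison.  Config dicts need a "model" key (ewhk, hknn or
    svm) and may carry model parameters.
    """
    if not configs:
        raise ValidationError("need at least one model config")
    rows = []
    for config in configs:
        report = repeated_evaluation(
            ds, config, train_per_class, n_repeats=n_repeats,
            seeds=seeds, positive_label=positive_label,
        )
        rows.append({"model": config.get("model", "ewhk"), **report.averaged})
    return pd.DataFrame(rows)
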