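"""Confusion matrices, one-vs-rest classification metrics, multi-run
aggregation, ROC/AUC, embedding projection, and the ablation harness.

Per class c the binary reduction is TP = cm[c][c], FP = column sum - TP,
FN = row sum - TP, TN = total - TP - FP - FN, and the binary metrics are

    precision   = TP / (TP + FP)
    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    specificity = TN / (TN + FP)
    F1          = 2 * precision * recall / (precision + recall)

with a metric defined as 0 (and logged) when its denominator vanishes.
Macro values are unweighted means over classes; the overall (micro)
accuracy is trace / total.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.metrics import silhouette_score

from .exceptions import ConfigError
from .model import CBGMModel, ModelConfig, count_parameters
from .signal_io import CLASSES, SegmentDataset

logger = logging.getLogger("cbgm")

__all__ = [
    "ConfusionMatrix",
    "MetricReport",
    "RunSummary",
    "confusion",
    "metrics_from_confusion",
    "report_from_confusion",
    "aggregate_runs",
    "roc_auc",
    "project_embeddings",
    "ablation",
]

METRICS = ("accuracy", "precision", "specificity", "f1", "sensitivity")


@dataclass
class ConfusionMatrix:
    """5x5 count table; rows = true class, columns = predicted, order N,A,V,L,R."""

    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (5, 5):
            raise ValueError("confusion matrix must be 5x5")
        if (self.counts < 0).any():
            raise ValueError("confusion matrix entries must be >= 0")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def micro_accuracy(self) -> float:
        return float(np.trace(self.counts)) / self.total if self.total else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=CLASSES, columns=CLASSES)


def confusion(true_labels: Sequence[str], predicted_labels: Sequence[str]) -> ConfusionMatrix:
    """Count table over the five-class alphabet."""
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label lists must have equal length")
    for lab in list(true_labels) + list(predicted_labels):
        if lab not in CLASSES:
            raise ValueError(f"label {lab!r} outside alphabet {CLASSES}")
    cm = _sk_confusion(true_labels, predicted_labels, labels=list(CLASSES))
    return ConfusionMatrix(cm)


def metrics_from_confusion(cm: ConfusionMatrix, cls: str) -> dict:
    """One-vs-rest metrics for class `cls` (zero on empty denominators)."""
    if cls not in CLASSES:
        raise ValueError(f"unknown class {cls!r}")
    c = CLASSES.index(cls)
    counts = cm.counts
    tp = int(counts[c, c])
    fp = int(counts[:, c].sum() - tp)
    fn = int(counts[c, :].sum() - tp)
    tn = int(counts.sum() - tp - fp - fn)

    def ratio(num, den, name):
        if den == 0:
            logger.warning("%s undefined for class %s (0 denominator); using 0", name, cls)
            return 0.0
        return num / den

    precision = ratio(tp, tp + fp, "precision")
    recall = ratio(tp, tp + fn, "sensitivity")
    return {
        "tp": tp, "fp": fp, "fn": fn, "tn": tn,
        "precision": precision,
        "sensitivity": recall,
        "specificity": ratio(tn, tn + fp, "specificity"),
        "accuracy": ratio(tp + tn, tp + tn + fp + fn, "accuracy"),
        "f1": ratio(2 * precision * recall, precision + recall, "f1")
        if (precision + recall) > 0 else 0.0,
    }


@dataclass
class MetricReport:
    """Per-class + macro metrics derived from one confusion matrix."""

    per_class: dict
    macro: dict
    micro_accuracy: float

    def to_frame(self) -> pd.DataFrame:
        rows = {c: {m: self.per_class[c][m] for m in METRICS} for c in CLASSES}
        rows["macro"] = dict(self.macro)
        return pd.DataFrame(rows).T


def report_from_confusion(cm: ConfusionMatrix) -> MetricReport:
    per_class = {c: metrics_from_confusion(cm, c) for c in CLASSES}
    macro = {
        m: float(np.mean([per_class[c][m] for c in CLASSES])) for m in METRICS
    }
    return MetricReport(per_class, macro, cm.micro_accuracy())


@dataclass
class RunSummary:
    """Multi-run summary: one row per run plus mean and sd rows."""

    table: pd.DataFrame
    mean: dict
    sd: dict
    single_run: bool = False


def aggregate_runs(reports: Sequence[MetricReport]) -> RunSummary:
    """Mean and sample sd of the macro metrics over repeated runs."""
    if not reports:
        raise ValueError("need at least one report")
    rows = [
        {m: r.macro[m] for m in METRICS} | {"micro_accuracy": r.micro_accuracy}
        for r in reports
    ]
    df = pd.DataFrame(rows, index=[f"run{i + 1}" for i in range(len(rows))])
    mean = df.mean().to_dict()
    single = len(reports) == 1
    if single:
        logger.warning("sample sd undefined for a single run; reporting 0")
        sd = {k: 0.0 for k in mean}
    else:
        sd = df.std(ddof=1).to_dict()
    table = pd.concat(
        [df, pd.DataFrame([mean, sd], index=["mean", "sd"])]
    )
    return RunSummary(table, mean, sd, single_run=single)


def roc_auc(true_labels: Sequence[str], probabilities: np.ndarray):
    """One-vs-rest ROC per class; AUC by the trapezoid rule; macro mean.

    Classes absent from the truth are excluded from the macro average
    (with a warning).  Returns ``(per_class_auc, macro_auc)``.
    """
    probabilities = np.asarray(probabilities, dtype=float)
    y = np.array([CLASSES.index(lab) for lab in true_labels])
    per_class, valid = {}, []
    for c, name in enumerate(CLASSES):
        pos = y == c
        if pos.all() or not pos.any():
            logger.warning("class %s absent from truth; AUC undefined", name)
            per_class[name] = np.nan
            continue
        fpr, tpr, _ = _sk_roc_curve(pos.astype(int), probabilities[:, c])
        per_class[name] = float(np.trapezoid(tpr, fpr))
        valid.append(per_class[name])
    macro = float(np.mean(valid)) if valid else np.nan
    return per_class, macro


def project_embeddings(
    model: CBGMModel,
    dataset: SegmentDataset,
    method: str = "tsne",
    seed: int = 0,
):
    """Project penultimate-layer embeddings to 2-D.

    Returns ``(coords, silhouette)`` where `silhouette` is the silhouette
    score of the 2-D coordinates grouped by true label (``nan``, flagged in
    the log, when the points collapse or only one class is present).
    """
    X, y = dataset.to_arrays()
    emb = np.concatenate(
        [model.forward(X[i : i + 256]).embedding for i in range(0, len(X), 256)]
    )
    if method == "pca":
        from sklearn.decomposition import PCA

        coords = PCA(n_components=2, random_state=seed).fit_transform(emb)
    elif method == "tsne":
        from sklearn.manifold import TSNE

        coords = TSNE(
            n_components=2,
            random_state=seed,
            perplexity=min(30.0, max(2.0, len(X) / 4 - 1)),
            init="pca",
        ).fit_transform(emb)
    else:
        raise ConfigError(f"unknown projection method {method!r}")
    if len(np.unique(y)) < 2 or np.allclose(coords.var(axis=0), 0):
        logger.warning("silhouette undefined (collapsed coordinates or one class)")
        return coords, float("nan")
    return coords, float(silhouette_score(coords, y))


def ablation(
    dataset: SegmentDataset,
    model_cfg: ModelConfig,
    train_cfg,
    components: Sequence[str] = ("bigru", "attention"),
    seeds: Sequence[int] = (0, 1, 2),
):
    """Train the full model and each component-ablated variant.

    For every variant and seed the dataset is re-split 7:3, a fresh model
    is trained, and macro metrics are computed on the test split.  Returns
    a DataFrame with mean +/- sd per metric and the variant parameter
    counts.
    """
    from .training import split, train

    for comp in components:
        if comp not in ("bigru", "attention"):
            raise ConfigError(f"unknown component {comp!r}")
    variants = {"full": model_cfg}
    if "bigru" in components:
        variants["minus_bigru"] = replace(
            model_cfg,
            use_bigru=False,
            d_model=model_cfg.conv_blocks[-1][0],
        )
    if "attention" in components:
        variants["minus_attention"] = replace(model_cfg, use_attention=False)
    rows = []
    for name, cfg in variants.items():
        accs = {m: [] for m in METRICS}
        for seed in seeds:
            tr, te = split(dataset, train_cfg.split_ratio, seed)
            model = CBGMModel(cfg, seed=seed)
            train(model, tr, te, replace(train_cfg, seed=seed))
            Xte, yte = te.to_arrays()
            pred = model.predict(Xte)
            cm = confusion([CLASSES[i] for i in yte], [CLASSES[i] for i in pred])
            rep = report_from_confusion(cm)
            for m in METRICS:
                accs[m].append(rep.macro[m])
            accs.setdefault("micro_accuracy", []).append(rep.micro_accuracy)
        row = {"variant": name, "n_parameters": count_parameters(cfg)}
        for m, vals in accs.items():
            v = np.asarray(vals)
            row[f"{m}_mean"] = float(v.mean())
            row[f"{m}_sd"] = float(v.std(ddof=1)) if len(v) > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows).set_index("variant")
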