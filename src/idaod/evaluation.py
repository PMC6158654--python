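"""Confusion-matrix metrics and the 10-fold cross-validation harness.

Metrics follow the standard definitions on TP/FP/TN/FN:

    Sn  = TP / (TP + FN)                    (sensitivity, positive recall)
    Sp  = TN / (TN + FP)                    (specificity, negative recall)
    Acc = (TP + TN) / (TP + FN + TN + FP)
    precision = TP / (TP + FP)
    F1  = 2 * precision * Sn / (precision + Sn)
    MCC = (TP*TN - FP*FN) /
          sqrt((TP+FN)(TP+FP)(TN+FP)(TN+FN))

A statistic whose denominator is zero is reported as *undefined* (None,
with its name flagged), never silently coerced to 0.

Cross-validation is stratified: with ~6x more negatives than positives,
unstratified 10-fold splits risk folds with almost no positives. Headline
metrics pool confusion counts across folds (micro); per-fold reports are
retained alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .config import PipelineConfig
from .embed_classify import (
    EVAL,
    TRAIN,
    Embedding2D,
    predict,
    train_svm,
    tsne_embed,
)
from .errors import StratificationError, ValidationError
from .features import apply_feature_scale, featurize_dataset, fit_feature_scale
from .network import (
    LabeledDataset,
    default_sample_weights,
    extract_representation,
    fine_tune,
    pretrain_autoencoder,
)
from .sequence_io import ProteinRecord

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "compute_metrics",
    "stratified_kfold",
    "run_cv_pipeline",
    "CVResult",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/TN/FN over a set of evaluated samples."""

    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.TP + other.TP, self.FP + other.FP,
            self.TN + other.TN, self.FN + other.FN,
        )

    @classmethod
    def from_predictions(
        cls, y_true: np.ndarray, y_pred: np.ndarray
    ) -> "ConfusionCounts":
        y_true = np.asarray(y_true).astype(int)
        y_pred = np.asarray(y_pred).astype(int)
        if y_true.shape != y_pred.shape:
            raise ValidationError("y_true and y_pred must align")
        return cls(
            TP=int(np.sum((y_true == 1) & (y_pred == 1))),
            FP=int(np.sum((y_true == 0) & (y_pred == 1))),
            TN=int(np.sum((y_true == 0) & (y_pred == 0))),
            FN=int(np.sum((y_true == 1) & (y_pred == 0))),
        )


@dataclass(frozen=True)
class MetricsReport:
    """Sn/Sp/Acc/precision/F1/MCC; undefined statistics are None + flagged."""

    counts: ConfusionCounts
    sn: float | None
    sp: float | None
    acc: float | None
    precision: float | None
    f1: float | None
    mcc: float | None
    undefined: frozenset[str] = frozenset()
    per_fold: tuple["MetricsReport", ...] = field(default_factory=tuple)

    def as_dict(self) -> dict[str, float | None]:
        return {
            "Sn": self.sn, "Sp": self.sp, "Acc": self.acc,
            "precision": self.precision, "F1": self.f1, "MCC": self.mcc,
            "TP": self.counts.TP, "FP": self.counts.FP,
            "TN": self.counts.TN, "FN": self.counts.FN,
        }


def _ratio(num: float, den: float) -> float | None:
    return num / den if den > 0 else None


def compute_metrics(counts: ConfusionCounts) -> MetricsReport:
    """All six statistics from the confusion counts."""
    if counts.total == 0:
        raise ValidationError("cannot evaluate an empty confusion table")
    tp, fp, tn, fn = counts.TP, counts.FP, counts.TN, counts.FN
    sn = _ratio(tp, tp + fn)
    sp = _ratio(tn, tn + fp)
    acc = (tp + tn) / counts.total
    precision = _ratio(tp, tp + fp)
    if precision is None or sn is None or precision + sn == 0:
        f1 = None
    else:
        f1 = 2 * precision * sn / (precision + sn)
    mcc_den = math.sqrt(
        float(tp + fn) * (tp + fp) * (tn + fp) * (tn + fn)
    )
    mcc = (tp * tn - fp * fn) / mcc_den if mcc_den > 0 else None
    undefined = frozenset(
        name for name, value in
        [("Sn", sn), ("Sp", sp), ("precision", precision),
         ("F1", f1), ("MCC", mcc)]
        if value is None
    )
    return MetricsReport(
        counts=counts, sn=sn, sp=sp, acc=acc,
        precision=precision, f1=f1, mcc=mcc, undefined=undefined,
    )


def stratified_kfold(
    labels: np.ndarray, k: int, seed: int
) -> list[np.ndarray]:
    """k disjoint validation index sets preserving class proportions.

    Fold sizes differ by at most 1, per-class counts across folds differ by
    at most 1, and the assignment is deterministic given the seed.
    """
    labels = np.asarray(labels)
    if k < 2:
        raise ValidationError("k must be at least 2")
    classes, class_counts = np.unique(labels, return_counts=True)
    small = classes[class_counts < k]
    if small.size:
        raise StratificationError(
            f"class(es) {small.tolist()} have fewer than k={k} members"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [val_idx for _, val_idx in skf.split(np.zeros(len(labels)), labels)]


@dataclass(frozen=True)
class CVResult:
    """Everything a cross-validation run produced."""

    pooled: MetricsReport
    per_fold: tuple[MetricsReport, ...]
    fold_indices: list[np.ndarray]
    embeddings: list[Embedding2D]
    ids: list[str]
    seed: int


def _fold_seeds(master_seed: int, k: int, streams: int = 3) -> np.ndarray:
    # one sub-seed per (fold, stage) from a SeedSequence, kept below 2^31
    ss = np.random.SeedSequence(master_seed)
    return ss.generate_state(k * streams).reshape(k, streams) % (2 ** 31)


def run_cv_pipeline(
    records: list[ProteinRecord],
    labels: dict[str, int] | np.ndarray,
    config: PipelineConfig | None = None,
    k: int | None = None,
    seed: int | None = None,
) -> CVResult:
    """Full k-fold cross-validation of the four-stage pipeline.

    Per fold: featurize -> pre-train autoencoder and fine-tune on the
    training portion only -> extract 50-dim representations for both
    portions -> embed them jointly with t-SNE (transductive, labels unseen)
    -> fit the class-weighted linear SVM on training points -> predict the
    validation points. Confusion counts are pooled across folds.
    """
    config = config or PipelineConfig()
    k = k if k is not None else config.cv_folds
    seed = seed if seed is not None else config.seed

    if isinstance(labels, dict):
        missing = [r.id for r in records if r.id not in labels]
        if missing:
            raise ValidationError(f"missing labels for record(s): {missing}")
        y = np.array([labels[r.id] for r in records], dtype=np.int64)
    else:
        y = np.asarray(labels, dtype=np.int64)
        if y.shape[0] != len(records):
            raise ValidationError("labels must align with records")

    X, ids = featurize_dataset(records)
    folds = stratified_kfold(y, k, seed)
    seeds = _fold_seeds(seed, k)

    pooled: ConfusionCounts | None = None
    per_fold: list[MetricsReport] = []
    embeddings: list[Embedding2D] = []

    for f, val_idx in enumerate(folds):
        train_mask = np.ones(len(records), dtype=bool)
        train_mask[val_idx] = False
        try:
            ae_cfg = dataclasses_replace_seed(config.autoencoder, seeds[f, 0])
            ft_cfg = dataclasses_replace_seed(config.fine_tune, seeds[f, 1])
            # feature scale fitted on the training portion only
            scale = fit_feature_scale(X[train_mask])
            Xs = apply_feature_scale(X, scale)
            train_data = LabeledDataset(
                features=Xs[train_mask],
                labels=y[train_mask],
                sample_weights=default_sample_weights(
                    y[train_mask], config.positive_sample_weight
                ),
                ids=[ids[i] for i in np.where(train_mask)[0]],
            )
            encoder, ae_losses = pretrain_autoencoder(train_data, ae_cfg)
            model = fine_tune(encoder, train_data, ft_cfg,
                              ae_config=ae_cfg, pretrain_losses=ae_losses)

            rep_train = extract_representation(model, Xs[train_mask])
            rep_val = extract_representation(model, Xs[val_idx])
            union = np.vstack([rep_train, rep_val])
            roles = [TRAIN] * rep_train.shape[0] + [EVAL] * rep_val.shape[0]
            union_ids = (
                [ids[i] for i in np.where(train_mask)[0]]
                + [ids[i] for i in val_idx]
            )
            tsne_cfg = dataclasses_replace_seed(config.tsne, seeds[f, 2])
            embedding = tsne_embed(union, tsne_cfg, ids=union_ids, roles=roles)

            svm = train_svm(embedding, y[train_mask], config.svm)
            y_pred = predict(
                svm, embedding.coordinates[embedding.rows(EVAL)]
            )
        except Exception as exc:
            exc.add_note(f"while processing cross-validation fold {f}")
            raise
        counts = ConfusionCounts.from_predictions(y[val_idx], y_pred)
        pooled = counts if pooled is None else pooled + counts
        per_fold.append(compute_metrics(counts))
        embeddings.append(embedding)

    pooled_report = compute_metrics(pooled)
    pooled_report = MetricsReport(
        counts=pooled_report.counts,
        sn=pooled_report.sn, sp=pooled_report.sp, acc=pooled_report.acc,
        precision=pooled_report.precision, f1=pooled_report.f1,
        mcc=pooled_report.mcc, undefined=pooled_report.undefined,
        per_fold=tuple(per_fold),
    )
    return CVResult(
        pooled=pooled_report,
        per_fold=tuple(per_fold),
        fold_indices=folds,
        embeddings=embeddings,
        ids=ids,
        seed=seed,
    )


def dataclasses_replace_seed(cfg, seed: int):
    """Copy a config dataclass with its seed replaced (per-fold seeding)."""
    import dataclasses

    return dataclasses.replace(cfg, seed=int(seed))
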