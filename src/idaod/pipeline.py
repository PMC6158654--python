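"""End-to-end orchestration: train, predict on new sequences, CV reports.

The pipeline order is fixed: g-gap features -> autoencoder pre-training +
FC fine-tuning -> t-SNE -> linear SVM. Because t-SNE has no out-of-sample
mapping, a trained pipeline stores its training representations and labels
so that prediction on new sequences can re-embed (stored training points
union new points) transductively and refit the SVM on the training side.

Every written artifact carries the master seed and a hash of the fully
resolved configuration; reruns with identical inputs produce byte-identical
files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .config import PipelineConfig, config_hash, config_to_dict
from .embed_classify import EVAL, TRAIN, predict, train_svm, tsne_embed
from .errors import ValidationError
from .evaluation import CVResult, dataclasses_replace_seed, run_cv_pipeline
from .features import apply_feature_scale, featurize_dataset, fit_feature_scale
from .network import (
    FeatureLearner,
    LabeledDataset,
    default_sample_weights,
    extract_representation,
    fine_tune,
    pretrain_autoencoder,
)
from .sequence_io import ProteinRecord, read_fasta, read_labels

__all__ = [
    "TrainedPipeline",
    "train_pipeline",
    "predict_pipeline",
    "run_end_to_end",
]

STAGES = ("ggap_features", "feature_learning", "tsne", "svm")


@dataclass
class TrainedPipeline:
    """A fitted feature learner plus what prediction needs for re-embedding."""

    learner: FeatureLearner
    feature_scale: np.ndarray  # (800,) per-column training scale
    train_representation: np.ndarray  # (n_train, 50)
    train_labels: np.ndarray  # (n_train,)
    train_ids: list[str]
    config: PipelineConfig
    seed: int

    def save(self, path: str | Path) -> None:
        arrays = {
            "feature_scale": self.feature_scale,
            "train_representation": self.train_representation,
            "train_labels": self.train_labels,
        }
        for i, layer in enumerate(self.learner.layers):
            arrays[f"W{i}"] = layer.W
            arrays[f"b{i}"] = layer.b
        meta = {
            "format_version": 1,
            "seed": int(self.seed),
            "config": config_to_dict(self.config),
            "config_hash": config_hash(self.config),
            "train_ids": self.train_ids,
            "n_encoder": len(self.learner.encoder_layers),
            "activations": [l.activation for l in self.learner.layers],
            "pretrain_losses": self.learner.pretrain_losses,
            "finetune_losses": self.learner.finetune_losses,
            "version": __version__,
        }
        arrays["meta_json"] = np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8
        )
        with open(path, "wb") as fh:
            np.savez(fh, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "TrainedPipeline":
        from .config import resolve_config
        from .network import Dense

        with np.load(path) as npz:
            meta = json.loads(bytes(npz["meta_json"]).decode())
            acts = meta["activations"]
            layers = [
                Dense(npz[f"W{i}"], npz[f"b{i}"], acts[i])
                for i in range(len(acts))
            ]
            feature_scale = npz["feature_scale"].copy()
            train_rep = npz["train_representation"].copy()
            train_labels = npz["train_labels"].copy()
        cfg = resolve_config(meta["config"])
        n_enc = meta["n_encoder"]
        learner = FeatureLearner(
            layers[:n_enc], layers[n_enc:], cfg.autoencoder, cfg.fine_tune,
            meta["pretrain_losses"], meta["finetune_losses"],
        )
        return cls(
            learner=learner,
            feature_scale=feature_scale,
            train_representation=train_rep,
            train_labels=train_labels,
            train_ids=meta["train_ids"],
            config=cfg,
            seed=meta["seed"],
        )


def _align_labels(
    records: list[ProteinRecord], labels: dict[str, int] | np.ndarray
) -> np.ndarray:
    if isinstance(labels, dict):
        missing = [r.id for r in records if r.id not in labels]
        if missing:
            raise ValidationError(f"missing labels for record(s): {missing}")
        return np.array([labels[r.id] for r in records], dtype=np.int64)
    y = np.asarray(labels, dtype=np.int64)
    if y.shape[0] != len(records):
        raise ValidationError("labels must align with records")
    return y


def train_pipeline(
    records: list[ProteinRecord],
    labels: dict[str, int] | np.ndarray,
    config: PipelineConfig | None = None,
    seed: int | None = None,
) -> TrainedPipeline:
    """Fit features -> autoencoder -> fine-tuning on the full dataset."""
    config = config or PipelineConfig()
    seed = seed if seed is not None else config.seed
    y = _align_labels(records, labels)
    X, ids = featurize_dataset(records, config.gaps)
    scale = fit_feature_scale(X)
    Xs = apply_feature_scale(X, scale)
    data = LabeledDataset(
        features=Xs,
        labels=y,
        sample_weights=default_sample_weights(y, config.positive_sample_weight),
        ids=ids,
    )
    ae_cfg = dataclasses_replace_seed(config.autoencoder, seed)
    ft_cfg = dataclasses_replace_seed(config.fine_tune, seed)
    encoder, ae_losses = pretrain_autoencoder(data, ae_cfg)
    learner = fine_tune(encoder, data, ft_cfg,
                        ae_config=ae_cfg, pretrain_losses=ae_losses)
    return TrainedPipeline(
        learner=learner,
        feature_scale=scale,
        train_representation=extract_representation(learner, Xs),
        train_labels=y,
        train_ids=ids,
        config=config,
        seed=seed,
    )


def predict_pipeline(
    pipeline: TrainedPipeline,
    records: list[ProteinRecord],
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Predict labels for new sequences.

    Re-embeds (stored training representations union new representations)
    with t-SNE, refits the SVM on the training points, and classifies the
    new points. Returns (ids, predicted labels, 2D coordinates of the new
    points).
    """
    config = pipeline.config
    X_new, new_ids = featurize_dataset(records, config.gaps)
    Xs_new = apply_feature_scale(X_new, pipeline.feature_scale)
    rep_new = extract_representation(pipeline.learner, Xs_new)
    union = np.vstack([pipeline.train_representation, rep_new])
    roles = [TRAIN] * len(pipeline.train_ids) + [EVAL] * len(new_ids)
    tsne_cfg = dataclasses_replace_seed(config.tsne, pipeline.seed)
    embedding = tsne_embed(
        union, tsne_cfg, ids=pipeline.train_ids + new_ids, roles=roles
    )
    svm = train_svm(embedding, pipeline.train_labels, config.svm)
    coords_new = embedding.coordinates[embedding.rows(EVAL)]
    y_pred = predict(svm, coords_new)
    return new_ids, y_pred, coords_new


# ---------------------------------------------------------------------------
# report writing


def _header_lines(seed: int, cfg_hash: str) -> str:
    return f"# seed={seed}\n# config_hash={cfg_hash}\n"


def _fmt(value: float | None) -> str:
    return "undefined" if value is None else f"{value:.6f}"


def _write_metrics_tsv(path: Path, rows: list[tuple[str, dict]],
                       seed: int, cfg_hash: str) -> None:
    cols = ["Sn", "Sp", "Acc", "precision", "F1", "MCC",
            "TP", "FP", "TN", "FN"]
    with open(path, "w") as fh:
        fh.write(_header_lines(seed, cfg_hash))
        fh.write("split\t" + "\t".join(cols) + "\n")
        for name, d in rows:
            cells = [
                _fmt(d[c]) if c in {"Sn", "Sp", "Acc", "precision", "F1", "MCC"}
                else str(d[c])
                for c in cols
            ]
            fh.write(name + "\t" + "\t".join(cells) + "\n")


def write_cv_report(
    result: CVResult,
    config: PipelineConfig,
    out_dir: str | Path,
) -> dict:
    """Write metrics_pooled.tsv, metrics_per_fold.tsv, folds.tsv, per-fold
    embeddings and a run manifest into ``out_dir``; returns the manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config_hash(config)
    seed = result.seed

    _write_metrics_tsv(
        out_dir / "metrics_pooled.tsv",
        [("pooled", result.pooled.as_dict())], seed, cfg_hash,
    )
    _write_metrics_tsv(
        out_dir / "metrics_per_fold.tsv",
        [(f"fold{f}", rep.as_dict()) for f, rep in enumerate(result.per_fold)],
        seed, cfg_hash,
    )
    with open(out_dir / "folds.tsv", "w") as fh:
        fh.write(_header_lines(seed, cfg_hash))
        fh.write("record_id\tfold\n")
        fold_of = {}
        for f, idx in enumerate(result.fold_indices):
            for i in idx:
                fold_of[result.ids[i]] = f
        for rec_id in result.ids:
            fh.write(f"{rec_id}\t{fold_of[rec_id]}\n")
    for f, emb in enumerate(result.embeddings):
        with open(out_dir / f"embedding_fold{f}.tsv", "w") as fh:
            fh.write(_header_lines(seed, cfg_hash))
            fh.write("record_id\trole\tx\ty\n")
            for rec_id, role, (x, yy) in zip(
                emb.ids, emb.roles, emb.coordinates
            ):
                fh.write(f"{rec_id}\t{role}\t{x:.6f}\t{yy:.6f}\n")

    manifest = {
        "stages": list(STAGES),
        "seed": seed,
        "config_hash": cfg_hash,
        "config": config_to_dict(config),
        "version": __version__,
        "outputs": sorted(p.name for p in out_dir.iterdir()),
        "pooled_metrics": result.pooled.as_dict(),
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def run_end_to_end(
    fasta_path: str | Path,
    labels_path: str | Path,
    config: PipelineConfig | None = None,
    out_dir: str | Path = "idaod_report",
    seed: int | None = None,
) -> dict:
    """Read data, cross-validate the full pipeline, train a final model,
    and write the report directory. Returns the run manifest."""
    config = config or PipelineConfig()
    seed = seed if seed is not None else config.seed
    records, rejected = read_fasta(fasta_path)
    labels = read_labels(labels_path)
    result = run_cv_pipeline(records, labels, config, seed=seed)
    manifest = write_cv_report(result, config, out_dir)
    final = train_pipeline(records, labels, config, seed=seed)
    final.save(Path(out_dir) / "model.idaod")
    manifest["rejected_records"] = rejected
    manifest["outputs"] = sorted(p.name for p in Path(out_dir).iterdir())
    with open(Path(out_dir) / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
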