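"""t-SNE embedding of the learned representation and class-weighted SVM.

The learned 50-dim representation is reduced to two dimensions with t-SNE,
turning every protein into a point in the plane; a linear SVM with penalty
C = 2 and class weights 5:1 (positive:negative) then draws the decision
boundary.

t-SNE has no native out-of-sample mapping, so evaluation points are
embedded *transductively*: the embedding is fitted jointly on the union of
training and evaluation representations (features only — labels are never
seen by t-SNE), rows are tagged with their role, the SVM is fitted on the
training-tagged points alone and evaluated on the rest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.manifold import TSNE
from sklearn.svm import SVC

from .errors import (
    ConfigError,
    DegenerateTrainingError,
    FeasibilityError,
    PipelineRuntimeError,
    ValidationError,
)

__all__ = [
    "TSNESettings",
    "Embedding2D",
    "SVMConfig",
    "FittedSVM",
    "tsne_embed",
    "train_svm",
    "predict",
]

TRAIN, EVAL = "train", "eval"


@dataclass
class TSNESettings:
    """t-SNE hyperparameters; the defaults are recorded into every result."""

    perplexity: float = 30.0
    n_iter: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.perplexity <= 0:
            raise ConfigError("perplexity must be positive")
        if self.n_iter < 250:
            raise ConfigError("t-SNE needs at least 250 iterations")


@dataclass(frozen=True)
class Embedding2D:
    """A 2D embedding with provenance: ids, settings, and row roles."""

    coordinates: np.ndarray  # (n, 2) float64, finite
    ids: list[str]
    settings: TSNESettings
    roles: list[str] = field(default_factory=list)  # "train" / "eval" per row

    def rows(self, role: str) -> np.ndarray:
        """Boolean mask of rows carrying the given role tag."""
        return np.array([r == role for r in self.roles], dtype=bool)


@dataclass
class SVMConfig:
    """Linear SVM with C = 2 and positive:negative class weights 5:1."""

    kernel: str = "linear"
    C: float = 2.0
    positive_class_weight: float = 5.0
    negative_class_weight: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ConfigError("C must be positive")
        if self.positive_class_weight <= 0 or self.negative_class_weight <= 0:
            raise ConfigError("class weights must be positive")

    @property
    def class_weight(self) -> dict[int, float]:
        return {1: self.positive_class_weight, 0: self.negative_class_weight}


@dataclass(frozen=True)
class FittedSVM:
    """A fitted linear SVM together with the configuration that produced it."""

    model: SVC
    config: SVMConfig
    training_accuracy: float


def tsne_embed(
    representation: np.ndarray,
    settings: TSNESettings | None = None,
    ids: list[str] | None = None,
    roles: list[str] | None = None,
) -> Embedding2D:
    """Embed representation rows into 2D; deterministic given the seed.

    Raises :class:`FeasibilityError` when n <= 3 * perplexity (the standard
    t-SNE feasibility bound), suggesting a smaller perplexity.
    """
    settings = settings or TSNESettings()
    X = np.asarray(representation, dtype=np.float64)
    if X.ndim != 2:
        raise ValidationError(f"representation must be 2D, got shape {X.shape}")
    if not np.all(np.isfinite(X)):
        raise ValidationError("representation contains non-finite values")
    n = X.shape[0]
    if n <= 3 * settings.perplexity:
        raise FeasibilityError(
            f"n={n} points require perplexity < n/3; "
            f"got {settings.perplexity} — try perplexity <= {max(1, (n - 1) // 3)}"
        )
    tsne = TSNE(
        n_components=2,
        perplexity=settings.perplexity,
        max_iter=settings.n_iter,
        init="random",
        random_state=settings.seed,
        n_jobs=1,
    )
    coords = np.asarray(tsne.fit_transform(X), dtype=np.float64)
    if not np.all(np.isfinite(coords)):
        raise PipelineRuntimeError("t-SNE produced non-finite coordinates")
    return Embedding2D(
        coordinates=coords,
        ids=list(ids) if ids is not None else [str(i) for i in range(n)],
        settings=settings,
        roles=list(roles) if roles is not None else [TRAIN] * n,
    )


def train_svm(
    embedding: Embedding2D,
    labels: np.ndarray,
    config: SVMConfig | None = None,
) -> FittedSVM:
    """Fit the class-weighted linear SVM on the training-tagged 2D points.

    ``labels`` aligns with the *training-tagged* rows of the embedding (or
    with all rows when every row is training-tagged).
    """
    config = config or SVMConfig()
    mask = embedding.rows(TRAIN)
    X = embedding.coordinates[mask]
    y = np.asarray(labels)
    if y.shape[0] != X.shape[0]:
        raise ValidationError(
            f"{X.shape[0]} training-tagged rows but {y.shape[0]} labels"
        )
    if len(np.unique(y)) < 2:
        raise DegenerateTrainingError("SVM training needs both classes")
    svc = SVC(
        kernel=config.kernel,
        C=config.C,
        class_weight=config.class_weight,
        random_state=config.seed,
    )
    svc.fit(X, y)
    acc = float(np.mean(svc.predict(X) == y))
    return FittedSVM(model=svc, config=config, training_accuracy=acc)


def predict(model: FittedSVM, points: np.ndarray) -> np.ndarray:
    """Predict binary labels (1 = antioxidant) for 2D points; deterministic."""
    points = np.asarray(points, dtype=np.float64)
    if points.ndim != 2 or points.shape[1] != 2:
        raise ValidationError(f"expected (n, 2) points, got {points.shape}")
    return np.asarray(model.model.predict(points), dtype=np.int64)
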