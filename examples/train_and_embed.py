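"""Learn a 50-dim representation and embed it in 2D.

Trains the autoencoder + fine-tuning stack on a small synthetic dataset
(reduced epochs for a quick demonstration), extracts the first-FC-layer
representation, embeds it with t-SNE and fits the class-weighted SVM.
"""

from idaod import (
    AutoencoderConfig,
    FineTuneConfig,
    LabeledDataset,
    SimulationConfig,
    TSNESettings,
    extract_representation,
    featurize_dataset,
    fine_tune,
    pretrain_autoencoder,
    simulate_dataset,
    train_svm,
    tsne_embed,
)
from idaod.features import apply_feature_scale, fit_feature_scale

sim = simulate_dataset(SimulationConfig(
    n_positive=20, n_negative=60, length_range=(50, 150),
    bias_strength=8.0, seed=7,
))
X, ids = featurize_dataset(sim.records)
X = apply_feature_scale(X, fit_feature_scale(X))
data = LabeledDataset(features=X, labels=sim.labels, ids=ids)

encoder, ae_losses = pretrain_autoencoder(
    data, AutoencoderConfig(epochs=10, seed=1)
)
print(f"autoencoder reconstruction loss: "
      f"{ae_losses[0]:.3f} -> {ae_losses[-1]:.3f} over {len(ae_losses)} epochs")

model = fine_tune(encoder, data, FineTuneConfig(epochs=200, seed=1))
print(f"fine-tuning cross-entropy: "
      f"{model.finetune_losses[0]:.3f} -> {model.finetune_losses[-1]:.3f}")

rep = extract_representation(model, X)
print(f"representation shape: {rep.shape}")

embedding = tsne_embed(rep, TSNESettings(perplexity=15, n_iter=500, seed=1),
                       ids=ids)
svm = train_svm(embedding, sim.labels)
print(f"SVM training accuracy on the 2D embedding: "
      f"{svm.training_accuracy:.3f}")
print("A high accuracy means the learned representation separates the")
print("two composition classes into distinct clusters in the t-SNE plane.")
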